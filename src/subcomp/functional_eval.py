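"""Functional characterization of a sub-compartment assignment.

Three views: (1) per-compartment enrichment of a continuous bin signal
(e.g. a histone mark), as the ratio of the compartment median to the
genome-wide median; (2) enrichment of interval annotations (enhancers,
super-enhancers) as observed-per-bin rates relative to genome-wide;
(3) co-expression structure: Spearman correlation of expression across
replicates for nearby gene pairs, averaged separately for pairs inside
one sub-compartment versus pairs straddling two, as a function of the
maximum pair distance.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import SubCompartmentAssignment
from .hic_graph import BinTable

logger = logging.getLogger(__name__)

DEFAULT_MAX_DIST = 10_000_000
DEFAULT_STEP = 100_000


@dataclass
class BinSignal:
    """Coverage-weighted mean signal per bin, with coverage fractions."""

    values: dict[int, float]
    coverage: dict[int, float]   # covered fraction of each bin


@dataclass
class ExpressionTable:
    """Genes as TSS points with per-replicate expression values."""

    gene_ids: list[str]
    chroms: np.ndarray      # str per gene
    tss: np.ndarray         # bp position of the representative 5' end
    expr: np.ndarray        # (n_genes, n_reps), nonnegative

    def __post_init__(self) -> None:
        self.tss = np.asarray(self.tss, dtype=np.int64)
        self.expr = np.asarray(self.expr, dtype=np.float64)
        if self.expr.ndim != 2 or self.expr.shape[0] != len(self.gene_ids):
            raise ValueError("expr must be (n_genes, n_reps)")
        if self.expr.shape[1] < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_reps(self) -> int:
        return self.expr.shape[1]

    def to_tsv(self, path: str) -> None:
        cols = {"gene_id": self.gene_ids, "chrom": self.chroms, "tss": self.tss}
        for r in range(self.n_reps):
            cols[f"expr_rep{r + 1}"] = self.expr[:, r]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t")
        rep_cols = [c for c in df.columns if c.startswith("expr_rep")]
        return cls(df["gene_id"].tolist(), df["chrom"].to_numpy(),
                   df["tss"].to_numpy(), df[rep_cols].to_numpy())


def read_bedgraph(path: str):
    """Yield (chrom, start, end, value) records from a bedGraph file."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns")
            yield parts[0], int(parts[1]), int(parts[2]), float(parts[3])


def aggregate_signal(bedgraph, bin_table: BinTable) -> BinSignal:
    """Coverage-weighted mean signal per bin.

    ``bedgraph`` is a path or an iterable of (chrom, start, end, value).
    Bins with no covering interval are absent from the result.
    """
    records = read_bedgraph(bedgraph) if isinstance(bedgraph, str) else bedgraph
    mass: dict[int, float] = {}
    covered: dict[int, float] = {}
    for chrom, start, end, value in records:
        if not math.isfinite(value):
            raise ValueError(f"non-finite value in interval {chrom}:{start}-{end}")
        if chrom not in bin_table.chroms or end > bin_table.chrom_size(chrom) \
                or start < 0 or end <= start:
            raise ValueError(f"interval {chrom}:{start}-{end} outside covered genome")
        first = bin_table.node_at(chrom, start)
        last = bin_table.node_at(chrom, end - 1)
        for node in range(first, last + 1):
            b = bin_table[node]
            ov = min(end, b.end) - max(start, b.start)
            mass[node] = mass.get(node, 0.0) + value * ov
            covered[node] = covered.get(node, 0.0) + ov
    values = {n: mass[n] / covered[n] for n in mass}
    frac = {n: covered[n] / (bin_table[n].end - bin_table[n].start) for n in covered}
    return BinSignal(values, frac)


def signal_enrichment(signal: BinSignal,
                      assignment: SubCompartmentAssignment
                      ) -> dict[str, float | None]:
    """Compartment median over genome-wide median of the bin signal.

    Bins without signal are excluded from both medians; a compartment
    with no covered bin is reported as None (missing), not 0.
    """
    all_vals = np.array(list(signal.values.values()))
    if all_vals.size == 0:
        raise ValueError("signal covers no bins")
    overall = float(np.median(all_vals))
    if overall == 0:
        raise ValueError("genome-wide median signal is zero")
    out: dict[str, float | None] = {}
    for lab in assignment.present_labels:
        vals = [signal.values[n] for n in assignment.members(lab)
                if n in signal.values]
        out[lab] = float(np.median(vals)) / overall if vals else None
    return out


def interval_enrichment(intervals: list[tuple[str, int, int]],
                        assignment: SubCompartmentAssignment,
                        bin_table: BinTable) -> dict[str, float | None]:
    """Per-compartment rate of interval midpoints relative to genome-wide.

    enrichment_c = (intervals with midpoint in label-c bins / bins of c)
    divided by (total intervals / total bins). Attribution by interval
    midpoint. A label with no bins is reported as None.
    """
    if not intervals:
        raise ValueError("empty interval set")
    counts: dict[str, int] = {}
    for chrom, start, end in intervals:
        mid = (start + end) // 2
        if chrom not in bin_table.chroms or not 0 <= mid < bin_table.chrom_size(chrom):
            continue
        lab = assignment.label_of(bin_table.node_at(chrom, mid))
        counts[lab] = counts.get(lab, 0) + 1
    total_rate = len(intervals) / len(bin_table)
    out: dict[str, float | None] = {}
    for lab in assignment.present_labels:
        n_bins = len(assignment.members(lab))
        out[lab] = (counts.get(lab, 0) / n_bins) / total_rate if n_bins else None
    return out


# ---------------------------------------------------------------------------
# expression correlation


def _spearman_exact_null(n: int) -> np.ndarray:
    """All Spearman rho values over the n! permutations of one ranking."""
    base = np.arange(n, dtype=float)
    rhos = []
    for perm in itertools.permutations(range(n)):
        rhos.append(float(np.corrcoef(base, np.array(perm, dtype=float))[0, 1]))
    return np.array(rhos)


_NULL_CACHE: dict[int, np.ndarray] = {}


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho and two-sided p.

    For <= 6 observations the p-value comes from the exact permutation
    distribution (few replicates make the t-approximation unusable);
    above that the usual t-approximation is used.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if np.std(x) == 0 or np.std(y) == 0:
        return math.nan, math.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 6:
        if n not in _NULL_CACHE:
            _NULL_CACHE[n] = _spearman_exact_null(n)
        null = _NULL_CACHE[n]
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def expression_correlation_profile(
        expr: ExpressionTable,
        assignment: SubCompartmentAssignment,
        bin_table: BinTable,
        max_dist: int = DEFAULT_MAX_DIST,
        step: int = DEFAULT_STEP,
        significant_only: bool = True,
        p_threshold: float = 0.05) -> pd.DataFrame:
    """Distance-resolved intra/inter co-expression comparison.

    Genes expressed in at least one replicate enter; each gene is one
    TSS. For every distance ceiling D in {step, 2*step, ..., max_dist}
    all same-chromosome pairs within D are split into intra-compartment
    (both TSS bins share a label) and inter-compartment pairs; Spearman
    rho across replicates is averaged per group (optionally only over
    pairs with p < ``p_threshold``) and the intra/inter ratio reported.
    Pairs with an NA bin are excluded. Distance bins with no qualifying
    pairs yield NaN.
    """
    min_reps = 3 if significant_only else 2
    if expr.n_reps < min_reps:
        raise ValueError(f"need >= {min_reps} replicates")
    expressed = np.any(expr.expr > 0, axis=1)
    labels = []
    for g in range(len(expr.gene_ids)):
        chrom, t = expr.chroms[g], int(expr.tss[g])
        if chrom in bin_table.chroms and 0 <= t < bin_table.chrom_size(chrom):
            labels.append(assignment.label_of(bin_table.node_at(chrom, t)))
        else:
            labels.append("NA")
    labels = np.array(labels)
    use = expressed & (labels != "NA")
    idx = np.flatnonzero(use)

    # enumerate qualifying pairs once, with distance, rho and p
    pair_dist: list[int] = []
    pair_intra: list[bool] = []
    pair_rho: list[float] = []
    pair_p: list[float] = []
    for a_pos in range(len(idx)):
        for b_pos in range(a_pos + 1, len(idx)):
            a, b = idx[a_pos], idx[b_pos]
            if expr.chroms[a] != expr.chroms[b]:
                continue
            d = abs(int(expr.tss[a]) - int(expr.tss[b]))
            if d > max_dist:
                continue
            rho, p = spearman_with_p(expr.expr[a], expr.expr[b])
            if math.isnan(rho):
                continue
            pair_dist.append(d)
            pair_intra.append(labels[a] == labels[b])
            pair_rho.append(rho)
            pair_p.append(p)
    dist_a = np.array(pair_dist)
    intra_a = np.array(pair_intra, dtype=bool)
    rho_a = np.array(pair_rho)
    p_a = np.array(pair_p)

    rows = []
    for D in range(step, max_dist + 1, step):
        within = dist_a <= D
        sig = (p_a < p_threshold) if significant_only else np.ones_like(within)
        def _mean(mask: np.ndarray) -> tuple[float, int]:
            vals = rho_a[mask]
            return (float(vals.mean()) if vals.size else math.nan, int(vals.size))
        m_intra, n_intra = _mean(within & intra_a & sig)
        m_inter, n_inter = _mean(within & ~intra_a & sig)
        u_intra, _ = _mean(within & intra_a)
        u_inter, _ = _mean(within & ~intra_a)
        ratio = m_intra / m_inter if (n_intra and n_inter and m_inter != 0) else math.nan
        rows.append({
            "max_dist": D, "n_intra": n_intra, "n_inter": n_inter,
            "mean_intra": m_intra, "mean_inter": m_inter, "ratio": ratio,
            "mean_intra_unfiltered": u_intra, "mean_inter_unfiltered": u_inter,
        })
    return pd.DataFrame(rows)
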