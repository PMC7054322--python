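"""External validation of an assignment with ChIA-PET loops.

Intra-chromosomal loops supported by at least ``min_pet`` paired-end
tags are kept; each anchor is attributed to the sub-compartment whose
bins cover strictly more than half of the anchor, else NA. Assigned
loops populate a k x k left-anchor-by-right-anchor count matrix M,
symmetrized as M_sym = M + M^T and normalized to M_norm by the sum of
all entries of M_sym. A well-resolved assignment concentrates loops on
the diagonal: the intra/inter loop ratio quantifies that, and two
assignments are compared on their intra/inter counts with Fisher's
exact test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clustering import SubCompartmentAssignment
from .hic_graph import BinTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_PET = 5


@dataclass(frozen=True)
class Loop:
    """One ChIA-PET loop: two anchor intervals plus PET read support."""

    chrom1: str
    start1: int
    end1: int
    chrom2: str
    start2: int
    end2: int
    pet_count: int

    def __post_init__(self) -> None:
        if self.start1 >= self.end1 or self.start2 >= self.end2:
            raise ValueError(f"malformed anchor interval in {self}")
        if self.pet_count < 1:
            raise ValueError("pet_count must be >= 1")


@dataclass
class LoopSet:
    loops: list[Loop]
    n_dropped_inter_chrom: int = 0
    n_dropped_low_pet: int = 0

    def __len__(self) -> int:
        return len(self.loops)

    def __iter__(self):
        return iter(self.loops)


def read_loops(bedpe_path: str, min_pet: int = DEFAULT_MIN_PET) -> LoopSet:
    """Read BEDPE, keeping intra-chromosomal loops with pet_count >= min_pet.

    The PET count is taken from the score column (column 8 of standard
    BEDPE: chrom1 start1 end1 chrom2 start2 end2 name score ...).
    """
    kept: list[Loop] = []
    n_inter = n_low = 0
    with open(bedpe_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise ValueError(f"{bedpe_path}:{lineno}: expected >= 8 BEDPE columns")
            c1, s1, e1, c2, s2, e2 = parts[0], int(parts[1]), int(parts[2]), \
                parts[3], int(parts[4]), int(parts[5])
            pet = int(float(parts[7]))
            if pet < 0:
                raise ValueError(f"{bedpe_path}:{lineno}: negative PET count")
            if c1 != c2:
                n_inter += 1
                continue
            if pet < min_pet:
                n_low += 1
                continue
            kept.append(Loop(c1, s1, e1, c2, s2, e2, pet))
    if n_inter or n_low:
        logger.info("dropped %d inter-chromosomal and %d low-support loops",
                    n_inter, n_low)
    return LoopSet(kept, n_inter, n_low)


def assign_anchor(anchor: tuple[str, int, int],
                  assignment: SubCompartmentAssignment,
                  bin_table: BinTable) -> str:
    """Label covering > 50% of the anchor, else NA.

    Overlap is measured in base pairs against the union of all bins of
    each label, so anchors spanning bin boundaries are handled.
    """
    chrom, start, end = anchor
    if end <= start:
        raise ValueError("malformed anchor interval")
    length = end - start
    if chrom not in bin_table.chroms or start < 0 \
            or start >= bin_table.chrom_size(chrom):
        logger.warning("anchor %s:%d-%d outside covered genome", chrom, start, end)
        return "NA"
    overlap: dict[str, int] = {}
    first = bin_table.node_at(chrom, start)
    last = bin_table.node_at(chrom, min(end - 1, bin_table.chrom_size(chrom) - 1))
    for node in range(first, last + 1):
        b = bin_table[node]
        ov = min(end, b.end) - max(start, b.start)
        if ov > 0:
            lab = assignment.label_of(node)
            overlap[lab] = overlap.get(lab, 0) + ov
    for lab, bp in overlap.items():
        if lab != "NA" and bp * 2 > length:  # strict > 0.5
            return lab
    return "NA"


@dataclass
class LoopCompartmentMatrix:
    """k x k loop counts between sub-compartments."""

    labels: list[str]
    M: np.ndarray
    n_excluded_na: int = 0

    @property
    def M_sym(self) -> np.ndarray:
        return self.M + self.M.T

    @property
    def M_norm(self) -> np.ndarray:
        total = self.M_sym.sum()
        return self.M_sym / total


def _assigned_pairs(loops: LoopSet | list[Loop],
                    assignment: SubCompartmentAssignment,
                    bin_table: BinTable) -> tuple[list[tuple[str, str]], int]:
    pairs: list[tuple[str, str]] = []
    n_na = 0
    for lp in loops:
        la = assign_anchor((lp.chrom1, lp.start1, lp.end1), assignment, bin_table)
        lb = assign_anchor((lp.chrom2, lp.start2, lp.end2), assignment, bin_table)
        if la == "NA" or lb == "NA":
            n_na += 1
            continue
        pairs.append((la, lb))
    return pairs, n_na


def loop_matrix(loops: LoopSet | list[Loop],
                assignment: SubCompartmentAssignment,
                bin_table: BinTable) -> LoopCompartmentMatrix:
    """Count loops by (left-anchor label, right-anchor label).

    Loops with any NA anchor are excluded and counted.
    """
    pairs, n_na = _assigned_pairs(loops, assignment, bin_table)
    if not pairs:
        raise ValueError("no loop has both anchors assigned")
    labels = assignment.present_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for la, lb in pairs:
        M[idx[la], idx[lb]] += 1
    return LoopCompartmentMatrix(labels, M, n_excluded_na=n_na)


def intra_inter_ratio(loops: LoopSet | list[Loop],
                      assignment: SubCompartmentAssignment,
                      bin_table: BinTable) -> tuple[int, int, float]:
    """Counts of intra- and inter-sub-compartment loops and their ratio.

    With no inter-compartment loop the ratio is reported as +inf.
    """
    pairs, _ = _assigned_pairs(loops, assignment, bin_table)
    if not pairs:
        raise ValueError("no loop has both anchors assigned")
    n_intra = sum(1 for a, b in pairs if a == b)
    n_inter = len(pairs) - n_intra
    if n_inter == 0:
        logger.warning("no inter-sub-compartment loops; ratio is infinite")
        return n_intra, 0, math.inf
    return n_intra, n_inter, n_intra / n_inter


def fisher_compare(n_intra_a: int, n_inter_a: int,
                   n_intra_b: int, n_inter_b: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the 2x2 intra/inter loop table."""
    table = np.array([[n_intra_a, n_inter_a], [n_intra_b, n_inter_b]])
    if np.any(table < 0):
        raise ValueError("counts must be nonnegative")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        raise ValueError("degenerate table: an all-zero margin")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)
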