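"""Synthetic inputs with planted sub-compartment structure.

The generators emulate the statistical signal the pipeline exploits:
bins carry latent compartment labels drawn independently across
chromosomes (so every compartment spans multiple chromosomes, as real
sub-compartments do), inter-chromosomal contact weights are Poisson
with a higher rate within a compartment than between (a planted
partition), loops prefer intra-compartment anchor pairs, bin signals
shift by compartment, and expression shares a per-replicate latent
factor within a compartment. Every generator is a pure function of its
config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chiapet_eval import Loop
from .functional_eval import ExpressionTable
from .hic_graph import BinTable, ContactGraph, make_bin_table


@dataclass
class SimConfig:
    """Study conditions for the planted-partition simulation."""

    n_chroms: int = 6
    bins_per_chrom: int = 40
    resolution: int = 100_000
    K: int = 5
    proportions: tuple[float, ...] | None = None  # uniform when None
    mu_in: float = 20.0        # mean contact weight within a compartment
    mu_out: float = 2.0        # mean contact weight between compartments
    overdispersion: float | None = None  # NB size parameter; None = Poisson
    n_loops: int = 2000
    p_intra: float = 0.8
    anchor_width: int = 10_000
    pet_geom_p: float = 0.2    # shifted geometric; mean PET = 1/p
    signal_effects: tuple[float, ...] | None = None
    signal_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mu_in > self.mu_out >= 0:
            raise ValueError("need mu_in > mu_out >= 0")
        if not 0.0 <= self.p_intra <= 1.0:
            raise ValueError("p_intra must be in [0, 1]")
        if self.proportions is not None:
            if len(self.proportions) != self.K:
                raise ValueError("need one proportion per compartment")
            if abs(sum(self.proportions) - 1.0) > 1e-9:
                raise ValueError("proportions must sum to 1")
        if self.K > self.n_chroms * self.bins_per_chrom:
            raise ValueError("more compartments than bins")

    @property
    def props(self) -> np.ndarray:
        if self.proportions is None:
            return np.full(self.K, 1.0 / self.K)
        return np.asarray(self.proportions)


def _truth_labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_chroms * config.bins_per_chrom
    return rng.choice(config.K, size=n, p=config.props)


def simulate_hic(config: SimConfig) -> tuple[BinTable, ContactGraph, np.ndarray]:
    """Planted-partition inter-chromosomal contact graph.

    Every inter-chromosomal bin pair draws a Poisson weight with rate
    mu_in if the latent labels match, mu_out otherwise (Negative
    Binomial with the configured size when ``overdispersion`` is set);
    zero draws are omitted. Returns the bin table, the graph, and the
    integer truth labels for scoring.
    """
    rng = np.random.default_rng(config.seed)
    sizes = {f"chr{c + 1}": config.bins_per_chrom * config.resolution
             for c in range(config.n_chroms)}
    bins = make_bin_table(sizes, config.resolution)
    labels = _truth_labels(config, rng)

    ci = bins.chrom_index
    n = len(bins)
    iu, ju = np.triu_indices(n, k=1)
    inter = ci[iu] != ci[ju]
    iu, ju = iu[inter], ju[inter]
    mu = np.where(labels[iu] == labels[ju], config.mu_in, config.mu_out)
    if config.overdispersion is None:
        w = rng.poisson(mu)
    else:
        size = config.overdispersion
        w = rng.negative_binomial(size, size / (size + mu))
    nz = w > 0
    graph = ContactGraph(bins, iu[nz], ju[nz], w[nz].astype(float))
    return bins, graph, labels


def truth_assignment(labels: np.ndarray) -> dict[int, str]:
    """Integer truth labels as a C1..CK bin->label map."""
    return {i: f"C{int(lab) + 1}" for i, lab in enumerate(labels)}


def simulate_loops(true_labels: np.ndarray, bin_table: BinTable,
                   config: SimConfig, seed: int | None = None) -> list[Loop]:
    """Loops biased toward intra-compartment anchors.

    With probability p_intra both anchors land in same-label bins of
    one chromosome, otherwise in different-label bins of one
    chromosome. Anchors are anchor_width intervals centered in their
    bin; PET counts are shifted geometric (>= 1). All loops are
    intra-chromosomal by construction.
    """
    if len(set(true_labels.tolist())) < 2:
        raise ValueError("need at least 2 labels present")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = np.asarray(true_labels)
    ci = bin_table.chrom_index
    loops: list[Loop] = []
    for _ in range(config.n_loops):
        intra = rng.random() < config.p_intra
        for _attempt in range(1000):
            b1 = int(rng.integers(0, len(bin_table)))
            same_chrom = np.flatnonzero(ci == ci[b1])
            pool = same_chrom[(labels[same_chrom] == labels[b1]) == intra]
            pool = pool[pool != b1]
            if pool.size:
                b2 = int(rng.choice(pool))
                break
        else:
            raise ValueError("no same-chromosome bin pair available for a "
                             f"{'intra' if intra else 'inter'}-compartment loop")
        if bin_table[b2].start < bin_table[b1].start:
            b1, b2 = b2, b1
        a1, a2 = bin_table[b1], bin_table[b2]
        half = config.anchor_width // 2
        m1 = (a1.start + a1.end) // 2
        m2 = (a2.start + a2.end) // 2
        pet = int(rng.geometric(config.pet_geom_p))
        loops.append(Loop(a1.chrom, max(0, m1 - half), m1 + half,
                          a2.chrom, max(0, m2 - half), m2 + half, pet))
    return loops


def write_loops(loops: list[Loop], path: str) -> None:
    """Write loops as standard BEDPE with the PET count in the score column."""
    with open(path, "w") as fh:
        for n, lp in enumerate(loops):
            fh.write(f"{lp.chrom1}\t{lp.start1}\t{lp.end1}\t"
                     f"{lp.chrom2}\t{lp.start2}\t{lp.end2}\t"
                     f"loop{n}\t{lp.pet_count}\t.\t.\n")


def simulate_signal(true_labels: np.ndarray, bin_table: BinTable,
                    effects: np.ndarray | None = None,
                    noise_sd: float = 0.5, seed: int = 0
                    ) -> list[tuple[str, int, int, float]]:
    """Per-bin signal = effect[label] + Gaussian noise, clipped at 0.

    Returns bedGraph records, one interval per bin.
    """
    if noise_sd < 0:
        raise ValueError("negative noise_sd")
    labels = np.asarray(true_labels)
    k = int(labels.max()) + 1
    if effects is None:
        effects = np.arange(k, 0, -1, dtype=float)  # open compartments high
    effects = np.asarray(effects, dtype=float)
    if len(effects) < k:
        raise ValueError("need one effect per label")
    rng = np.random.default_rng(seed)
    vals = np.clip(effects[labels] + rng.normal(0, noise_sd, size=len(labels)), 0, None)
    return [(b.chrom, b.start, b.end, float(vals[b.node_id])) for b in bin_table]


def write_bedgraph(records: list[tuple[str, int, int, float]], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


def simulate_expression(true_labels: np.ndarray, bin_table: BinTable,
                        n_genes: int = 300, n_reps: int = 6,
                        shared_factor_sd: float = 1.0, noise_sd: float = 0.5,
                        global_factor_sd: float = 1.0,
                        seed: int = 0) -> ExpressionTable:
    """Expression with a per-replicate latent factor shared within a compartment.

    Genes are placed uniformly over bins; each value is
    baseline_gene + global[replicate] + factor[label, replicate] + noise,
    clipped at 0. The global factor plays the role of a library-size
    effect common to all genes; the compartment factor makes genes of
    the same compartment co-vary beyond it. With shared_factor_sd = 0
    intra- and inter-compartment pairs correlate equally (through the
    global factor only), so their mean-correlation ratio is ~1.
    """
    if n_reps < 3:
        raise ValueError("need n_reps >= 3")
    rng = np.random.default_rng(seed)
    labels = np.asarray(true_labels)
    k = int(labels.max()) + 1
    gene_bins = rng.integers(0, len(bin_table), size=n_genes)
    chroms = np.array([bin_table[int(b)].chrom for b in gene_bins])
    tss = np.array([
        int(rng.integers(bin_table[int(b)].start, bin_table[int(b)].end))
        for b in gene_bins
    ])
    baseline = rng.uniform(2.0, 8.0, size=n_genes)
    glob = rng.normal(0.0, global_factor_sd, size=n_reps)
    factors = rng.normal(0.0, shared_factor_sd, size=(k, n_reps))
    noise = rng.normal(0.0, noise_sd, size=(n_genes, n_reps))
    expr = np.clip(
        baseline[:, None] + glob[None, :] + factors[labels[gene_bins]] + noise,
        0, None)
    ids = [f"gene{i}" for i in range(n_genes)]
    return ExpressionTable(ids, chroms, tss, expr)
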