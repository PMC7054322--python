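"""Genomic bins, the inter-chromosomal contact graph, and text-format I/O.

Coordinates are 0-based half-open (BED convention) throughout. The
contact graph stores each undirected edge once with ``i < j``; every
edge joins bins on different chromosomes, since intra-chromosomal
contacts carry no information for the embedding objective used here and
are dropped (and counted) at parse time. Upstream matrix normalization
(KR/ICE) is assumed already applied: weights are taken as-is and never
rebalanced.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from . import __version__

logger = logging.getLogger(__name__)

LABEL_RE = re.compile(r"^(C[0-9]+|NA)$")

DEFAULT_RESOLUTION = 100_000


@dataclass(frozen=True)
class GenomicBin:
    """A fixed-resolution genome tile indexing one graph node."""

    chrom: str
    start: int
    end: int
    node_id: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"bin end must exceed start: {self}")


class BinTable:
    """Ordered, fixed-resolution partition of the genome.

    Bins are tiled chromosome by chromosome in file order; node ids are
    dense integers from 0. The last bin of a chromosome may be shorter
    than the resolution.
    """

    def __init__(self, bins: list[GenomicBin], resolution: int):
        if resolution <= 0:
            raise ValueError("resolution must be positive")
        self.bins = bins
        self.resolution = resolution
        self._chrom_offsets: dict[str, int] = {}
        self._chrom_sizes: dict[str, int] = {}
        for b in bins:
            if b.chrom not in self._chrom_offsets:
                self._chrom_offsets[b.chrom] = b.node_id
                self._chrom_sizes[b.chrom] = b.end
            else:
                self._chrom_sizes[b.chrom] = max(self._chrom_sizes[b.chrom], b.end)
        # chromosome index per node, used for the inter-chromosomal check
        chrom_order = {c: i for i, c in enumerate(self._chrom_offsets)}
        self.chrom_index = np.array([chrom_order[b.chrom] for b in bins], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self) -> Iterator[GenomicBin]:
        return iter(self.bins)

    def __getitem__(self, node_id: int) -> GenomicBin:
        return self.bins[node_id]

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_offsets)

    def chrom_size(self, chrom: str) -> int:
        return self._chrom_sizes[chrom]

    def node_at(self, chrom: str, pos: int) -> int:
        """Node id of the bin covering ``chrom:pos``."""
        if chrom not in self._chrom_offsets:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self._chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (size {self._chrom_sizes[chrom]})")
        return self._chrom_offsets[chrom] + pos // self.resolution

    def same_chrom(self, i: int, j: int) -> bool:
        return self.chrom_index[i] == self.chrom_index[j]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BinTable)
            and self.resolution == other.resolution
            and self.bins == other.bins
        )


def load_bin_table(chrom_sizes_path: str, resolution: int = DEFAULT_RESOLUTION) -> BinTable:
    """Tile each chromosome of a UCSC chrom.sizes file into bins.

    Each chromosome of length L contributes ceil(L/resolution) bins;
    node ids follow file order, then position order within a chromosome.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bins: list[GenomicBin] = []
    seen: set[str] = set()
    node_id = 0
    with open(chrom_sizes_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{chrom_sizes_path}:{lineno}: expected 'name<TAB>length'")
            chrom, length_s = parts
            if chrom in seen:
                raise ValueError(f"duplicate chromosome {chrom!r}")
            seen.add(chrom)
            length = int(length_s)
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {chrom!r}")
            for start in range(0, length, resolution):
                bins.append(GenomicBin(chrom, start, min(start + resolution, length), node_id))
                node_id += 1
    return BinTable(bins, resolution)


def make_bin_table(chrom_sizes: Mapping[str, int], resolution: int) -> BinTable:
    """In-memory counterpart of :func:`load_bin_table`."""
    bins: list[GenomicBin] = []
    node_id = 0
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"non-positive length for chromosome {chrom!r}")
        for start in range(0, length, resolution):
            bins.append(GenomicBin(chrom, start, min(start + resolution, length), node_id))
            node_id += 1
    return BinTable(bins, resolution)


class ContactGraph:
    """Weighted undirected inter-chromosomal interaction graph.

    Edges are stored once with ``i < j`` and strictly positive weights.
    ``W`` is the total edge weight and ``degree[i]`` the sum of weights
    incident to node i (the out-degree d_i of the second-order
    objective's empirical distribution).
    """

    def __init__(self, bins: BinTable, edge_i: np.ndarray, edge_j: np.ndarray,
                 edge_w: np.ndarray, dropped_intra: int = 0, dropped_nonpos: int = 0):
        self.bins = bins
        self.edge_i = np.asarray(edge_i, dtype=np.int64)
        self.edge_j = np.asarray(edge_j, dtype=np.int64)
        self.edge_w = np.asarray(edge_w, dtype=np.float64)
        self.dropped_intra = dropped_intra
        self.dropped_nonpos = dropped_nonpos
        self._validate()
        self.W = float(self.edge_w.sum())
        self.degree = np.zeros(len(bins), dtype=np.float64)
        np.add.at(self.degree, self.edge_i, self.edge_w)
        np.add.at(self.degree, self.edge_j, self.edge_w)

    def _validate(self) -> None:
        if len({len(self.edge_i), len(self.edge_j), len(self.edge_w)}) != 1:
            raise ValueError("edge arrays must have equal length")
        if np.any(self.edge_i >= self.edge_j):
            raise ValueError("edges must be stored with i < j")
        if np.any(self.edge_w <= 0) or not np.all(np.isfinite(self.edge_w)):
            raise ValueError("edge weights must be positive and finite")
        ci = self.bins.chrom_index
        if len(self.edge_i) and np.any(ci[self.edge_i] == ci[self.edge_j]):
            raise ValueError("intra-chromosomal edge in ContactGraph")

    @property
    def n_nodes(self) -> int:
        return len(self.bins)

    @property
    def n_edges(self) -> int:
        return len(self.edge_w)

    def edges(self) -> Iterator[tuple[int, int, float]]:
        yield from zip(self.edge_i.tolist(), self.edge_j.tolist(), self.edge_w.tolist())

    @classmethod
    def from_records(cls, bins: BinTable,
                     records: Iterable[tuple[int, int, float]]) -> "ContactGraph":
        """Build a graph from (i, j, w) node-id records.

        Intra-chromosomal records are dropped (counted), duplicate
        (i,j)/(j,i) records summed, and non-positive or non-finite
        weights dropped with a warning count.
        """
        acc: dict[tuple[int, int], float] = {}
        n_intra = n_nonpos = 0
        n = len(bins)
        for i, j, w in records:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"node id out of range: ({i},{j}) with {n} bins")
            if not math.isfinite(w) or w <= 0:
                n_nonpos += 1
                continue
            if bins.same_chrom(i, j):
                n_intra += 1
                continue
            key = (i, j) if i < j else (j, i)
            acc[key] = acc.get(key, 0.0) + w
        if n_intra:
            logger.info("dropped %d intra-chromosomal contact records", n_intra)
        if n_nonpos:
            logger.warning("dropped %d zero/negative/non-finite weights", n_nonpos)
        if acc:
            keys = sorted(acc)
            ei = np.array([k[0] for k in keys], dtype=np.int64)
            ej = np.array([k[1] for k in keys], dtype=np.int64)
            ew = np.array([acc[k] for k in keys], dtype=np.float64)
        else:
            ei = ej = np.empty(0, dtype=np.int64)
            ew = np.empty(0, dtype=np.float64)
        return cls(bins, ei, ej, ew, dropped_intra=n_intra, dropped_nonpos=n_nonpos)


def _parse_triplet_line(line: str, lineno: int, bins: BinTable) -> tuple[int, int, float]:
    parts = line.split("\t")
    if len(parts) == 3:
        return int(parts[0]), int(parts[1]), float(parts[2])
    if len(parts) == 5:
        c1, s1, c2, s2, w = parts
        res = bins.resolution
        for chrom, start in ((c1, int(s1)), (c2, int(s2))):
            if int(start) % res != 0:
                raise ValueError(
                    f"line {lineno}: start {start} is not a multiple of resolution {res}")
        return bins.node_at(c1, int(s1)), bins.node_at(c2, int(s2)), float(w)
    raise ValueError(f"line {lineno}: expected 3 or 5 tab-separated fields")


def load_contacts(triplet_path: str, bin_table: BinTable) -> ContactGraph:
    """Read sparse contact triplets (node-id or coordinate dialect)."""

    def records() -> Iterator[tuple[int, int, float]]:
        with open(triplet_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                yield _parse_triplet_line(line, lineno, bin_table)

    return ContactGraph.from_records(bin_table, records())


def write_contacts(graph: ContactGraph, path: str) -> None:
    """Write the edge list in the node-id triplet dialect."""
    with open(path, "w") as fh:
        fh.write(f"# subcomp v{__version__} resolution={graph.bins.resolution}\n")
        for i, j, w in graph.edges():
            fh.write(f"{i}\t{j}\t{w!r}\n")


def connected_nodes(graph: ContactGraph) -> set[int]:
    """Nodes with at least one inter-chromosomal contact.

    The complement cannot be embedded and is later labeled NA.
    """
    return set(np.flatnonzero(graph.degree > 0).tolist())


def write_assignments(labels: Mapping[int, str], bin_table: BinTable, path: str) -> None:
    """Write a bin -> label map as BED4 (chrom, start, end, label)."""
    with open(path, "w") as fh:
        fh.write(f"# subcomp v{__version__} resolution={bin_table.resolution}\n")
        for node_id in sorted(labels):
            label = labels[node_id]
            if not LABEL_RE.match(label):
                raise ValueError(f"invalid label {label!r} (expected C<k> or NA)")
            b = bin_table[node_id]
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\t{label}\n")


def read_assignments(path: str, bin_table: BinTable) -> dict[int, str]:
    """Read a BED4 assignment file written by :func:`write_assignments`."""
    labels: dict[int, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected BED4")
            chrom, start, _end, label = parts[:4]
            if not LABEL_RE.match(label):
                raise ValueError(f"{path}:{lineno}: invalid label {label!r}")
            labels[bin_table.node_at(chrom, int(start))] = label
    return labels
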