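"""Homology graph, single-linkage clusters and leakage-free cross-validation folds.

Proteins are vertices; an edge records pairwise similarity evidence below an
E-value threshold (either search direction suffices).  Single-linkage
clusters are the connected components, so no two proteins in different
clusters share an edge.  Whole clusters — never individual proteins — are
packed onto ten folds, which guarantees that train, cross-train and test
sets of any rotation are never significantly sequence similar.

The pairwise scorer is pluggable.  The built-in scorer computes global
alignment percent identity (Needleman–Wunsch via Biopython) and converts it
into a pseudo-E-value: a strong hit (identity >= 30% over >= 50 aligned
columns) maps below any sensible threshold, everything else above.  Tabular
output of an external all-vs-all search can be loaded instead with
:func:`load_edge_list`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align

from .io import NEUTRAL, ProteinRecord, VariantRecord

logger = logging.getLogger(__name__)


class PercentIdentityScorer:
    """Pseudo-E-value scorer from global-alignment percent identity.

    Returns a value far below any E-value threshold for pairs with
    identity >= ``min_identity`` percent over >= ``min_aligned`` aligned
    columns, and a large value otherwise.
    """

    HIT = 1e-10
    MISS = 10.0

    def __init__(self, min_identity: float = 30.0, min_aligned: int = 50):
        self.min_identity = min_identity
        self.min_aligned = min_aligned
        self._aligner = Align.PairwiseAligner()
        self._aligner.mode = "global"
        self._aligner.match_score = 1.0
        self._aligner.mismatch_score = -1.0
        self._aligner.open_gap_score = -2.0
        self._aligner.extend_gap_score = -0.5
        self._cache: dict[tuple[str, str], float] = {}

    def identity(self, a: ProteinRecord, b: ProteinRecord) -> tuple[float, int]:
        """Percent identity and number of aligned columns of the best alignment."""
        aln = self._aligner.align(a.sequence, b.sequence)[0]
        sa, sb = aln[0], aln[1]
        ncols = len(sa)
        matches = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
        return 100.0 * matches / ncols, ncols

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> float:
        key = (a.id, b.id) if a.id <= b.id else (b.id, a.id)
        if key not in self._cache:
            ident, ncols = self.identity(a, b)
            hit = ident >= self.min_identity and ncols >= self.min_aligned
            self._cache[key] = self.HIT if hit else self.MISS
        return self._cache[key]


def build_homology_graph(
    proteins: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    scorer: Callable[[ProteinRecord, ProteinRecord], float] | None = None,
    e_threshold: float = 1e-3,
) -> nx.Graph:
    """Undirected graph with an edge wherever either-direction E-value < threshold."""
    if e_threshold <= 0:
        raise ValueError("e_threshold must be > 0")
    if isinstance(proteins, Mapping):
        records = list(proteins.values())
    else:
        records = list(proteins)
    if scorer is None:
        scorer = PercentIdentityScorer()
    graph = nx.Graph()
    graph.add_nodes_from(p.id for p in records)
    for i, a in enumerate(records):
        for b in records[i + 1:]:
            try:
                e_ab = scorer(a, b)
                e_ba = scorer(b, a)
            except Exception:  # noqa: BLE001 — missing evidence, not fatal
                logger.warning("scorer failed on pair (%s, %s); no edge", a.id, b.id)
                continue
            if min(e_ab, e_ba) < e_threshold:
                graph.add_edge(a.id, b.id, evalue=min(e_ab, e_ba))
    return graph


def load_edge_list(path, e_threshold: float = 1e-3,
                   vertices: Iterable[str] | None = None) -> nx.Graph:
    """Build the homology graph from a precomputed TSV (id_a, id_b, evalue)."""
    df = pd.read_csv(path, sep="\t", dtype={"id_a": str, "id_b": str})
    graph = nx.Graph()
    if vertices is not None:
        graph.add_nodes_from(vertices)
    for row in df.itertuples(index=False):
        graph.add_node(row.id_a)
        graph.add_node(row.id_b)
        if row.id_a != row.id_b and float(row.evalue) < e_threshold:
            graph.add_edge(row.id_a, row.id_b, evalue=float(row.evalue))
    return graph


def single_linkage_clusters(graph: nx.Graph) -> dict[str, int]:
    """Cluster ids by connected component; ids are stable (sorted by smallest member)."""
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    partition = {}
    for cid, members in enumerate(components):
        for pid in members:
            partition[pid] = cid
    return partition


@dataclass(frozen=True)
class FoldAssignment:
    """Mapping of clusters (and therefore proteins) onto k cross-validation folds."""

    cluster_to_fold: dict[int, int]
    protein_to_fold: dict[str, int]
    k: int

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.k
        for fold in self.protein_to_fold.values():
            sizes[fold] += 1
        return sizes

    def imbalance(self) -> float:
        """Max fold size over mean fold size."""
        sizes = self.fold_sizes()
        return max(sizes) / (sum(sizes) / self.k)


def assign_folds(partition: Mapping[str, int], k: int = 10, seed: int = 0,
                 allow_empty: bool = False) -> FoldAssignment:
    """Greedy largest-first packing of clusters onto the currently smallest fold.

    Ties in cluster size are broken in seeded random order; the assignment is
    deterministic given the seed.  Whole clusters stay intact, so fold sizes
    are only roughly similar when one cluster dominates.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    clusters: dict[int, list[str]] = {}
    for pid, cid in partition.items():
        clusters.setdefault(cid, []).append(pid)
    if len(clusters) < k and not allow_empty:
        raise ValueError(
            f"only {len(clusters)} clusters for {k} folds; pass allow_empty=True "
            "to accept empty folds"
        )
    rng = np.random.default_rng(seed)
    order = sorted(
        clusters, key=lambda cid: (-len(clusters[cid]), rng.random(), cid)
    )
    fold_counts = [0] * k
    cluster_to_fold = {}
    for cid in order:
        fold = int(np.argmin(fold_counts))
        cluster_to_fold[cid] = fold
        fold_counts[fold] += len(clusters[cid])
    protein_to_fold = {pid: cluster_to_fold[cid] for pid, cid in partition.items()}
    return FoldAssignment(cluster_to_fold, protein_to_fold, k)


@dataclass(frozen=True)
class Rotation:
    """One cross-validation rotation: 8 train folds, 1 cross-train, 1 test."""

    train_folds: tuple[int, ...]
    crosstrain_fold: int
    test_fold: int


def crossval_splits(folds: FoldAssignment) -> list[Rotation]:
    """Ten rotations; test fold t, cross-train fold (t+1) mod k, rest train."""
    k = folds.k
    rotations = []
    for t in range(k):
        ct = (t + 1) % k
        train = tuple(f for f in range(k) if f not in (t, ct))
        rotations.append(Rotation(train, ct, t))
    return rotations


def export_folds(folds: FoldAssignment, path) -> None:
    rows = [{"protein_id": pid, "fold": f}
            for pid, f in sorted(folds.protein_to_fold.items())]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_folds(path) -> FoldAssignment:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "fold": int})
    protein_to_fold = dict(zip(df["protein_id"], df["fold"]))
    k = max(protein_to_fold.values()) + 1
    # treat each protein as its own cluster on reload; fold structure is preserved
    cluster_to_fold = {i: f for i, f in enumerate(protein_to_fold.values())}
    return FoldAssignment(cluster_to_fold, protein_to_fold, k)


def hssp_identity_threshold(aligned_length: int) -> float:
    """Length-dependent identity threshold separating homologs from chance.

    480 * L^-0.32 for alignments up to 450 columns, 19.5% beyond; pairwise
    identity minus this curve is the HSSP-value (positive = homologous).
    """
    if aligned_length < 1:
        raise ValueError("aligned_length must be >= 1")
    if aligned_length > 450:
        return 19.5
    return 480.0 * aligned_length ** -0.32


@dataclass(frozen=True)
class EnzymePair:
    """Two enzymes sharing an experimentally assigned EC number."""

    id_a: str
    id_b: str
    ec_number: str
    identity: float
    aligned_length: int

    def __post_init__(self):
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")


def mine_ec_neutral_variants(
    pairs: Iterable[EnzymePair],
    alignments: Mapping[tuple[str, str], tuple[str, str]],
    hssp_curve: Callable[[int], float] = hssp_identity_threshold,
) -> list[VariantRecord]:
    """Infer neutral variants from aligned mismatches of same-function enzyme pairs.

    A pair contributes only when identity > 40% and its HSSP-value
    (identity minus ``hssp_curve(aligned length)``) is positive.  Every
    aligned non-gap mismatch column yields one neutral variant on the first
    protein of the pair (wt = residue of protein 1, var = residue of
    protein 2).  Pairs without an alignment are skipped with a warning.
    """
    variants = []
    for pair in pairs:
        aln = alignments.get((pair.id_a, pair.id_b))
        if aln is None:
            logger.warning("no alignment for pair (%s, %s); skipped", pair.id_a, pair.id_b)
            continue
        if pair.identity <= 40.0:
            continue
        if pair.identity - hssp_curve(pair.aligned_length) <= 0:
            continue
        seq_a, seq_b = aln
        if len(seq_a) != len(seq_b):
            raise ValueError(f"alignment rows differ in length for ({pair.id_a}, {pair.id_b})")
        pos_a = 0
        for col_a, col_b in zip(seq_a, seq_b):
            if col_a != "-":
                pos_a += 1
            if col_a == "-" or col_b == "-":
                continue
            if col_a != col_b:
                variants.append(
                    VariantRecord(pair.id_a, pos_a, col_a, col_b,
                                  label=NEUTRAL, source=f"EC:{pair.ec_number}")
                )
    return variants
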