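"""Query-interpretation strategies against a local reference library.

Four complementary readings of "what does this barcode match":

* closest-match search — all-pairs overlap-alignment identity, ranked
  (:func:`search_library`, :func:`top_band`);
* user-specified divergence threshold per taxon group
  (:func:`threshold_call`);
* BIN-style clustering — single-linkage at a divergence threshold, a
  documented proxy for BOLD's RESL refinement (:func:`bin_cluster`);
* phylogenetic placement — Kimura two-parameter distances, neighbor
  joining, and inspection of the query's attachment neighborhood
  (:func:`phylo_place`).

Identity is raw (uncorrected) fraction of matching columns over an overlap
alignment with end gaps excluded; K2P correction is used only for tree
building. Libraries here are desk-scale snapshots, so exhaustive scoring
replaces heuristic seeding.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as _skbio_nj

from ._align import identity_overlap
from .iupac import CODE_TO_BASES

#: distance reported for saturated K2P pairs (log argument <= 0)
K2P_SATURATION_CAP = 5.0

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


class SaturationWarning(UserWarning):
    """K2P distance is saturated and has been capped."""


class PlacementFailure(Exception):
    """All pairwise distances saturated; no meaningful tree."""


@dataclass(frozen=True)
class Hit:
    record_id: str
    species: str
    genus: str
    identity: float
    overlap: int
    locus: str


@dataclass(frozen=True)
class HitTable:
    """Ranked library matches for one query, best identity first."""

    query_id: str
    locus: str
    hits: tuple[Hit, ...]

    def __post_init__(self) -> None:
        ids = [h.record_id for h in self.hits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record_id in hit table")
        key = [(-h.identity, h.record_id) for h in self.hits]
        if key != sorted(key):
            raise ValueError("hits not sorted by identity desc, record_id asc")

    @property
    def best_identity(self) -> float | None:
        return self.hits[0].identity if self.hits else None

    def __len__(self) -> int:
        return len(self.hits)


@dataclass(frozen=True)
class BinAssignment:
    """Single-linkage partition of references plus the query."""

    clusters: dict[str, int]  # record_id (or query id) -> cluster index
    query_cluster: int | None
    threshold: float


@dataclass(frozen=True)
class PlacementResult:
    tree: TreeNode = field(repr=False)
    sister_taxa: frozenset[str]
    level: str  # 'species' | 'genus' | 'none'


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """(identity, overlap) under overlap alignment with free end gaps.

    A column counts as a match when the two IUPAC base sets intersect, so an
    'R' in a consensus matches an 'A' in a reference. Internal gaps count as
    mismatched columns; end gaps are excluded entirely.
    """
    return identity_overlap(a, b)


def search_library(
    query_id: str,
    query_seq: str,
    library,
    locus: str,
    cfg,
) -> HitTable:
    """Score the query against every library record for the locus.

    Hits with identity below ``cfg.near_match_floor`` or overlap below
    ``cfg.min_overlap_fraction`` x query length are dropped. A locus absent
    from the library gives an empty table, not an error.
    """
    hits = []
    min_overlap = cfg.min_overlap_fraction * len(query_seq)
    for rec in library.by_locus(locus):
        ident, overlap = pairwise_identity(query_seq, rec.sequence)
        if ident >= cfg.near_match_floor and overlap >= min_overlap:
            hits.append(
                Hit(
                    record_id=rec.record_id,
                    species=rec.species,
                    genus=rec.genus,
                    identity=ident,
                    overlap=overlap,
                    locus=locus,
                )
            )
    hits.sort(key=lambda h: (-h.identity, h.record_id))
    return HitTable(query_id=query_id, locus=locus, hits=tuple(hits))


def top_band(ht: HitTable, cfg) -> frozenset[str]:
    """Species whose best hit lies within ``top_band_width`` of the top hit.

    This is the 'closest matches in the results table' set: equal-best ties
    (e.g. two congeners at the same identity) all enter the band.
    """
    if not ht.hits:
        return frozenset()
    floor = ht.best_identity - cfg.top_band_width
    return frozenset(h.species for h in ht.hits if h.identity >= floor)


def threshold_call(ht: HitTable, expected_species: str, species_threshold: float) -> str:
    """'within' / 'outside' / 'absent' for the expected species.

    within: some hit to the expected species has divergence (1 - identity)
    <= threshold (inclusive); outside: expected present only above the
    threshold; absent: no hit to the expected species at all.
    """
    divs = [1.0 - h.identity for h in ht.hits if h.species == expected_species]
    if not divs:
        return "absent"
    # inclusive boundary, robust to float noise in 1 - identity
    return "within" if min(divs) <= species_threshold + 1e-9 else "outside"


def bin_cluster(records, query_id: str, query_seq: str, threshold: float) -> BinAssignment:
    """Single-linkage clustering of references plus query at a divergence cut.

    Two sequences link when 1 - identity <= threshold; clusters are the
    connected components (so chains merge, as in single linkage). This is a
    deliberate, documented proxy for the RESL algorithm behind BOLD BINs.
    """
    items = [(r.record_id, r.sequence) for r in records] + [(query_id, query_seq)]
    n = len(items)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident, _ = pairwise_identity(items[i][1], items[j][1])
            if 1.0 - ident <= threshold:
                parent[find(i)] = find(j)

    # canonical cluster ids: order of first appearance over sorted item ids
    order = sorted(range(n), key=lambda k: items[k][0])
    root_to_cluster: dict[int, int] = {}
    clusters: dict[str, int] = {}
    for k in order:
        root = find(k)
        if root not in root_to_cluster:
            root_to_cluster[root] = len(root_to_cluster)
    for k in range(n):
        clusters[items[k][0]] = root_to_cluster[find(k)]
    return BinAssignment(
        clusters=clusters, query_cluster=clusters[query_id], threshold=threshold
    )


def _aligned_columns(a: str, b: str) -> list[tuple[str, str]]:
    """Base pairs at aligned (non-gap) columns of the overlap alignment."""
    if len(a) == len(b):
        return list(zip(a, b))
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    aln = aligner.align(a, b)[0]
    pairs: list[tuple[str, str]] = []
    for (sa, ea), (sb, _eb) in zip(*[blocks.tolist() for blocks in aln.aligned]):
        for k in range(ea - sa):
            pairs.append((a[sa + k], b[sb + k]))
    return pairs


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance in substitutions per site.

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q) with P the transition and Q the
    transversion fraction over unambiguous aligned columns. Ambiguity
    columns are excluded. Saturated pairs (log argument <= 0) are capped at
    ``K2P_SATURATION_CAP`` with a :class:`SaturationWarning`.
    """
    cols = [
        (x, y)
        for x, y in _aligned_columns(a, b)
        if len(CODE_TO_BASES.get(x, ())) == 1 and len(CODE_TO_BASES.get(y, ())) == 1
    ]
    if not cols:
        raise ValueError("no unambiguous aligned columns")
    n = len(cols)
    ts = sum(1 for x, y in cols if x != y and frozenset((x, y)) in _TRANSITIONS)
    tv = sum(1 for x, y in cols if x != y and frozenset((x, y)) not in _TRANSITIONS)
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        warnings.warn("K2P distance saturated; capped", SaturationWarning)
        return K2P_SATURATION_CAP
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def nj_tree(ids, matrix) -> TreeNode:
    """Neighbor-joining tree from a symmetric distance matrix.

    Taxa are sorted lexicographically before agglomeration so the result is
    invariant to input order; negative branch-length estimates are clamped
    to zero. Fewer than 4 taxa give a trivial star tree with a warning.
    """
    ids = list(ids)
    matrix = np.asarray(matrix, dtype=float)
    order = sorted(range(len(ids)), key=lambda i: ids[i])
    ids_sorted = [ids[i] for i in order]
    matrix = matrix[np.ix_(order, order)]
    if len(ids_sorted) < 4:
        warnings.warn("fewer than 4 taxa: returning trivial star tree")
        root = TreeNode(name=None)
        for i, name in enumerate(ids_sorted):
            child = TreeNode(name=name, length=float(matrix[0, i]) / 2 if i else 0.0)
            root.append(child)
        return root
    dm = DistanceMatrix(matrix, ids_sorted)
    return _skbio_nj(dm, neg_as_zero=True)


#: query-to-nearest-reference K2P distance above which placement reports
#: 'none' regardless of topology (between-genus scale; tunable per call)
PLACEMENT_MAX_DISTANCE = 0.15


def phylo_place(
    query_id: str,
    query_seq: str,
    refs,
    cfg=None,
    max_distance: float = PLACEMENT_MAX_DISTANCE,
) -> PlacementResult:
    """Place a query on a K2P neighbor-joining tree over the references.

    The query's attachment node splits the unrooted tree into sides; the
    smallest side (ties broken by distance to the query, then by name) is
    the attachment neighborhood. level is 'species' when that neighborhood
    holds a single species, 'genus' when a single genus, and 'none'
    otherwise — or when the query's nearest reference is more than
    ``max_distance`` substitutions/site away, in which case the topology
    carries no placement signal (an outlier attaches to the backbone
    wherever NJ can absorb its long branch). Raises
    :class:`PlacementFailure` when every query distance is saturated.
    """
    refs = list(refs)
    if len(refs) < 3:
        raise ValueError("phylogenetic placement requires >= 3 references")
    names = [r.record_id for r in refs] + [query_id]
    seqs = [r.sequence for r in refs] + [query_seq]
    n = len(names)
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SaturationWarning)
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = k2p_distance(seqs[i], seqs[j])
    query_dists = dict(zip(names[:-1], d[n - 1, : n - 1]))
    if all(v >= K2P_SATURATION_CAP for v in query_dists.values()):
        raise PlacementFailure("all query distances saturated")

    tree = nj_tree(names, d)
    if min(query_dists.values()) > max_distance:
        return PlacementResult(tree=tree, sister_taxa=frozenset(), level="none")

    by_id = {r.record_id: r for r in refs}
    tip = tree.find(query_id)
    v = tip.parent
    all_names = set(names[:-1])
    sides: list[frozenset[str]] = []
    under_v: set[str] = set()
    for child in v.children:
        leaves = {t.name for t in ([child] if child.is_tip() else child.tips())}
        under_v |= leaves
        if query_id not in leaves:
            sides.append(frozenset(leaves))
    rest = all_names - under_v
    if rest:
        sides.append(frozenset(rest))
    sides = [s for s in sides if s]
    side = min(
        sides,
        key=lambda s: (len(s), min(query_dists[x] for x in s), tuple(sorted(s))),
    )
    neighborhood = [by_id[x] for x in side]
    species = {r.species for r in neighborhood}
    genera = {r.genus for r in neighborhood}
    if len(species) == 1:
        level = "species"
    elif len(genera) == 1:
        level = "genus"
    else:
        level = "none"
    return PlacementResult(tree=tree, sister_taxa=frozenset(species), level=level)
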