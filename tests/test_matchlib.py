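"""Matching strategies: identity DP vs oracle, ranking, BINs, K2P, NJ."""

from __future__ import annotations

import math

import numpy as np
import pytest

from barcodeverify.iolib import VerifyConfig
from barcodeverify.matchlib import (
    SaturationWarning,
    bin_cluster,
    k2p_distance,
    nj_tree,
    pairwise_identity,
    phylo_place,
    search_library,
    threshold_call,
    top_band,
)

from conftest import diverged, make_hit_table, make_library, rand_seq


# ---------------------------------------------------------------------------
# identity oracle: independent tuple-DP over (score, matches, -columns)


def identity_oracle(a: str, b: str):
    """Plain-python semi-global DP maximising the documented lexicographic
    objective; independent of the vectorised implementation."""
    from barcodeverify.iupac import compatible

    n, m = len(a), len(b)
    NEG = (-(10 ** 9), 0, 0)
    V = [[(0, 0, 0) if i == 0 or j == 0 else NEG for j in range(m + 1)]
         for i in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if compatible(a[i - 1], b[j - 1]):
                d = (1, 1, -1)
            else:
                d = (-1, 0, -1)
            s, mt, c = V[i - 1][j - 1]
            best = (s + d[0], mt + d[1], c + d[2])
            s, mt, c = V[i - 1][j]
            best = max(best, (s - 2, mt, c - 1))
            s, mt, c = V[i][j - 1]
            best = max(best, (s - 2, mt, c - 1))
            V[i][j] = best
    best = max(
        [V[n][j] for j in range(m + 1)] + [V[i][m] for i in range(n + 1)]
    )
    _, matches, neg_cols = best
    cols = -neg_cols
    return (matches / cols if cols else 0.0, cols)


def enumerate_alignments(a: str, b: str):
    """Exhaustive enumeration of all overlap alignments (tiny inputs only),
    yielding (score, matches, -columns); validates the DP oracle itself."""
    from barcodeverify.iupac import compatible

    out = []

    def rec(i, j, score, matches, cols):
        # free trailing end gaps: may stop once one sequence is exhausted
        if i == len(a) or j == len(b):
            out.append((score, matches, -cols))
            return
        rec(i + 1, j + 1,
            score + (1 if compatible(a[i], b[j]) else -1),
            matches + (1 if compatible(a[i], b[j]) else 0),
            cols + 1)
        # internal gaps
        rec(i + 1, j, score - 2, matches, cols + 1)
        rec(i, j + 1, score - 2, matches, cols + 1)

    # free leading end gaps on one side: enumerate every start offset
    for i0 in range(len(a) + 1):
        rec(i0, 0, 0, 0, 0)
    for j0 in range(1, len(b) + 1):
        rec(0, j0, 0, 0, 0)
    return max(out)


class TestPairwiseIdentity:
    def test_identical(self):
        seq = "ACGT" * 25
        assert pairwise_identity(seq, seq) == (1.0, 100)

    def test_two_substitutions(self, rng):
        a = rand_seq(rng, 100)
        b = diverged(a, 2, rng)
        assert pairwise_identity(a, b) == (0.98, 100)

    def test_iupac_compatible_column_is_match(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "RCGTACGTACGTACGTACGT"
        assert pairwise_identity(a, b) == (1.0, 20)

    def test_end_gaps_excluded(self, rng):
        core = rand_seq(rng, 40)
        ident, overlap = pairwise_identity("TT" * 10 + core, core + "GG" * 10)
        assert (ident, overlap) == (1.0, 40)

    def test_symmetry_and_oracle_agreement(self, rng):
        for _ in range(150):
            a = rand_seq(rng, int(rng.integers(5, 31)))
            b = rand_seq(rng, int(rng.integers(5, 31)))
            got = pairwise_identity(a, b)
            assert got == pairwise_identity(b, a)
            assert got == pytest.approx(identity_oracle(a, b))

    def test_oracle_validated_by_exhaustive_enumeration(self, rng):
        for _ in range(30):
            a = rand_seq(rng, int(rng.integers(2, 7)))
            b = rand_seq(rng, int(rng.integers(2, 7)))
            score, matches, neg_cols = enumerate_alignments(a, b)
            ident, cols = identity_oracle(a, b)
            assert (-neg_cols) == cols
            assert ident == pytest.approx(matches / cols if cols else 0.0)


# ---------------------------------------------------------------------------
# library search and bands


class TestSearch:
    def test_exact_query_tops_table(self, rng, cfg):
        base = rand_seq(rng, 200)
        lib = make_library(
            {
                "Gena alpha": base,
                "Gena beta": diverged(base, 6, rng),
                "Genb gamma": diverged(base, 30, rng),
            }
        )
        ht = search_library("q", base, lib, "COI", cfg)
        assert ht.hits[0].species == "Gena alpha"
        assert ht.hits[0].identity == 1.0

    def test_calibrated_divergence_ranking(self, rng, cfg):
        base = rand_seq(rng, 300)
        lib = make_library(
            {
                "Gena one": diverged(base, 3, rng),     # 1%
                "Gena two": diverged(base, 9, rng),     # 3%
                "Genb three": diverged(base, 30, rng),  # 10%
            }
        )
        ht = search_library("q", base, lib, "COI", cfg)
        assert [h.species for h in ht.hits] == ["Gena one", "Gena two", "Genb three"]
        assert [h.identity for h in ht.hits] == [
            pytest.approx(1 - 3 / 300),
            pytest.approx(1 - 9 / 300),
            pytest.approx(1 - 30 / 300),
        ]

    def test_floor_drops_weak_hits(self, rng, cfg):
        base = rand_seq(rng, 200)
        lib = make_library({"Genx far": diverged(base, 60, rng)})  # 30% divergence
        ht = search_library("q", base, lib, "COI", cfg)
        assert len(ht) == 0

    def test_empty_or_absent_locus(self, cfg, rng):
        lib = make_library({})
        assert len(search_library("q", rand_seq(rng, 50), lib, "COI", cfg)) == 0
        lib2 = make_library({"Gena a": rand_seq(rng, 50)}, locus="ITS2")
        assert len(search_library("q", rand_seq(rng, 50), lib2, "COI", cfg)) == 0

    def test_ranking_invariant_to_record_order(self, rng, cfg):
        base = rand_seq(rng, 150)
        species = {f"Gena sp{i:02d}": diverged(base, i + 1, rng) for i in range(8)}
        lib1 = make_library(dict(species))
        lib2 = make_library(dict(reversed(list(species.items()))))
        h1 = search_library("q", base, lib1, "COI", cfg)
        h2 = search_library("q", base, lib2, "COI", cfg)
        assert [h.record_id for h in h1.hits] == [h.record_id for h in h2.hits]


class TestTopBandAndThreshold:
    def test_equal_best_hits_both_in_band(self, cfg):
        ht = make_hit_table(
            {"Plectiscus ridibundus": 1.0, "Plectiscus callidulus": 1.0,
             "Plectiscus other": 0.95}
        )
        assert top_band(ht, cfg) == {
            "Plectiscus ridibundus", "Plectiscus callidulus"
        }

    def test_dominant_hit_single_band(self, cfg):
        ht = make_hit_table({"Gena a": 1.0, "Gena b": 0.93})
        assert top_band(ht, cfg) == {"Gena a"}

    def test_band_width_one_keeps_everything(self, cfg):
        ht = make_hit_table({"Gena a": 1.0, "Genb b": 0.85})
        wide = cfg.replace(top_band_width=1.0)
        assert top_band(ht, wide) == {"Gena a", "Genb b"}

    def test_empty_table_empty_band(self, cfg):
        ht = make_hit_table({})
        assert top_band(ht, cfg) == frozenset()

    @pytest.mark.parametrize(
        "identity,expected",
        [(0.995, "within"), (0.98, "within"), (0.97, "outside")],
    )
    def test_threshold_call_inclusive_boundary(self, identity, expected):
        ht = make_hit_table({"Gena a": identity})
        assert threshold_call(ht, "Gena a", 0.02) == expected

    def test_threshold_call_absent(self):
        ht = make_hit_table({"Gena b": 1.0})
        assert threshold_call(ht, "Gena a", 0.02) == "absent"


# ---------------------------------------------------------------------------
# BIN-style clustering


class TestBinCluster:
    def test_two_pairs_split_at_threshold(self, rng):
        base = rand_seq(rng, 500)
        a1 = base
        a2 = diverged(base, 5, rng)  # 1% within pair
        far = diverged(base, 25, rng)  # 5% away
        far2 = diverged(far, 5, rng)
        recs = make_library(
            {"Gena a1": a1, "Gena a2": a2, "Gena b1": far, "Gena b2": far2}
        ).records
        res = bin_cluster(recs[:3], "q", far2, threshold=0.022)
        labels = res.clusters
        assert labels["R_Gena_a1_COI"] == labels["R_Gena_a2_COI"]
        assert labels["R_Gena_b1_COI"] == labels["q"] == res.query_cluster
        assert labels["R_Gena_a1_COI"] != labels["q"]

    def test_single_sequence_single_cluster(self, rng):
        res = bin_cluster([], "q", rand_seq(rng, 50), threshold=0.022)
        assert res.clusters == {"q": 0}

    def test_single_linkage_chaining(self, rng):
        # a-b 2%, b-c 2%, a-c 4%: all one cluster at 2.2%
        from conftest import mutate_at

        b = rand_seq(rng, 500)
        sites = rng.choice(500, size=20, replace=False)
        a = mutate_at(b, sites[:10], rng)
        c = mutate_at(b, sites[10:], rng)
        recs = make_library({"Gena a": a, "Gena b": b}).records
        res = bin_cluster(recs, "c", c, threshold=0.022)
        assert len(set(res.clusters.values())) == 1

    def test_partition_invariant_to_order(self, rng):
        base = rand_seq(rng, 300)
        seqs = {f"Gena s{i}": diverged(base, 3 * i, rng) for i in range(6)}
        recs = make_library(seqs).records
        r1 = bin_cluster(recs, "q", base, 0.022)
        r2 = bin_cluster(list(reversed(recs)), "q", base, 0.022)
        assert r1.clusters == r2.clusters


# ---------------------------------------------------------------------------
# K2P and neighbor joining


class TestK2P:
    def test_identical_is_zero(self, rng):
        s = rand_seq(rng, 200)
        assert k2p_distance(s, s) == 0.0

    def test_transition_only_closed_form(self):
        # P = 0.1, Q = 0 over 100 sites
        a = "A" * 50 + "C" * 50
        b = "G" * 5 + "A" * 45 + "T" * 5 + "C" * 45
        expected = -0.5 * math.log(1 - 0.2) - 0.25 * math.log(1.0)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.11157, abs=1e-4)

    def test_transversion_only_closed_form(self):
        a = "A" * 100
        b = "C" * 10 + "A" * 90  # Q = 0.1
        expected = -0.5 * math.log(1 - 0.1) - 0.25 * math.log(1 - 0.2)
        assert k2p_distance(a, b) == pytest.approx(expected, abs=1e-12)

    def test_ambiguity_columns_excluded(self):
        a = "ARAAAAAAAAAAAAAAAAAA"
        b = "AGAAAAAAAAAAAAAAAAAA"
        assert k2p_distance(a, b) == 0.0

    def test_saturation_capped_with_warning(self):
        a = "A" * 40
        b = "G" * 40
        with pytest.warns(SaturationWarning):
            d = k2p_distance(a, b)
        assert d == pytest.approx(5.0)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with positive branch lengths; returns
    (leaf names, distance matrix, set of non-trivial splits)."""
    import itertools

    nodes = [(f"t{i}", None) for i in range(n_taxa)]
    # adjacency with branch lengths
    adj: dict[object, list] = {}
    labels = [f"t{i}" for i in range(n_taxa)]
    live = list(labels)
    adj = {l: [] for l in labels}
    counter = 0
    while len(live) > 3:
        i, j = sorted(rng.choice(len(live), 2, replace=False))
        new = f"int{counter}"
        counter += 1
        adj[new] = []
        for x in (live[i], live[j]):
            w = float(rng.uniform(0.05, 1.0))
            adj[new].append((x, w))
            adj[x].append((new, w))
        live = [x for k, x in enumerate(live) if k not in (i, j)] + [new]
    center = "center"
    adj[center] = []
    for x in live:
        w = float(rng.uniform(0.05, 1.0))
        adj[center].append((x, w))
        adj[x].append((center, w))

    # all-pairs leaf distances by DFS
    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i, li in enumerate(labels):
        d = dists_from(li)
        for j, lj in enumerate(labels):
            D[i, j] = d[lj]
    D = (D + D.T) / 2  # remove float-order asymmetry from path sums
    np.fill_diagonal(D, 0.0)

    # splits: for each internal edge, the leaf set on one side
    splits = set()
    for u in adj:
        for v, _ in adj[u]:
            if str(u).startswith("t") or str(v).startswith("t"):
                continue
            # leaves on v's side when edge u-v removed
            side = set()
            stack = [v]
            seen = {u, v}
            while stack:
                x = stack.pop()
                if x in labels:
                    side.add(x)
                for y, _ in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            splits.add(frozenset(side) if f"t0" not in side
                       else frozenset(set(labels) - side))
    return labels, D, splits


def tree_splits(tree, labels):
    """Non-trivial splits of an unrooted tree, normalised away from t0."""
    all_leaves = set(labels)
    splits = set()
    for node in tree.non_tips():
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(all_leaves) - 1:
            splits.add(
                frozenset(side) if "t0" not in side
                else frozenset(all_leaves - side)
            )
    return splits


class TestNeighborJoining:
    def test_additive_four_taxon_exact(self):
        # classic additive matrix; tip-to-tip distances must be reproduced
        ids = ["a", "b", "c", "d"]
        D = np.array(
            [[0, 5, 9, 9], [5, 0, 10, 10], [9, 10, 0, 8], [9, 10, 8, 0]],
            dtype=float,
        )
        tree = nj_tree(ids, D)
        tt = tree.tip_tip_distances(list("abcd"))
        got = np.asarray(tt.data)
        order = list(tt.ids)
        idx = [order.index(x) for x in "abcd"]
        assert np.allclose(got[np.ix_(idx, idx)], D)

    def test_topology_recovery_on_random_additive_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 9))
            labels, D, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(labels, D)
            assert tree_splits(tree, labels) == true_splits

    def test_input_order_invariance(self, rng):
        labels, D, _ = random_additive_tree(rng, 6)
        perm = rng.permutation(6)
        tree1 = nj_tree(labels, D)
        tree2 = nj_tree(
            [labels[i] for i in perm], D[np.ix_(perm, perm)]
        )
        assert tree_splits(tree1, labels) == tree_splits(tree2, labels)

    def test_fewer_than_four_taxa_trivial_tree(self):
        with pytest.warns(UserWarning, match="fewer than 4"):
            tree = nj_tree(["a", "b", "c"], np.array(
                [[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float))
        assert {t.name for t in tree.tips()} == {"a", "b", "c"}

    def test_branch_lengths_non_negative(self, rng):
        # noisy matrix can push NJ estimates negative; they must be clamped
        labels, D, _ = random_additive_tree(rng, 6)
        noisy = D + rng.uniform(0, 0.3, size=D.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        tree = nj_tree(labels, noisy)
        assert all((n.length or 0) >= 0 for n in tree.traverse())


class TestPhyloPlace:
    def test_conspecific_neighborhood_species_level(self, rng):
        from barcodeverify.iolib import ReferenceRecord
        from conftest import mutate_at

        base = rand_seq(rng, 400)
        sites = [int(i) for i in rng.choice(400, size=100, replace=False)]
        stem = mutate_at(base, sites[:20], rng)  # species-specific stem
        refs = [
            ReferenceRecord("r1", "Gena alpha", "COI", stem),
            ReferenceRecord("r2", "Gena alpha", "COI", mutate_at(stem, sites[20:21], rng)),
            ReferenceRecord("r3", "Gena alpha", "COI", mutate_at(stem, sites[21:22], rng)),
            ReferenceRecord("r4", "Gena beta", "COI", mutate_at(base, sites[22:42], rng)),
            ReferenceRecord("r5", "Gena gamma", "COI", mutate_at(base, sites[42:62], rng)),
            ReferenceRecord("r6", "Genb delta", "COI", mutate_at(base, sites[62:100], rng)),
        ]
        query = mutate_at(stem, sites[99:100], rng)  # inside the alpha clade
        res = phylo_place("QUERY", query, refs)
        assert res.level == "species"
        assert res.sister_taxa == {"Gena alpha"}

    def test_between_two_congeners_genus_level(self, rng):
        from barcodeverify.iolib import ReferenceRecord
        from conftest import mutate_at

        base = rand_seq(rng, 400)
        sites = [int(i) for i in rng.choice(400, size=142, replace=False)]
        # query shares part of the two congeners' stem, so it attaches on
        # the internal edge leading to their clade (equidistant from both)
        half_stem = mutate_at(base, sites[:3], rng)
        pair_stem = mutate_at(half_stem, sites[3:6], rng)
        sp1 = mutate_at(pair_stem, sites[6:14], rng)
        sp2 = mutate_at(pair_stem, sites[14:22], rng)
        refs = [
            ReferenceRecord("r1", "Gena alpha", "COI", sp1),
            ReferenceRecord("r2", "Gena beta", "COI", sp2),
            ReferenceRecord("r3", "Genb delta", "COI", mutate_at(base, sites[22:62], rng)),
            ReferenceRecord("r4", "Genb epsilon", "COI", mutate_at(base, sites[62:102], rng)),
            ReferenceRecord("r5", "Genb zeta", "COI", mutate_at(base, sites[102:138], rng)),
        ]
        query = mutate_at(half_stem, sites[138:142], rng)
        res = phylo_place("QUERY", query, refs)
        assert res.level == "genus"
        assert res.sister_taxa == {"Gena alpha", "Gena beta"}

    def test_distant_outlier_level_none(self, rng):
        from barcodeverify.iolib import ReferenceRecord

        base = rand_seq(rng, 400)
        refs = [
            ReferenceRecord("r1", "Gena alpha", "COI", diverged(base, 2, rng)),
            ReferenceRecord("r2", "Gena beta", "COI", diverged(base, 6, rng)),
            ReferenceRecord("r3", "Genb delta", "COI", diverged(base, 40, rng)),
            ReferenceRecord("r4", "Genb epsilon", "COI", diverged(base, 44, rng)),
            ReferenceRecord("r5", "Genc zeta", "COI", diverged(base, 48, rng)),
        ]
        query = diverged(base, 160, rng)  # ~40% from everything
        res = phylo_place("QUERY", query, refs)
        assert res.level == "none"
        assert res.sister_taxa == frozenset()
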