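"""Zero-insertion calling, repeat masking, expansion, and RBH tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tnseqfit.essentiality import (
    call_zero_insertion,
    cluster_repeat_spans,
    core_concordance,
    expand_candidates,
    filter_self_hits,
    finalize_core_set,
    hit_spans,
    pairwise_identity,
    rbh_orthologs,
    repeat_gene_exclusions,
    RepeatCluster,
)
from tnseqfit.library_qc import filter_barcode_map, gene_insertion_stats


def _blast6(rows):
    cols = [
        "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    return pd.DataFrame(rows, columns=cols)


def _hit(q, s, pid, length, qs, qe, ss, se, ev=1e-50, bs=100.0):
    return (q, s, pid, length, 0, 0, qs, qe, ss, se, ev, bs)


class TestFilterSelfHits:
    def test_strict_length_and_identity_boundaries(self):
        hits = _blast6(
            [
                _hit("c", "c", 95.0, 1000, 0, 1000, 5000, 6000),  # length == min: drop
                _hit("c", "c", 90.0, 1500, 0, 1500, 5000, 6500),  # id == min: drop
                _hit("c", "c", 95.0, 1500, 0, 1500, 7000, 8500),  # retained
            ]
        )
        out = filter_self_hits(hits)
        assert len(out) == 1
        assert out.loc[0, "sstart"] == 7000

    def test_diagonal_dropped_and_reciprocals_collapsed(self):
        hits = _blast6(
            [
                _hit("c", "c", 100.0, 9000, 0, 9000, 0, 9000),  # trivial diagonal
                _hit("c", "c", 99.0, 2000, 100, 2100, 5000, 7000),
                _hit("c", "c", 99.0, 2000, 5000, 7000, 100, 2100),  # reciprocal dup
            ]
        )
        out = filter_self_hits(hits)
        assert len(out) == 1

    def test_planted_repeat_copies_all_pairwise_hits_retained(self):
        """3 planted 2-kb copies yield exactly the C(3,2) enumerated
        pairs after diagonal and reciprocal removal."""
        copies = [(500, 2500), (5000, 7000), (9000, 11000)]
        rows = [_hit("c", "c", 100.0, 12000, 0, 12000, 0, 12000)]
        for (a0, a1), (b0, b1) in itertools.permutations(copies, 2):
            rows.append(_hit("c", "c", 100.0, 2000, a0, a1, b0, b1))
        out = filter_self_hits(_blast6(rows))
        assert len(out) == len(list(itertools.combinations(copies, 2)))
        spans = hit_spans(out)
        assert set(zip(spans["start"], spans["end"])) == set(copies)


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestClusterRepeatSpans:
    def test_identical_copies_form_one_cluster(self):
        rng = np.random.default_rng(1)
        block = _rand_seq(rng, 2000)
        genome = "".join(
            _rand_seq(rng, 300) + block for _ in range(6)
        ) + _rand_seq(rng, 300)
        starts = [300 + i * 2300 for i in range(6)]
        spans = pd.DataFrame(
            [("c", s, s + 2000) for s in starts], columns=["contig", "start", "end"]
        )
        clusters = cluster_repeat_spans(spans, {"c": genome})
        assert len(clusters) == 1
        assert len(clusters[0].members) == 6

    def test_unrelated_sequences_stay_separate(self):
        rng = np.random.default_rng(2)
        genome = _rand_seq(rng, 4000)
        spans = pd.DataFrame(
            [("c", 0, 2000), ("c", 2000, 4000)], columns=["contig", "start", "end"]
        )
        clusters = cluster_repeat_spans(spans, {"c": genome})
        assert len(clusters) == 2

    def test_two_families_match_brute_force_identity_matrix(self):
        """Family partition agrees with thresholding the all-pairs
        identity matrix computed by a brute-force aligner."""
        import edlib

        rng = np.random.default_rng(3)
        fam_a = _rand_seq(rng, 2000)
        fam_b = _rand_seq(rng, 1500)
        segs = [fam_a, fam_a, fam_a, fam_b, fam_b]
        genome = ""
        spans = []
        for seg in segs:
            genome += _rand_seq(rng, 200)
            spans.append(("c", len(genome), len(genome) + len(seg)))
            genome += seg
        frame = pd.DataFrame(spans, columns=["contig", "start", "end"])
        clusters = cluster_repeat_spans(frame, {"c": genome})
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [2, 3]
        # brute-force all-pairs identity via global edit distance
        for (c1, s1, e1), (c2, s2, e2) in itertools.combinations(spans, 2):
            x, y = genome[s1:e1], genome[s2:e2]
            dist = edlib.align(x, y, mode="NW", task="distance")["editDistance"]
            ident = 1 - dist / max(len(x), len(y))
            same_family = (len(x) == len(y)) and (x == y)
            assert (ident >= 0.9) == same_family

    def test_order_stability_under_permutation(self):
        rng = np.random.default_rng(4)
        block = _rand_seq(rng, 1200)
        other = _rand_seq(rng, 900)
        genome = _rand_seq(rng, 100) + block + _rand_seq(rng, 100) + block \
            + _rand_seq(rng, 100) + other + _rand_seq(rng, 100)
        spans = [
            ("c", 100, 1300),
            ("c", 1400, 2600),
            ("c", 2700, 3600),
        ]
        frame = pd.DataFrame(spans, columns=["contig", "start", "end"])
        ref = cluster_repeat_spans(frame, {"c": genome})
        for perm in itertools.permutations(range(3)):
            got = cluster_repeat_spans(frame.iloc[list(perm)], {"c": genome})
            assert sorted(
                tuple(sorted(c.members)) for c in got
            ) == sorted(tuple(sorted(c.members)) for c in ref)

    def test_missing_sequence_raises(self):
        frame = pd.DataFrame([("ghost", 0, 100)], columns=["contig", "start", "end"])
        with pytest.raises(ValueError, match="ghost"):
            cluster_repeat_spans(frame, {"c": "ACGT" * 100})

    def test_kmer_estimate_agrees_with_alignment_near_threshold(self):
        rng = np.random.default_rng(5)
        base = list(_rand_seq(rng, 1000))
        mutated = base.copy()
        for i in rng.choice(1000, size=50, replace=False):  # ~95% identity
            mutated[i] = rng.choice([b for b in "ACGT" if b != mutated[i]])
        ident = pairwise_identity("".join(base), "".join(mutated), borderline=0.9)
        assert 0.93 <= ident <= 0.97


class TestRepeatGeneExclusions:
    def _genes(self, rows):
        return pd.DataFrame(
            [(t, "c", s, e, "+", True, "") for t, s, e in rows],
            columns=[
                "locus_tag", "contig", "start", "end", "strand",
                "is_protein_coding", "product",
            ],
        )

    def test_full_containment_required(self):
        clusters = [RepeatCluster(("c", 0, 1200), members=[("c", 0, 1200)])]
        genes = self._genes(
            [("inside", 100, 400), ("partial", 900, 1500), ("outside", 2000, 2500)]
        )
        assert repeat_gene_exclusions(clusters, genes) == {"inside"}


class TestZeroInsertionAndCoreSet:
    def test_planted_essentials_recovered_in_saturating_library(self, saturating_library):
        lib = saturating_library
        filtered, _ = filter_barcode_map(lib.barcode_map, lib.ta_index)
        called, no_data = call_zero_insertion(filtered, lib.genes, lib.ta_index)
        planted = lib.truth.essential_set()
        assert planted <= called | no_data
        # repeat-family genes are the expected contaminants of the raw call
        repeat_tags = set(
            lib.truth.genes.loc[lib.truth.genes["repeat_family"] >= 0, "locus_tag"]
        )
        assert called - planted <= repeat_tags

    def test_head_only_insertion_still_called(self):
        genes = pd.DataFrame(
            [("g", "c", 0, 1000, "+", True, "")],
            columns=[
                "locus_tag", "contig", "start", "end", "strand",
                "is_protein_coding", "product",
            ],
        )
        from tnseqfit.core import TASiteIndex

        idx = TASiteIndex({"c": [30, 500]})
        bmap = pd.DataFrame(
            [("a", "c", 30, "+", 1)],
            columns=["barcode", "contig", "position", "strand", "n_sites"],
        )
        called, _ = call_zero_insertion(bmap, genes, idx)
        assert called == {"g"}
        bmap2 = pd.DataFrame(
            [("a", "c", 500, "+", 1)],
            columns=["barcode", "contig", "position", "strand", "n_sites"],
        )
        called2, _ = call_zero_insertion(bmap2, genes, idx)
        assert called2 == set()

    def test_published_bookkeeping_arithmetic(self):
        """382 zero-insertion candidates minus 94 repeat-masked tags
        minus 4 manual removals leaves 284."""
        zero = {f"g{i}" for i in range(382)}
        repeat = {f"g{i}" for i in range(94)}
        manual = {f"g{i}" for i in range(94, 98)}
        call = finalize_core_set(zero, repeat, manual)
        assert len(call.final_core) == 284
        assert call.final_core == zero - repeat - manual

    def test_overlapping_exclusions_not_double_counted(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            zero = {f"g{i}" for i in rng.choice(60, rng.integers(5, 40), replace=False)}
            repeat = {f"g{i}" for i in rng.choice(60, rng.integers(0, 30), replace=False)}
            manual = {f"g{i}" for i in rng.choice(60, rng.integers(0, 10), replace=False)}
            call = finalize_core_set(zero, repeat, manual)
            assert call.final_core == zero - repeat - manual
            assert call.final_core <= zero

    def test_empty_exclusions_identity(self):
        zero = {"a", "b"}
        call = finalize_core_set(zero, set(), set())
        assert call.final_core == zero


class TestExpandCandidates:
    def test_boundary_is_inclusive(self):
        stats = pd.DataFrame(
            {
                "locus_tag": ["at", "above", "nodata"],
                "n_internal_ta": [40, 40, 0],
                "frac_ta_hit": [0.05, 0.075, np.nan],
            }
        )
        assert expand_candidates(stats) == {"at"}

    def test_superset_of_zero_insertion_genes(self, saturating_library):
        lib = saturating_library
        filtered, _ = filter_barcode_map(lib.barcode_map, lib.ta_index)
        called, _ = call_zero_insertion(filtered, lib.genes, lib.ta_index)
        stats, _ = gene_insertion_stats(filtered, lib.genes, lib.ta_index)
        expanded = expand_candidates(stats)
        with_sites = set(stats.loc[stats["n_internal_ta"] > 0, "locus_tag"])
        assert (called & with_sites) <= expanded


class TestRBH:
    def _hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue"])

    def test_mutual_best_pair_emitted(self):
        ab = self._hits([("A1", "B1", 200.0, 1e-80), ("A1", "B2", 100.0, 1e-30)])
        ba = self._hits([("B1", "A1", 195.0, 1e-78), ("B2", "A1", 90.0, 1e-20)])
        pairs = rbh_orthologs(ab, ba)
        assert list(map(tuple, pairs.to_numpy())) == [("A1", "B1")]

    def test_one_sided_best_is_not_a_pair(self):
        ab = self._hits([("A1", "B1", 200.0, 1e-80)])
        ba = self._hits([("B1", "A2", 300.0, 1e-99), ("B1", "A1", 100.0, 1e-10)])
        assert rbh_orthologs(ab, ba).empty

    def test_matches_brute_force_mutual_argmax(self):
        """Random 20x20 bipartite score matrix: RBH pairs equal the
        brute-force mutual-argmax with the documented tie-breaks."""
        rng = np.random.default_rng(11)
        n = 20
        scores = np.round(rng.uniform(50, 250, size=(n, n)), 0)  # ties likely
        a_ids = [f"A{i}" for i in range(n)]
        b_ids = [f"B{j}" for j in range(n)]
        ab = self._hits(
            [(a_ids[i], b_ids[j], scores[i, j], 1e-10) for i in range(n) for j in range(n)]
        )
        ba = self._hits(
            [(b_ids[j], a_ids[i], scores[i, j], 1e-10) for i in range(n) for j in range(n)]
        )
        pairs = set(map(tuple, rbh_orthologs(ab, ba).to_numpy()))

        def best(ids_other, row_scores):
            # max bitscore, tie -> lexicographically smallest id
            m = row_scores.max()
            return min(o for o, sc in zip(ids_other, row_scores) if sc == m)

        expected = set()
        for i in range(n):
            b = best(b_ids, scores[i, :])
            j = b_ids.index(b)
            if best(a_ids, scores[:, j]) == a_ids[i]:
                expected.add((a_ids[i], b))
        assert pairs == expected


class TestCoreConcordance:
    def test_counts_match_brute_force_on_synthetic_five_strain_fixture(self):
        rng = np.random.default_rng(13)
        focal = [f"F{i}" for i in range(60)]
        strains = {}
        rbh = {}
        for s in range(5):
            name = f"S{s}"
            partners = {g: f"{name}_{g}" for g in focal if rng.random() < 0.9}
            rbh[name] = pd.DataFrame(
                sorted(partners.items()), columns=["a", "b"]
            )
            strains[name] = {
                p for g, p in partners.items() if rng.random() < 0.7
            }
        focal_core = set(rng.choice(focal, 25, replace=False))
        focal_expanded = focal_core | set(rng.choice(focal, 15, replace=False))
        report = core_concordance(strains, rbh, focal_core, focal_expanded)
        brute = {
            g
            for g in focal
            if all(
                any((a == g and b in strains[s]) for a, b in rbh[s].to_numpy())
                for s in strains
            )
        }
        assert report.shared_core == brute
        assert report.in_focal_core == brute & focal_core
        assert report.in_focal_expanded == brute & focal_expanded
        assert report.increment == (brute & focal_expanded) - (brute & focal_core)

    def test_focal_core_containing_all_core_orthologs(self):
        rbh = {"S": pd.DataFrame({"a": ["F1", "F2"], "b": ["S1", "S2"]})}
        strains = {"S": {"S1", "S2"}}
        report = core_concordance(strains, rbh, {"F1", "F2"}, {"F1", "F2"})
        assert report.counts()["in_focal_core"] == 2

    def test_missing_rbh_map_raises(self):
        with pytest.raises(ValueError, match="S2"):
            core_concordance(
                {"S1": set(), "S2": set()},
                {"S1": pd.DataFrame({"a": [], "b": []})},
                set(),
                set(),
            )
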