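"""CIP/CALP scoring and duplicate-relationship classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polyfate import homology as H
from polyfate import simulate as sim


def make_hsp(q0, q1, nid, bit, qid="q", sid="s"):
    return H.HSP(qid, sid, q0, q1, q0, q1, q1 - q0, nid, bit)


def brute_force_score(hsps, qlen):
    """Independent per-column recount: each query column is owned by the
    highest-priority HSP covering it and contributes its identity density."""
    column_density = {}
    for h in sorted(hsps, key=H._hsp_priority):
        density = h.n_identities / (h.q_end - h.q_start)
        for col in range(h.q_start, h.q_end):
            column_density.setdefault(col, density)
    al = len(column_density)
    identities = sum(column_density.values())
    return al, 100.0 * identities / al, al / qlen


def random_hsp_set(rng, max_hsps=6):
    qlen = int(rng.integers(50, 400))
    n = int(rng.integers(1, max_hsps))
    bits = rng.permutation(10_000)[:n]  # distinct bitscores: unambiguous winners
    hsps = []
    for b in bits:
        q0 = int(rng.integers(0, qlen - 5))
        q1 = int(rng.integers(q0 + 1, qlen + 1))
        nid = int(rng.integers(0, q1 - q0 + 1))
        hsps.append(make_hsp(q0, q1, nid, float(b)))
    return hsps, qlen


class TestScoreAlignment:
    def test_single_perfect_hsp(self):
        sc = H.score_alignment([make_hsp(0, 200, 200, 400.0)], 200)
        assert (sc.AL, sc.CIP, sc.CALP) == (200, 100.0, 1.0)

    def test_two_disjoint_hsps(self):
        hsps = [make_hsp(0, 100, 90, 200.0), make_hsp(120, 170, 45, 90.0)]
        sc = H.score_alignment(hsps, 200)
        assert sc.AL == 150
        assert sc.CIP == pytest.approx(90.0)
        assert sc.CALP == pytest.approx(0.75)

    def test_overlap_merging_keeps_calp_below_one(self):
        hsps = [make_hsp(0, 150, 150, 300.0), make_hsp(100, 200, 100, 200.0)]
        sc = H.score_alignment(hsps, 200)
        assert sc.AL == 200
        assert sc.CALP == 1.0

    def test_mixed_pairs_rejected(self):
        with pytest.raises(ValueError):
            H.score_alignment([make_hsp(0, 10, 10, 1.0), make_hsp(0, 10, 10, 1.0, sid="t")], 50)
        with pytest.raises(ValueError):
            H.score_alignment([], 50)

    def test_matches_brute_force_recount(self, rng):
        for _ in range(300):
            hsps, qlen = random_hsp_set(rng)
            sc = H.score_alignment(hsps, qlen)
            al, cip, calp = brute_force_score(hsps, qlen)
            assert sc.AL == al
            assert sc.CIP == pytest.approx(cip, abs=1e-9)
            assert sc.CALP == pytest.approx(calp, abs=1e-9)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_input_order_invariance(self, data):
        qlen = data.draw(st.integers(60, 300))
        n = data.draw(st.integers(1, 5))
        hsps = []
        for i in range(n):
            q0 = data.draw(st.integers(0, qlen - 10))
            q1 = data.draw(st.integers(q0 + 1, qlen))
            nid = data.draw(st.integers(0, q1 - q0))
            hsps.append(make_hsp(q0, q1, nid, 100.0 + i))
        perm = data.draw(st.permutations(hsps))
        a = H.score_alignment(hsps, qlen)
        b = H.score_alignment(list(perm), qlen)
        assert (a.AL, a.CIP, a.CALP) == (b.AL, b.CIP, b.CALP)

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_split_invariance(self, data):
        """Splitting one HSP into two abutting halves with prorated
        identities leaves AL/CIP/CALP unchanged."""
        qlen = data.draw(st.integers(100, 400))
        q0 = data.draw(st.integers(0, qlen - 40))
        half = data.draw(st.integers(10, 20))
        density_num = data.draw(st.integers(0, half))
        whole = make_hsp(q0, q0 + 2 * half, 2 * density_num, 50.0)
        parts = [
            make_hsp(q0, q0 + half, density_num, 50.0),
            make_hsp(q0 + half, q0 + 2 * half, density_num, 50.0),
        ]
        a = H.score_alignment([whole], qlen)
        b = H.score_alignment(parts, qlen)
        assert a.AL == b.AL
        assert a.CIP == pytest.approx(b.CIP, abs=1e-9)
        assert a.CALP == pytest.approx(b.CALP, abs=1e-9)


class TestCallOrthologs:
    def test_threshold_boundaries_inclusive(self):
        passing = H.AlignmentScore("q1", "s1", 120, 60.0, 0.70, 1)
        failing = H.AlignmentScore("q2", "s1", 120, 59.9, 0.70, 1)
        assert H.call_orthologs([passing, failing]) == [("q1", "s1")]

    def test_empty_input(self):
        assert H.call_orthologs([]) == []

    def test_best_subject_by_cip_first(self):
        scores = [
            H.AlignmentScore("q", "high_calp", 100, 80.0, 0.95, 1),
            H.AlignmentScore("q", "high_cip", 100, 95.0, 0.90, 1),
        ]
        assert H.call_orthologs(scores) == [("q", "high_cip")]

    def test_rank_rule_matches_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 8))
            scores = [
                H.AlignmentScore(
                    "q", f"s{i}", 100, float(rng.integers(60, 101)),
                    float(rng.integers(70, 101)) / 100.0, 1,
                )
                for i in range(n)
            ]
            result = H.call_orthologs(scores)
            best = min(scores, key=lambda s: (-s.CIP, -s.CALP, s.subject_id))
            assert result == [("q", best.subject_id)]

    def test_true_source_recovered_on_simulation(self, loss_sim_cos, loss_sim):
        _config, _genome, copies = loss_sim
        retained = {c.copy_id for c in copies if not c.deleted}
        correct = sum(
            1 for cid, gene in loss_sim_cos if cid.rsplit("_", 1)[0] == gene
        )
        assert len(loss_sim_cos) / len(retained) >= 0.95
        assert correct / len(loss_sim_cos) >= 0.95


class TestDomainHomologs:
    def test_below_threshold_is_species_specific(self):
        scores = pd.DataFrame(
            {"cluster_id": ["c1"], "proteome": ["rice"], "identity": [0.49]}
        )
        homologs, specific = H.call_domain_homologs(scores)
        assert homologs == {} and specific == ["c1"]

    def test_venn_counts_on_toy_set(self):
        rows = []
        # 4 clusters hit 1 proteome, 3 hit 2, 2 hit 3, 1 hits none.
        for i in range(4):
            rows.append((f"one{i}", "rice", 0.8))
        for i in range(3):
            rows += [(f"two{i}", "rice", 0.7), (f"two{i}", "maize", 0.6)]
        for i in range(2):
            rows += [(f"three{i}", p, 0.9) for p in ("rice", "maize", "sorghum")]
        rows.append(("none0", "rice", 0.2))
        scores = pd.DataFrame(rows, columns=["cluster_id", "proteome", "identity"])
        homologs, specific = H.call_domain_homologs(scores)
        assert H.shared_proteome_counts(homologs) == {1: 4, 2: 3, 3: 2}
        assert specific == ["none0"]

    def test_all_identical_gives_full_homology(self):
        scores = pd.DataFrame(
            {"cluster_id": ["a", "b"], "proteome": ["rice", "rice"], "identity": [1.0, 1.0]}
        )
        homologs, specific = H.call_domain_homologs(scores)
        assert len(homologs) == 2 and specific == []


class TestClassifyCnvPav:
    def _models(self):
        return [
            sim.GeneModel("g1", "chr1", 0, 100, "+"),
            sim.GeneModel("g1t", "chr1", 150, 250, "+", tandem_parent="g1"),
            sim.GeneModel("g2", "chr1", 300, 400, "+"),
            sim.GeneModel("g3", "chr2", 0, 100, "+"),
        ]

    def test_zero_matches_is_pav(self):
        calls = H.classify_cnv_pav([("c1", "g2")], self._models())
        by_id = {c.reference_gene_id: c for c in calls}
        assert by_id["g3"].relation == "PAV"
        assert by_id["g3"].homoeolog_copy_count == 0
        assert by_id["g3"].matched_cluster_ids == []

    def test_matched_tandem_pair_is_cnv(self):
        calls = H.classify_cnv_pav([("c1", "g1"), ("c2", "g1t")], self._models())
        by_id = {c.reference_gene_id: c for c in calls}
        assert by_id["g1"].relation == "CNV"
        assert by_id["g1t"].relation == "CNV"
        assert by_id["g2"].relation == "PAV"

    def test_all_single_matches_are_cos(self):
        models = [
            sim.GeneModel("g1", "chr1", 0, 100, "+"),
            sim.GeneModel("g2", "chr1", 200, 300, "+"),
        ]
        calls = H.classify_cnv_pav([("c1", "g1"), ("c2", "g2")], models)
        assert all(c.relation == "COS" for c in calls)

    def test_unknown_gene_rejected(self):
        with pytest.raises(ValueError):
            H.classify_cnv_pav([("c1", "nope")], self._models())

    def test_planted_tandems_recovered_from_simulation(self):
        config = sim.SimulationConfig(
            n_chromosomes=1, genes_per_chromosome=40, cnv_prob=0.2,
            homoeolog_loss_prob=1.0, seed=21,
        )
        # Delete all homoeologs, then match every gene's reference sequence
        # to itself: tandem pairs (both matched) must come back as CNV.
        genome = sim.generate_genome(config)
        pairs = [(f"cl_{g.gene_id}", g.gene_id) for g in genome.genes]
        calls = H.classify_cnv_pav(pairs, genome.genes)
        tandem_ids = {g.gene_id for g in genome.genes if g.tandem_parent}
        tandem_ids |= {g.tandem_parent for g in genome.genes if g.tandem_parent}
        assert tandem_ids
        for c in calls:
            expected = "CNV" if c.reference_gene_id in tandem_ids else "COS"
            assert c.relation == expected


class TestCopyCounting:
    def test_published_histogram_triplet_fraction(self):
        hist = {1: 6024, 2: 941, 3: 193}
        assert H.triplet_fraction_from_histogram(hist) == 2.7

    def test_all_triplets(self):
        pairs = [(f"c{g}{s}", f"g{g}") for g in range(5) for s in "ABD"]
        hist, frac = H.count_homoeolog_copies(pairs)
        assert hist == {1: 0, 2: 0, 3: 5} and frac == 100.0

    def test_loss_simulation_matches_closed_form(self, loss_sim_cos):
        hist, frac = H.count_homoeolog_copies(loss_sim_cos)
        n = sum(hist.values())
        expected = 100 * 0.8**3
        bound = 100 * 2.576 * np.sqrt(0.512 * 0.488 / n)
        assert abs(frac - expected) < bound


class TestFlagMerged:
    def test_uniform_coverage_flags_nothing(self):
        table = pd.DataFrame({"cluster_id": [f"c{i}" for i in range(10)], "n_reads": [40] * 10})
        flagged, frac = H.flag_merged_homoeologs(table)
        assert flagged == [] and frac == 0.0

    def test_published_operating_point(self):
        table = pd.DataFrame(
            {"cluster_id": ["big"] + [f"c{i}" for i in range(99)], "n_reads": [150] + [40] * 99}
        )
        flagged, _ = H.flag_merged_homoeologs(table, k=3.5)
        assert flagged == ["big"]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            H.flag_merged_homoeologs(pd.DataFrame({"cluster_id": [], "n_reads": []}))


class TestParalogStatus:
    def test_published_retention_percentages(self):
        pairs = [(f"a{i}", f"b{i}") for i in range(862)]
        matched = {f"a{i}" for i in range(862)} | {f"b{i}" for i in range(166)}
        status = H.paralog_pair_status(pairs, matched)
        assert status["both"] == 166
        assert status["both_matched_pct"] == 19.3
        assert status["not_both_matched_pct"] == 80.7

    def test_no_pairs_matched(self):
        pairs = [("a", "b"), ("c", "d")]
        status = H.paralog_pair_status(pairs, set())
        assert status == {
            "both": 0, "one": 0, "none": 2, "total": 2,
            "both_matched_pct": 0.0, "not_both_matched_pct": 100.0,
        }


class TestM8Roundtrip:
    def test_write_read_roundtrip(self, tmp_path, rng):
        hsps = [make_hsp(5, 105, 95, 180.0, qid="q1", sid="s1"),
                make_hsp(0, 60, 60, 120.0, qid="q2", sid="s2")]
        path = tmp_path / "hits.m8"
        H.write_m8(path, hsps)
        back = H.read_m8(path)
        assert [(h.query_id, h.q_start, h.q_end, h.n_identities) for h in back] == [
            (h.query_id, h.q_start, h.q_end, h.n_identities) for h in hsps
        ]


def test_pipeline_loss_estimate_unbiased(loss_sim_cos):
    """The homoeolog-loss fraction inferred from copy counts matches the
    planted loss probability within Monte-Carlo error."""
    hist, _ = H.count_homoeolog_copies(loss_sim_cos)
    n = sum(hist.values())
    # Estimate per-copy retention from the copy-count distribution mean.
    mean_copies = (hist[1] + 2 * hist[2] + 3 * hist[3]) / n
    loss_hat = 1 - mean_copies / 3
    se = np.sqrt(0.2 * 0.8 / (3 * n))
    assert abs(loss_hat - 0.2) < 3 * se
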