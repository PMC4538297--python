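"""Signal2Noise ranking, enrichment scores, permutation null, NES/FDR."""

import numpy as np
import pandas as pd
import pytest

from britepipe import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    RankedList,
    enrichment_score,
    es_trajectory,
    normalize_and_fdr,
    phenotype_permutation_null,
    run_gsea,
    signal2noise_ranking,
    split_by_timepoint,
)
from britepipe.scenarios import expression_pipeline, gsea_planted_config


def brute_force_es(metric, hit, weight):
    """Independent running-sum oracle: explicit loop over positions.

    Returns (max positive excursion, max negative excursion); the ES is
    whichever has the larger magnitude (positive preferred on a tie).
    """
    n, nh = len(metric), int(np.sum(hit))
    denom = sum(abs(metric[i]) ** weight if weight else 1.0 for i in range(n) if hit[i])
    run, best_pos, best_neg = 0.0, -np.inf, np.inf
    for i in range(n):
        if hit[i]:
            run += (abs(metric[i]) ** weight if weight else 1.0) / denom
        else:
            run -= 1.0 / (n - nh)
        best_pos = max(best_pos, run)
        best_neg = min(best_neg, run)
    return best_pos, best_neg


def assert_es_matches_oracle(es, metric, hit, weight, tol=1e-12):
    best_pos, best_neg = brute_force_es(metric, hit, weight)
    if abs(best_pos) - abs(best_neg) > 1e-9:
        assert es == pytest.approx(best_pos, abs=tol)
    elif abs(best_neg) - abs(best_pos) > 1e-9:
        assert es == pytest.approx(best_neg, abs=tol)
    else:  # magnitude tie: either excursion is a valid extremum
        assert min(abs(es - best_pos), abs(es - best_neg)) < tol


def _ranked(metric, genes=None):
    metric = np.asarray(metric, dtype=float)
    genes = np.array(genes if genes is not None else [f"G{i}" for i in range(len(metric))])
    return RankedList(genes, metric)


def _matrix(X, meta):
    return ExpressionMatrix(
        pd.DataFrame(X, index=[f"G{i}" for i in range(len(X))], columns=meta["sample_id"]),
        scale="log2",
    )


class TestSignal2Noise:
    def test_equal_means_zero(self, two_group_meta):
        X = np.array([[4.0, 5.0, 6.0, 4.0, 5.0, 6.0]])
        rl = signal2noise_ranking(_matrix(X, two_group_meta), two_group_meta, "A", "B")
        assert rl.metric[0] == pytest.approx(0.0)

    def test_sd_floor_hand_examples(self, two_group_meta):
        # A=(4,4,4), B=(2,2,2): floors 0.8 and 0.4 -> 2/1.2
        X = np.array([[4.0, 4.0, 4.0, 2.0, 2.0, 2.0], [1.0, 2.0, 3.0, 1.0, 1.0, 1.0]])
        rl = signal2noise_ranking(_matrix(X, two_group_meta), two_group_meta, "A", "B")
        by_gene = dict(zip(rl.genes, rl.metric))
        assert by_gene["G0"] == pytest.approx(2.0 / 1.2)
        # A=(1,2,3) sd 1, B constant floored to 0.2 -> 1/1.2
        assert by_gene["G1"] == pytest.approx(1.0 / 1.2)

    def test_descending_with_gene_id_tiebreak(self, two_group_meta):
        X = np.array([[4.0, 4.0, 4.0, 2.0, 2.0, 2.0]] * 3)
        rl = signal2noise_ranking(_matrix(X, two_group_meta), two_group_meta, "A", "B")
        assert rl.genes.tolist() == ["G0", "G1", "G2"]
        assert np.all(np.diff(rl.metric) <= 1e-12)

    def test_missing_group_raises(self, small_log2_matrix, two_group_meta):
        with pytest.raises(ValueError):
            signal2noise_ranking(small_log2_matrix, two_group_meta, "A", "C")


class TestEnrichmentScore:
    def test_single_member_at_top_unweighted(self):
        rl = _ranked(np.linspace(5, 0.1, 10))
        es = enrichment_score(rl, GeneSet("s", "", ("G0",)), weight=0)
        assert es.es == pytest.approx(1.0)

    def test_single_member_at_bottom_unweighted(self):
        rl = _ranked([4.0, 3.0, 2.0, 1.0])
        es = enrichment_score(rl, GeneSet("s", "", ("G3",)), weight=0)
        assert es.es == pytest.approx(-1.0)

    def test_weighted_hand_example(self):
        rl = _ranked([3.0, 2.0, 1.0, 0.5, 0.1])
        prof = enrichment_score(rl, GeneSet("s", "", ("G0", "G2")), weight=1)
        assert np.allclose(prof.running, [0.75, 0.75 - 1 / 3, 2 / 3, 1 / 3, 0.0])
        assert prof.es == pytest.approx(0.75)
        assert prof.es_index == 0
        assert prof.leading_edge == ("G0",)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = 50
            metric = np.sort(rng.normal(0, 1, n))[::-1]
            genes = np.array([f"G{i}" for i in range(n)])
            members = tuple(genes[rng.choice(n, size=rng.integers(1, 15), replace=False)])
            hit = np.isin(genes, members)
            for weight in (0.0, 1.0):
                prof = enrichment_score(_ranked(metric, genes), GeneSet("s", "", members), weight)
                assert_es_matches_oracle(prof.es, metric, hit, weight)

    def test_unweighted_equals_ks_statistic(self):
        rng = np.random.default_rng(1)
        n = 40
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        genes = np.array([f"G{i}" for i in range(n)])
        members = tuple(genes[rng.choice(n, size=8, replace=False)])
        hit = np.isin(genes, members)
        prof = enrichment_score(_ranked(metric, genes), GeneSet("s", "", members), weight=0)
        cdf_hit = np.cumsum(hit) / hit.sum()
        cdf_miss = np.cumsum(~hit) / (~hit).sum()
        dev = cdf_hit - cdf_miss
        assert abs(prof.es) == pytest.approx(np.abs(dev).max(), abs=1e-12)

    def test_reversal_negates_unweighted_es(self):
        rng = np.random.default_rng(2)
        n = 30
        metric = np.sort(rng.normal(0, 1, n))[::-1]
        genes = np.array([f"G{i}" for i in range(n)])
        members = tuple(genes[rng.choice(n, size=6, replace=False)])
        fwd = enrichment_score(_ranked(metric, genes), GeneSet("s", "", members), weight=0)
        rev = enrichment_score(
            _ranked(-metric[::-1], genes[::-1]), GeneSet("s", "", members), weight=0
        )
        assert fwd.es == pytest.approx(-rev.es, abs=1e-12)

    def test_no_members_raises(self):
        rl = _ranked([1.0, 0.5])
        with pytest.raises(ValueError):
            enrichment_score(rl, GeneSet("s", "", ("ABSENT",)))


class TestRankedListInvariants:
    def test_rejects_increasing_metric(self):
        with pytest.raises(ValueError):
            RankedList(np.array(["a", "b"]), np.array([0.1, 0.5]))

    def test_rejects_duplicate_genes(self):
        with pytest.raises(ValueError):
            RankedList(np.array(["a", "a"]), np.array([0.5, 0.1]))


class TestPermutationNull:
    def test_three_vs_three_enumerates_twenty(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection(
            [GeneSet("s1", "", tuple(f"G{i:03d}" for i in range(0, 20)))]
        )
        null = phenotype_permutation_null(
            small_log2_matrix, two_group_meta, coll, "A", "B", n_perm=1000, seed=0
        )
        assert null.exhaustive
        assert len(null.assignments) == 20  # C(6,3)
        assert null.warning is not None
        assert null.assignments[null.observed_index] == (0, 1, 2)

    def test_seeded_runs_identical(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection([GeneSet("s1", "", tuple(f"G{i:03d}" for i in range(15)))])
        a = phenotype_permutation_null(small_log2_matrix, two_group_meta, coll, "A", "B", seed=3)
        b = phenotype_permutation_null(small_log2_matrix, two_group_meta, coll, "A", "B", seed=3)
        assert np.array_equal(a.es, b.es)

    def test_null_es_symmetric_on_exchangeable_data(self, small_log2_matrix, two_group_meta):
        rng = np.random.default_rng(4)
        coll = GeneSetCollection(
            [GeneSet(f"s{k}", "", tuple(rng.choice([f"G{i:03d}" for i in range(60)], 12, replace=False)))
             for k in range(6)]
        )
        null = phenotype_permutation_null(small_log2_matrix, two_group_meta, coll, "A", "B", seed=1)
        vals = null.es[np.isfinite(null.es)]
        assert abs(np.mean(vals)) < 0.15  # centred about 0 within Monte-Carlo error


class TestNormalizeAndFdr:
    def test_nes_hand_example(self):
        # positive null {0.2, 0.4}, observed 0.4 -> NES = 0.4/0.3
        null = np.array([[0.2, 0.4]])
        recs = normalize_and_fdr(["s"], [10], [0.4], null)
        assert recs[0].nes == pytest.approx(0.4 / 0.3)

    def test_observed_equal_to_null_mean_gives_unit_nes(self):
        null = np.array([[0.1, 0.3, -0.2]])
        recs = normalize_and_fdr(["s"], [10], [0.2], null)
        assert recs[0].nes == pytest.approx(1.0)

    def test_zero_es_gives_zero_nes_unit_p(self):
        null = np.array([[0.1, -0.1, 0.2]])
        recs = normalize_and_fdr(["s"], [10], [0.0], null)
        assert recs[0].nes == 0.0
        assert recs[0].p_nominal == 1.0
        assert recs[0].fdr_q == 1.0

    def test_no_same_sign_null_flagged_nan(self):
        null = np.array([[-0.1, -0.3]])
        recs = normalize_and_fdr(["s"], [10], [0.5], null)
        assert np.isnan(recs[0].nes)
        assert recs[0].fdr_q == 1.0


class TestRunGsea:
    def test_size_filter_logged(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection(
            [
                GeneSet("tiny", "", ("G000", "G001")),
                GeneSet("ok", "", tuple(f"G{i:03d}" for i in range(20))),
                GeneSet("absent", "", ("ZZZ",)),
            ]
        )
        report = run_gsea(
            small_log2_matrix, two_group_meta, coll, "A", "B", min_size=15, seed=0
        )
        skipped = {name: reason for name, _, reason in report.skipped}
        assert "tiny" in skipped and "absent" in skipped
        assert [r.name for r in report.records] == ["ok"]

    def test_planted_set_recovered(self):
        cfg = gsea_planted_config(seed=0)
        matrix, meta, collection, _ = expression_pipeline(cfg)
        report = run_gsea(matrix, meta, collection, "cPGI2", "Control", seed=0)
        assert report.exhaustive and report.n_assignments == 20
        assert report.records[0].name == "SET_UP"
        assert report.records[0].fdr_q < 0.05
        assert report.records[0].es > 0

    def test_gene_set_permutation_mode(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection([GeneSet("ok", "", tuple(f"G{i:03d}" for i in range(20)))])
        report = run_gsea(
            small_log2_matrix, two_group_meta, coll, "A", "B",
            permutation="gene_set", n_perm=50, seed=1,
        )
        assert not report.exhaustive
        assert 0.0 <= report.records[0].fdr_q <= 1.0

    def test_report_sorted_by_q_then_nes(self):
        cfg = gsea_planted_config(seed=1)
        matrix, meta, collection, _ = expression_pipeline(cfg)
        report = run_gsea(matrix, meta, collection, "cPGI2", "Control", seed=1)
        qs = [r.fdr_q for r in report.records]
        assert qs == sorted(qs)


class TestTrajectory:
    def test_identical_matrix_gives_constant_es(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection([GeneSet("s", "", tuple(f"G{i:03d}" for i in range(20)))])
        mats = {"0h": small_log2_matrix, "24h": small_log2_matrix}
        traj = es_trajectory(mats, two_group_meta, coll, ["s"], "A", "B", seed=0)
        es_values = traj["es"].values
        assert es_values[0] == pytest.approx(es_values[1])

    def test_flag_iff_q_below_alpha(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection([GeneSet("s", "", tuple(f"G{i:03d}" for i in range(20)))])
        traj = es_trajectory({"0h": small_log2_matrix}, two_group_meta, coll, ["s"], "A", "B", seed=0)
        for _, row in traj.iterrows():
            assert row["significant"] == (row["fdr_q"] < 0.05)

    def test_unknown_set_raises(self, small_log2_matrix, two_group_meta):
        coll = GeneSetCollection([GeneSet("s", "", ("G000",))])
        with pytest.raises(ValueError):
            es_trajectory({"0h": small_log2_matrix}, two_group_meta, coll, ["nope"], "A", "B")

    def test_split_by_timepoint_partitions(self, small_log2_matrix, two_group_meta):
        meta = two_group_meta.copy()
        meta["timepoint"] = ["0h", "0h", "0h", "24h", "24h", "24h"]
        mats = split_by_timepoint(small_log2_matrix, meta)
        assert set(mats) == {"0h", "24h"}
        assert all(m.data.shape[1] == 3 for m in mats.values())
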