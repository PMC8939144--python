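"""Paired tests, variance moderation, multiple testing and DMR gating."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from methfield import differential as diff
from methfield import SimulationConfig, simulate_block_matrix
from methfield.io import SampleRecord
from methfield.quantify import BlockMatrix


def matrix_from_values(values: np.ndarray, patients: int) -> BlockMatrix:
    """BlockMatrix with given corrected values, tissue order TUM/ADJ/DIS per patient."""
    manifest = [
        SampleRecord(f"P{p + 1}", t) for p in range(patients) for t in ("TUM", "ADJ", "DIS")
    ]
    idx = pd.Index([f"b{i}" for i in range(values.shape[0])], name="block_id")
    cols = pd.Index([s.sample_id for s in manifest], name="sample_id")
    df = pd.DataFrame(values, index=idx, columns=cols)
    nanframe = df * np.nan
    return BlockMatrix(df, nanframe, nanframe, nanframe.astype(str),
                       pd.Series(0.0, index=cols), manifest)


class TestPairedT:
    def test_identical_vectors(self):
        r = diff.paired_t_test([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert (r.t_stat, r.p_value) == (0.0, 1.0)

    def test_closed_form_df2(self):
        # diffs [1, 2, 3]: t = 2*sqrt(3), df = 2, p = 1 - t/sqrt(t^2 + 2)
        r = diff.paired_t_test([1, 2, 3], [0, 0, 0])
        t = 2 * math.sqrt(3)
        assert r.t_stat == pytest.approx(t, abs=1e-12)
        assert r.df == 2
        assert r.p_value == pytest.approx(1 - t / math.sqrt(t * t + 2), abs=1e-12)

    def test_pairing_invariance_under_joint_shuffle(self):
        rng = np.random.default_rng(0)
        x, y = rng.random(8), rng.random(8)
        order = rng.permutation(8)
        a = diff.paired_t_test(x, y)
        b = diff.paired_t_test(x[order], y[order])
        assert a.t_stat == pytest.approx(b.t_stat) and a.p_value == pytest.approx(b.p_value)

    def test_too_few_pairs_returns_none(self):
        assert diff.paired_t_test([1, 2, np.nan], [1, 1, 1]) is None

    def test_degenerate_zero_variance_nonzero_diff(self):
        r = diff.paired_t_test([2, 2, 2], [1, 1, 1])
        assert r.degenerate and r.p_value == 0.0


class TestVariancePrior:
    def test_all_equal_variances(self):
        p = diff.fit_variance_prior(np.full(20, 0.04), 10)
        assert math.isinf(p.d0) and p.s0_sq == pytest.approx(0.04)

    def test_single_variance_disables_moderation(self):
        p = diff.fit_variance_prior([0.02], 10)
        assert p.d0 == 0.0

    def test_moment_recovery(self):
        rng = np.random.default_rng(12)
        d0, s0, d, n = 6.0, 0.05, 20, 4000
        sigma2 = s0 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(d, n) / d
        p = diff.fit_variance_prior(s2, d)
        assert p.d0 == pytest.approx(d0, abs=1.5)
        assert p.s0_sq == pytest.approx(s0, rel=0.1)


class TestModeratedT:
    def test_d0_zero_is_bitwise_ordinary_t(self):
        rng = np.random.default_rng(1)
        D = pd.DataFrame(rng.normal(0, 0.1, (50, 8)))
        D.iloc[3, 2] = np.nan
        res = diff.moderated_paired_t(D, prior=diff.ModerationParams(0.0, 1.0))
        for i in range(len(D)):
            row = D.iloc[i].to_numpy()
            r = diff.paired_t_test(row, np.zeros(len(row)))
            assert res["t"].iloc[i] == r.t_stat  # bitwise
            assert res["p"].iloc[i] == r.p_value

    def test_d0_infinite_uses_prior_variance_exactly(self):
        rng = np.random.default_rng(2)
        D = pd.DataFrame(rng.normal(0, 0.1, (20, 6)))
        s0 = 0.02
        res = diff.moderated_paired_t(D, prior=diff.ModerationParams(math.inf, s0))
        n = D.shape[1]
        expected_t = D.mean(axis=1).to_numpy() / np.sqrt(s0 / n)
        np.testing.assert_allclose(res["t"].to_numpy(), expected_t, rtol=1e-12)
        expected_p = 2 * stats.norm.sf(np.abs(expected_t))
        np.testing.assert_allclose(res["p"].to_numpy(), expected_p, rtol=1e-9)

    def test_hand_example_against_independent_formula(self):
        D = pd.DataFrame([
            [0.10, 0.05, 0.20, 0.01],
            [-0.02, 0.03, -0.01, 0.00],
            [0.30, 0.25, 0.35, 0.40],
        ])
        d0, s0 = 3.0, 0.004
        res = diff.moderated_paired_t(D, prior=diff.ModerationParams(d0, s0))
        for i in range(3):
            row = D.iloc[i].to_numpy()
            n = 4
            mean = row.mean()
            s2 = row.var(ddof=1)
            s2_post = (d0 * s0 + (n - 1) * s2) / (d0 + n - 1)
            t = mean / math.sqrt(s2_post / n)
            p = 2 * stats.t.sf(abs(t), n - 1 + d0)
            assert res["t"].iloc[i] == pytest.approx(t, abs=1e-12)
            assert res["p"].iloc[i] == pytest.approx(p, abs=1e-12)

    def test_p_invariant_to_patient_relabeling(self):
        rng = np.random.default_rng(3)
        D = pd.DataFrame(rng.normal(0, 0.1, (30, 10)))
        perm = rng.permutation(10)
        a = diff.moderated_paired_t(D)
        b = diff.moderated_paired_t(D.iloc[:, perm])
        np.testing.assert_allclose(a["p"].to_numpy(), b["p"].to_numpy(), rtol=1e-12)


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        assert diff.log2_fold_change(0.3, 0.3, eps=0.01) == pytest.approx(0.0)

    def test_exact_doubling(self):
        assert diff.log2_fold_change(0.4, 0.2, eps=0.0) == pytest.approx(1.0)

    def test_offset_example(self):
        assert diff.log2_fold_change(0.2, 0.1, eps=0.01) == pytest.approx(
            math.log2(0.21 / 0.11), abs=1e-12
        )

    def test_both_zero_without_offset_is_missing(self):
        assert math.isnan(diff.log2_fold_change(0.0, 0.0, eps=0.0))


def brute_force_bh(p):
    """Textbook step-up with monotone enforcement."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        for method in ("BH", "bonferroni"):
            assert diff.adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_step_up_example(self):
        out = diff.adjust_pvalues([0.01, 0.02, 0.03, 0.04], "BH")
        np.testing.assert_allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_bonferroni_example(self):
        np.testing.assert_allclose(diff.adjust_pvalues([0.3, 0.4], "bonferroni"), [0.6, 0.8])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_bh_matches_brute_force(self, p):
        np.testing.assert_array_equal(diff.adjust_pvalues(p, "BH"), brute_force_bh(np.array(p)))

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(4)
        p = rng.random(500)
        for ours, theirs in (("BH", "fdr_bh"), ("bonferroni", "bonferroni")):
            np.testing.assert_allclose(
                diff.adjust_pvalues(p, ours), multipletests(p, method=theirs)[1], rtol=1e-12
            )

    def test_nan_preserved_in_place(self):
        out = diff.adjust_pvalues([0.01, np.nan, 0.04], "BH")
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], brute_force_bh(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            diff.adjust_pvalues([1.2], "BH")


class TestTumorDmrGating:
    def make_matrix(self, rng, n_blocks=40, patients=10, effect_blocks=(), delta=0.3):
        base = rng.uniform(0.2, 0.5, n_blocks)
        vals = np.empty((n_blocks, patients * 3))
        for p in range(patients):
            noise = rng.normal(0, 0.01, (n_blocks, 3))
            trio = np.stack([base, base, base], axis=1) + noise
            for b in effect_blocks:
                trio[b, 0] += delta  # TUM column
            vals[:, p * 3: p * 3 + 3] = trio
        return matrix_from_values(np.clip(vals, 0, 1), patients)

    def test_planted_blocks_called_hyper(self):
        rng = np.random.default_rng(0)
        bm = self.make_matrix(rng, effect_blocks=(1, 5))
        out = diff.call_tumor_dmrs(bm)
        assert set(out["block_id"]) == {"b1", "b5"}
        assert (out["direction"] == "hyper").all()

    def test_effect_size_gate_blocks_small_fold_change(self):
        # strong significance but tiny log2FC: high baseline, small shift
        rng = np.random.default_rng(1)
        n, patients = 30, 12
        vals = np.empty((n, patients * 3))
        base = np.full(n, 0.9)
        for p in range(patients):
            noise = rng.normal(0, 0.002, (n, 3))
            trio = np.stack([base, base, base], axis=1) + noise
            trio[0, 0] += 0.02
            vals[:, p * 3: p * 3 + 3] = trio
        bm = matrix_from_values(np.clip(vals, 0, 1), patients)
        table = diff.tumor_dmr_table(bm, diff.Thresholds(value_transform="identity"))
        assert table.loc[0, "p_adj"] < 0.05  # significant
        assert abs(table.loc[0, "log2fc"]) < 0.1  # but below the fold gate
        assert "b0" not in set(diff.call_tumor_dmrs(bm, diff.Thresholds(value_transform="identity"))["block_id"])

    def test_direction_agrees_with_sign(self):
        cfg = SimulationConfig(n_blocks=150, n_patients=12, seed=3,
                               n_tumor_hyper=20, n_tumor_hypo=20, n_fc_up=0, n_fc_down=0)
        bm, truth = simulate_block_matrix(cfg)
        out = diff.call_tumor_dmrs(bm)
        assert ((out["mean_diff"] > 0) == (out["direction"] == "hyper")).all()


class TestFcDmrGating:
    def test_tumor_only_pattern_not_called_fc(self):
        cfg = SimulationConfig(n_blocks=150, n_patients=24, seed=4, delta_tumor=0.3,
                               n_tumor_hyper=40, n_tumor_hypo=0, n_fc_up=0, n_fc_down=0)
        bm, truth = simulate_block_matrix(cfg)
        fc = diff.call_fc_dmrs(bm)
        hyper_ids = set(truth[truth["effect_class"] == "tumor_hyper"]["block_id"])
        assert not (set(fc["block_id"]) & hyper_ids)

    def test_emitted_blocks_have_strictly_ordered_means(self):
        cfg = SimulationConfig(n_blocks=200, n_patients=24, seed=5,
                               n_tumor_hyper=0, n_tumor_hypo=0, n_fc_up=60, n_fc_down=20)
        bm, _ = simulate_block_matrix(cfg)
        fc = diff.call_fc_dmrs(bm)
        assert len(fc) > 0
        up = fc[fc["category"] == "up"]
        assert ((up["mean_DIS"] < up["mean_ADJ"]) & (up["mean_ADJ"] < up["mean_TUM"])).all()
        down = fc[fc["category"] == "down"]
        assert ((down["mean_DIS"] > down["mean_ADJ"]) & (down["mean_ADJ"] > down["mean_TUM"])).all()

    def test_monotone_means_without_significance_not_called(self):
        rng = np.random.default_rng(6)
        patients = 8
        # strictly increasing means but noise swamps the ADJ - DIS step
        vals = np.empty((20, patients * 3))
        for p in range(patients):
            trio = np.stack([
                np.full(20, 0.32), np.full(20, 0.305), np.full(20, 0.30)
            ], axis=1) + rng.normal(0, 0.2, (20, 3))
            vals[:, p * 3: p * 3 + 3] = trio
        bm = matrix_from_values(np.clip(vals, 0, 1), patients)
        assert len(diff.call_fc_dmrs(bm)) == 0


class TestOverlapSets:
    def test_printed_report_arithmetic(self):
        fc = [f"f{i}" for i in range(332)]
        tumor = fc[:187] + [f"t{i}" for i in range(2000)]
        n, pct = diff.overlap_sets(fc, tumor)
        assert (n, pct) == (187, 56.3)

    def test_disjoint(self):
        assert diff.overlap_sets(["a"], ["b"]) == (0, 0.0)

    def test_subset_is_100_percent(self):
        assert diff.overlap_sets(["a", "b"], ["a", "b", "c"]) == (2, 100.0)

    def test_empty_fc_fraction_missing(self):
        n, pct = diff.overlap_sets([], ["a"])
        assert n == 0 and math.isnan(pct)
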