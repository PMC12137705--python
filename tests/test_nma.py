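"""Node-measure-assignment models: masks, features, CV protocol, inference."""

import numpy as np
import pandas as pd
import pytest

from couplemap import (
    AnalysisConfig,
    ParticipantTable,
    build_nma_mask,
    extract_features,
    fit_predict_bnma,
    fit_predict_enma,
    model_difference_test,
    permutation_test,
)
from couplemap.coupling import CouplingTable
from couplemap.datatypes import ValidationError
from couplemap.nma import NMAMask, _build_contexts, _prepare, cross_sample_generalize
from couplemap.synthetic import CouplingGenConfig, SignalSpec, generate_coupling_cohort

MEASURES = ["CoS", "PL", "G", "SI"]


def _participants(n, g, rng, conditions=("WM",)):
    df = pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(n)],
        "g": g,
        "age": rng.uniform(22, 36, n),
        "gender": rng.integers(0, 2, n),
        "handedness": rng.uniform(-100, 100, n),
    })
    for c in conditions:
        df[f"motion_{c}"] = rng.uniform(0.05, 0.2, n)
    return ParticipantTable(df)


class TestBuildMask:
    def test_dominant_measure_uniform_mask(self, rng):
        n, R = 300, 10
        u = rng.standard_normal(n)
        coupling = rng.normal(0.3, 0.05, size=(n, R, 4))
        coupling[:, :, 2] += 0.1 * u[:, None]  # G associated everywhere
        g = u + 0.3 * rng.standard_normal(n)
        mask = build_nma_mask(coupling, g, None, "WM", MEASURES)
        assert np.all(mask.positive == 2)

    def test_all_negative_region_flagged(self, rng):
        n, R = 400, 3
        u = rng.standard_normal(n)
        coupling = rng.normal(0.3, 0.05, size=(n, R, 4))
        coupling[:, 0, :] -= 0.1 * u[:, None]  # all measures negative in region 0
        mask = build_nma_mask(coupling, u, None, "WM", MEASURES)
        assert mask.flagged_positive[0]
        # positive assignment still the least negative measure
        assert mask.r_P[0, mask.positive[0]] == mask.r_P[0].max()

    def test_degenerate_cell_gets_zero(self, rng):
        n = 50
        coupling = rng.normal(0.3, 0.05, size=(n, 4, 4))
        coupling[:, 1, 2] = 0.5  # constant cell
        mask = build_nma_mask(coupling, rng.standard_normal(n), None)
        assert mask.r_P[1, 2] == 0.0

    def test_planted_recovery_rate(self):
        """Planted +G / -SI regions (|r|=0.3, n=400) recovered in >= 90% of
        signal-region draws."""
        hits = total = 0
        sig = tuple(SignalSpec(r, "G", 0.3, "WM") for r in range(3)) + \
            tuple(SignalSpec(r, "SI", -0.3, "WM") for r in range(3, 6))
        for s in range(30):
            table, parts, _ = generate_coupling_cohort(
                CouplingGenConfig(n_participants=400, signal=sig), seed=6000 + s
            )
            mask = build_nma_mask(
                table.condition_slice("WM"), parts.g, parts.covariates("WM"), "WM"
            )
            hits += int(np.sum(mask.positive[:3] == 2))
            hits += int(np.sum(mask.negative[3:6] == 3))
            total += 6
        assert hits / total >= 0.90


class TestExtractFeatures:
    def test_constant_table(self):
        mask = NMAMask("WM", np.zeros(5, dtype=int), np.ones(5, dtype=int),
                       np.zeros((5, 4)))
        coupling = np.full((7, 5, 4), 0.42)
        feats = extract_features(mask, coupling)
        np.testing.assert_allclose(feats, 0.42)

    def test_mask_swap_swaps_features(self, rng):
        coupling = rng.uniform(-0.5, 0.5, size=(6, 8, 4))
        pos = rng.integers(0, 4, 8)
        neg = rng.integers(0, 4, 8)
        a = extract_features(NMAMask("WM", pos, neg, np.zeros((8, 4))), coupling)
        b = extract_features(NMAMask("WM", neg, pos, np.zeros((8, 4))), coupling)
        np.testing.assert_array_equal(a[:, 0], b[:, 1])
        np.testing.assert_array_equal(a[:, 1], b[:, 0])

    def test_hand_built_three_region_example(self):
        coupling = np.zeros((1, 3, 4))
        coupling[0] = [[0.1, 0.2, 0.3, 0.4],
                       [0.5, 0.6, 0.7, 0.8],
                       [-0.1, -0.2, -0.3, -0.4]]
        mask = NMAMask("WM", np.array([2, 0, 3]), np.array([0, 1, 1]),
                       np.zeros((3, 4)))
        feats = extract_features(mask, coupling)
        assert feats[0, 0] == pytest.approx((0.3 + 0.5 + (-0.4)) / 3)
        assert feats[0, 1] == pytest.approx((0.1 + 0.6 + (-0.2)) / 3)


class TestFitPredict:
    def test_noiseless_planted_linear_recovery(self, rng):
        """Phenotype exactly linear in the planted features -> r ~ 1."""
        n, R = 200, 12
        coupling = rng.normal(0.3, 0.05, size=(n, 1, 4, R))
        u = rng.standard_normal(n)
        coupling[:, 0, 2, :4] += 0.2 * u[:, None]
        table = CouplingTable(np.clip(coupling, -1, 1), [f"p{i}" for i in range(n)],
                              ["WM"], MEASURES)
        g = u  # noiseless target of the planted coupling factor
        parts = _participants(n, g, rng)
        res = fit_predict_bnma(table, parts, "WM", AnalysisConfig(rng_seed=1),
                               n_repetitions=5)
        assert res.r > 0.9

    def test_null_phenotype_centered_near_zero(self):
        rs = []
        for s in range(20):
            table, parts, _ = generate_coupling_cohort(
                CouplingGenConfig(n_participants=500, total_signal_r2=0.0),
                seed=7000 + s,
            )
            res = fit_predict_bnma(table, parts, "WM",
                                   AnalysisConfig(rng_seed=s), n_repetitions=10)
            rs.append(res.r)
        mean_r = float(np.mean(rs))
        # CV pessimism pulls slightly negative, never systematically positive
        assert abs(mean_r) < 0.05
        assert mean_r < 0.02

    def test_determinism_bitwise(self):
        sig = (SignalSpec(0, "G", 0.2, "WM"),)
        table, parts, _ = generate_coupling_cohort(
            CouplingGenConfig(n_participants=150, signal=sig), seed=3
        )
        cfg = AnalysisConfig(rng_seed=11)
        a = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=5)
        b = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=5)
        assert a.r == b.r
        np.testing.assert_array_equal(a.per_repetition_r, b.per_repetition_r)

    def test_leakage_guard_masks_ignore_test_participants(self):
        """Replacing a test-fold participant leaves training masks
        bit-identical."""
        table, parts, _ = generate_coupling_cohort(
            CouplingGenConfig(n_participants=100), seed=5
        )
        cfg = AnalysisConfig(rng_seed=2)
        C, Z, g = _prepare(table, parts, ["WM"])
        ctxs = _build_contexts(C, Z, len(g), cfg, 1, cfg.rng_seed)
        ctx = ctxs[0][0]
        from couplemap.nma import _fold_fit_predict

        _, masks_a, _ = _fold_fit_predict(ctx, g, ["WM"])
        # plant a wildly different marker participant inside the test fold
        marker = ctx.test[0]
        C2 = {"WM": C["WM"].copy()}
        C2["WM"][marker] = 0.9
        g2 = g.copy()
        g2[marker] = 10.0
        ctxs2 = _build_contexts(C2, Z, len(g), cfg, 1, cfg.rng_seed)
        _, masks_b, _ = _fold_fit_predict(ctxs2[0][0], g2, ["WM"])
        np.testing.assert_array_equal(masks_a[0].positive, masks_b[0].positive)
        np.testing.assert_array_equal(masks_a[0].negative, masks_b[0].negative)
        np.testing.assert_array_equal(masks_a[0].r_P, masks_b[0].r_P)

    def test_enma_reduces_to_bnma_for_single_task(self):
        sig = (SignalSpec(0, "G", 0.2, "WM"),)
        table, parts, _ = generate_coupling_cohort(
            CouplingGenConfig(conditions=("WM",), signal=sig), seed=9
        )
        cfg = AnalysisConfig(rng_seed=4, rest_condition="RES")
        a = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=5)
        b = fit_predict_enma(table, parts, cfg, n_repetitions=5)
        np.testing.assert_array_equal(a.per_repetition_r, b.per_repetition_r)

    def test_enma_feature_count_guard(self, rng):
        # 2 x n_task_conditions features must stay below the training fold size
        n, R = 20, 4
        conds = tuple(f"T{i}" for i in range(8))
        coupling = rng.uniform(-0.5, 0.5, size=(n, 8, 4, R))
        table = CouplingTable(coupling, [f"p{i}" for i in range(n)],
                              list(conds), MEASURES)
        parts = _participants(n, rng.standard_normal(n), rng, conds)
        with pytest.raises(ValidationError, match="saturate"):
            fit_predict_enma(table, parts, AnalysisConfig(rng_seed=0),
                             n_repetitions=2)

    def test_small_fold_rejected(self, rng):
        n = 10
        coupling = rng.uniform(-0.5, 0.5, size=(n, 1, 4, 5))
        table = CouplingTable(coupling, [f"p{i}" for i in range(n)], ["WM"],
                              MEASURES)
        parts = _participants(n, rng.standard_normal(n), rng)
        with pytest.raises(ValidationError, match="folds"):
            fit_predict_bnma(table, parts, "WM", AnalysisConfig(rng_seed=0),
                             n_repetitions=2)


@pytest.fixture(scope="module")
def planted():
    sig = tuple(SignalSpec(r, "G", 0.3, "WM") for r in range(3)) + \
        tuple(SignalSpec(r, "SI", -0.3, "WM") for r in range(3, 6))
    return generate_coupling_cohort(CouplingGenConfig(signal=sig), seed=21)


class TestPermutationInference:
    def test_strong_signal_hits_p_floor(self, planted):
        table, parts, _ = planted
        cfg = AnalysisConfig(rng_seed=1)
        res = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=10)
        p = permutation_test(res, table, parts, cfg, n_permutations=100)
        assert p == pytest.approx(1 / 101)
        assert res.p == p

    def test_p_in_half_open_interval(self, planted):
        table, parts, _ = planted
        cfg = AnalysisConfig(rng_seed=2)
        res = fit_predict_bnma(table, parts, "MOT", cfg, n_repetitions=5)
        p = permutation_test(res, table, parts, cfg, n_permutations=50)
        assert 0.0 < p <= 1.0

    def test_model_compared_with_itself_gives_p_one(self, planted):
        table, parts, _ = planted
        cfg = AnalysisConfig(rng_seed=3)
        res = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=5)
        p = model_difference_test(res, res, table, parts, cfg, n_permutations=20)
        assert p == 1.0

    def test_planted_vs_noise_model_difference(self, planted):
        table, parts, _ = planted
        cfg = AnalysisConfig(rng_seed=4)
        strong = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=10)
        weak = fit_predict_bnma(table, parts, "MOT", cfg, n_repetitions=10)
        p = model_difference_test(strong, weak, table, parts, cfg,
                                  n_permutations=100)
        assert p < 0.05

    def test_doubling_permutations_refines_p(self, planted):
        """More permutations cannot move a small p far: the estimate is a
        monotone refinement up to Monte-Carlo error."""
        table, parts, _ = planted
        cfg = AnalysisConfig(rng_seed=5)
        res = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=5)
        p1 = permutation_test(res, table, parts, cfg, n_permutations=50)
        p2 = permutation_test(res, table, parts, cfg, n_permutations=100)
        assert abs(p2 - p1) < 0.05


class TestCrossSample:
    def test_replication_equals_training_cohort(self):
        sig = tuple(SignalSpec(r, "G", 0.3, "WM") for r in range(6))
        table, parts, _ = generate_coupling_cohort(
            CouplingGenConfig(signal=sig), seed=31
        )
        cfg = AnalysisConfig(rng_seed=6)
        internal = fit_predict_bnma(table, parts, "WM", cfg, n_repetitions=10)
        self_applied = cross_sample_generalize(
            table, parts, table, parts, "B-NMA", "WM", cfg,
            n_repetitions=10, n_permutations=0,
        )
        # applying frozen models back to their own cohort includes the
        # training folds: an upper bound on the internal CV estimate
        assert self_applied.r >= internal.r - 0.02

    def test_missing_condition_rejected(self):
        table, parts, _ = generate_coupling_cohort(
            CouplingGenConfig(n_participants=100), seed=32
        )
        repl_cfg = CouplingGenConfig(n_participants=100,
                                     conditions=("RES", "GAM"))
        repl_t, repl_p, _ = generate_coupling_cohort(repl_cfg, seed=33)
        with pytest.raises(ValidationError, match="lacks condition"):
            cross_sample_generalize(table, parts, repl_t, repl_p,
                                    "B-NMA", "WM", AnalysisConfig(rng_seed=0),
                                    n_repetitions=2, n_permutations=0)
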