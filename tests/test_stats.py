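"""Crossover statistics: ANOVA/contrast identities, Holm, correlations, calibration."""

import numpy as np
import pandas as pd
import pytest

from p300lab.stats import (
    correlate_changes,
    eta_p_squared,
    holm_adjust,
    interaction_contrast,
    paired_t,
    rm_anova_2x2,
)
from p300lab.synthetic import EffectSpec, simulate_outcome_measures


def _outcomes_from_cells(cells: np.ndarray) -> pd.DataFrame:
    """cells: (n_subjects, 4) ordered actual/pre, actual/post, sham/pre, sham/post."""
    rows = []
    for s, row in enumerate(cells):
        for (iv, bl), v in zip(
            [("actual", "pre"), ("actual", "post"), ("sham", "pre"), ("sham", "post")], row
        ):
            rows.append((s, iv, bl, "m", v))
    return pd.DataFrame(rows, columns=["subject", "intervention", "block", "measure", "value"])


class TestRmAnova:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_interaction_f_equals_squared_paired_t_of_contrast(self, seed):
        rng = np.random.default_rng(seed)
        outcomes = _outcomes_from_cells(rng.normal(size=(15, 4)))
        res = rm_anova_2x2(outcomes)
        contrast = interaction_contrast(outcomes)
        tt = paired_t(contrast, np.zeros_like(contrast))
        assert res.interaction.F == pytest.approx(tt.t**2, rel=1e-8)
        assert res.interaction.p == pytest.approx(tt.p, rel=1e-8)
        assert res.interaction.df_effect == 1
        assert res.interaction.df_error == 14

    def test_block_effect_f_matches_block_contrast(self):
        rng = np.random.default_rng(7)
        outcomes = _outcomes_from_cells(rng.normal(size=(12, 4)))
        res = rm_anova_2x2(outcomes)
        cells = outcomes.pivot_table(index="subject", columns=["intervention", "block"], values="value")
        post = (cells[("actual", "post")] + cells[("sham", "post")]) / 2
        pre = (cells[("actual", "pre")] + cells[("sham", "pre")]) / 2
        tt = paired_t(post.to_numpy(), pre.to_numpy())
        assert res.block.F == pytest.approx(tt.t**2, rel=1e-8)

    def test_eta_identity(self):
        assert eta_p_squared(20.13, 1, 18) == pytest.approx(0.53, abs=0.005)
        for f in (0.5, 3.3, 42.0):
            e = eta_p_squared(f, 1, 18)
            assert e == pytest.approx(f / (f + 18))

    def test_zero_interaction_variance_with_mean_gives_tiny_p(self):
        cells = np.tile([0.0, 1.0, 0.0, 0.0], (8, 1))
        cells += np.random.default_rng(0).normal(0, 1e-9, size=cells.shape)
        res = rm_anova_2x2(_outcomes_from_cells(cells))
        assert res.interaction.p < 1e-10

    def test_incomplete_subjects_dropped_listwise(self):
        rng = np.random.default_rng(3)
        outcomes = _outcomes_from_cells(rng.normal(size=(10, 4)))
        outcomes.loc[(outcomes.subject == 4) & (outcomes.block == "post") & (outcomes.intervention == "sham"), "value"] = np.nan
        res = rm_anova_2x2(outcomes)
        assert res.n_subjects == 9
        assert res.dropped_subjects == [4]

    def test_too_few_cases_rejected(self):
        outcomes = _outcomes_from_cells(np.zeros((1, 4)))
        with pytest.raises(ValueError, match="at least 2"):
            rm_anova_2x2(outcomes)


class TestPairedT:
    def test_closed_form_example(self):
        # differences [1,2,3]: t = 2 / (1/sqrt(3)) = 3.464, df = 2
        res = paired_t(np.array([2.0, 4.0, 6.0]), np.array([1.0, 2.0, 3.0]))
        assert res.t == pytest.approx(2 * np.sqrt(3), abs=1e-9)
        assert res.df == 2
        assert res.cohen_d == pytest.approx(2.0)

    def test_equal_samples_give_zero(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0
        assert res.cohen_d == 0.0
        assert res.p == 1.0

    def test_sign_flip_negates_t_keeps_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1, r2 = paired_t(a, b), paired_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_variance_nonzero_mean_reports_infinite_t(self):
        res = paired_t(np.array([1.0, 1.0, 1.0]), np.array([0.0, 0.0, 0.0]))
        assert np.isinf(res.t) and res.t > 0
        assert res.p == 0.0


class TestHolm:
    def test_hand_computed_step_down(self):
        adj = holm_adjust([0.01, 0.03, 0.04])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_scale_by_family_size_capped(self):
        assert np.allclose(holm_adjust([0.3] * 4), [1.0] * 4)
        assert np.allclose(holm_adjust([0.01] * 4), [0.04] * 4)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestCorrelateChanges:
    def _outcomes(self, changes: dict) -> pd.DataFrame:
        rows = []
        n = len(next(iter(changes.values())))
        for m, vals in changes.items():
            for i, v in enumerate(vals):
                s, iv = divmod(i, 2)
                iv = ["actual", "sham"][iv]
                rows.append((s, iv, "pre", m, 0.0))
                rows.append((s, iv, "post", m, v))
        return pd.DataFrame(rows, columns=["subject", "intervention", "block", "measure", "value"])

    def test_linear_dependence_gives_unit_correlation(self):
        x = np.arange(12.0)
        out = correlate_changes(self._outcomes({"a": x, "b": 2 * x}))
        assert out.r.loc["a", "b"] == pytest.approx(1.0)
        assert np.isnan(out.r.loc["a", "a"])  # diagonal excluded

    def test_constant_change_reported_missing(self):
        x = np.arange(12.0)
        out = correlate_changes(self._outcomes({"a": x, "b": np.ones(12)}))
        assert np.isnan(out.r.loc["a", "b"])

    def test_holm_at_least_raw(self):
        rng = np.random.default_rng(2)
        out = correlate_changes(
            self._outcomes({m: rng.normal(size=16) for m in "abcde"})
        )
        mask = ~out.p_raw.isna().to_numpy()
        ph, pr = out.p_holm.to_numpy()[mask], out.p_raw.to_numpy()[mask]
        assert (ph >= pr - 1e-12).all()

    def test_familywise_error_controlled_under_null(self):
        # 8 independent measures (28 pairs), n=20 changes: after Holm the
        # probability of any false positive stays at or below alpha
        rng = np.random.default_rng(42)
        fw_errors = 0
        reps = 400
        for _ in range(reps):
            out = correlate_changes(self._outcomes({f"m{i}": rng.normal(size=20) for i in range(8)}))
            fw_errors += np.nanmin(out.p_holm.to_numpy()) < 0.05
        rate = fw_errors / reps
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / reps)

    def test_coupled_changes_recover_true_correlation(self):
        # late-ERP and RT changes correlated at rho = 0.7
        rng = np.random.default_rng(3)
        rs = []
        for _ in range(200):
            x = rng.normal(size=20)
            y = 0.7 * x + np.sqrt(1 - 0.49) * rng.normal(size=20)
            out = correlate_changes(self._outcomes({"late": x, "rt": y}))
            rs.append(out.r.loc["late", "rt"])
        assert np.mean(rs) == pytest.approx(0.7, abs=0.05)


class TestCalibration:
    def test_type_one_error_nominal_under_null_outcome_model(self):
        # distributional study model, null effects: interaction rejections ~ alpha
        rej = 0
        reps = 400
        for rep in range(reps):
            df = simulate_outcome_measures(19, EffectSpec.null(), seed=rep, measures=("late_erp",))
            rej += rm_anova_2x2(df).interaction.p < 0.05
        rate = rej / reps
        assert 0.02 <= rate <= 0.09

    def test_power_for_actual_only_late_component_shift(self):
        # actual-only late-ERP shift sized to d ~ 0.62 (0.55 uV against a
        # 0.886 uV contrast SD): power at n=19 should be at least 0.6
        eff = EffectSpec(0, 0, 0.55, 0.0, 0, 0, 0, 0, 0, 0)
        rej = 0
        reps = 500
        for rep in range(reps):
            df = simulate_outcome_measures(19, eff, seed=10_000 + rep, measures=("late_erp",))
            rej += rm_anova_2x2(df).interaction.p < 0.05
        assert rej / reps >= 0.6
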