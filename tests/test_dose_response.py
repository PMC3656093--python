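import numpy as np
import pandas as pd
import pytest

from screenkit.dose_response import (
    fit_4pl,
    fit_dose_table,
    fit_smoothed,
    four_pl,
    ic50_ci,
    pct_max_inhibition,
    relative_ic50,
    viability_gate,
)
from screenkit.synthetic import DoseDesign, generate_dose_series

DESIGN = DoseDesign()
LADDER = DESIGN.concentrations


def _series(L=100.0, h=100.0, alpha=5.0, beta=2.0, reps=2):
    x = np.repeat(LADDER, reps)
    return x, four_pl(x, L, h, alpha, beta)


class TestFourPL:
    def test_halfway_point_is_alpha_by_construction(self):
        assert four_pl(5.0, 100, 100, 5.0, 2.0) == pytest.approx(50.0)

    def test_zero_noise_recovers_truth(self):
        x, y = _series()
        fit = fit_4pl(x, y)
        assert fit.method == "nls" and fit.converged
        assert (fit.L, fit.h, fit.alpha, fit.beta) == pytest.approx(
            (100.0, 100.0, 5.0, 2.0), rel=1e-6
        )
        assert relative_ic50(fit) == pytest.approx(5.0, rel=1e-6)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match=">=4 distinct doses"):
            fit_4pl([50, 25, 12.5], [10, 20, 30])
        with pytest.raises(ValueError, match="positive"):
            fit_4pl([50, 25, -1, 6], [1, 2, 3, 4])

    def test_flat_series_falls_back_flagged(self):
        x = np.repeat(LADDER, 2)
        fit = fit_4pl(x, np.full(x.size, 80.0))
        assert fit.method == "smoothed"
        assert fit.alpha is None and not fit.converged
        assert relative_ic50(fit) is None

    def test_no_lower_plateau_uses_smoothing(self):
        x, y = _series(alpha=1000.0)  # midpoint far beyond the top dose
        fit = fit_4pl(x, y)
        assert fit.method == "smoothed"
        assert fit.L is None and fit.h is None and fit.beta is None

    def test_ic50_scale_equivariance(self):
        x, y = _series()
        a1 = fit_4pl(x, y).alpha
        a2 = fit_4pl(x * 3.0, y).alpha
        assert a2 == pytest.approx(3.0 * a1, rel=1e-6)

    def test_bias_vanishes_as_noise_shrinks(self):
        med_err = {}
        for cv in (0.10, 0.01, 0.0):
            errs = []
            for i in range(30):
                df = generate_dose_series(100, 100, 5.0, 2.0, DESIGN,
                                          noise_cv=cv, seed=1000 + i)
                fit = fit_4pl(df["concentration_uM"], df["response"])
                if fit.method == "nls":
                    errs.append(abs(fit.alpha - 5.0))
            med_err[cv] = np.median(errs)
        assert med_err[0.0] < 1e-6
        assert med_err[0.01] < med_err[0.10]


class TestSmoothedFallback:
    def test_consistent_with_parametric_fit_on_clean_curve(self):
        x, y = _series()
        fit = fit_smoothed(x, y)
        assert fit.alpha == pytest.approx(5.0, rel=0.05)

    def test_flat_series_has_undefined_ic50(self):
        x = np.repeat(LADDER, 2)
        fit = fit_smoothed(x, np.full(x.size, 50.0))
        assert fit.alpha is None and not fit.converged

    def test_crossing_is_bracketed_by_adjacent_doses(self):
        # responses step from top to bottom plateau between 6.25 and 3.125 uM
        y = np.where(LADDER >= 6.25, 20.0, 100.0)
        ramp = np.clip((np.log(LADDER) - np.log(3.125))
                       / (np.log(6.25) - np.log(3.125)), 0, 1)
        y = 100.0 - 80.0 * ramp
        fit = fit_smoothed(LADDER, y)
        assert 3.125 < fit.alpha < 6.25


class TestPctMaxInhibition:
    def test_definition_and_identity(self):
        x = np.array([0.39, 50.0, 0.39, 50.0])
        assert pct_max_inhibition(x, np.array([100, 20, 100, 20.0])) == pytest.approx(80.0)
        assert pct_max_inhibition(x, np.array([70, 70, 70, 70.0])) == 0.0

    def test_scale_invariance(self):
        x, y = _series()
        assert pct_max_inhibition(x, 7.3 * y) == pytest.approx(pct_max_inhibition(x, y))

    def test_zero_low_dose_response_rejected(self):
        x = np.array([0.39, 50.0])
        with pytest.raises(ValueError):
            pct_max_inhibition(x, np.array([0.0, 10.0]))

    def test_forward_simulated_high_inhibitor(self):
        # full plateaus, span 90.2% of the top: the observed-extremes metric
        # lands slightly under the true span because plateaus are finite
        x, y = _series(L=100.0, h=90.2, alpha=5.0, beta=2.0)
        assert pct_max_inhibition(x, y) == pytest.approx(90.2, abs=1.5)


class TestBootstrapCI:
    def test_zero_noise_gives_degenerate_interval(self):
        x, y = _series()
        fit = fit_4pl(x, y)
        lo, hi = ic50_ci(x, y, fit, n_boot=50, seed=0)
        assert lo == pytest.approx(5.0, rel=1e-5)
        assert hi == pytest.approx(5.0, rel=1e-5)

    def test_seed_stability(self):
        df = generate_dose_series(100, 100, 5.0, 2.0, DESIGN, noise_cv=0.05, seed=3)
        x = df["concentration_uM"].to_numpy()
        y = df["response"].to_numpy()
        fit = fit_4pl(x, y)
        assert ic50_ci(x, y, fit, n_boot=60, seed=9) == ic50_ci(x, y, fit, n_boot=60, seed=9)

    def test_skipped_for_smoothed_fits(self):
        x = np.repeat(LADDER, 2)
        fit = fit_smoothed(x, np.full(x.size, 50.0))
        assert ic50_ci(x, np.full(x.size, 50.0), fit, n_boot=10) is None

    def test_coverage_near_nominal(self):
        covered = 0
        n_sim = 40
        for i in range(n_sim):
            df = generate_dose_series(100, 100, 5.0, 2.0, DESIGN,
                                      noise_cv=0.05, seed=5000 + i)
            x = df["concentration_uM"].to_numpy()
            y = df["response"].to_numpy()
            fit = fit_4pl(x, y)
            ci = ic50_ci(x, y, fit, n_boot=199, seed=i)
            if ci and ci[0] <= 5.0 <= ci[1]:
                covered += 1
        assert covered >= 33  # ~95% nominal; binomial slack at n=40


class TestViabilityGate:
    def test_flat_healthy_not_toxic(self):
        assert viability_gate(5.0, LADDER, np.full(8, 100.0)) is False

    def test_dead_everywhere_toxic(self):
        assert viability_gate(5.0, LADDER, np.full(8, 20.0)) is True

    def test_toxicity_only_above_ic50_passes(self):
        viab = np.where(LADDER > 20, 30.0, 100.0)  # drops only at 25 and 50 uM
        assert viability_gate(2.0, LADDER, viab) is False

    def test_missing_viability_skips_gate(self):
        assert viability_gate(5.0, LADDER, None) is None
        assert viability_gate(5.0, LADDER, np.full(8, np.nan)) is None


def test_fit_dose_table_end_to_end():
    frames = [
        generate_dose_series(100, 90, 3.8, 1.5, DESIGN, noise_cv=0.0, seed=0,
                             compound_id="CID5282230", assay_context="BL2/tCD40L"),
        generate_dose_series(100, 0, None, 1.0, DESIGN, noise_cv=0.0, seed=1,
                             compound_id="Cflat", assay_context="BL2/tCD40L"),
    ]
    out = fit_dose_table(pd.concat(frames, ignore_index=True))
    out = out.set_index("compound_id")
    assert out.loc["CID5282230", "relative_ic50_uM"] == pytest.approx(3.8, rel=1e-4)
    assert out.loc["CID5282230", "method"] == "nls"
    assert out.loc["Cflat", "method"] == "smoothed"
    assert pd.isna(out.loc["Cflat", "relative_ic50_uM"])


def test_monotone_curve_for_positive_span_and_slope():
    x = np.sort(np.repeat(LADDER, 2))
    y = four_pl(x, 100, 80, 5.0, 1.7)
    assert (np.diff(y) <= 1e-12).all()
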