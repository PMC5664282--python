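"""Validation statistics: thresholds, LOD, verdicts, selectivity."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eggscreen import (
    CCBetaVerdict,
    CoverageError,
    InsufficientDataError,
    InterferentSpec,
    UndefinedLODError,
    ValidationDesign,
    ValidationSimConfig,
    ccbeta_verdict,
    cutoff_factor,
    lod,
    selectivity_check,
    sensitivity,
    simulate_validation,
    t_value,
    validate_panel,
)


# ---- independent oracles: direct arithmetic, no numpy ----

def naive_mean(xs):
    return sum(xs) / len(xs)


def naive_sd(xs):
    m = naive_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def naive_t(xs, k=1.64):
    return naive_mean(xs) + k * naive_sd(xs)


def naive_fc(xs, k=1.64):
    return naive_mean(xs) - k * naive_sd(xs)


def naive_sensitivity(xs, fc):
    return 100.0 * sum(1 for x in xs if x >= fc) / len(xs)


class TestTValue:
    def test_zero_spread(self):
        assert t_value([2.0] * 20) == 2.0

    def test_hand_arithmetic(self):
        # mean 2, sample sd 1 -> 2 + 1.64
        assert t_value([1.0, 2.0, 3.0]) == pytest.approx(3.64)

    def test_bimodal(self):
        xs = [1.0] * 10 + [3.0] * 10  # mean 2, sd sqrt(20/19)
        assert t_value(xs) == pytest.approx(2 + 1.64 * math.sqrt(20 / 19))

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            t_value([1.0])


class TestCutoffFactor:
    def test_zero_spread(self):
        assert cutoff_factor([100.0] * 60) == 100.0

    def test_bimodal(self):
        xs = [90.0] * 30 + [110.0] * 30  # mean 100, sd sqrt(6000/59)
        assert cutoff_factor(xs) == pytest.approx(100 - 1.64 * math.sqrt(6000 / 59))

    def test_negative_fc_returned_as_is(self):
        # mean 10, sd 10: Fc = 10 - 16.4 < 0, not clamped
        xs = [0.0, 20.0] * 10
        fc = cutoff_factor(xs)
        assert fc == pytest.approx(naive_fc(xs))
        assert fc < 0

    def test_too_few(self):
        with pytest.raises(InsufficientDataError):
            cutoff_factor([5.0])


class TestLOD:
    def test_noiseless_limit(self):
        assert lod(0.0, 10.0, 150.0) == 0.0

    def test_hand_arithmetic(self):
        assert lod(5.0, 10.0, 150.0) == pytest.approx(1.0)

    def test_identity_noise_one_third_of_response(self):
        # B = M/3 -> LOD = C, for any C and M
        for c, m in [(10.0, 60.0), (300.0, 9.0), (50.0, 1234.5)]:
            assert lod(m / 3.0, c, m) == pytest.approx(c)

    def test_undefined(self):
        with pytest.raises(UndefinedLODError):
            lod(5.0, 10.0, 0.0)


class TestVerdictAndSensitivity:
    def test_verdict_rule(self):
        assert ccbeta_verdict(120.0, 80.0) is CCBetaVerdict.below_level
        assert ccbeta_verdict(50.0, 80.0) is CCBetaVerdict.above_level

    def test_tie_is_above_level(self):
        assert ccbeta_verdict(80.0, 80.0) is CCBetaVerdict.above_level

    def test_sensitivity_values(self):
        xs = [10.0] * 19 + [1.0]
        assert sensitivity(xs, 5.0) == 95.0
        assert sensitivity([10.0] * 20, 5.0) == 100.0
        assert sensitivity([1.0] * 20, 5.0) == 0.0

    def test_tie_counts_as_detected(self):
        assert sensitivity([5.0, 10.0], 5.0) == 100.0

    def test_empty(self):
        with pytest.raises(InsufficientDataError):
            sensitivity([], 1.0)


# ---- property tests ----

finite_lists = st.lists(
    st.floats(min_value=0.0, max_value=1e6, allow_nan=False), min_size=2, max_size=10
)


@given(finite_lists)
def test_thresholds_match_naive_oracle(xs):
    assert t_value(xs) == pytest.approx(naive_t(xs), rel=1e-12, abs=1e-9)
    assert cutoff_factor(xs) == pytest.approx(naive_fc(xs), rel=1e-12, abs=1e-9)


@given(finite_lists, st.floats(min_value=0.0, max_value=1e6))
def test_sensitivity_matches_naive_oracle(xs, fc):
    s = sensitivity(xs, fc)
    assert s == pytest.approx(naive_sensitivity(xs, fc))
    assert s in {100.0 * i / len(xs) for i in range(len(xs) + 1)}


@given(finite_lists)
def test_t_above_mean_fc_below_mean(xs):
    m = naive_mean(xs)
    assert t_value(xs) >= m - 1e-9
    assert cutoff_factor(xs) <= m + 1e-9


@given(st.floats(min_value=0.01, max_value=1e3), st.floats(min_value=0.01, max_value=1e3),
       st.floats(min_value=0.01, max_value=1e6))
def test_lod_scaling_laws(b, c, m):
    base = lod(b, c, m)
    assert lod(2 * b, c, m) == pytest.approx(2 * base, rel=1e-12)
    assert lod(b, 2 * c, m) == pytest.approx(2 * base, rel=1e-12)
    assert lod(b, c, 2 * m) == pytest.approx(base / 2, rel=1e-12)


def test_monte_carlo_false_negative_rate():
    """Normal responses vs the population cut-off mu - 1.64 sigma miss with
    probability Phi(-1.64) ~ 5.05%; blank noise crosses the population
    T-value with the same frequency."""
    from scipy.stats import norm

    rng = np.random.default_rng(12345)
    mu, sigma = 100.0, 10.0
    draws = rng.normal(mu, sigma, size=100_000)
    frac_missed = np.mean(draws < mu - 1.64 * sigma)
    assert frac_missed == pytest.approx(norm.cdf(-1.64), abs=0.005)
    frac_blank_positive = np.mean(draws > mu + 1.64 * sigma)
    assert frac_blank_positive == pytest.approx(norm.cdf(-1.64), abs=0.005)


# ---- selectivity ----

class TestSelectivity:
    def test_interfering_blank_flagged(self, panel, records_factory):
        blanks = records_factory(
            [dict(analyte="flumequine", transition_rank="major", response=50.0,
                  noise=5.0, observed_rt=7.0, sample_kind="blank")]
        )
        flags = selectivity_check(blanks, panel)
        assert len(flags) == 1
        assert flags[0].analyte == "flumequine"
        assert flags[0].snr == pytest.approx(10.0)

    def test_clean_blanks_no_flags(self, panel, records_factory):
        blanks = records_factory(
            [dict(analyte="flumequine", transition_rank="major", response=0.0,
                  noise=0.0, observed_rt=7.0, sample_kind="blank")]
        )
        assert selectivity_check(blanks, panel) == []

    def test_peak_outside_rt_window_not_flagged(self, panel, records_factory):
        blanks = records_factory(
            [dict(analyte="flumequine", transition_rank="major", response=50.0,
                  noise=5.0, observed_rt=6.0, sample_kind="blank")]
        )
        assert selectivity_check(blanks, panel) == []


# ---- end-to-end validate_panel ----

class TestValidatePanel:
    def test_strong_signal_passes_everywhere(self, panel):
        cfg = ValidationSimConfig(seed=3, spike_mean=500.0, spike_sd=5.0,
                                  day_effect_sd=1.0, noise_mean=5.0, noise_sd=0.5)
        table = simulate_validation(cfg, panel, "oxytetracycline")
        results = validate_panel(table, panel)
        assert len(results) == 2
        for r in results:
            assert r.ccbeta_verdict is CCBetaVerdict.below_level
            # Fc sits 1.64 sd below the spike mean, so ~5% of a day's 20
            # replicates (binomially, sometimes 2) fall under it even for
            # a strong signal.
            assert r.sensitivity_pct >= 90.0
            assert r.n_spiked_fc == 60 and r.n_blanks == 20

    def test_interferent_sinks_only_target_transition(self, panel):
        cfg = ValidationSimConfig(
            seed=3, interferent=InterferentSpec(transition_rank="major", added_mean=1000.0)
        )
        results = validate_panel(simulate_validation(cfg, panel, "flumequine"), panel)
        verdicts = {r.transition_rank.value: r.ccbeta_verdict for r in results}
        assert verdicts["major"] is CCBetaVerdict.above_level
        assert verdicts["minor1"] is CCBetaVerdict.below_level

    def test_empty_table_is_coverage_error(self, panel, records_factory):
        with pytest.raises(CoverageError):
            validate_panel(records_factory([]), panel)

    def test_insufficient_replicates_reported_with_gap(self, panel, records_factory):
        rows = [dict(analyte="lincomycin", transition_rank=rank, sample_kind=kind,
                     response=10.0, noise=1.0)
                for rank in ("major", "minor1") for kind in ("blank", "spiked")]
        with pytest.raises(CoverageError, match="lincomycin/major"):
            validate_panel(records_factory(rows), panel, ValidationDesign())
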