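"""LER arithmetic, percent contrasts, peak-timing shifts, exudation bands."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from intercrop import metrics
from intercrop.errors import IntercropError
from intercrop.fitting import ParamSummary
from intercrop.metrics import _pair_shift  # antisymmetry checked on the primitive


def _summary(species, context, partner, response, nu, r, tm, se_tm=0.0, n=3):
    return ParamSummary(
        species=species, context=context, partner=partner, response=response,
        nu_max_mean=nu, nu_max_se=0.0, r_mean=r, r_se=0.0,
        t_max_mean=tm, t_max_se=se_tm, n_replicates=n,
    )


class TestLER:
    def test_published_partials_sum(self):
        res = metrics.compute_ler({"oat": 0.51, "lupin": 0.86}, {"oat": 1.0, "lupin": 1.0})
        assert res.partial == {"oat": 0.51, "lupin": 0.86}
        assert round(res.total, 2) == 1.37
        res = metrics.compute_ler({"oat": 0.96, "camelina": 0.18}, {"oat": 1.0, "camelina": 1.0})
        assert round(res.total, 2) == 1.14

    def test_equal_yields_give_total_two(self):
        res = metrics.compute_ler({"a": 3.0, "b": 7.0}, {"a": 3.0, "b": 7.0})
        assert res.total == pytest.approx(2.0)

    def test_total_is_sum_of_partials(self):
        res = metrics.compute_ler({"a": 1.2, "b": 0.4}, {"a": 2.0, "b": 1.0})
        assert res.total == pytest.approx(sum(res.partial.values()), abs=1e-12)

    def test_errors(self):
        with pytest.raises(IntercropError):
            metrics.compute_ler({"a": 1.0}, {"a": 0.0})
        with pytest.raises(IntercropError):
            metrics.compute_ler({"a": 1.0}, {"b": 1.0})

    def test_replicate_yields_give_se(self):
        res = metrics.compute_ler(
            {"a": [2.0, 2.2, 1.8], "b": [1.0, 1.1, 0.9]},
            {"a": [4.0, 4.0, 4.0], "b": [2.0, 2.0, 2.0]},
        )
        assert res.partial["a"] == pytest.approx(0.5)
        assert res.partial_se["a"] > 0
        assert res.total_se > 0

    @given(st.floats(0.01, 100.0))
    def test_scale_invariance(self, c):
        base = metrics.compute_ler({"a": 1.3, "b": 0.6}, {"a": 2.0, "b": 1.5})
        scaled = metrics.compute_ler(
            {"a": 1.3 * c, "b": 0.6 * c}, {"a": 2.0 * c, "b": 1.5 * c}
        )
        assert scaled.total == pytest.approx(base.total, rel=1e-9)


class TestPercentContrast:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (15.26, 11.35, 34),   # lupin B_max, mixture over monoculture
            (61.26, 38.70, 58),   # lupin P NU_max
            (516.4, 367.6, 40),   # lupin N NU_max
            (2.45, 1.50, 63),     # oat B_max, with camelina over monoculture
            (2.45, 1.62, 51),     # oat B_max, with camelina over with lupin
            (24.9, 15.15, 64),    # oat N NU_max
            (24.9, 17.45, 43),
            (0.73, 0.52, 40),     # camelina B_max, monoculture over mixture
            (5.0, 5.0, 0),
        ],
    )
    def test_printed_convention(self, a, b, expected):
        assert metrics.percent_contrast(a, b) == expected

    def test_rounds_half_away_from_zero(self):
        # 9/8 and 7/8 are binary-exact, giving contrasts of exactly +/-12.5
        assert metrics.percent_contrast(9.0, 8.0) == 13
        assert metrics.percent_contrast(7.0, 8.0) == -13

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(IntercropError):
            metrics.percent_contrast(1.0, 0.0)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    def test_reciprocal_contrasts_compose_to_unity(self, a, b):
        p_ab = metrics.percent_contrast(a, b)
        p_ba = metrics.percent_contrast(b, a)
        # each percent is within 0.5 of the true value, so the product can
        # deviate by at most 0.005*(R + 1/R) + 2.5e-5 for ratio R = a/b
        ratio = a / b
        bound = 0.005 * (ratio + 1 / ratio) + 2.5e-5
        assert abs((1 + p_ab / 100) * (1 + p_ba / 100) - 1) <= bound


class TestPeakRateContrast:
    def test_lupin_biomass_mixture_advantage(self):
        a = _summary("lupin", "mixture", "oat", "biomass", 15.26, 1.15, 9.71)
        b = _summary("lupin", "monoculture", "", "biomass", 11.35, 0.92, 9.44)
        assert metrics.peak_rate_contrast(a, b) == 68

    def test_oat_nitrogen_mixture_advantage(self):
        a = _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72)
        b = _summary("oat", "monoculture", "", "n", 15.15, 0.94, 7.68)
        assert metrics.peak_rate_contrast(a, b) == 150

    def test_identical_summaries_contrast_zero(self):
        a = _summary("oat", "monoculture", "", "n", 15.15, 0.94, 7.68)
        assert metrics.peak_rate_contrast(a, a) == 0

    def test_mixed_responses_rejected(self):
        a = _summary("oat", "monoculture", "", "n", 15.15, 0.94, 7.68)
        b = _summary("oat", "monoculture", "", "p", 7.23, 1.30, 8.56)
        with pytest.raises(IntercropError):
            metrics.peak_rate_contrast(a, b)


class TestTemporalDifferentiation:
    def test_oat_peaks_two_weeks_before_lupin(self):
        oat = _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72, se_tm=0.48)
        lupin = _summary("lupin", "mixture", "oat", "n", 516.4, 1.36, 8.98, se_tm=0.46)
        shifts = metrics.temporal_differentiation([oat, lupin], mode="inter")
        assert len(shifts) == 1
        s = shifts[0]
        assert s.key_a[0] == "lupin" and s.key_b[0] == "oat"  # sorted partner order
        assert s.delta_t_max == pytest.approx(2.26)           # lupin 2.26 weeks later
        assert s.direction == "later"
        assert s.se == pytest.approx(np.hypot(0.48, 0.46))

    def test_identical_trajectories_no_shift(self):
        a = _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72, se_tm=0.5)
        b = _summary("lupin", "mixture", "oat", "n", 516.4, 1.36, 6.72, se_tm=0.5)
        (s,) = metrics.temporal_differentiation([a, b], mode="inter")
        assert s.delta_t_max == 0 and s.direction == "none"

    def test_antisymmetry(self):
        a = _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72, se_tm=0.48)
        b = _summary("lupin", "mixture", "oat", "n", 516.4, 1.36, 8.98, se_tm=0.46)
        ab = _pair_shift(a, b, alpha=0.05)
        ba = _pair_shift(b, a, alpha=0.05)
        assert ab.delta_t_max == -ba.delta_t_max
        assert ab.se == ba.se

    def test_intra_mode_compares_contexts_within_species(self):
        rows = [
            _summary("oat", "monoculture", "", "n", 15.15, 0.94, 7.68, se_tm=0.43),
            _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72, se_tm=0.48),
            _summary("oat", "single", "", "n", 282.0, 0.61, 11.01, se_tm=1.05),
        ]
        shifts = metrics.temporal_differentiation(rows, mode="intra")
        assert len(shifts) == 3  # all context pairs

    def test_missing_partner_errors(self):
        lone = _summary("oat", "mixture", "lupin", "n", 17.45, 2.04, 6.72)
        with pytest.raises(IntercropError, match="lupin-oat"):
            metrics.temporal_differentiation([lone], mode="inter")


class TestExudationSummary:
    @staticmethod
    def _frame(oa_values, roots=None):
        import pandas as pd

        n = len(oa_values)
        return pd.DataFrame(
            {
                "species": ["oat"] * n, "context": ["monoculture"] * n,
                "partner": [""] * n, "week": [6] * n,
                "block_id": range(1, n + 1), "individual_id": [1] * n,
                "oa_umol": oa_values, "root_dw_g": roots or [1.0] * n,
            }
        )

    def test_textbook_t_band(self):
        out = metrics.exudation_summary(self._frame([1.0, 2.0, 3.0]))
        row = out.iloc[0]
        assert row["oa_mean_umol_per_g"] == pytest.approx(2.0)
        assert row["se"] == pytest.approx(0.5774, abs=1e-4)
        assert row["band_halfwidth"] == pytest.approx(2.484, abs=1e-3)

    def test_identical_values_zero_band(self):
        out = metrics.exudation_summary(self._frame([4.0, 4.0, 4.0]))
        assert out.iloc[0]["band_halfwidth"] == pytest.approx(0.0)

    def test_single_observation_flagged(self):
        out = metrics.exudation_summary(self._frame([4.0]))
        assert out.iloc[0]["flag"] == "n=1"
        assert np.isnan(out.iloc[0]["band_halfwidth"])

    def test_zero_root_mass_excluded(self):
        out = metrics.exudation_summary(self._frame([1.0, 2.0, 3.0], roots=[1.0, 0.0, 1.0]))
        assert out.iloc[0]["n"] == 2
        assert out.attrs["n_excluded_zero_root"] == 1
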