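"""Starting-value heuristic, two-stage fits, aggregation, and calibration."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import minimize

from intercrop import fitting, synthetic
from intercrop.errors import InsufficientDataError, NonIdentifiableError
from intercrop.growth import LogisticParams, logistic_value

TRUTH = LogisticParams(15.26, 1.15, 9.71)  # lupin-in-mixture biomass curve
WEEKS = np.arange(1, 19, dtype=float)


def _series(truth=TRUTH, cv=0.0, seed=0, weeks=WEEKS, n_rep=1):
    noise = synthetic.NoiseSpec(cv_or_sd=cv, seed=seed)
    return synthetic.generate_trajectory(truth, weeks, noise, n_rep)


class TestInitialValues:
    def test_heuristic_on_clean_series(self):
        obs = logistic_value(LogisticParams(10, 1, 5), WEEKS)
        init = fitting.initial_values(WEEKS, obs)
        assert init.nu_max == pytest.approx(1.05 * obs.max())
        assert init.nu_max == pytest.approx(10.5, rel=1e-3)
        assert init.t_max == 5
        assert 0.5 <= init.r <= 2.0

    def test_constant_series_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fitting.initial_values(WEEKS, np.full_like(WEEKS, 3.0))

    def test_all_zero_series_not_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            fitting.initial_values(WEEKS, np.zeros_like(WEEKS))

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            fitting.initial_values([5], [2.0])


class TestFitLogistic:
    def test_noiseless_recovery_to_machine_precision(self):
        obs = _series()[:, 0]
        fit = fitting.fit_logistic(WEEKS, obs)
        assert fit.converged
        assert fit.params.as_array() == pytest.approx(TRUTH.as_array(), rel=1e-6)
        assert fit.residual_sse < 1e-12
        assert np.all(fit.std_errors >= 0)

    def test_too_few_points_raise(self):
        with pytest.raises(InsufficientDataError):
            fitting.fit_logistic(WEEKS[:4], _series()[:4, 0])

    def test_truncated_preplateau_data_flagged(self):
        """Without a plateau the asymptote is non-identifiable and diagnosed."""
        obs = _series(cv=0.10, seed=3)[:, 0]
        fit = fitting.fit_logistic(WEEKS[:6], obs[:6])
        assert (not fit.converged) or fit.flags
        assert not fit.identifiable or "t_max_at_bound" in fit.flags

    def test_matches_grid_refinement_oracle(self, rng):
        """Two-stage fit reaches the same SSE as an exhaustive grid + polish."""
        for _ in range(20):
            truth = LogisticParams(
                rng.uniform(1, 100), rng.uniform(0.3, 2.0), rng.uniform(4, 14)
            )
            obs = logistic_value(truth, WEEKS)

            def sse(x):
                if x[0] <= 0 or x[1] <= 0:
                    return np.inf
                return float(
                    np.sum((logistic_value(LogisticParams(*x), WEEKS) - obs) ** 2)
                )

            best = None
            for nu in np.linspace(0.5 * obs.max(), 2.0 * obs.max(), 8):
                for r in np.linspace(0.1, 3.0, 8):
                    for tm in np.linspace(2, 16, 8):
                        res = minimize(sse, [nu, r, tm], method="Nelder-Mead")
                        if best is None or res.fun < best:
                            best = res.fun
            fit = fitting.fit_logistic(WEEKS, obs)
            assert abs(fit.residual_sse - best) < 1e-8

    def test_more_harvests_reduce_error(self):
        """Parameter RMSE with 18 weekly harvests <= with 9 biweekly harvests."""
        dense, sparse = WEEKS, WEEKS[::2]

        def rmse(weeks):
            errs = []
            for seed in range(100, 140):
                obs = _series(cv=0.10, seed=seed, weeks=weeks)[:, 0]
                fit = fitting.fit_logistic(weeks, obs)
                if fit.converged:
                    errs.append(fit.params.as_array() / TRUTH.as_array() - 1)
            return float(np.sqrt((np.array(errs) ** 2).mean()))

        assert rmse(dense) <= rmse(sparse)

    def test_wald_interval_calibration(self):
        """95% t-based Wald intervals for NU_max cover the truth 90-99% of
        the time when the noise matches the estimator (additive gaussian)."""
        tq = stats.t.ppf(0.975, len(WEEKS) - 3)
        cover = n = 0
        for seed in range(500):
            noise = synthetic.NoiseSpec(model="additive-gaussian", cv_or_sd=0.5, seed=seed)
            obs = synthetic.generate_trajectory(TRUTH, WEEKS, noise, 1)[:, 0]
            fit = fitting.fit_logistic(WEEKS, obs)
            if fit.converged and np.isfinite(fit.std_errors[0]):
                n += 1
                cover += abs(fit.params.nu_max - TRUTH.nu_max) <= tq * fit.std_errors[0]
        assert n >= 450
        assert 0.90 <= cover / n <= 0.99


class TestFitAll:
    def test_full_design_fit_count(self, noiseless_dataset):
        fits, summary = fitting.fit_all(noiseless_dataset)
        # 10 species x context combos, 3 responses, 3 replicates
        assert len(fits) == 90
        assert len(summary) == 30
        assert all(f.converged for f in fits)

    def test_absent_response_degrades_gracefully(self, design, truth):
        growth = dict(truth.growth)
        del growth[("camelina", "single", "n")]
        slim = synthetic.TruthSet(
            growth=growth, ndfa_true=truth.ndfa_true,
            beta_by_week=truth.beta_by_week,
            ref_delta15n_by_week=truth.ref_delta15n_by_week,
        )
        df = synthetic.generate_experiment(
            design, slim, synthetic.NoiseSpec(cv_or_sd=0.0, seed=0), allow_missing=True
        )
        fits, _ = fitting.fit_all(df)
        assert len(fits) == 87

    def test_output_is_deterministic(self, noisy_dataset):
        f1, s1 = fitting.fit_all(noisy_dataset)
        f2, s2 = fitting.fit_all(noisy_dataset)
        assert fitting.fits_frame(f1).equals(fitting.fits_frame(f2))
        assert s1.equals(s2)

    def test_pooled_mode_fits_once_per_trajectory(self, noiseless_dataset):
        fits, summary = fitting.fit_all(noiseless_dataset, per_replicate=False)
        assert len(fits) == 30
        assert all(f.replicate is None for f in fits)
        # pooled noiseless fits also recover truth
        f = next(x for x in fits if (x.species, x.context, x.response) == ("lupin", "mixture", "biomass"))
        assert f.params.as_array() == pytest.approx(TRUTH.as_array(), rel=1e-6)

    def test_summary_recovers_truth_means(self, noisy_dataset, truth):
        _, summary = fitting.fit_all(noisy_dataset)
        row = summary[
            (summary["species"] == "lupin")
            & (summary["context"] == "mixture")
            & (summary["response"] == "biomass")
        ].iloc[0]
        tr = truth.growth[("lupin", "mixture:oat", "biomass")]
        assert row["nu_max_mean"] == pytest.approx(tr.nu_max, rel=0.15)
        assert row["t_max_mean"] == pytest.approx(tr.t_max, abs=1.0)
        assert row["n_replicates"] == 3
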