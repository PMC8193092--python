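"""Two-stage nonlinear least-squares estimation of logistic parameters.

Each trajectory — one (species, context, response, replicate) time series of
weekly cumulative values — is fitted by minimizing the residual sum of
squares of the three-parameter logistic curve.  Mirroring the common
practice of seeding a plain Gauss-Newton fit with a damped
Levenberg-Marquardt solution, stage 1 runs a damped (trust-region) least
squares pass from heuristic starting values and stage 2 polishes from the
stage-1 optimum at tight tolerances.  Per-replicate estimates are then
aggregated to mean +/- SE summaries (n = number of converged replicate
fits), the form in which trial results are reported.

Fits are bounded (nu_max > 0, r > 0, 0 < t_max < 2 x last week) and always
return a :class:`FitResult`; non-convergence sets ``converged=False`` rather
than raising.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import InsufficientDataError, NonIdentifiableError
from .growth import LogisticParams, logistic_value

__all__ = [
    "FitResult",
    "ParamSummary",
    "initial_values",
    "fit_logistic",
    "fit_all",
    "summaries_from_frame",
    "MIN_POINTS",
]

log = logging.getLogger("intercrop.fitting")

#: Minimum (week, value) points for a fit to be attempted.
MIN_POINTS = 5
#: Optimizer tolerances / iteration cap, echoed into output metadata.
FIT_TOLERANCES = {"ftol": 1e-12, "xtol": 1e-12, "gtol": 1e-10, "max_nfev": 1000}
_R_FLOOR = 0.05


@dataclass
class FitResult:
    """One fitted trajectory with uncertainty and diagnostics."""

    species: str | None
    context: str | None
    partner: str | None
    response: str | None
    replicate: int | None
    params: LogisticParams | None
    std_errors: np.ndarray | None          # SE of (nu_max, r, t_max)
    covariance: np.ndarray | None          # 3x3
    residual_sse: float
    n_points: int
    converged: bool
    n_iterations: int
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def identifiable(self) -> bool:
        """False when the asymptote SE exceeds its estimate (no plateau seen)."""
        if not self.converged or self.params is None or self.std_errors is None:
            return False
        return bool(self.std_errors[0] < self.params.nu_max)


@dataclass(frozen=True)
class ParamSummary:
    """Mean +/- SE of logistic parameters across replicate fits."""

    species: str
    context: str
    partner: str
    response: str
    nu_max_mean: float
    nu_max_se: float
    r_mean: float
    r_se: float
    t_max_mean: float
    t_max_se: float
    n_replicates: int


def _clean_series(weeks, values):
    weeks = np.asarray(weeks, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(weeks) & np.isfinite(values)
    return weeks[keep], values[keep]


def initial_values(weeks, values) -> LogisticParams:
    """Heuristic starting values for the logistic fit.

    nu_max0 is 1.05 x the observed maximum; t_max0 the earliest week whose
    value reaches half the observed maximum; r0 the slope of a straight line
    through logit(value / nu_max0) over the interior points (5-95% of the
    provisional asymptote), floored at 0.05 per week.
    """
    weeks, values = _clean_series(weeks, values)
    if weeks.size < MIN_POINTS or np.unique(weeks).size < 3:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} points on >= 3 distinct weeks, got {weeks.size}"
        )
    vmax = values.max(initial=-np.inf)
    if not (vmax > 0) or np.ptp(values) == 0:
        raise NonIdentifiableError("series is constant or non-positive; no growth signal")
    nu_max0 = 1.05 * vmax
    t_max0 = float(weeks[values >= 0.5 * vmax].min())
    frac = values / nu_max0
    interior = (frac > 0.05) & (frac < 0.95)
    r0 = _R_FLOOR
    if interior.sum() >= 2 and np.unique(weeks[interior]).size >= 2:
        logit = np.log(frac[interior] / (1.0 - frac[interior]))
        slope = np.polyfit(weeks[interior], logit, 1)[0]
        r0 = max(slope, _R_FLOOR)
    return LogisticParams(nu_max=nu_max0, r=r0, t_max=max(t_max0, 1e-6))


def fit_logistic(
    weeks,
    values,
    init: LogisticParams | None = None,
    key: tuple = (None, None, None, None, None),
) -> FitResult:
    """Fit one trajectory; returns a FitResult, never raises on non-convergence."""
    weeks, obs = _clean_series(weeks, values)
    if weeks.size < MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} points, got {weeks.size}"
        )
    if init is None:
        init = initial_values(weeks, obs)

    t_hi = 2.0 * weeks.max()
    lb = np.array([1e-12, 1e-6, 1e-9])
    ub = np.array([np.inf, 200.0, t_hi])
    x0 = np.clip(init.as_array(), lb * (1 + 1e-9), np.minimum(ub * (1 - 1e-9), 1e300))

    def resid(x):
        return logistic_value(LogisticParams(*x), weeks) - obs

    stage1 = least_squares(resid, x0, bounds=(lb, ub), method="trf", **FIT_TOLERANCES)
    stage2 = least_squares(resid, stage1.x, bounds=(lb, ub), method="trf", **FIT_TOLERANCES)
    nfev = int(stage1.nfev + stage2.nfev)
    best = stage2 if stage2.cost <= stage1.cost else stage1

    x = best.x
    sse = float(2.0 * best.cost)
    n = weeks.size
    converged = bool(best.status > 0)
    flags: list[str] = []

    dof = n - 3
    J = best.jac
    cov = None
    se = None
    if dof > 0:
        s2 = sse / dof
        try:
            cov = s2 * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            flags.append("covariance_failed")
    if se is None or not np.all(np.isfinite(se)):
        flags.append("se_undefined")
        converged = False
        se = np.full(3, np.nan) if se is None else se
    params = LogisticParams(*x)
    if se is not None and np.isfinite(se[0]) and se[0] >= params.nu_max:
        flags.append("nonidentifiable_numax")
    if x[2] >= 0.999 * t_hi:
        flags.append("t_max_at_bound")

    return FitResult(
        species=key[0], context=key[1], partner=key[2], response=key[3], replicate=key[4],
        params=params, std_errors=se, covariance=cov, residual_sse=sse,
        n_points=n, converged=converged, n_iterations=nfev, flags=tuple(flags),
    )


_RESPONSE_COLS = {"biomass": "biomass_g", "n": "n_mg", "p": "p_mg"}


def fit_all(
    dataset: pd.DataFrame,
    per_replicate: bool = True,
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every (species, context, partner, response[, replicate]) trajectory.

    Per-replicate fitting (default) treats each block's weekly series as one
    trajectory and reports mean +/- SE across replicate estimates; the
    pooled alternative fits all blocks' points jointly.  Groups with fewer
    than :data:`MIN_POINTS` valid points, or no growth signal, are skipped
    with a structured warning.  Output order is deterministic by key.
    """
    fits: list[FitResult] = []
    group_cols = ["species", "context", "partner", "block_id"] if per_replicate \
        else ["species", "context", "partner"]
    grouped = dataset.groupby(group_cols, dropna=False, sort=True)
    for key, grp in grouped:
        if per_replicate:
            species, context, partner, block = key
        else:
            species, context, partner = key
            block = None
        for response, col in _RESPONSE_COLS.items():
            sub = grp[["week", col]].dropna()
            if len(sub) < MIN_POINTS:
                log.warning(
                    "skipping %s/%s/%s/%s rep=%s: %d valid points (< %d)",
                    species, context, partner, response, block, len(sub), MIN_POINTS,
                )
                continue
            try:
                fit = fit_logistic(
                    sub["week"], sub[col],
                    key=(species, context, partner, response, block),
                )
            except (InsufficientDataError, NonIdentifiableError) as exc:
                log.warning(
                    "skipping %s/%s/%s/%s rep=%s: %s",
                    species, context, partner, response, block, exc,
                )
                continue
            fits.append(fit)
    summary = summarize(fits)
    return fits, summary


def summarize(fits: list[FitResult]) -> pd.DataFrame:
    """Aggregate converged fits to a mean +/- SE table (one row per trajectory).

    SE is sd/sqrt(n) over replicate estimates; NaN when fewer than two
    converged replicates exist.  Excluded (non-converged) fits are counted.
    """
    rows: dict[tuple, dict] = {}
    for f in fits:
        k = (f.species, f.context, f.partner, f.response)
        rows.setdefault(k, {"est": [], "n_excluded": 0})
        if f.converged:
            rows[k]["est"].append(f.params.as_array())
        else:
            rows[k]["n_excluded"] += 1
    out = []
    for k in sorted(rows, key=lambda t: tuple(str(x) for x in t)):
        est = np.array(rows[k]["est"])
        n = len(est)
        if n == 0:
            means = np.full(3, np.nan)
            ses = np.full(3, np.nan)
        else:
            means = est.mean(axis=0)
            ses = est.std(axis=0, ddof=1) / np.sqrt(n) if n >= 2 else np.full(3, np.nan)
        out.append(
            {
                "species": k[0], "context": k[1], "partner": k[2], "response": k[3],
                "nu_max_mean": means[0], "nu_max_se": ses[0],
                "r_mean": means[1], "r_se": ses[1],
                "t_max_mean": means[2], "t_max_se": ses[2],
                "n_replicates": n, "n_excluded": rows[k]["n_excluded"],
            }
        )
    return pd.DataFrame(out)


def fits_frame(fits: list[FitResult]) -> pd.DataFrame:
    """Flatten FitResults to one row per fit (for the fits CSV)."""
    rows = []
    for f in fits:
        p = f.params
        se = f.std_errors if f.std_errors is not None else np.full(3, np.nan)
        rows.append(
            {
                "species": f.species, "context": f.context, "partner": f.partner,
                "response": f.response, "replicate": f.replicate,
                "nu_max": p.nu_max if p else np.nan,
                "r": p.r if p else np.nan,
                "t_max": p.t_max if p else np.nan,
                "nu_max_se": se[0], "r_se": se[1], "t_max_se": se[2],
                "sse": f.residual_sse, "n_points": f.n_points,
                "converged": f.converged, "n_iterations": f.n_iterations,
                "flags": ";".join(f.flags),
            }
        )
    return pd.DataFrame(rows)


def summaries_from_frame(summary: pd.DataFrame) -> list[ParamSummary]:
    """Typed view of a summary table's rows."""
    out = []
    for row in summary.itertuples(index=False):
        out.append(
            ParamSummary(
                species=row.species, context=row.context, partner=row.partner,
                response=row.response,
                nu_max_mean=row.nu_max_mean, nu_max_se=row.nu_max_se,
                r_mean=row.r_mean, r_se=row.r_se,
                t_max_mean=row.t_max_mean, t_max_se=row.t_max_se,
                n_replicates=int(row.n_replicates),
            )
        )
    return out
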