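"""Comparative statistics of the temporal-niche analysis.

Covers the Land Equivalent Ratio (LER) decomposition, signed percent
contrasts between cumulative maxima and peak instantaneous rates, temporal
differentiation of peak-rate timing (t_max shifts within a species across
contexts, or between the two partners of a mixture), and the per-week
rhizosphere organic-acid summaries with t-based standard-error bands.

Conventions follow the trial's reporting: contrasts are ratios of mean
parameters rounded to whole percent (half away from zero), LER to two
decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, IntercropError
from .fitting import ParamSummary

__all__ = [
    "LERResult",
    "TemporalShift",
    "compute_ler",
    "ler_from_harvest",
    "percent_contrast",
    "peak_rate_contrast",
    "temporal_differentiation",
    "exudation_summary",
]


@dataclass(frozen=True)
class LERResult:
    """Land equivalent ratio of one mixture.

    ``partial[s]`` is species ``s``'s mixture yield divided by its
    monoculture yield; ``total`` their sum.  Values above 1 indicate a
    mixture yield advantage over the component monocultures.
    """

    partial: dict[str, float]
    total: float
    partial_se: dict[str, float] | None = None
    total_se: float | None = None
    mixture_yields: dict[str, float] | None = None
    monoculture_yields: dict[str, float] | None = None


@dataclass(frozen=True)
class TemporalShift:
    """Difference in peak-rate timing between two trajectories (first - second)."""

    key_a: tuple[str, str, str, str]
    key_b: tuple[str, str, str, str]
    delta_t_max: float        # weeks; negative = first peaks earlier
    se: float
    direction: str            # "earlier" | "later" | "none" (for the first key)


def _as_arrays(yields: Mapping[str, float | Sequence[float]]) -> dict[str, np.ndarray]:
    return {s: np.atleast_1d(np.asarray(v, dtype=float)) for s, v in yields.items()}


def compute_ler(
    mixture_yields: Mapping[str, float | Sequence[float]],
    monoculture_yields: Mapping[str, float | Sequence[float]],
) -> LERResult:
    """LER from per-species plot yields (scalars, or replicate sequences).

    With replicate sequences of equal length, replicates are paired by
    position (block order) to yield per-block partials, reported as
    mean +/- SE.  Scale-invariant: rescaling all yields by c > 0 changes
    nothing.
    """
    mix = _as_arrays(mixture_yields)
    mono = _as_arrays(monoculture_yields)
    if set(mix) != set(mono):
        raise IntercropError(
            f"species mismatch: mixture has {sorted(mix)}, monoculture {sorted(mono)}"
        )
    partial: dict[str, float] = {}
    partial_se: dict[str, float] = {}
    per_block_totals: np.ndarray | None = None
    have_reps = all(v.size > 1 for v in mix.values()) and all(v.size > 1 for v in mono.values())
    for s in sorted(mix):
        m, mo = mix[s], mono[s]
        if np.any(mo <= 0):
            raise IntercropError(f"monoculture yield of {s!r} must be > 0")
        if np.any(m < 0):
            raise IntercropError(f"mixture yield of {s!r} must be >= 0")
        if have_reps and m.size == mo.size:
            ratios = m / mo
            partial[s] = float(ratios.mean())
            partial_se[s] = float(ratios.std(ddof=1) / np.sqrt(ratios.size))
            per_block_totals = ratios if per_block_totals is None else per_block_totals + ratios
        else:
            partial[s] = float(m.mean() / mo.mean())
    total = float(sum(partial.values()))
    total_se = (
        float(per_block_totals.std(ddof=1) / np.sqrt(per_block_totals.size))
        if per_block_totals is not None else None
    )
    return LERResult(
        partial=partial,
        total=total,
        partial_se=partial_se or None,
        total_se=total_se,
        mixture_yields={s: float(v.mean()) for s, v in mix.items()},
        monoculture_yields={s: float(v.mean()) for s, v in mono.items()},
    )


def ler_from_harvest(dataset: pd.DataFrame, yield_weeks: Sequence[int] | None = None) -> dict[str, LERResult]:
    """LER per mixture from the harvest table's plot-level yields.

    Uses ``plot_yield_g`` from the final two harvest weeks by default (the
    trial's convention for final grain yield), averaged per block.
    """
    with_yield = dataset.dropna(subset=["plot_yield_g"])
    if yield_weeks is None:
        weeks = sorted(with_yield["week"].unique())
        yield_weeks = weeks[-2:]
    sub = with_yield[with_yield["week"].isin(list(yield_weeks))]
    if sub.empty:
        raise IntercropError("no plot_yield_g records in the requested weeks")
    out: dict[str, LERResult] = {}
    mixtures = sub[sub["context"] == "mixture"]
    for pair_key, grp in mixtures.groupby(
        mixtures.apply(lambda r: "-".join(sorted([r["species"], r["partner"]])), axis=1)
    ):
        mix_y = {}
        mono_y = {}
        for s in sorted(grp["species"].unique()):
            mix_y[s] = (
                grp[grp["species"] == s].groupby("block_id")["plot_yield_g"].mean().to_numpy()
            )
            mono_rows = sub[(sub["species"] == s) & (sub["context"] == "monoculture")]
            if mono_rows.empty:
                raise IntercropError(f"no monoculture yields for {s!r}")
            mono_y[s] = mono_rows.groupby("block_id")["plot_yield_g"].mean().to_numpy()
        out[pair_key] = compute_ler(mix_y, mono_y)
    return out


def percent_contrast(a: float, b: float) -> int:
    """Signed percent difference of a relative to b: round((a/b - 1)*100).

    Rounded to the nearest integer, halves away from zero (the reporting
    convention for "x% more/higher").
    """
    if not b > 0:
        raise IntercropError(f"contrast baseline must be > 0, got {b}")
    x = (a / b - 1.0) * 100.0
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def peak_rate_contrast(summary_a: ParamSummary, summary_b: ParamSummary) -> int:
    """Percent contrast of peak instantaneous rates I = r_mean * nu_max_mean / 4.

    Computed from each summary's mean parameters (ratio of means, not mean
    of per-replicate ratios).
    """
    if summary_a.response != summary_b.response:
        raise IntercropError(
            f"summaries compare different responses: "
            f"{summary_a.response!r} vs {summary_b.response!r}"
        )
    i_a = summary_a.r_mean * summary_a.nu_max_mean / 4.0
    i_b = summary_b.r_mean * summary_b.nu_max_mean / 4.0
    return percent_contrast(i_a, i_b)


def _pair_shift(a: ParamSummary, b: ParamSummary, alpha: float) -> TemporalShift:
    delta = a.t_max_mean - b.t_max_mean
    se_a = a.t_max_se if np.isfinite(a.t_max_se) else 0.0
    se_b = b.t_max_se if np.isfinite(b.t_max_se) else 0.0
    se = math.sqrt(se_a**2 + se_b**2)
    direction = "none"
    if delta != 0 and se > 0:
        df = max(a.n_replicates + b.n_replicates - 2, 1)
        tval = abs(delta) / se
        p = 2.0 * stats.t.sf(tval, df)
        if p < alpha:
            direction = "earlier" if delta < 0 else "later"
    return TemporalShift(
        key_a=(a.species, a.context, a.partner, a.response),
        key_b=(b.species, b.context, b.partner, b.response),
        delta_t_max=delta, se=se, direction=direction,
    )


def temporal_differentiation(
    summaries: Sequence[ParamSummary],
    mode: str,
    alpha: float = 0.05,
) -> list[TemporalShift]:
    """Peak-timing shifts between trajectories.

    ``intra`` compares each species with itself across community contexts
    (all context pairs, per response); ``inter`` compares the two partners
    within each mixture (per response).  Shifts are first minus second, so
    a negative value means the first trajectory peaks earlier; the
    direction label applies the same t-test convention used for the letter
    displays.
    """
    if mode not in ("intra", "inter"):
        raise ConfigurationError(f"mode must be 'intra' or 'inter', got {mode!r}")
    shifts: list[TemporalShift] = []
    if mode == "intra":
        by_sp: dict[tuple[str, str], list[ParamSummary]] = {}
        for s in summaries:
            by_sp.setdefault((s.species, s.response), []).append(s)
        for key in sorted(by_sp):
            group = sorted(by_sp[key], key=lambda s: (s.context, s.partner))
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    shifts.append(_pair_shift(group[i], group[j], alpha))
    else:
        mixtures: dict[tuple[str, str], dict[str, ParamSummary]] = {}
        for s in summaries:
            if s.context == "mixture":
                pair = "-".join(sorted([s.species, s.partner]))
                mixtures.setdefault((pair, s.response), {})[s.species] = s
        for (pair, response) in sorted(mixtures):
            members = mixtures[(pair, response)]
            names = sorted(members)
            if len(names) != 2:
                raise IntercropError(
                    f"mixture {pair!r} ({response}) is missing a partner summary: "
                    f"have {names}"
                )
            shifts.append(_pair_shift(members[names[0]], members[names[1]], alpha))
    return shifts


def exudation_summary(dataset: pd.DataFrame, conf: float = 0.95) -> pd.DataFrame:
    """Rhizosphere organic acids per g root dry weight, per group and week.

    Each plant's organic-acid total (umol) is divided by its root dry
    weight (g); rows with zero/absent root mass are excluded with a
    warning flag in the output.  Per (species, context, partner, week) the
    mean, SE and a t-based band half-width SE * t_{(1+conf)/2, n-1} are
    reported; the band is NaN (flagged) for n = 1.
    """
    sub = dataset.dropna(subset=["oa_umol", "root_dw_g"]).copy()
    n_zero_root = int((sub["root_dw_g"] <= 0).sum())
    sub = sub[sub["root_dw_g"] > 0]
    sub["oa_per_g_root"] = sub["oa_umol"] / sub["root_dw_g"]
    rows = []
    for key, grp in sub.groupby(["species", "context", "partner", "week"], sort=True):
        v = grp["oa_per_g_root"].to_numpy()
        n = v.size
        mean = float(v.mean())
        if n >= 2:
            se = float(v.std(ddof=1) / np.sqrt(n))
            half = se * float(stats.t.ppf(0.5 + conf / 2.0, n - 1))
            flag = ""
        else:
            se, half, flag = np.nan, np.nan, "n=1"
        rows.append(
            {
                "species": key[0], "context": key[1], "partner": key[2], "week": key[3],
                "oa_mean_umol_per_g": mean, "se": se, "band_halfwidth": half,
                "n": n, "flag": flag,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["n_excluded_zero_root"] = n_zero_root
    return out
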