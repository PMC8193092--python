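"""15N natural-abundance estimation of biological N2 fixation.

The fraction of a legume's above-ground N derived from the atmosphere is
estimated by isotope dilution:

    %Ndfa = 100 * (d15N_ref - d15N_legume) / (d15N_ref - beta)

where ``d15N_ref`` is the mean delta-15N of a non-fixing reference plant
grown at the same diversity level and week, ``d15N_legume`` the legume's
delta-15N, and ``beta`` the legume's signature when grown on atmospheric N2
only (greenhouse calibration, supplied as a per-week table).

Reference-plant rule: oat when available, otherwise camelina, matched by
diversity level — oat from the oat-camelina mixture serves as reference for
mixtures (the oat-lupin oat may itself receive legume-derived N), oat
monoculture for monocultures, and isolated single oat for single plants.

Estimates outside [0, 100] are reported and flagged, never clamped, so
calibration problems stay visible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CalibrationError, IntercropError, ReferencePlantError

__all__ = ["NdfaRecord", "ndfa", "select_reference", "ndfa_timeseries", "LEGUME"]

LEGUME = "lupin"
_REFERENCE_PREFERENCE = ("oat", "camelina")


@dataclass(frozen=True)
class NdfaRecord:
    """Weekly %Ndfa at one diversity level, with estimation provenance."""

    week: int
    diversity: str
    ndfa_mean: float
    ndfa_se: float
    n: int                     # legume replicate plots
    delta_ref: float
    delta_legume_mean: float
    beta: float
    ref_species: str
    ref_n: int
    flags: tuple[str, ...]


def ndfa(delta_ref: float, delta_legume, beta: float):
    """Percent N derived from the atmosphere (may fall outside [0, 100]).

    Raises when ``delta_ref == beta`` (undefined denominator).  Accepts a
    scalar or array ``delta_legume``.
    """
    if delta_ref == beta:
        raise IntercropError(
            f"delta15N_ref equals beta ({beta} per mil): %Ndfa denominator is zero"
        )
    delta_legume = np.asarray(delta_legume, dtype=float)
    out = 100.0 * (delta_ref - delta_legume) / (delta_ref - beta)
    return out if out.ndim else float(out)


def select_reference(dataset: pd.DataFrame, week: int, diversity: str) -> tuple[float, str, int]:
    """Mean reference-plant delta15N at one week x diversity level.

    Returns ``(mean delta15N, species used, n plots)``.  Averages the
    plot-level values (each already the pooled sample of the plot's three
    individuals), then across replicate plots.  Prefers oat, falling back
    to camelina; at the mixture level the oat-camelina oat is used.
    """
    at_week = dataset[(dataset["week"] == week) & dataset["delta15n_permil"].notna()]
    for species in _REFERENCE_PREFERENCE:
        rows = at_week[(at_week["species"] == species) & (at_week["context"] == diversity)]
        if diversity == "mixture" and species == "oat":
            preferred = rows[rows["partner"] == "camelina"]
            rows = preferred if not preferred.empty else rows
        if not rows.empty:
            per_plot = rows.groupby("block_id")["delta15n_permil"].mean()
            return float(per_plot.mean()), species, int(per_plot.size)
    raise ReferencePlantError(
        f"no non-legume delta15N records at week {week}, diversity {diversity!r}"
    )


def ndfa_timeseries(
    dataset: pd.DataFrame,
    beta_table: pd.DataFrame,
    legume: str = LEGUME,
) -> pd.DataFrame:
    """Weekly %Ndfa per diversity level (mean +/- SE over legume plots).

    ``beta_table`` has columns (week, beta_permil).  Every week with legume
    delta15N must have a beta entry; missing weeks raise, listing them.
    Out-of-range estimates are flagged per record.
    """
    beta = dict(zip(beta_table["week"].astype(int), beta_table["beta_permil"].astype(float)))
    leg = dataset[(dataset["species"] == legume) & dataset["delta15n_permil"].notna()]
    if leg.empty:
        raise IntercropError(f"no delta15N records for legume {legume!r}")
    missing = sorted(set(leg["week"].astype(int)) - set(beta))
    if missing:
        raise CalibrationError(f"no beta calibration for weeks {missing}")
    records = []
    for (week, diversity), grp in leg.groupby(["week", "context"], sort=True):
        week = int(week)
        d_ref, ref_species, ref_n = select_reference(dataset, week, diversity)
        b = beta[week]
        if d_ref == b:
            raise IntercropError(
                f"week {week} {diversity}: reference delta15N equals beta ({b} per mil)"
            )
        per_plot = grp.groupby("block_id")["delta15n_permil"].mean()
        values = ndfa(d_ref, per_plot.to_numpy(), b)
        values = np.atleast_1d(values)
        n = values.size
        flags = []
        if np.any((values < 0) | (values > 100)):
            flags.append("out_of_range")
        records.append(
            {
                "week": week,
                "diversity": diversity,
                "ndfa_mean": float(values.mean()),
                "ndfa_se": float(values.std(ddof=1) / np.sqrt(n)) if n >= 2 else np.nan,
                "n": n,
                "delta_ref": d_ref,
                "delta_legume_mean": float(per_plot.mean()),
                "beta": b,
                "ref_species": ref_species,
                "ref_n": ref_n,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(records).sort_values(["week", "diversity"]).reset_index(drop=True)


def records_from_frame(frame: pd.DataFrame) -> list[NdfaRecord]:
    """Typed view of an ndfa_timeseries output frame."""
    return [
        NdfaRecord(
            week=int(r.week), diversity=r.diversity, ndfa_mean=r.ndfa_mean,
            ndfa_se=r.ndfa_se, n=int(r.n), delta_ref=r.delta_ref,
            delta_legume_mean=r.delta_legume_mean, beta=r.beta,
            ref_species=r.ref_species, ref_n=int(r.ref_n),
            flags=tuple(f for f in str(r.flags).split(";") if f),
        )
        for r in frame.itertuples(index=False)
    ]
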