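"""Seeded generator of design-faithful destructive-harvest datasets.

Emulates a three-species intercropping trial (oat, lupin, camelina) grown
at three diversity levels — isolated single plants, monocultures and
2-species mixtures — with weekly destructive harvests over an 18-week
season and three replicate plots per harvest.  Every trajectory is a
phenomenological logistic curve (see :mod:`intercrop.growth`) around a
known ground truth, so each downstream stage (fitting, contrasts, Ndfa)
can be verified by parameter recovery.

Replicates are independent draws around one shared truth (no block random
effect).  All randomness flows from a single top-level seed: substreams
are derived per (species, context) combination via
``numpy.random.SeedSequence.spawn`` in sorted key order, so the output is
byte-stable under one seed and insensitive to dictionary ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, ConfigurationError, MissingTruthError
from .growth import LogisticParams, logistic_value
from . import reference

__all__ = [
    "Context",
    "ExperimentDesign",
    "TruthSet",
    "NoiseSpec",
    "generate_trajectory",
    "generate_isotope_data",
    "generate_experiment",
    "default_design",
    "default_truth",
    "truth_key",
    "invert_ndfa",
    "RESPONSES",
    "LEGUME",
]

RESPONSES = ("biomass", "n", "p")
LEGUME = "lupin"

#: Plot area (m^2) and the sowing densities (seeds/m^2) of the emulated trial.
PLOT_AREA_M2 = 0.25
DEFAULT_SOWING_DENSITIES = {"oat": 400, "lupin": 160, "camelina": 592}

# Harvest-index-like factor converting final per-plant shoot biomass into
# plot grain yield, and species organic-acid exudation intensities
# (umol per g root dry weight) ordered camelina > oat > lupin as observed.
HARVEST_INDEX = 0.4
ROOT_SHOOT_RATIO = 0.25
OA_RATE_UMOL_PER_G = {"camelina": 12.0, "oat": 6.0, "lupin": 2.0}

_NOISE_ALIASES = {
    "multiplicative-lognormal": "lognormal",
    "lognormal": "lognormal",
    "additive-gaussian": "gaussian",
    "gaussian": "gaussian",
}


@dataclass(frozen=True)
class Context:
    """A community context: isolated single, monoculture, or a 2-species mixture."""

    kind: str                               # "single" | "monoculture" | "mixture"
    pair: tuple[str, str] | None = None     # only for mixtures

    def __post_init__(self) -> None:
        if self.kind not in ("single", "monoculture", "mixture"):
            raise ConfigurationError(f"unknown context kind {self.kind!r}")
        if self.kind == "mixture":
            if self.pair is None or len(self.pair) != 2 or self.pair[0] == self.pair[1]:
                raise ConfigurationError(
                    "a mixture context must name exactly two distinct species"
                )
        elif self.pair is not None:
            raise ConfigurationError(f"{self.kind} context takes no species pair")


def truth_key(species: str, kind: str, partner: str = "") -> tuple[str, str]:
    """Map a record's (context kind, partner) to the truth-table context label."""
    return (species, f"mixture:{partner}" if kind == "mixture" else kind)


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated destructive-harvest experiment."""

    species: tuple[str, ...] = ("oat", "lupin", "camelina")
    contexts: tuple[Context, ...] = (
        Context("single"),
        Context("monoculture"),
        Context("mixture", ("oat", "lupin")),
        Context("mixture", ("oat", "camelina")),
    )
    harvest_weeks: tuple[int, ...] = tuple(range(1, 19))
    replicates_per_harvest: int = 3
    sowing_densities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SOWING_DENSITIES)
    )

    def __post_init__(self) -> None:
        weeks = self.harvest_weeks
        if not weeks or any(b <= a for a, b in zip(weeks, weeks[1:])):
            raise ConfigurationError("harvest_weeks must be non-empty and strictly increasing")
        if self.replicates_per_harvest < 1:
            raise ConfigurationError("replicates_per_harvest must be >= 1")
        for c in self.contexts:
            if c.kind == "mixture":
                missing = [s for s in c.pair if s not in self.species]
                if missing:
                    raise ConfigurationError(f"mixture names unknown species {missing}")

    @property
    def n_harvests(self) -> int:
        return len(self.harvest_weeks)

    def combinations(self) -> list[tuple[str, str, str]]:
        """All (species, context kind, partner) trajectories, sorted."""
        combos = []
        for c in self.contexts:
            if c.kind == "mixture":
                a, b = c.pair
                combos.append((a, "mixture", b))
                combos.append((b, "mixture", a))
            else:
                combos.extend((s, c.kind, "") for s in self.species)
        return sorted(combos)

    def plants_per_plot(self, species: str, kind: str) -> float:
        if kind == "single":
            return 1.0
        n = self.sowing_densities[species] * PLOT_AREA_M2
        return n / 2.0 if kind == "mixture" else n  # substitutive mixture design


@dataclass(frozen=True)
class NoiseSpec:
    """Replicate noise model.

    ``multiplicative-lognormal`` (default) multiplies the noiseless curve by
    a mean-one log-normal factor with coefficient of variation ``cv_or_sd``,
    guaranteeing positivity; ``additive-gaussian`` adds N(0, cv_or_sd) in
    response units and truncates at zero.  ``delta15n_sd`` is the additive
    per-mil SD applied to isotope values.
    """

    model: str = "multiplicative-lognormal"
    cv_or_sd: float = 0.10
    seed: int = 0
    delta15n_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.model not in _NOISE_ALIASES:
            raise ConfigurationError(
                f"unknown noise model {self.model!r}; "
                f"expected one of {sorted(_NOISE_ALIASES)}"
            )
        if self.cv_or_sd < 0 or self.delta15n_sd < 0:
            raise ConfigurationError("noise scales must be >= 0")

    @property
    def canonical_model(self) -> str:
        return _NOISE_ALIASES[self.model]


@dataclass
class TruthSet:
    """Ground-truth parameters behind one synthetic experiment.

    ``growth`` maps (species, context label, response) to logistic
    parameters, where the context label is ``single``, ``monoculture`` or
    ``mixture:<partner>``.  ``ndfa_true`` holds the prescribed weekly %Ndfa
    of the legume per diversity level; ``beta_by_week`` the greenhouse
    calibration (per mil) and ``ref_delta15n_by_week`` the reference-plant
    delta15N (per mil).
    """

    growth: dict[tuple[str, str, str], LogisticParams]
    ndfa_true: dict[str, dict[int, float]] = field(default_factory=dict)
    beta_by_week: dict[int, float] = field(default_factory=dict)
    ref_delta15n_by_week: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level, series in self.ndfa_true.items():
            for week, pct in series.items():
                if not 0.0 <= pct <= 100.0:
                    raise ConfigurationError(
                        f"ndfa_true[{level!r}][{week}] = {pct} outside [0, 100]"
                    )

    def params_for(self, species: str, kind: str, partner: str, response: str) -> LogisticParams:
        key = truth_key(species, kind, partner) + (response,)
        try:
            return self.growth[key]
        except KeyError:
            raise MissingTruthError(
                f"no truth parameters for species={key[0]!r} "
                f"context={key[1]!r} response={key[2]!r}"
            ) from None

    def to_yaml(self, path) -> None:
        doc = {
            "growth": {
                "|".join(k): {"nu_max": p.nu_max, "r": p.r, "t_max": p.t_max}
                for k, p in sorted(self.growth.items())
            },
            "ndfa_true": {lvl: dict(sorted(s.items())) for lvl, s in sorted(self.ndfa_true.items())},
            "beta_by_week": dict(sorted(self.beta_by_week.items())),
            "ref_delta15n_by_week": dict(sorted(self.ref_delta15n_by_week.items())),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TruthSet":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        growth = {
            tuple(k.split("|")): LogisticParams(v["nu_max"], v["r"], v["t_max"])
            for k, v in doc["growth"].items()
        }
        return cls(
            growth=growth,
            ndfa_true={lvl: {int(w): float(x) for w, x in s.items()}
                       for lvl, s in doc.get("ndfa_true", {}).items()},
            beta_by_week={int(w): float(x) for w, x in doc.get("beta_by_week", {}).items()},
            ref_delta15n_by_week={int(w): float(x)
                                  for w, x in doc.get("ref_delta15n_by_week", {}).items()},
        )


def default_design() -> ExperimentDesign:
    """The emulated trial's layout: 3 species x 3 diversity levels, 18 weeks, n=3."""
    return ExperimentDesign()


# Plausible stand-in for the camelina-single nitrogen curve, which the trial
# could not estimate: single-plant asymptote scaled like the other species'
# single/community ratios, community-like steepness, published late t_max.
_CAMELINA_SINGLE_N = LogisticParams(300.0, 0.9, 16.61)


def default_truth(isotope_weeks: Sequence[int] | None = None) -> TruthSet:
    """Ground truth equal to the trial's published parameter estimates."""
    growth = dict(reference.PARAM_ESTIMATES)
    growth[("camelina", "single", "n")] = _CAMELINA_SINGLE_N
    ndfa = {lvl: dict(series) for lvl, series in reference.NDFA_WEEKLY.items()}
    if isotope_weeks is None:
        isotope_weeks = sorted({w for s in ndfa.values() for w in s})
    return TruthSet(
        growth=growth,
        ndfa_true=ndfa,
        beta_by_week={int(w): reference.BETA_PERMIL_DEFAULT for w in isotope_weeks},
        ref_delta15n_by_week={int(w): reference.REF_DELTA15N_DEFAULT for w in isotope_weeks},
    )


def _noise_factors(noise: NoiseSpec, rng: np.random.Generator, shape) -> np.ndarray:
    """Mean-one multiplicative factors for the log-normal model."""
    if noise.cv_or_sd == 0:
        return np.ones(shape)
    sigma = math.sqrt(math.log1p(noise.cv_or_sd**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=shape)


def _apply_noise(clean: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.canonical_model == "lognormal":
        return clean * _noise_factors(noise, rng, clean.shape)
    out = clean + rng.normal(0.0, noise.cv_or_sd, size=clean.shape)
    return np.clip(out, 0.0, None)  # responses are never negative


def generate_trajectory(
    truth: LogisticParams,
    weeks: Sequence[float],
    noise: NoiseSpec,
    n_rep: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a (week x replicate) grid of one response around ``truth``.

    The expected value at week t is the noiseless logistic curve; the same
    seed yields identical output; all values are >= 0.
    """
    weeks = np.asarray(list(weeks), dtype=float)
    if weeks.size == 0:
        raise ConfigurationError("weeks must be non-empty")
    if n_rep < 1:
        raise ConfigurationError("n_rep must be >= 1")
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    clean = np.repeat(logistic_value(truth, weeks)[:, None], n_rep, axis=1)
    return _apply_noise(clean, noise, rng)


def invert_ndfa(ndfa_pct: float, delta_ref: float, beta: float) -> float:
    """delta15N a legume must show for a given %Ndfa (inverse of the
    isotope-dilution estimator): delta_ref - (Ndfa/100) * (delta_ref - beta)."""
    return delta_ref - (ndfa_pct / 100.0) * (delta_ref - beta)


def generate_isotope_data(
    ndfa_true: Mapping[int, float],
    beta_by_week: Mapping[int, float],
    ref_delta_by_week: Mapping[int, float],
    noise: NoiseSpec,
    n_rep: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per week x replicate delta15N of the legume and the reference plant.

    ``noise.cv_or_sd`` is interpreted as an additive per-mil SD here.  The
    noiseless legume value satisfies the isotope-dilution identity exactly,
    so applying the Ndfa estimator to noiseless output returns the
    prescribed series.
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    missing = [w for w in ndfa_true if w not in beta_by_week]
    if missing:
        raise CalibrationError(f"no beta calibration for weeks {sorted(missing)}")
    missing = [w for w in ndfa_true if w not in ref_delta_by_week]
    if missing:
        raise CalibrationError(f"no reference delta15N for weeks {sorted(missing)}")
    rows = []
    for week in sorted(ndfa_true):
        pct = ndfa_true[week]
        if not 0.0 <= pct <= 100.0:
            raise ConfigurationError(f"ndfa_true[{week}] = {pct} outside [0, 100]")
        d_ref = ref_delta_by_week[week]
        d_leg = invert_ndfa(pct, d_ref, beta_by_week[week])
        for rep in range(1, n_rep + 1):
            eps = rng.normal(0.0, noise.cv_or_sd, size=2) if noise.cv_or_sd else (0.0, 0.0)
            rows.append(
                {
                    "week": week,
                    "replicate": rep,
                    "delta15n_legume": d_leg + eps[0],
                    "delta15n_ref": d_ref + eps[1],
                }
            )
    return pd.DataFrame(rows)


HARVEST_COLUMNS = [
    "species", "context", "partner", "block_id", "week", "individual_id",
    "biomass_g", "n_mg", "p_mg", "delta15n_permil", "oa_umol", "root_dw_g",
    "plot_yield_g",
]


def generate_experiment(
    design: ExperimentDesign,
    truth: TruthSet,
    noise: NoiseSpec,
    allow_missing: bool = False,
) -> pd.DataFrame:
    """Simulate a full harvest dataset in the tidy harvest schema.

    One record per (species, context, week, replicate block); the three
    sampled individuals of a plot are pooled for nutrient analysis, so each
    record carries the plot's pooled per-individual measurements
    (individual_id = 1).  Record count = combinations x weeks x replicates.

    A truth entry absent for some (species, context, response) raises an
    error naming the key, unless ``allow_missing`` is set, in which case
    that response column is emitted as NaN (emulating a trajectory the
    trial could not measure).
    """
    weeks = np.asarray(design.harvest_weeks, dtype=float)
    horizon = design.harvest_weeks[-1]
    combos = design.combinations()
    streams = np.random.SeedSequence(noise.seed).spawn(len(combos))
    yield_weeks = set(design.harvest_weeks[-2:])
    rows = []
    for (species, kind, partner), ss in zip(combos, streams):
        rng = np.random.default_rng(ss)
        params = {}
        for resp in RESPONSES:
            try:
                params[resp] = truth.params_for(species, kind, partner, resp)
            except MissingTruthError:
                if not allow_missing:
                    raise
                params[resp] = None
        for p in params.values():
            if p is not None and not 0 < p.t_max <= 1.5 * horizon:
                raise ConfigurationError(
                    f"truth t_max={p.t_max} outside the simulated horizon +/- 50% "
                    f"for {species}/{kind}/{partner}"
                )
        nan_grid = np.full((len(weeks), design.replicates_per_harvest), np.nan)
        traj = {
            resp: (
                generate_trajectory(params[resp], weeks, noise, design.replicates_per_harvest, rng)
                if params[resp] is not None else nan_grid
            )
            for resp in RESPONSES
        }
        diversity = kind
        ndfa_series = truth.ndfa_true.get(diversity, {}) if species == LEGUME else {}
        n_plants = design.plants_per_plot(species, kind)
        # auxiliary columns (roots, organic acids, plot yield) stay positive,
        # so they always use mean-one multiplicative factors
        aux = noise if noise.canonical_model == "lognormal" else replace(noise, model="lognormal", cv_or_sd=0.0)
        for wi, week in enumerate(design.harvest_weeks):
            for rep in range(1, design.replicates_per_harvest + 1):
                biomass = traj["biomass"][wi, rep - 1]
                root_dw = biomass * ROOT_SHOOT_RATIO * float(_noise_factors(aux, rng, ()))
                oa = OA_RATE_UMOL_PER_G[species] * root_dw * float(_noise_factors(aux, rng, ())) \
                    if species in OA_RATE_UMOL_PER_G else np.nan
                delta = np.nan
                if species == LEGUME and week in ndfa_series:
                    if week not in truth.beta_by_week or week not in truth.ref_delta15n_by_week:
                        raise CalibrationError(
                            f"legume ndfa prescribed for week {week} but beta/reference "
                            "delta15N calibration is missing"
                        )
                    delta = invert_ndfa(
                        ndfa_series[week],
                        truth.ref_delta15n_by_week[week],
                        truth.beta_by_week[week],
                    ) + (rng.normal(0.0, noise.delta15n_sd) if noise.delta15n_sd else 0.0)
                elif species != LEGUME and week in truth.ref_delta15n_by_week:
                    delta = truth.ref_delta15n_by_week[week] + (
                        rng.normal(0.0, noise.delta15n_sd) if noise.delta15n_sd else 0.0
                    )
                plot_yield = np.nan
                if week in yield_weeks:
                    plot_yield = biomass * n_plants * HARVEST_INDEX * float(_noise_factors(aux, rng, ()))
                rows.append(
                    (species, kind, partner, rep, int(week), 1,
                     biomass, traj["n"][wi, rep - 1], traj["p"][wi, rep - 1],
                     delta, oa, float(root_dw), plot_yield)
                )
    df = pd.DataFrame(rows, columns=HARVEST_COLUMNS)
    return df


def beta_table_frame(truth: TruthSet) -> pd.DataFrame:
    """Two-column beta calibration table (week, beta_permil)."""
    return pd.DataFrame(
        {"week": sorted(truth.beta_by_week), "beta_permil": [truth.beta_by_week[w] for w in sorted(truth.beta_by_week)]}
    )


def with_seed(noise: NoiseSpec, seed: int) -> NoiseSpec:
    """Copy of a noise spec with a different top-level seed."""
    return replace(noise, seed=seed)
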