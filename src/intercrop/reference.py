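"""Reference parameter estimates from the oat-lupin-camelina field trial.

The package's synthetic designs emulate a Mediterranean raised-bed
intercropping experiment with three crop species — oat (*Avena sativa*),
lupin (*Lupinus angustifolius*) and camelina (*Camelina sativa*) — grown as
isolated single plants, in monocultures, and in two 2-species mixtures
(oat-lupin, oat-camelina), with 18 weekly destructive harvests of three
replicate plots each.  The tables below hold the trial's published
logistic-curve parameter estimates (mean and SE over n = 3 replicate fits)
for biomass, N and P accumulation, the weekly %Ndfa means for lupin at each
diversity level, and the final-harvest partial land equivalent ratios.

These values serve two purposes: they are the default ground truth of the
synthetic-data generator (so simulated experiments look like the real one),
and they are the inputs to the desk-scale contrast computations (peak-rate
and asymptote comparisons between community contexts).

Context labels: ``single`` (isolated plant), ``monoculture``, and
``mixture:<partner>`` (grown in a 2-species mixture with the named partner).
"""

from __future__ import annotations

from .growth import LogisticParams

__all__ = [
    "PARAM_ESTIMATES",
    "PARAM_SE",
    "NDFA_WEEKLY",
    "PARTIAL_LER",
    "BETA_PERMIL_DEFAULT",
    "REF_DELTA15N_DEFAULT",
    "param_means",
]

# (species, context, response) -> (mean, SE) for (nu_max, r, t_max).
# response in {"biomass", "n", "p"}; nu_max in g (biomass) or mg (N, P)
# per individual, r per week, t_max in weeks after emergence.
_T: dict[tuple[str, str, str], tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    # --- biomass (B_max in g) ---
    ("oat", "mixture:lupin", "biomass"):    ((1.62, 0.37, 10.48), (0.21, 0.10, 1.09)),
    ("oat", "mixture:camelina", "biomass"): ((2.45, 0.40, 11.59), (0.29, 0.09, 0.88)),
    ("oat", "monoculture", "biomass"):      ((1.50, 0.47, 10.23), (0.12, 0.11, 0.63)),
    ("oat", "single", "biomass"):           ((21.16, 0.55, 12.91), (4.77, 0.25, 1.26)),
    ("lupin", "mixture:oat", "biomass"):    ((15.26, 1.15, 9.71), (1.09, 0.49, 0.43)),
    ("lupin", "monoculture", "biomass"):    ((11.35, 0.92, 9.44), (0.65, 0.27, 0.38)),
    ("lupin", "single", "biomass"):         ((126.8, 2.18, 11.68), (7.37, 0.93, 0.24)),
    ("camelina", "mixture:oat", "biomass"): ((0.52, 1.97, 10.60), (0.08, 2.40, 0.74)),
    ("camelina", "monoculture", "biomass"): ((0.73, 0.68, 11.02), (0.11, 0.34, 0.91)),
    ("camelina", "single", "biomass"):      ((19.56, 0.82, 10.92), (3.18, 0.55, 0.99)),
    # --- phosphorus (NU_max in mg) ---
    ("oat", "mixture:lupin", "p"):    ((5.36, 1.13, 7.85), (0.72, 0.82, 0.74)),
    ("oat", "mixture:camelina", "p"): ((7.15, 1.18, 8.31), (0.49, 0.43, 0.36)),
    ("oat", "monoculture", "p"):      ((7.23, 1.30, 8.56), (0.92, 0.88, 0.61)),
    ("oat", "single", "p"):           ((38.91, 0.68, 9.82), (9.89, 0.47, 1.34)),
    ("lupin", "mixture:oat", "p"):    ((61.26, 1.29, 9.61), (5.44, 0.60, 0.41)),
    ("lupin", "monoculture", "p"):    ((38.70, 1.11, 8.95), (3.37, 0.46, 0.43)),
    ("lupin", "single", "p"):         ((33.56, 2.49, 11.07), (2.49, 1.37, 0.20)),
    ("camelina", "mixture:oat", "p"): ((2.25, 1.37, 9.48), (0.55, 1.70, 1.04)),
    ("camelina", "monoculture", "p"): ((2.33, 1.76, 9.32), (0.39, 1.83, 0.69)),
    ("camelina", "single", "p"):      ((36.02, 3.89, 8.76), (8.58, 18.22, 1.21)),
    # --- nitrogen (NU_max in mg) ---
    ("oat", "mixture:lupin", "n"):    ((17.45, 2.04, 6.72), (1.65, 1.72, 0.48)),
    ("oat", "mixture:camelina", "n"): ((24.90, 0.58, 8.95), (2.59, 0.18, 0.70)),
    ("oat", "monoculture", "n"):      ((15.15, 0.94, 7.68), (1.01, 0.33, 0.43)),
    ("oat", "single", "n"):           ((282.0, 0.61, 11.01), (56.41, 0.26, 1.05)),
    ("lupin", "mixture:oat", "n"):    ((516.4, 1.36, 8.98), (46.22, 0.73, 0.46)),
    ("lupin", "monoculture", "n"):    ((367.6, 1.13, 8.42), (26.07, 0.45, 0.41)),
    ("lupin", "single", "n"):         ((5072.0, 2.12, 11.37), (506.8, 1.16, 0.32)),
    ("camelina", "mixture:oat", "n"): ((16.42, 1.38, 10.02), (4.04, 1.72, 1.06)),
    ("camelina", "monoculture", "n"): ((14.61, 0.91, 9.91), (2.00, 0.47, 0.70)),
    # The trial could not estimate the camelina-single nitrogen curve (its
    # reported row is NA).  The generator default in synthetic.py fills the
    # gap with a plausible single-plant value; no published estimate exists.
}

PARAM_ESTIMATES: dict[tuple[str, str, str], LogisticParams] = {
    k: LogisticParams(*v[0]) for k, v in _T.items()
}
PARAM_SE: dict[tuple[str, str, str], tuple[float, float, float]] = {
    k: v[1] for k, v in _T.items()
}


def param_means(species: str, context: str, response: str) -> LogisticParams:
    """Published mean logistic parameters for one trajectory key."""
    return PARAM_ESTIMATES[(species, context, response)]


# Weekly mean %Ndfa of lupin (n = 3) at each diversity level; the trial
# detected fixation from week 5 through the last isotope harvest in week 16.
NDFA_WEEKLY: dict[str, dict[int, float]] = {
    "mixture": {
        5: 83.06, 6: 76.00, 7: 79.41, 8: 78.98, 9: 76.07, 10: 76.51,
        11: 72.38, 12: 67.18, 13: 74.10, 14: 76.63, 15: 72.68, 16: 64.92,
    },
    "monoculture": {
        5: 77.16, 6: 69.33, 7: 70.63, 8: 72.67, 9: 76.91, 10: 74.13,
        11: 70.27, 12: 54.03, 13: 66.87, 14: 76.53, 15: 71.21, 16: 70.05,
    },
    "single": {
        5: 44.90, 6: 43.83, 7: 76.63, 8: 57.69, 9: 57.39, 10: 47.67,
        11: 48.60, 12: 38.66, 13: 45.71, 14: 36.91, 15: 37.14, 16: 28.14,
    },
}

# Final-harvest partial land equivalent ratios (plot-level grain yield of a
# species in mixture divided by its monoculture yield).
PARTIAL_LER: dict[str, dict[str, float]] = {
    "oat-lupin": {"oat": 0.51, "lupin": 0.86},
    "oat-camelina": {"oat": 0.96, "camelina": 0.18},
}

# Default isotope calibration used by the synthetic generator: beta is the
# delta15N of lupin grown on atmospheric N2 only (greenhouse calibration,
# per mil), REF_DELTA15N the soil-grown reference-plant signature.
BETA_PERMIL_DEFAULT: float = -0.5
REF_DELTA15N_DEFAULT: float = 3.0
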