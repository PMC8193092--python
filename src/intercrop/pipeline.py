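"""End-to-end pipeline: simulate (or load) -> fit -> rates -> metrics -> report.

``run_pipeline`` composes the stages into one deterministic run: a harvest
dataset (simulated from the default truth, or read from CSV), per-replicate
logistic fits with mean +/- SE summaries, peak instantaneous rates, percent
contrasts between community contexts, LER, the weekly %Ndfa series with a
diversity-level test, letter displays per (species, response, parameter),
and a JSON report collecting warnings and configuration provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import fitting, fixation, groupstats, metrics, synthetic
from .io import RunConfig, read_beta_table, read_harvest, write_csv, write_harvest

__all__ = ["ArtifactBundle", "run_pipeline", "contrast_table", "rates_table"]

log = logging.getLogger("intercrop.pipeline")


@dataclass
class ArtifactBundle:
    """In-memory results of one pipeline run plus where they were written."""

    harvest: pd.DataFrame
    fits: pd.DataFrame
    summary: pd.DataFrame
    rates: pd.DataFrame
    contrasts: pd.DataFrame
    ler: pd.DataFrame
    ndfa: pd.DataFrame | None
    letters: pd.DataFrame
    report: dict
    paths: dict[str, str]


def rates_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Peak instantaneous rates I = r_mean * nu_max_mean / 4 per trajectory."""
    out = summary[["species", "context", "partner", "response"]].copy()
    out["i_max"] = summary["r_mean"] * summary["nu_max_mean"] / 4.0
    out["t_at_peak"] = summary["t_max_mean"]
    return out


def contrast_table(summary: pd.DataFrame) -> pd.DataFrame:
    """All within-species context contrasts of NU_max and I_max (whole percent)."""
    rows = []
    summaries = fitting.summaries_from_frame(summary)
    by_key: dict[tuple[str, str], list] = {}
    for s in summaries:
        by_key.setdefault((s.species, s.response), []).append(s)
    for (species, response) in sorted(by_key):
        group = sorted(by_key[(species, response)], key=lambda s: (s.context, s.partner))
        for i in range(len(group)):
            for j in range(len(group)):
                if i == j:
                    continue
                a, b = group[i], group[j]
                if not (np.isfinite(a.nu_max_mean) and np.isfinite(b.nu_max_mean)
                        and b.nu_max_mean > 0):
                    continue
                rows.append(
                    {
                        "species": species, "response": response,
                        "context_a": a.context, "partner_a": a.partner,
                        "context_b": b.context, "partner_b": b.partner,
                        "nu_max_contrast_pct": metrics.percent_contrast(
                            a.nu_max_mean, b.nu_max_mean
                        ),
                        "i_max_contrast_pct": metrics.peak_rate_contrast(a, b),
                    }
                )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> ArtifactBundle:
    """Run the full analysis under one seed; deterministic given the config."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []
    handler = _CollectHandler(warnings)
    logging.getLogger("intercrop").addHandler(handler)
    try:
        design = synthetic.ExperimentDesign(
            harvest_weeks=tuple(config.harvest_weeks),
            replicates_per_harvest=config.replicates_per_harvest,
        )
        truth = synthetic.default_truth()
        noise = synthetic.NoiseSpec(
            model=config.noise_model, cv_or_sd=config.noise_cv_or_sd,
            seed=config.seed, delta15n_sd=config.delta15n_sd,
        )
        if config.input_harvest:
            log.info("stage simulate: skipped, reading %s", config.input_harvest)
            harvest = read_harvest(config.input_harvest)
        else:
            log.info("stage simulate: seed=%d", config.seed)
            harvest = synthetic.generate_experiment(design, truth, noise)
        beta_table = synthetic.beta_table_frame(truth)

        log.info("stage fit: %d records", len(harvest))
        fits, summary = fitting.fit_all(harvest, per_replicate=config.per_replicate)
        fits_df = fitting.fits_frame(fits)

        rates = rates_table(summary)
        contrasts = contrast_table(summary)

        log.info("stage ler")
        ler_rows = []
        for mixture, res in metrics.ler_from_harvest(harvest).items():
            for s, p in sorted(res.partial.items()):
                ler_rows.append(
                    {
                        "mixture": mixture, "species": s,
                        "partial_ler": round(p, config.ler_percent_decimals),
                        "partial_se": (res.partial_se or {}).get(s, np.nan),
                    }
                )
            ler_rows.append(
                {
                    "mixture": mixture, "species": "TOTAL",
                    "partial_ler": round(res.total, config.ler_percent_decimals),
                    "partial_se": res.total_se,
                }
            )
        ler = pd.DataFrame(ler_rows)

        ndfa_frame = None
        ndfa_report = None
        if harvest["delta15n_permil"].notna().any():
            log.info("stage ndfa")
            ndfa_frame = fixation.ndfa_timeseries(harvest, beta_table)
            ndfa_report = groupstats.diversity_effect_ndfa(ndfa_frame, alpha=config.alpha)

        log.info("stage stats")
        letters = _letter_table(fits_df, alpha=config.alpha)

        report = {
            "config": config.to_dict(),
            "config_hash": config.hash(),
            "n_records": int(len(harvest)),
            "n_fits": int(len(fits_df)),
            "n_converged": int(fits_df["converged"].sum()) if len(fits_df) else 0,
            "ndfa_diversity_test": ndfa_report,
            "warnings": list(warnings),
        }

        paths = {}
        for name, frame in [
            ("harvest", harvest), ("beta", beta_table), ("fits", fits_df),
            ("summary", summary), ("rates", rates), ("contrasts", contrasts),
            ("ler", ler),
        ] + ([("ndfa", ndfa_frame)] if ndfa_frame is not None else []):
            p = out / f"{name}.csv"
            if name == "harvest":
                write_harvest(frame, p, config)
            else:
                write_csv(frame, p, config)
            paths[name] = str(p)
        write_csv(letters, out / "letters.csv", config)
        paths["letters"] = str(out / "letters.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        paths["report"] = str(out / "report.json")
        return ArtifactBundle(
            harvest=harvest, fits=fits_df, summary=summary, rates=rates,
            contrasts=contrasts, ler=ler, ndfa=ndfa_frame, letters=letters,
            report=report, paths=paths,
        )
    finally:
        logging.getLogger("intercrop").removeHandler(handler)


def _letter_table(fits_df: pd.DataFrame, alpha: float) -> pd.DataFrame:
    """Letter display per (species, response, parameter) over context groups."""
    rows = []
    conv = fits_df[fits_df["converged"]]
    for (species, response), grp in conv.groupby(["species", "response"], sort=True):
        labels = grp["context"].where(grp["partner"] == "", grp["context"] + ":" + grp["partner"])
        for parameter in ("nu_max", "r", "t_max"):
            groups = {
                str(ctx): sub[parameter].to_numpy()
                for ctx, sub in grp.groupby(labels)
            }
            usable = {k: v for k, v in groups.items() if np.isfinite(v).sum() >= 2}
            if len(usable) < 2:
                continue
            disp = groupstats.compare_contexts(usable, alpha=alpha)
            for ctx in sorted(disp.letters):
                rows.append(
                    {
                        "species": species, "response": response, "parameter": parameter,
                        "context": ctx, "mean": disp.means[ctx],
                        "letter": disp.letters[ctx], "anova_p": disp.anova_p,
                    }
                )
    return pd.DataFrame(rows)


class _CollectHandler(logging.Handler):
    def __init__(self, sink: list[str]):
        super().__init__(level=logging.WARNING)
        self.sink = sink

    def emit(self, record):
        self.sink.append(self.format(record))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
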