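"""File formats and run configuration.

The tidy harvest schema: one CSV row per sampled plot-level individual per
weekly destructive harvest, keyed by (species, context, partner, block_id,
week, individual_id).  Units are fixed by the schema: biomass in g, N and P
in mg per individual, delta15N in per mil, organic acids in umol, root dry
weight in g, plot yield in g.  Weeks are integers >= 1, counted from
seedling emergence.

All CSVs are written with 9-significant-digit floats and a comment header
carrying the run-configuration hash, so reruns under the same seed are
byte-identical and diffs stay stable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .synthetic import HARVEST_COLUMNS

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_harvest",
    "write_harvest",
    "write_csv",
    "read_beta_table",
    "RunConfig",
]

REQUIRED_COLUMNS = [
    "species", "context", "partner", "block_id", "week", "individual_id",
    "biomass_g", "n_mg", "p_mg",
]
OPTIONAL_COLUMNS = ["delta15n_permil", "oa_umol", "root_dw_g", "plot_yield_g"]
_NONNEGATIVE = ["biomass_g", "n_mg", "p_mg", "oa_umol", "root_dw_g", "plot_yield_g"]
_CONTEXTS = {"single", "monoculture", "mixture"}
_KEY = ["species", "context", "partner", "block_id", "week", "individual_id"]
FLOAT_FORMAT = "%.9g"


def read_harvest(path) -> pd.DataFrame:
    """Read and validate a harvest CSV; raises ValidationError listing rows."""
    df = pd.read_csv(path, comment="#")
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing required column(s): {', '.join(missing)}"])
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["partner"] = df["partner"].fillna("")
    bad_ctx = df.index[~df["context"].isin(_CONTEXTS)]
    problems += [
        f"row {i + 2}: unknown context {df.at[i, 'context']!r}" for i in bad_ctx[:20]
    ]
    mix_no_partner = df.index[(df["context"] == "mixture") & (df["partner"] == "")]
    problems += [f"row {i + 2}: mixture row without partner" for i in mix_no_partner[:20]]
    nonmix_partner = df.index[(df["context"] != "mixture") & (df["partner"] != "")]
    problems += [
        f"row {i + 2}: partner given for non-mixture context" for i in nonmix_partner[:20]
    ]
    weeks = pd.to_numeric(df["week"], errors="coerce")
    bad_week = df.index[weeks.isna() | (weeks < 1) | (weeks % 1 != 0)]
    problems += [f"row {i + 2}: invalid week {df.at[i, 'week']!r}" for i in bad_week[:20]]
    for c in _NONNEGATIVE:
        vals = pd.to_numeric(df[c], errors="coerce")
        neg = df.index[vals.notna() & (vals < 0)]
        problems += [f"row {i + 2}: negative {c} ({df.at[i, c]!r})" for i in neg[:20]]
    dup = df.index[df.duplicated(subset=_KEY, keep="first")]
    problems += [f"row {i + 2}: duplicate key {tuple(df.loc[i, _KEY])}" for i in dup[:20]]
    if problems:
        raise ValidationError(problems)
    df["week"] = weeks.astype(int)
    return df[HARVEST_COLUMNS]


def write_csv(df: pd.DataFrame, path, config: "RunConfig | None" = None) -> None:
    """Write a CSV with fixed float precision and an optional config header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        if config is not None:
            fh.write(f"# intercrop config hash: {config.hash()}\n")
            fh.write(f"# seed: {config.seed}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FORMAT)


def write_harvest(df: pd.DataFrame, path, config: "RunConfig | None" = None) -> None:
    write_csv(df[HARVEST_COLUMNS], path, config)


def read_beta_table(path) -> pd.DataFrame:
    """Read the two-column beta calibration CSV (week, beta_permil)."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in ("week", "beta_permil") if c not in df.columns]
    if missing:
        raise ValidationError([f"beta table missing column(s): {', '.join(missing)}"])
    return df


@dataclass
class RunConfig:
    """Fully serializable configuration of one pipeline run."""

    seed: int = 0
    harvest_weeks: tuple[int, ...] = tuple(range(1, 19))
    replicates_per_harvest: int = 3
    noise_model: str = "multiplicative-lognormal"
    noise_cv_or_sd: float = 0.10
    delta15n_sd: float = 0.3
    alpha: float = 0.05
    per_replicate: bool = True
    min_points: int = 5
    output_dir: str = "intercrop-out"
    input_harvest: str | None = None   # fit this CSV instead of simulating
    ler_percent_decimals: int = 2
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["harvest_weeks"] = list(self.harvest_weeks)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        doc["harvest_weeks"] = tuple(doc.get("harvest_weeks", range(1, 19)))
        return cls(**doc)
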