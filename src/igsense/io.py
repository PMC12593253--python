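"""Table schemas, CSV I/O and pipeline configuration.

All tables are UTF-8 CSV with a header row; quadrant labels are "A"-"D",
times are in milliseconds, and trial/sequence indices are 0-based in
files (human-readable reports add 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class SchemaError(ValueError):
    pass


#: column -> kind ("num", "int", "str", "bool") per named table schema
SCHEMAS: dict[str, dict[str, str]] = {
    "looking": {
        "infant_id": "str",
        "sequence_index": "int",
        "trial_index": "int",
        "looking_time": "num",
        "saccadic_latency": "num",
        "looked_away": "bool",
        "trial_predictable": "bool",
    },
    "metrics": {
        "sequence_index": "int",
        "trial_index": "int",
        "observed_location": "str",
        "information_gain": "num",
        "surprise": "num",
        "predictability": "num",
    },
    "sensitivity": {
        "infant_id": "str",
        "slope_mean": "num",
        "slope_sd": "num",
        "slope_z": "num",
    },
    "outcomes": {
        "infant_id": "str",
        "fsiq": "num",
        "vci": "num",
        "vsi": "num",
        "wmi": "num",
        "ses": "num",
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Missing columns raise a :class:`SchemaError` naming them; cells that
    fail numeric parsing are reported with their (1-based, header
    included) line numbers.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; have {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype="object")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if df.empty:
        raise SchemaError(f"{path}: table has no rows")
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing} for schema {schema!r}")
    out = pd.DataFrame(index=df.index)
    for col, kind in spec.items():
        raw = df[col]
        if kind in ("num", "int"):
            vals = pd.to_numeric(raw, errors="coerce")
            bad = vals.isna() & raw.notna()
            if bad.any():
                lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]
                raise SchemaError(
                    f"{path}: unparseable numeric value(s) in column {col!r} "
                    f"at line(s) {lines}"
                )
            out[col] = vals.astype(int) if kind == "int" else vals.astype(float)
        elif kind == "bool":
            out[col] = raw.astype(str).str.lower().isin(("true", "1", "t", "yes"))
        else:
            out[col] = raw.astype(str)
    # keep any extra columns untouched
    for col in df.columns:
        if col not in out.columns:
            out[col] = df[col]
    return out


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


@dataclass
class PipelineConfig:
    """End-to-end configuration; every stochastic stage carries a seed."""

    outdir: str = "igsense_out"
    design_seed: int | None = 1
    infant_seed: int | None = 2
    looking_seed: int | None = 3
    outcome_seed: int | None = 4
    fit_seed: int | None = 5
    alpha: float = 1.0  # ideal-learner prior pseudo-count
    n_infants: int = 90
    link: str = "exponential"
    chains: int = 4
    warmup_draws: int = 300
    sampling_draws: int = 700
    outlier_k_sd: float = 3.0

    SEED_FIELDS = (
        "design_seed",
        "infant_seed",
        "looking_seed",
        "outcome_seed",
        "fit_seed",
    )

    def validate(self) -> None:
        for name in self.SEED_FIELDS:
            if getattr(self, name) is None:
                raise ValueError(f"missing seed: {name}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_infants < 2:
            raise ValueError("need at least 2 infants")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        data = {f: getattr(self, f) for f in self.__dataclass_fields__}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
        return path
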