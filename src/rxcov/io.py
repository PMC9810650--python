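"""File I/O: measurement-table reading and validation, result serialization,
scenario config parsing, and run manifests for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, ValidationError
from .simulate import DistributionSpec, Scenario

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["sample_id", "group", "analyte", "aliquot", "value"]
OPTIONAL_COLUMNS = ["weight", "replicate"]


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def validate_measurements(
    table: pd.DataFrame, normalize_weight: bool = False
) -> pd.DataFrame:
    """Validate (and optionally weight-normalize) a tidy measurement table.

    Checks the schema, coerces types, drops rows with missing values (with
    a logged count — never imputed), and enforces: nonnegative expression
    values, aliquot index in {1, 2}, strictly positive weights, and
    uniqueness of (sample_id, analyte, aliquot[, replicate]).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {missing}")
    df = table.copy()
    n_before = len(df)
    df = df.dropna(subset=["sample_id", "group", "analyte", "aliquot", "value"])
    if len(df) < n_before:
        logger.warning("dropped %d row(s) with missing fields", n_before - len(df))
    try:
        df["aliquot"] = df["aliquot"].astype(int)
        df["value"] = df["value"].astype(float)
    except (TypeError, ValueError) as err:
        raise ValidationError(f"non-numeric aliquot or value column: {err}") from err
    bad_aliquot = df.loc[~df["aliquot"].isin([1, 2])]
    if len(bad_aliquot):
        raise ValidationError(
            f"aliquot must be 1 or 2; offending rows: {bad_aliquot.index.tolist()[:5]}"
        )
    neg = df.loc[df["value"] < 0]
    if len(neg):
        raise ValidationError(
            "expression values must be nonnegative (ratio scale); "
            f"offending rows: {neg.index.tolist()[:5]}"
        )
    if not np.isfinite(df["value"]).all():
        raise ValidationError("expression values must be finite")

    key = ["sample_id", "analyte", "aliquot"]
    if "replicate" in df.columns and df["replicate"].notna().any():
        df["replicate"] = df["replicate"].astype(int)
        key.append("replicate")
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(
            f"duplicate measurement keys {key}: rows {df.index[dup].tolist()[:5]}"
        )

    if normalize_weight:
        if "weight" not in df.columns:
            raise ValidationError("--normalize-weight requires a 'weight' column")
        w = df["weight"].astype(float)
        if not (w > 0).all():
            raise ValidationError("weights must be strictly positive")
        df["value"] = df["value"] / w
    return df.reset_index(drop=True)


def read_measurements(path, normalize_weight: bool = False) -> pd.DataFrame:
    """Read and validate a long-format measurement CSV.

    Expected header: sample_id, group, analyte, aliquot (1 or 2), value,
    and optionally weight and replicate.  UTF-8, '.' decimal separator.
    """
    try:
        raw = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as err:
        raise ValidationError(f"cannot read measurement CSV {path}: {err}") from err
    return validate_measurements(raw, normalize_weight=normalize_weight)


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def _format_float(x: Any) -> Any:
    if isinstance(x, float):
        if np.isnan(x):
            return ""
        return format(x, ".6g")
    return x


def write_result_table(table: pd.DataFrame, path) -> None:
    """Write a per-analyte result table as CSV, floats at 6 significant digits."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].map(_format_float)
    out.to_csv(path, index=False)


def write_scan_outputs(scan, prefix: str | Path) -> tuple[Path, Path]:
    """Write a gamma scan as <prefix>_scan.csv plus <prefix>_summary.csv.

    The scan CSV carries one row per gamma (tracks and statuses); the
    summary CSV carries the detected thresholds and run settings.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scan_path = prefix.with_name(prefix.name + "_scan.csv")
    summary_path = prefix.with_name(prefix.name + "_summary.csv")
    write_result_table(scan.to_frame(), scan_path)
    summary = pd.DataFrame(
        [
            {
                "gamma_star": scan.gamma_star,
                "gamma_sig": scan.gamma_sig,
                "n_later_crossings": len(scan.later_crossings),
                "n_replicates": scan.n_replicates,
                "alpha": scan.alpha,
                "k_smooth": scan.k_smooth,
                "seed": scan.seed,
            }
        ]
    )
    write_result_table(summary, summary_path)
    return scan_path, summary_path


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------

def _dist_from_config(node: Any, key: str) -> DistributionSpec:
    if not isinstance(node, dict):
        raise ConfigError(f"config key {key!r} must be a mapping with family/loc/scale")
    try:
        return DistributionSpec(
            family=node.get("family", "normal"),
            loc=float(node["loc"]),
            scale=float(node["scale"]),
        )
    except KeyError as err:
        raise ConfigError(f"config key {key!r} is missing field {err}") from err


def load_scenario_config(path) -> dict:
    """Parse a YAML scenario config into a dict with a Scenario plus scan
    settings (gamma grid, replicate counts, test, alpha, smoothing).

    Recognized keys: n_per_group, signal_x, signal_y, noise_x, noise_y
    (each family/loc/scale), gamma_grid (min/max/count/spacing),
    r_replicates (int or list), k_smooth, test, alpha, seed, and the
    fixture keys analytes, gamma, group_a, group_b.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as err:
        raise ConfigError(f"cannot parse config {path}: {err}") from err
    if not isinstance(cfg, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")

    try:
        scenario = Scenario(
            n_per_group=int(cfg.get("n_per_group", 12)),
            dist_sx=_dist_from_config(cfg["signal_x"], "signal_x"),
            dist_sy=_dist_from_config(cfg["signal_y"], "signal_y"),
            dist_noise_x=_dist_from_config(cfg["noise_x"], "noise_x"),
            dist_noise_y=_dist_from_config(cfg["noise_y"], "noise_y"),
            seed=int(cfg.get("seed", 0)),
        )
    except KeyError as err:
        raise ConfigError(f"config is missing required key {err}") from err

    grid_cfg = cfg.get("gamma_grid", {"min": 0.1, "max": 5.0, "count": 50})
    try:
        lo, hi = float(grid_cfg["min"]), float(grid_cfg["max"])
        count = int(grid_cfg.get("count", 50))
        spacing = grid_cfg.get("spacing", "linear")
    except (KeyError, TypeError, ValueError) as err:
        raise ConfigError(f"invalid gamma_grid config: {err}") from err
    if not (0 < lo < hi) or count < 2:
        raise ConfigError(
            f"gamma_grid requires 0 < min < max and count >= 2, got {grid_cfg}"
        )
    if spacing == "linear":
        grid = np.linspace(lo, hi, count)
    elif spacing == "log":
        grid = np.geomspace(lo, hi, count)
    else:
        raise ConfigError(f"gamma_grid spacing must be linear or log, got {spacing!r}")

    reps = cfg.get("r_replicates", 1)
    if isinstance(reps, int):
        reps = [reps]
    reps = [int(r) for r in reps]

    return {
        "scenario": scenario,
        "gamma_grid": grid,
        "r_replicates": reps,
        "k_smooth": int(cfg.get("k_smooth", 1)),
        "test": cfg.get("test", "welch_t"),
        "alpha": float(cfg.get("alpha", 0.05)),
        "analytes": cfg.get("analytes", ["A1", "A2", "A3", "A4", "A5", "A6"]),
        "gamma": float(cfg.get("gamma", 1.0)),
        "group_a": str(cfg.get("group_a", "G1")),
        "group_b": str(cfg.get("group_b", "G2")),
    }


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a command bit-identically
    (the timestamp is informational and excluded from determinism checks)."""

    command: str
    seed: int | None
    version: str
    config_hash: str | None = None
    input_digest: str | None = None
    timestamp: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def make_manifest(
    command: str,
    seed: int | None = None,
    config_path=None,
    input_path=None,
) -> RunManifest:
    from . import __version__

    return RunManifest(
        command=command,
        seed=seed,
        version=__version__,
        config_hash=file_digest(config_path) if config_path else None,
        input_digest=file_digest(input_path) if input_path else None,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
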