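"""CSV/JSON/YAML readers and writers, schema validation, manifest hashing.

Unit convention enforced at the I/O boundary: ejection fractions are stored
as fractions in (0, 1) in every file; percentages appear only in rendered
report text.  Volumes and thickness are written with 2 decimals, fractions
and ratios with 4 (the precision of the source tables on the percent scale).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .simulate import COHORT_COLUMNS, SimConfig

__all__ = [
    "SchemaError",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_truth_csv",
    "read_ground_truth_csv",
    "write_ground_truth_csv",
    "load_config",
    "save_config",
    "write_manifest",
]

#: columns rounded to 2 decimals on write (mL/m² and mm scales)
_COARSE_COLS = ["V_RV_ED", "V_LV_ES", "MT_LVM_ED"]
#: columns rounded to 4 decimals on write (fractions and dimensionless ratios)
_FINE_COLS = ["EF_RV", "EF_LV", "R_RVLV_ED", "R_LVMLV_ED", "RMD", "TMD"]


class SchemaError(ValueError):
    """Raised when a file does not match the expected schema."""


def _check_columns(df: pd.DataFrame, expected, path) -> None:
    got = list(df.columns)
    missing = [c for c in expected if c not in got]
    extra = [c for c in got if c not in expected]
    if missing or extra:
        raise SchemaError(
            f"{path}: column mismatch; missing={missing}, unexpected={extra}; "
            f"expected exactly {list(expected)}"
        )


def _check_numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for c in cols:
        parsed = pd.to_numeric(df[c], errors="coerce")
        bad = parsed.isna() & df[c].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise SchemaError(
                f"{path}: non-numeric value {df[c].iloc[row]!r} in column {c}, data row {row + 1}"
            )
        if parsed.isna().any():
            row = int(np.nonzero(parsed.isna().to_numpy())[0][0])
            raise SchemaError(f"{path}: missing value in column {c}, data row {row + 1}")
        df[c] = parsed
    return df


def read_cohort_csv(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a canonical 10-column cohort feature table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"case_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    _check_columns(df, COHORT_COLUMNS, path)
    df = _check_numeric(df, [c for c in COHORT_COLUMNS if c != "case_id"], path)
    for c in ("EF_RV", "EF_LV"):
        vals = df[c].to_numpy(float)
        if np.any((vals <= 0) | (vals >= 1)):
            row = int(np.nonzero((vals <= 0) | (vals >= 1))[0][0])
            raise SchemaError(
                f"{path}: {c}={vals[row]} at data row {row + 1} outside (0, 1); "
                "ejection fractions must be fractions — a value like 66.41 "
                "suggests the percent scale was written by mistake"
            )
    return df[COHORT_COLUMNS]


def write_cohort_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort table with the canonical header and rounding policy."""
    _check_columns(df, COHORT_COLUMNS, path)
    out = df[COHORT_COLUMNS].copy()
    for c in _COARSE_COLS:
        out[c] = out[c].astype(float).round(2)
    for c in _FINE_COLS:
        out[c] = out[c].astype(float).round(4)
    out.to_csv(path, index=False)


def write_truth_csv(latent: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write the truth-label table (case_id, subgroup, pathology)."""
    out = latent[["case_id", "subgroup"]].copy()
    out["pathology"] = np.where(
        out["subgroup"].isin(["RVA", "DCM"]), out["subgroup"], "NOR"
    )
    out.to_csv(path, index=False)


_GT_COLUMNS = ["case_id", "gt_V_LV_ED", "gt_V_LV_ES", "gt_EF_LV", "is_outlier"]


def write_ground_truth_csv(gt: pd.DataFrame, path: Union[str, Path]) -> None:
    out = gt[_GT_COLUMNS].copy()
    for c in ("gt_V_LV_ED", "gt_V_LV_ES"):
        out[c] = out[c].astype(float).round(2)
    out["gt_EF_LV"] = out["gt_EF_LV"].astype(float).round(4)
    out.to_csv(path, index=False)


def read_ground_truth_csv(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"case_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    _check_columns(df, _GT_COLUMNS, path)
    df = _check_numeric(df, ["gt_V_LV_ED", "gt_V_LV_ES", "gt_EF_LV"], path)
    df["is_outlier"] = df["is_outlier"].astype(bool)
    return df[_GT_COLUMNS]


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))


def sim_config_to_file(config: SimConfig, path: Union[str, Path]) -> None:
    save_config(config.to_dict(), path)


def sim_config_from_file(path: Union[str, Path]) -> SimConfig:
    return SimConfig.from_dict(load_config(path))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: Union[str, Path], extra: Optional[Dict] = None) -> Path:
    """Hash every artifact in ``outdir`` into manifest.json (reproducibility check)."""
    outdir = Path(outdir)
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
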