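"""File readers/writers and model serialization.

Formats (all plain text, UTF-8, comma decimal point, missing = empty cell):

* BMO marks — CSV ``scan_index,side,x_mm,y_mm,z_um`` or a JSON array of
  point objects with those keys (+ top-level is a list).
* ILM surface — numeric matrix CSV/TSV, row 0 = superior edge, plus a JSON
  sidecar ``{"x_extent_mm": ..., "y_extent_mm": ...}`` (default sidecar
  path: the matrix path with ``.json`` appended).
* Cohort — CSV with ``eye_id,laterality,disc_type,cprnflt_um,md_db,se_d,
  iop_mmhg,age_y`` plus the 20 parameter columns and ``rp_height_um``;
  unknown columns are preserved as per-record metadata.
* Model — versioned JSON.

Left eyes are mirrored about the vertical axis into right-eye orientation
on ingest (x → −x, ILM columns reversed) and flagged; mirroring twice
restores the input exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .classify import DiscTypeModel
from .types import (
    DISC_TYPES,
    PARAMETER_NAMES,
    BMOPointSet,
    DiscParameters,
    EyeRecord,
    ILMSurface,
    SegmentationInput,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_segmentation",
    "read_cohort",
    "write_parameters",
    "save_model",
    "load_model",
    "mirror_to_od",
]

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1

_COHORT_FIELDS = ("eye_id", "laterality", "disc_type", "cprnflt_um",
                  "md_db", "se_d", "iop_mmhg", "age_y")


class ParseError(ValueError):
    """A file could not be parsed into a valid domain object."""


def _read_bmo(path: Union[str, Path]) -> BMOPointSet:
    path = Path(path)
    required = ["scan_index", "side", "x_mm", "y_mm", "z_um"]
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(data, list):
            raise ParseError(f"{path}: expected a JSON array of point objects")
        df = pd.DataFrame(data)
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise ParseError(f"{path}: unreadable CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing BMO columns {missing}")
    for col in ("scan_index", "x_mm", "y_mm", "z_um"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric values in {col!r}") from exc
    if len(df) < 3:
        raise ParseError(f"{path}: need >=3 BMO points, got {len(df)}")
    try:
        return BMOPointSet(
            scan_index=df["scan_index"].to_numpy(dtype=int),
            side=df["side"].to_numpy(dtype=object),
            x_mm=df["x_mm"].to_numpy(dtype=float),
            y_mm=df["y_mm"].to_numpy(dtype=float),
            z_um=df["z_um"].to_numpy(dtype=float),
        )
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def _read_ilm(path: Union[str, Path],
              meta_path: Optional[Union[str, Path]] = None) -> ILMSurface:
    path = Path(path)
    text = path.read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    try:
        heights = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric ILM grid: {exc}") from exc
    meta_path = Path(meta_path) if meta_path else Path(str(path) + ".json")
    x_extent, y_extent = 6.0, 6.0
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        x_extent = float(meta.get("x_extent_mm", x_extent))
        y_extent = float(meta.get("y_extent_mm", y_extent))
    else:
        warnings.warn(f"{meta_path} not found; assuming 6x6 mm extents")
    try:
        return ILMSurface(heights=heights, x_extent_mm=x_extent,
                          y_extent_mm=y_extent)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def mirror_to_od(seg: SegmentationInput) -> SegmentationInput:
    """Mirror a segmentation about the vertical axis (x → −x).

    An involution: applying it twice restores the coordinates exactly.
    The anatomical side labels are untouched (temporal stays temporal).
    """
    bmo = seg.bmo
    new_bmo = BMOPointSet(
        scan_index=bmo.scan_index.copy(),
        side=bmo.side.copy(),
        x_mm=-bmo.x_mm,
        y_mm=bmo.y_mm.copy(),
        z_um=bmo.z_um.copy(),
        laterality=bmo.laterality,
        mirrored=not bmo.mirrored,
    )
    new_ilm = ILMSurface(
        heights=seg.ilm.heights[:, ::-1].copy(),
        x_extent_mm=seg.ilm.x_extent_mm,
        y_extent_mm=seg.ilm.y_extent_mm,
    )
    return SegmentationInput(bmo=new_bmo, ilm=new_ilm, eye_id=seg.eye_id)


def read_segmentation(bmo_path: Union[str, Path], ilm_path: Union[str, Path],
                      laterality: str, eye_id: str = "",
                      ilm_meta_path: Optional[Union[str, Path]] = None
                      ) -> SegmentationInput:
    """Read and validate one eye's BMO marks + ILM surface.

    Left-eye (OS) inputs are mirrored into OD orientation and flagged.
    """
    if laterality not in ("OD", "OS"):
        raise ParseError(f"laterality must be OD or OS, got {laterality!r}")
    bmo = _read_bmo(bmo_path)
    ilm = _read_ilm(ilm_path, ilm_meta_path)
    bmo = BMOPointSet(scan_index=bmo.scan_index, side=bmo.side,
                      x_mm=bmo.x_mm, y_mm=bmo.y_mm, z_um=bmo.z_um,
                      laterality=laterality)
    try:
        seg = SegmentationInput(bmo=bmo, ilm=ilm,
                                eye_id=eye_id or Path(bmo_path).stem)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc
    if laterality == "OS":
        seg = mirror_to_od(seg)
    return seg


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return float(value)


def read_cohort(path: Union[str, Path]) -> list[EyeRecord]:
    """Read a cohort CSV into EyeRecords.

    Missing optional fields come back as ``None`` (an empty cell, never a
    zero). Duplicate eye ids or unknown disc-type labels raise with the
    offending rows listed. Unknown columns land in ``record.extra``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty cohort file", path)
        return []
    if df.empty:
        logger.warning("%s: cohort file has a header but no rows", path)
        return []
    if "eye_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'eye_id'")
    dup = df["eye_id"][df["eye_id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"{path}: duplicate eye_id values: {sorted(set(dup))}")
    if "disc_type" in df.columns:
        labels = df["disc_type"].dropna()
        bad = labels[~labels.isin(DISC_TYPES)]
        if len(bad):
            rows = [f"row {i + 2}: {v!r}" for i, v in bad.items()]
            raise ParseError(f"{path}: unknown disc_type labels ({'; '.join(rows)})")

    has_params = all(c in df.columns for c in PARAMETER_NAMES)
    some_params = any(c in df.columns for c in PARAMETER_NAMES)
    if some_params and not has_params:
        missing = [c for c in PARAMETER_NAMES if c not in df.columns]
        raise ParseError(f"{path}: partial parameter columns; missing {missing}")
    known = set(_COHORT_FIELDS) | set(PARAMETER_NAMES) | {"rp_height_um", "flags"}

    records = []
    for i, row in df.iterrows():
        params = None
        if has_params and not any(pd.isna(row[c]) for c in PARAMETER_NAMES):
            rp = row.get("rp_height_um", np.nan)
            try:
                params = DiscParameters(
                    **{c: float(row[c]) for c in PARAMETER_NAMES},
                    rp_height_um=float(rp) if not pd.isna(rp) else 120.0,
                ).validate()
            except (ValidationError, ValueError) as exc:
                raise ParseError(f"{path} row {i + 2}: {exc}") from exc
        extra = {c: row[c] for c in df.columns if c not in known}
        try:
            records.append(EyeRecord(
                eye_id=str(row["eye_id"]),
                laterality=(str(row["laterality"])
                            if "laterality" in df.columns and not pd.isna(row["laterality"])
                            else None),
                disc_type=(str(row["disc_type"])
                           if "disc_type" in df.columns and not pd.isna(row["disc_type"])
                           else None),
                cprnflt_um=_opt_float(row.get("cprnflt_um", np.nan)),
                md_db=_opt_float(row.get("md_db", np.nan)),
                se_d=_opt_float(row.get("se_d", np.nan)),
                iop_mmhg=_opt_float(row.get("iop_mmhg", np.nan)),
                age_y=_opt_float(row.get("age_y", np.nan)),
                params=params,
                extra=extra,
            ))
        except ValidationError as exc:
            raise ParseError(f"{path} row {i + 2}: {exc}") from exc
    return records


def write_parameters(records: Sequence[EyeRecord], path: Union[str, Path]) -> Path:
    """Write cohort records (+ parameters) to CSV with a stable column order.

    Values round-trip through :func:`read_cohort` to better than 1e-9;
    missing fields are written as empty cells.
    """
    if not records:
        raise ValidationError("refusing to write an empty cohort")
    path = Path(path)
    rows = []
    for r in records:
        row = {
            "eye_id": r.eye_id,
            "laterality": r.laterality,
            "disc_type": r.disc_type,
            "cprnflt_um": r.cprnflt_um,
            "md_db": r.md_db,
            "se_d": r.se_d,
            "iop_mmhg": r.iop_mmhg,
            "age_y": r.age_y,
        }
        if r.params is not None:
            row.update(r.params.as_dict())
            row["rp_height_um"] = r.params.rp_height_um
            row["flags"] = "|".join(r.params.flags)
        rows.append(row)
    columns = list(_COHORT_FIELDS)
    if any(r.params is not None for r in records):
        columns += list(PARAMETER_NAMES) + ["rp_height_um", "flags"]
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format="%.17g", na_rep="")
    return path


def save_model(model: DiscTypeModel, path: Union[str, Path]) -> Path:
    """Serialize a DiscTypeModel to versioned JSON (validates first)."""
    psum = sum(model.priors.values())
    if abs(psum - 1.0) > 1e-9:
        raise ValidationError(f"refusing to save model: priors sum to {psum}")
    if np.linalg.eigvalsh(model.covariance).min() <= 0:
        raise ValidationError("refusing to save model: covariance not PD")
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "kind": "disc-type-lda",
        "features": model.features,
        "classes": model.classes,
        "means": {c: model.means[c].tolist() for c in model.classes},
        "covariance": np.asarray(model.covariance).tolist(),
        "priors": {c: model.priors[c] for c in model.classes},
        "rp_height_um": model.rp_height_um,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def load_model(path: Union[str, Path]) -> DiscTypeModel:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid model JSON: {exc}") from exc
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ParseError(
            f"{path}: model schema version {version!r} != {MODEL_SCHEMA_VERSION}"
        )
    try:
        return DiscTypeModel(
            features=list(payload["features"]),
            classes=list(payload["classes"]),
            means={c: np.asarray(m, dtype=float)
                   for c, m in payload["means"].items()},
            covariance=np.asarray(payload["covariance"], dtype=float),
            priors={c: float(v) for c, v in payload["priors"].items()},
            rp_height_um=payload.get("rp_height_um"),
        )
    except (KeyError, ValidationError) as exc:
        raise ParseError(f"{path}: invalid model payload: {exc}") from exc
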