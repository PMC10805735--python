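"""Readers and writers for the pipeline's on-disk formats.

Images travel as plain multi-page TIFF (one page per channel, float32) with
a JSON sidecar holding channel roles, pixel size and labels; label masks as
16-bit TIFF with their own sidecar (source role, parent map, border flags).
Tables are CSV via pandas.  Every writer has a paired reader with lossless
field recovery, which the round-trip tests assert.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .profiling import ProfileSummary, RadialProfile
from .types import ImageField, LabeledMask

SIDECAR_SUFFIX = ".json"


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + SIDECAR_SUFFIX)


def write_field(field: ImageField, path: str | Path) -> Path:
    """Write a multi-channel field as TIFF + JSON sidecar; returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path, np.asarray(field.pixels, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "kind": "image_field",
        "pixel_size_um": field.pixel_size,
        "z_spacing_um": field.z_spacing,
        "channel_roles": dict(field.channel_roles),
        "field_id": field.field_id,
        "condition": field.condition,
        "metadata": field.metadata,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_field(path: str | Path) -> ImageField:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return ImageField(
        pixels=pixels,
        pixel_size=meta["pixel_size_um"],
        z_spacing=meta.get("z_spacing_um"),
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        field_id=meta.get("field_id", path.stem),
        condition=meta.get("condition", ""),
        metadata=meta.get("metadata", {}),
    )


def write_mask(mask: LabeledMask, path: str | Path) -> Path:
    """Write a label mask as 16-bit TIFF + JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = np.asarray(mask.labels)
    if labels.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))
    meta = {
        "kind": "label_mask",
        "source_role": mask.source_role,
        "parent": {str(k): int(v) for k, v in (mask.parent or {}).items()},
        "border_labels": sorted(int(v) for v in mask.border_labels),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_mask(path: str | Path) -> LabeledMask:
    path = Path(path)
    labels = tifffile.imread(path).astype(np.int32)
    meta = json.loads(_sidecar(path).read_text())
    parent = {int(k): int(v) for k, v in meta.get("parent", {}).items()}
    return LabeledMask(
        labels=labels,
        source_role=meta.get("source_role", ""),
        parent=parent or None,
        border_labels=frozenset(meta.get("border_labels", [])),
    )


def regions_table(mask: LabeledMask) -> pd.DataFrame:
    """Tidy per-region table: label, parent, area, centroid, border flag."""
    rows = []
    for lab in mask.region_labels:
        region = mask.labels == lab
        coords = np.nonzero(region)
        cent = [float(c.mean()) for c in coords]
        row = {
            "label": lab,
            "parent": mask.parent_of(lab),
            "area_px": int(region.sum()),
            "border": lab in mask.border_labels,
        }
        axes = ["plane", "row", "col"][-mask.labels.ndim :]
        for ax, c in zip(axes, cent):
            row[f"centroid_{ax}"] = c
        rows.append(row)
    return pd.DataFrame(rows)


def profiles_table(profiles: list[RadialProfile]) -> pd.DataFrame:
    """Long-format per-nucleolus profile table (one row per bin)."""
    rows = []
    for p in profiles:
        for center, mean, n in zip(p.bin_centers, p.mean_intensity, p.n_samples):
            rows.append(
                {
                    "field_id": p.field_id,
                    "cell_id": p.cell_id,
                    "nucleolus_id": p.nucleolus_id,
                    "condition": p.condition,
                    "d_bin_center": float(center),
                    "mean_intensity": float(mean) if np.isfinite(mean) else np.nan,
                    "n_samples": int(n),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "field_id",
            "cell_id",
            "nucleolus_id",
            "condition",
            "d_bin_center",
            "mean_intensity",
            "n_samples",
        ],
    )


def summary_table(summary: ProfileSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "d_bin_center": summary.bin_centers,
            "mean": summary.mean,
            "sd": summary.sd,
            "n_per_bin": summary.n_per_bin,
            "n_nucleoli": summary.n_nucleoli,
            "n_cells": summary.n_cells,
            "condition": summary.condition,
            "normalization": summary.normalization,
        }
    )


def write_csv(table: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV writer (fixed float representation, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"cannot serialize {type(o)!r}")
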