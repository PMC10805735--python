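"""End-to-end orchestration: simulate -> segment -> profile -> compare.

A :class:`RunConfig` fully determines a run (it round-trips through YAML and
is copied, resolved, into every output directory together with the package
version).  All randomness flows from the single ``seed``; a rerun with the
same config and seed produces byte-identical CSV outputs.

The manifest written at the end records per-stage counts (fields, nuclei,
nucleoli found / excluded with machine-readable reasons) so that a run can
be audited without re-reading the images.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ConfigError, NoRegionsError
from .io import (
    profiles_table,
    regions_table,
    summary_table,
    write_csv,
    write_field,
    write_json,
    write_mask,
)
from .profiling import (
    DEFAULT_D_MAX,
    DEFAULT_N_BINS,
    DEFAULT_N_RAYS,
    DEFAULT_STEP,
    INNER_WINDOW,
    OUTER_WINDOW,
    aggregate,
    profile_field,
    smooth_profile,
    window_means_table,
)
from .segmentation import segment_nuclei, segment_nucleoli
from .simulate import CONDITION_PRESETS, SyntheticSpec, condition_preset, generate_field
from .stats import compare_conditions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one synthetic two-or-more-condition run."""

    conditions: tuple[str, ...] = ("control", "RNAPI_inhibited_like")
    n_fields_per_condition: int = 4
    seed: int = 0
    # segmentation
    min_nucleus_area: float = 2000.0
    min_nucleolus_area: float = float(np.pi * 25.0)
    # profiling
    n_rays: int = DEFAULT_N_RAYS
    step: float = DEFAULT_STEP
    d_max: float = DEFAULT_D_MAX
    n_bins: int = DEFAULT_N_BINS
    smooth_window: int = 5
    inner_window: tuple[float, float] = INNER_WINDOW
    outer_window: tuple[float, float] = OUTER_WINDOW
    target_role: str = "target"
    # simulation overrides (None -> SyntheticSpec defaults)
    spec_overrides: dict = field(default_factory=dict)
    save_images: bool = False
    version: str = ""

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.inner_window = tuple(self.inner_window)
        self.outer_window = tuple(self.outer_window)
        if len(self.conditions) < 1:
            raise ConfigError("at least one condition required")
        for c in self.conditions:
            if c not in CONDITION_PRESETS:
                raise ConfigError(
                    f"unknown condition {c!r}; valid: {', '.join(CONDITION_PRESETS)}"
                )
        if self.n_fields_per_condition < 1:
            raise ConfigError("n_fields_per_condition must be >= 1")
        lo_i, hi_i = self.inner_window
        lo_o, hi_o = self.outer_window
        if not (0 <= lo_i < hi_i and lo_o < hi_o <= self.d_max):
            raise ConfigError("windows must be increasing and within [0, d_max]")
        if hi_i > lo_o:
            raise ConfigError(
                f"inside window {self.inner_window} overlaps outside window "
                f"{self.outer_window}"
            )
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd and >= 1")
        # canonicalize overrides to YAML/JSON-native types so that a config
        # round-trips losslessly (tuples become lists)
        import json as _json

        self.spec_overrides = _json.loads(_json.dumps(self.spec_overrides))
        if not self.version:
            self.version = __version__

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        d["inner_window"] = list(self.inner_window)
        d["outer_window"] = list(self.outer_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def profiling_params(self) -> dict:
        return {
            "n_rays": self.n_rays,
            "step": self.step,
            "d_max": self.d_max,
            "n_bins": self.n_bins,
        }


def _condition_seeds(seed: int, conditions, n_fields: int) -> dict[str, list[int]]:
    """One child seed per (condition, field), all below 2**31."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(conditions))
    return {
        cond: [int(s % 2**31) for s in child.generate_state(n_fields)]
        for cond, child in zip(conditions, children)
    }


def simulate_condition(
    config: RunConfig, condition: str, field_seeds: list[int]
) -> list:
    """Generate the fields of one condition from its per-field seeds."""
    preset = condition_preset(condition)
    fields = []
    for i, s in enumerate(field_seeds):
        spec = preset(SyntheticSpec(seed=s, **config.spec_overrides))
        fld, truth = generate_field(spec)
        fld.field_id = f"{condition}-f{i:03d}"
        fields.append((fld, truth))
    return fields


def analyze_field(fld, config: RunConfig):
    """Segment and profile one field; returns (profiles, counts, exclusions)."""
    counts = {"nuclei": 0, "nucleoli": 0}
    exclusions: list[dict] = []
    try:
        nuclei = segment_nuclei(fld, min_area=config.min_nucleus_area)
    except NoRegionsError:
        return [], counts, [{"stage": "segment_nuclei", "reason": "no-regions"}], None, None
    nucleoli = segment_nucleoli(fld, nuclei, min_area=config.min_nucleolus_area)
    counts["nuclei"] = nuclei.n_regions
    counts["nucleoli"] = nucleoli.n_regions
    profiles, excluded = profile_field(
        fld,
        nucleoli,
        nuclei=nuclei,
        role=config.target_role,
        **config.profiling_params(),
    )
    for lab, reason in excluded:
        exclusions.append(
            {"stage": "profile", "field_id": fld.field_id, "label": lab, "reason": reason}
        )
    return profiles, counts, exclusions, nuclei, nucleoli


def collect_window_means(
    condition: str,
    n_nucleoli: int,
    seed: int,
    config: RunConfig | None = None,
    max_fields: int = 200,
):
    """Simulate fields of one condition until ``n_nucleoli`` window means
    are collected (then truncate), running the full segment-and-profile
    path on every field.

    This is the building block for power/recovery experiments where the
    number of nucleoli per group is fixed by design (e.g. 60 per condition).
    Returns the window-means table (exactly ``n_nucleoli`` rows).
    """
    config = config or RunConfig(conditions=(condition,))
    preset = condition_preset(condition)
    ss = np.random.SeedSequence(seed)
    field_seeds = [int(s % 2**31) for s in ss.generate_state(max_fields)]
    tables = []
    total = 0
    for i, s in enumerate(field_seeds):
        spec = preset(SyntheticSpec(seed=s, **config.spec_overrides))
        fld, _truth = generate_field(spec)
        fld.field_id = f"{condition}-f{i:03d}"
        profiles, _, _, _, _ = analyze_field(fld, config)
        wm, _ = window_means_table(
            profiles, inner=config.inner_window, outer=config.outer_window
        )
        tables.append(wm)
        total += len(wm)
        if total >= n_nucleoli:
            break
    if total < n_nucleoli:
        raise RuntimeError(
            f"only {total} nucleoli collected after {max_fields} fields"
        )
    import pandas as pd

    return pd.concat(tables, ignore_index=True).iloc[:n_nucleoli].reset_index(drop=True)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    Stages: simulate each condition, segment nuclei and nucleoli, profile
    every nucleolus, compute window means, compare conditions (when >= 2).
    Any stage error aborts with the stage name and offending object in the
    exception message; outputs written so far are flagged as partial in the
    manifest.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    manifest: dict = {
        "version": config.version,
        "seed": config.seed,
        "partial": True,
        "conditions": {},
        "exclusions": [],
    }
    write_json(manifest, out / "manifest.json")

    seeds = _condition_seeds(config.seed, config.conditions, config.n_fields_per_condition)
    all_profiles: dict[str, list] = {}
    windows: dict[str, object] = {}

    try:
        for cond in config.conditions:
            stage = f"simulate[{cond}]"
            fields = simulate_condition(config, cond, seeds[cond])
            cond_profiles = []
            n_fields = 0
            n_nuclei = 0
            n_nucleoli = 0
            for fld, _truth in fields:
                stage = f"analyze[{fld.field_id}]"
                profiles, counts, exclusions, nuclei, nucleoli = analyze_field(fld, config)
                n_fields += 1
                n_nuclei += counts["nuclei"]
                n_nucleoli += counts["nucleoli"]
                manifest["exclusions"].extend(exclusions)
                cond_profiles.extend(profiles)
                if config.save_images and nuclei is not None:
                    write_field(fld, out / "images" / f"{fld.field_id}.tif")
                    write_mask(nuclei, out / "masks" / f"{fld.field_id}_nuclei.tif")
                    write_mask(nucleoli, out / "masks" / f"{fld.field_id}_nucleoli.tif")
                    write_csv(
                        regions_table(nucleoli),
                        out / "masks" / f"{fld.field_id}_regions.csv",
                    )
            stage = f"profile[{cond}]"
            all_profiles[cond] = cond_profiles
            wm, wm_excluded = window_means_table(
                cond_profiles, inner=config.inner_window, outer=config.outer_window
            )
            for lab, reason in wm_excluded:
                manifest["exclusions"].append(
                    {"stage": "window_means", "condition": cond, "label": lab,
                     "reason": reason}
                )
            windows[cond] = wm
            if cond_profiles:
                summary = aggregate(
                    [smooth_profile(p, config.smooth_window) for p in cond_profiles]
                )
                write_csv(summary_table(summary), out / f"summary_{cond}.csv")
            write_csv(profiles_table(cond_profiles), out / f"profiles_{cond}.csv")
            write_csv(wm, out / f"windows_{cond}.csv")
            manifest["conditions"][cond] = {
                "n_fields": n_fields,
                "n_nuclei": n_nuclei,
                "n_nucleoli": n_nucleoli,
                "n_profiled": len(cond_profiles),
                "n_window_means": int(len(wm)),
            }

        if len(config.conditions) >= 2:
            stage = "compare"
            params = {c: config.profiling_params() for c in config.conditions}
            stats = compare_conditions({c: windows[c] for c in config.conditions}, params)
            write_csv(stats, out / "stats.csv")
            manifest["stats"] = stats.to_dict(orient="records")
    except Exception as e:  # noqa: BLE001 - annotate stage, re-raise
        write_json(manifest, out / "manifest.json")
        raise type(e)(f"pipeline stage {stage!r} failed: {e}") from e

    manifest["partial"] = False
    write_json(manifest, out / "manifest.json")
    write_json(
        {"profiling": config.profiling_params(), "version": config.version},
        out / "params.json",
    )
    return manifest
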