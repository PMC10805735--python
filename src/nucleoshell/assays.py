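"""Table-based assay quantification.

Two readouts accompany the imaging pipeline:

* the in vitro psoralen crosslink-protection assay: crosslinking protects
  DNA from heat denaturation, so the protected (crosslinked) fraction of a
  gel lane is the non-denatured band divided by the total band;
* ChIP-qPCR percent input: the fraction of input chromatin recovered by an
  immunoprecipitation, computed from the Ct difference between the IP and a
  known input aliquot, then normalized to a control condition so a
  one-sample t test against 1 asks whether the treatment changed binding.

Percent input assumes per-cycle amplification ``efficiency`` (2.0 = ideal
doubling, config-exposed):

    %input = 100 * input_fraction * efficiency ** (ct_input - ct_ip)

which is algebraically identical to the adjusted-input formulation where
the input Ct is first corrected by log2(1 / input_fraction).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ConfigError
from .stats import one_sample_t

logger = logging.getLogger(__name__)


def crosslink_fraction(
    band_nondenatured: float, band_total: float
) -> tuple[float, bool]:
    """Crosslink-protected fraction of one gel lane.

    Returns ``(fraction, clipped)``: the ratio non-denatured / total,
    clipped into [0, 1] with ``clipped=True`` when measurement noise pushed
    the raw ratio outside the physical range.  ``band_total`` must be
    positive.
    """
    if band_total <= 0:
        raise ValueError(f"band_total must be positive, got {band_total}")
    if band_nondenatured < 0:
        raise ValueError(f"band_nondenatured must be >= 0, got {band_nondenatured}")
    raw = band_nondenatured / band_total
    clipped = raw > 1.0
    if clipped:
        logger.info(
            "crosslink fraction %.4f exceeds 1 (noise); clipping to 1.0", raw
        )
    return min(raw, 1.0), clipped


def crosslink_fraction_table(lanes: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`crosslink_fraction` to a gel-lane table.

    Expects columns ``band_nondenatured`` and ``band_total``; returns a copy
    with ``fraction`` and ``clipped`` columns appended.
    """
    out = lanes.copy()
    res = [
        crosslink_fraction(nd, tot)
        for nd, tot in zip(out["band_nondenatured"], out["band_total"])
    ]
    out["fraction"] = [f for f, _ in res]
    out["clipped"] = [c for _, c in res]
    return out


def percent_input(
    ip_ct: float,
    input_ct: float,
    input_fraction: float = 0.02,
    efficiency: float = 2.0,
) -> float:
    """ChIP-qPCR percent input for one IP / input Ct pair."""
    if not (0.0 < input_fraction < 1.0):
        raise ValueError(f"input_fraction must lie in (0, 1), got {input_fraction}")
    if efficiency <= 1.0:
        raise ValueError(f"efficiency must exceed 1, got {efficiency}")
    if not (math.isfinite(ip_ct) and math.isfinite(input_ct)):
        raise ValueError("Ct values must be finite")
    return 100.0 * input_fraction * efficiency ** (input_ct - ip_ct)


def percent_input_table(
    ct_table: pd.DataFrame,
    input_antibody: str = "input",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Percent input for every IP row of a Ct table.

    The table must carry columns ``target_region``, ``antibody``,
    ``condition``, ``ct`` and ``input_fraction`` (plus ``replicate`` when
    replicates are present); input rows are identified by
    ``antibody == input_antibody`` and matched to IP rows on
    (region, condition[, replicate]).
    """
    keys = ["target_region", "condition"]
    if "replicate" in ct_table.columns:
        keys.append("replicate")
    inputs = ct_table[ct_table["antibody"] == input_antibody]
    if inputs.empty:
        raise ConfigError(f"no rows with antibody == {input_antibody!r}")
    ref = inputs.set_index(keys)[["ct", "input_fraction"]]
    if ref.index.duplicated().any():
        raise ConfigError("multiple input rows for one (region, condition, replicate)")
    ips = ct_table[ct_table["antibody"] != input_antibody].copy()
    rows = []
    for _, row in ips.iterrows():
        key = tuple(row[k] for k in keys)
        try:
            input_ct, frac = ref.loc[key, "ct"], ref.loc[key, "input_fraction"]
        except KeyError:
            raise ConfigError(f"no input row matching {dict(zip(keys, key))}") from None
        rows.append(
            percent_input(row["ct"], float(input_ct), float(frac), efficiency)
        )
    ips["percent_input"] = rows
    return ips.reset_index(drop=True)


def normalize_percent_input(
    table: pd.DataFrame,
    control_condition: str = "water",
) -> pd.DataFrame:
    """Divide each percent-input value by its matched control value.

    Matching is on (target_region, antibody[, replicate]); every such key
    must be present in the control condition with a nonzero value, else an
    error names the missing pair.  Control entries become exactly 1, so the
    normalized treated values are ready for a one-sample t test against 1.
    Normalizing an already-normalized table is idempotent.
    """
    keys = ["target_region", "antibody"]
    if "replicate" in table.columns:
        keys.append("replicate")
    ctrl = table[table["condition"] == control_condition]
    if ctrl.empty:
        raise ConfigError(f"control condition {control_condition!r} absent from table")
    ref = ctrl.set_index(keys)["percent_input"]
    out = table.copy()
    normalized = []
    for _, row in out.iterrows():
        key = tuple(row[k] for k in keys)
        try:
            denom = float(ref.loc[key])
        except KeyError:
            raise ConfigError(
                f"no control ({control_condition!r}) entry for "
                f"{dict(zip(keys, key))}"
            ) from None
        if denom == 0:
            raise ConfigError(
                f"control percent input is zero for {dict(zip(keys, key))}"
            )
        normalized.append(row["percent_input"] / denom)
    out["normalized_percent_input"] = normalized
    return out


def analyze_chip(
    ct_table: pd.DataFrame,
    control_condition: str = "water",
    antibody: str = "NPM",
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Full ChIP-qPCR analysis: percent input -> control normalization ->
    one-sample t test of the treated condition against 1, per region.

    Returns a tidy table (region, condition, mean normalized percent input,
    s.d., n, t, p) for the requested antibody; replicates are the sampling
    unit.
    """
    pi = percent_input_table(ct_table, efficiency=efficiency)
    norm = normalize_percent_input(pi, control_condition=control_condition)
    sel = norm[norm["antibody"] == antibody]
    rows = []
    for (region, cond), grp in sel.groupby(["target_region", "condition"], sort=True):
        vals = grp["normalized_percent_input"].to_numpy()
        rec = {
            "target_region": region,
            "condition": cond,
            "mean_normalized": float(vals.mean()),
            "sd_normalized": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
            "t": np.nan,
            "p_value": np.nan,
        }
        if cond != control_condition and vals.size >= 2 and vals.std(ddof=1) > 0:
            res = one_sample_t(vals, 1.0)
            rec["t"], rec["p_value"] = res.statistic, res.p_value
        rows.append(rec)
    return pd.DataFrame(rows)
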