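"""Shared fixtures-in-code: analytic disk fields and independent oracles."""

from __future__ import annotations

import numpy as np

from nucleoshell.types import ImageField, LabeledMask

# generic (non-integer) center: integer centers place Pythagorean-triple
# pixels at exactly d = 1, a degenerate grid alignment
GENERIC_CENTER = (127.37, 128.81)


def disk_field(
    radius: float,
    law,
    shape: tuple[int, int] = (256, 256),
    center: tuple[float, float] = GENERIC_CENTER,
    role: str = "target",
):
    """Noiseless single-disk field: image = law(analytic d), mask = d <= 1.

    Returns (field, mask, d) where d is the analytic normalized distance of
    every pixel — the independent ground truth for profiling oracles.
    """
    rr, cc = np.meshgrid(
        np.arange(shape[0], dtype=float), np.arange(shape[1], dtype=float),
        indexing="ij",
    )
    d = np.hypot(rr - center[0], cc - center[1]) / radius
    field = ImageField(
        pixels=np.asarray(law(d))[None], pixel_size=0.063, channel_roles={role: 0}
    )
    mask = LabeledMask((d <= 1.0).astype(np.int32), source_role="shell_marker")
    return field, mask, d


def pixel_binning_oracle(img, d, n_bins=40, d_max=2.0):
    """Independent per-pixel oracle: bin every pixel by its analytic d."""
    sel = d <= d_max
    width = d_max / n_bins
    idx = np.minimum((d[sel] / width).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=img[sel], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def matched_ious(segmented: LabeledMask, truth: LabeledMask) -> list[float]:
    """Best IoU of each truth region against any segmented region."""
    out = []
    for lab in truth.region_labels:
        t = truth.labels == lab
        best = 0.0
        for sl in segmented.region_labels:
            s = segmented.labels == sl
            if np.logical_and(s, t).any():
                best = max(best, iou(s, t))
        out.append(best)
    return out


def profile_crossing(profile, lo=None, hi=None) -> float:
    """d at which a (step-like) profile crosses its half level."""
    y = profile.mean_intensity
    top = np.nanmax(y) if hi is None else hi
    bot = np.nanmin(y) if lo is None else lo
    mid = (top + bot) / 2.0
    below = np.flatnonzero(y < mid)
    below = below[below > 2]
    k = below[0]
    frac = (y[k - 1] - mid) / (y[k - 1] - y[k])
    return float(profile.bin_centers[k - 1] + profile.bin_width * frac)
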