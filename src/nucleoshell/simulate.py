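"""Synthetic core-shell condensate images with analytic ground truth.

The generator emulates the imaging situation the analysis pipeline is built
for: nuclei containing a handful of nucleoli, each with a core-shell
architecture (fibrillar core surrounded by a granular-component-like shell),
observed in three fluorescence channels:

* ``nucleus_marker`` - a DAPI-like stain, uniform over the nucleus;
* ``shell_marker``   - an NPM-like protein enriched in the shell annulus;
* ``target``         - the signal of interest, whose radial distribution is
  parameterized (core-enriched under control conditions, flattened or
  globally reduced under drug-like perturbations).

Every channel's noiseless expectation at a pixel is a function of the
pixel's normalized distance ``d`` to the nearest nucleolus centroid, where
``d = (distance to centroid) / (boundary radius along that direction)``:
``d = 1`` is the nucleolar boundary, ``d <= 2`` the annulus profiled
downstream, and beyond that the channel sits at its nucleoplasm baseline.
Ground-truth masks are the pre-blur analytic disks, so segmentation and
profiling can be tested against exact geometry.

Determinism: a single integer seed drives one ``numpy`` Generator stream;
identical (spec, seed) gives bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import PlacementError
from .types import ImageField, LabeledMask

logger = logging.getLogger(__name__)

MAX_PLACEMENT_ATTEMPTS = 10_000

CONDITION_PRESETS = ("control", "BLM_like", "RNAPI_inhibited_like", "G4_ligand_like")


# ---------------------------------------------------------------------------
# Radial intensity laws
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PiecewiseConstantLaw:
    """Piecewise-constant radial law f(d) on [0, d_max], baseline beyond.

    ``levels[i]`` applies on the i-th interval delimited by ``edges``
    (interior breakpoints, increasing); intervals are closed on the right,
    so a pixel at exactly d = 1 belongs to the nucleolus body, matching the
    mask convention d <= 1.  ``baseline`` is the nucleoplasm level for
    d > d_max.
    """

    levels: tuple[float, ...]
    edges: tuple[float, ...] = ()
    baseline: float = 0.0
    d_max: float = 2.0

    def __post_init__(self):
        if len(self.levels) != len(self.edges) + 1:
            raise ValueError("need len(levels) == len(edges) + 1")
        if any(e1 >= e2 for e1, e2 in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        idx = np.searchsorted(np.asarray(self.edges), d, side="left")
        out = np.asarray(self.levels)[idx]
        return np.where(d > self.d_max, self.baseline, out)

    def scaled(self, factor: float) -> "PiecewiseConstantLaw":
        """Multiply the whole law (all levels and the baseline) by ``factor``."""
        return replace(
            self,
            levels=tuple(v * factor for v in self.levels),
            baseline=self.baseline * factor,
        )

    def window_mean(self, lo: float, hi: float) -> float:
        """Analytic mean of f over d in [lo, hi] (uniform measure in d)."""
        pts = [lo] + [e for e in self.edges if lo < e < hi] + [hi]
        total = 0.0
        for a, b in zip(pts, pts[1:]):
            total += self((a + b) / 2.0) * (b - a)
        return total / (hi - lo)


@dataclass(frozen=True)
class UniformLaw:
    """Constant law: f(d) = value everywhere, including the nucleoplasm."""

    value: float
    d_max: float = 2.0

    @property
    def baseline(self) -> float:
        return self.value

    def __call__(self, d: np.ndarray) -> np.ndarray:
        return np.full_like(np.asarray(d, dtype=float), self.value)

    def scaled(self, factor: float) -> "UniformLaw":
        return replace(self, value=self.value * factor)

    def window_mean(self, lo: float, hi: float) -> float:
        return self.value


@dataclass(frozen=True)
class CustomLaw:
    """Arbitrary radial law wrapping a vectorized callable (test utility)."""

    fn: Callable[[np.ndarray], np.ndarray]
    baseline: float = 0.0
    d_max: float = 2.0

    def __call__(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        return np.where(d > self.d_max, self.baseline, np.asarray(self.fn(d), float))

    def window_mean(self, lo: float, hi: float, n: int = 10_001) -> float:
        d = np.linspace(lo, hi, n)
        return float(np.trapezoid(self(d), d) / (hi - lo))


def core_step_law(inside: float, outside: float) -> PiecewiseConstantLaw:
    """Core-enriched target law: ``inside`` for d <= 1, ``outside`` beyond."""
    return PiecewiseConstantLaw(levels=(inside, outside), edges=(1.0,), baseline=outside)


def shell_marker_law(
    core: float, shell: float, outside: float, shell_thickness: float
) -> PiecewiseConstantLaw:
    """Shell-enriched (NPM-like) law peaking on [1 - thickness, 1]."""
    return PiecewiseConstantLaw(
        levels=(core, shell, outside),
        edges=(1.0 - shell_thickness, 1.0),
        baseline=outside,
    )


# ---------------------------------------------------------------------------
# Specification and ground truth
# ---------------------------------------------------------------------------

#: Default intensity scale conventions (arbitrary camera units).  The real
#: instrument's units/SNR are unknown; these are stated conventions, echoed
#: into output metadata by the writers.
DEFAULT_NUCLEOPLASM = 50.0
DEFAULT_CORE_RATIO = 3.0  # inside/outside contrast of the control target law


def default_channel_laws(
    shell_thickness: float = 0.25, core_ratio: float = DEFAULT_CORE_RATIO
) -> dict:
    return {
        "nucleus_marker": UniformLaw(100.0),
        "shell_marker": shell_marker_law(60.0, 200.0, 20.0, shell_thickness),
        "target": core_step_law(core_ratio * DEFAULT_NUCLEOPLASM, DEFAULT_NUCLEOPLASM),
    }


@dataclass
class SyntheticSpec:
    """Full description of one synthetic field.

    Geometry defaults approximate a 40x/1.4 super-resolution field of view
    (512 x 512 px at 0.063 um/px; nucleus radius ~120 px; nucleoli
    25 +/- 5 px with a shell occupying the outer 25% of the radius).  The
    values are stated conventions, not measurements.

    Noise model: optional Gaussian PSF blur, then Poisson photon noise
    (``poisson_scale`` photons per intensity unit; ``None`` disables), then
    additive Gaussian read noise.  ``blur_sigma = 0`` and
    ``gaussian_noise_sd = 0`` disable those stages, which the analytic
    oracle tests rely on.
    """

    image_shape: tuple[int, ...] = (512, 512)
    pixel_size: float = 0.063
    z_spacing: float = 0.3
    n_cells: int = 1
    nucleus_radius: tuple[float, float] = (120.0, 10.0)
    nucleoli_per_nucleus: tuple[int, int] = (3, 5)
    nucleolus_radius: tuple[float, float] = (25.0, 5.0)
    nucleolus_radius_limits: tuple[float, float] = (15.0, 35.0)
    shell_thickness: float = 0.25
    boundary_harmonics: tuple[tuple[int, float], ...] = ()
    channel_laws: dict = field(default_factory=default_channel_laws)
    blur_sigma: float = 2.0
    poisson_scale: float | None = 1.0
    gaussian_noise_sd: float = 2.0
    condition_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_shape) not in (2, 3):
            raise ValueError("image_shape must be 2D (H, W) or 3D (Z, H, W)")
        if self.pixel_size <= 0 or self.z_spacing <= 0:
            raise ValueError("pixel sizes must be strictly positive")
        if self.nucleus_radius[0] <= 0 or self.nucleolus_radius[0] <= 0:
            raise ValueError("radii must be strictly positive")
        if not (0.0 < self.shell_thickness < 1.0):
            raise ValueError("shell_thickness must lie in (0, 1)")
        lo, hi = self.nucleoli_per_nucleus
        if not (1 <= lo <= hi):
            raise ValueError("nucleoli_per_nucleus must be an increasing range >= 1")
        if self.blur_sigma < 0 or self.gaussian_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.poisson_scale is not None and self.poisson_scale <= 0:
            raise ValueError("poisson_scale must be positive (or None to disable)")
        if not self.channel_laws:
            raise ValueError("at least one channel law is required")

    @property
    def is_3d(self) -> bool:
        return len(self.image_shape) == 3


@dataclass(frozen=True)
class BoundaryShape:
    """Analytic nucleolus outline: radius modulated by angular harmonics.

    r_b(theta) = radius * (1 + sum_m amp_m * cos(m*theta + phase_m)).
    With no harmonics this is a circle (sphere in 3D).
    """

    radius: float
    harmonics: tuple[tuple[int, float, float], ...] = ()  # (order, amp, phase)

    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        r = np.full_like(theta, self.radius)
        for m, amp, phase in self.harmonics:
            r = r + self.radius * amp * np.cos(m * theta + phase)
        return r

    @property
    def max_radius(self) -> float:
        return self.radius * (1.0 + sum(abs(a) for _, a, _ in self.harmonics))


@dataclass
class SyntheticTruth:
    """Ground truth of a generated field, for oracle tests.

    Masks are the pre-blur analytic disks; ``centroids`` are the exact
    placement centers; ``boundary`` the analytic outline of each nucleolus.
    """

    nucleus_mask: LabeledMask
    nucleolus_mask: LabeledMask
    centroids: dict[int, tuple[float, ...]]
    boundary: dict[int, BoundaryShape]
    channel_laws: dict
    parent: dict[int, int]

    @property
    def boundary_radius(self) -> dict[int, float]:
        return {k: b.radius for k, b in self.boundary.items()}

    def distance_field(self, label: int) -> np.ndarray:
        """Analytic normalized distance d of every pixel to nucleolus ``label``.

        This is the independent per-pixel oracle used to validate the
        ray-based profiler: bin pixels by this d and average.
        """
        shape = self.nucleolus_mask.labels.shape
        center = self.centroids[label]
        b = self.boundary[label]
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
        deltas = [g - c for g, c in zip(grids, center)]
        if len(shape) == 3:
            # anisotropic z handled by the caller via scaled coordinates
            raise NotImplementedError("use 2D fields for the per-pixel oracle")
        dist = np.hypot(deltas[0], deltas[1])
        theta = np.arctan2(deltas[0], deltas[1])
        rb = b.radius_at(theta)
        with np.errstate(invalid="ignore"):
            d = dist / rb
        d[np.isnan(d)] = 0.0
        return d


# ---------------------------------------------------------------------------
# Condition presets
# ---------------------------------------------------------------------------


def condition_preset(
    name: str,
    rho: float = DEFAULT_CORE_RATIO,
    reduction: float = 0.5,
    shell_reduction: float = 0.5,
    nucleoplasm: float = DEFAULT_NUCLEOPLASM,
):
    """Return a spec modifier implementing one perturbation condition.

    * ``control``             - core-enriched target, inside/outside ratio rho;
    * ``BLM_like``            - strand-break-like: the whole target law (all d,
      including the nucleoplasm baseline) multiplied by ``reduction``;
    * ``RNAPI_inhibited_like``- polymerase-I-inhibition-like: core contrast
      collapses (rho -> 1), nucleoplasm unchanged;
    * ``G4_ligand_like``      - shell-anchor-blocking: core contrast collapses
      and the shell-marker law is scaled by ``shell_reduction``.

    The modifier takes and returns a :class:`SyntheticSpec` (the input is not
    mutated) and stamps ``condition_label``.
    """
    if name not in CONDITION_PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(CONDITION_PRESETS)}"
        )

    def modifier(spec: SyntheticSpec) -> SyntheticSpec:
        laws = dict(spec.channel_laws)
        if name == "control":
            laws["target"] = core_step_law(rho * nucleoplasm, nucleoplasm)
        elif name == "BLM_like":
            laws["target"] = core_step_law(rho * nucleoplasm, nucleoplasm).scaled(
                reduction
            )
        elif name == "RNAPI_inhibited_like":
            laws["target"] = core_step_law(nucleoplasm, nucleoplasm)
        elif name == "G4_ligand_like":
            laws["target"] = core_step_law(nucleoplasm, nucleoplasm)
            laws["shell_marker"] = laws["shell_marker"].scaled(shell_reduction)
        return replace(spec, channel_laws=laws, condition_label=name)

    modifier.__name__ = f"preset_{name}"
    return modifier


def make_condition_spec(name: str, seed: int = 0, **preset_kwargs) -> SyntheticSpec:
    """Convenience: default spec with a condition preset applied."""
    return condition_preset(name, **preset_kwargs)(SyntheticSpec(seed=seed))


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v
    return float(np.clip(mean, lo, hi))


def _place_nuclei(rng, spec: SyntheticSpec):
    """Sample non-overlapping nucleus centers/radii; error when infeasible."""
    shape = spec.image_shape
    centers, radii = [], []
    attempts = 0
    zscale = spec.z_spacing / spec.pixel_size if spec.is_3d else 1.0
    for _ in range(spec.n_cells):
        mean, sd = spec.nucleus_radius
        while True:
            attempts += 1
            if attempts > MAX_PLACEMENT_ATTEMPTS:
                raise PlacementError(
                    f"could not place {spec.n_cells} nuclei of radius ~{mean} px "
                    f"in a {shape} image after {MAX_PLACEMENT_ATTEMPTS} attempts"
                )
            # +/- 2 sd truncation: extreme nuclei are neither realistic nor
            # placeable once the condensate margins are accounted for
            r = _truncated_normal(rng, mean, sd, mean - 2 * sd, mean + 2 * sd)
            margin = r + 2.0
            lims = []
            ok = True
            for ax, n in enumerate(shape):
                m = margin / zscale if (spec.is_3d and ax == 0) else margin
                if n - m <= m:
                    ok = False
                    break
                lims.append((m, n - m))
            if not ok:
                continue
            c = tuple(rng.uniform(lo, hi) for lo, hi in lims)
            clash = False
            for c2, r2 in zip(centers, radii):
                dvec = np.array(c) - np.array(c2)
                if spec.is_3d:
                    dvec[0] *= zscale
                if np.linalg.norm(dvec) < r + r2 + 4.0:
                    clash = True
                    break
            if not clash:
                centers.append(c)
                radii.append(r)
                break
    return centers, radii


def _place_nucleoli(rng, spec: SyntheticSpec, nuc_center, nuc_radius):
    """Place nucleoli fully inside one nucleus with their whole d<=2 annulus.

    Pairwise center separation >= 2 * max(r_i, r_j) + 2 px guarantees that
    the d<=2 annulus of one nucleolus never overlaps another nucleolus body;
    an additional 3 * blur_sigma is added so that neighboring condensates
    remain *resolvable* under the PSF (two bodies closer than the blur
    support fuse into one apparent object, which the threshold segmentation
    deliberately does not split).  Positions (and, on congestion, radii and
    count) are redrawn by rejection sampling; a global attempt cap turns
    infeasible requests into an explicit :class:`PlacementError` rather
    than silent overlap.
    """
    lo, hi = spec.nucleoli_per_nucleus
    rlo, rhi = spec.nucleolus_radius_limits
    mean, sd = spec.nucleolus_radius
    harm_amp = sum(abs(a) for _, a in spec.boundary_harmonics)
    zscale = spec.z_spacing / spec.pixel_size if spec.is_3d else 1.0
    attempts = 0
    while True:
        count = int(rng.integers(lo, hi + 1))
        radii = [_truncated_normal(rng, mean, sd, rlo, rhi) for _ in range(count)]
        placed: list[tuple] = []
        for r in radii:
            rmax = r * (1.0 + harm_amp)
            margin = 2.0 * rmax + 2.0  # keep the whole d<=2 annulus inside
            ok_pos = None
            for _ in range(200):
                attempts += 1
                if attempts > MAX_PLACEMENT_ATTEMPTS:
                    raise PlacementError(
                        f"could not place {count} nucleoli (radii ~{mean} px) "
                        f"inside a nucleus of radius {nuc_radius:.0f} px after "
                        f"{MAX_PLACEMENT_ATTEMPTS} attempts"
                    )
                u = rng.normal(size=len(nuc_center))
                u /= np.linalg.norm(u)
                rho = (nuc_radius - margin) * rng.uniform() ** (1.0 / len(nuc_center))
                if rho <= 0:
                    continue
                offset = u * rho
                if spec.is_3d:
                    offset[0] /= zscale
                cand = tuple(np.array(nuc_center) + offset)
                clash = False
                for (c2, r2) in placed:
                    dvec = np.array(cand) - np.array(c2)
                    if spec.is_3d:
                        dvec[0] *= zscale
                    sep = (
                        2.0 * max(r, r2) * (1.0 + harm_amp)
                        + 2.0
                        + 3.0 * spec.blur_sigma
                    )
                    if np.linalg.norm(dvec) < sep:
                        clash = True
                        break
                if not clash:
                    ok_pos = cand
                    break
            if ok_pos is None:
                placed = []
                break  # redraw count and radii
            placed.append((ok_pos, r))
        if placed:
            return placed


def _harmonic_phases(rng, spec: SyntheticSpec) -> tuple:
    return tuple(
        (m, a, float(rng.uniform(0.0, 2.0 * math.pi)))
        for m, a in spec.boundary_harmonics
    )


def generate_field(spec: SyntheticSpec) -> tuple[ImageField, SyntheticTruth]:
    """Render one synthetic field and its ground truth.

    The noiseless expectation of each channel at a pixel inside a nucleus is
    ``law(d)`` where ``d`` is the normalized distance to the *nearest*
    nucleolus (smallest d); pixels farther than d_max from every nucleolus
    sit at the law's nucleoplasm baseline, and pixels outside all nuclei are
    dark.  Blur and noise are then applied to the image only - the truth
    masks stay analytic.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.image_shape)
    roles = list(spec.channel_laws)
    role_index = {r: i for i, r in enumerate(roles)}
    laws = [spec.channel_laws[r] for r in roles]
    zscale = spec.z_spacing / spec.pixel_size if spec.is_3d else 1.0

    nuc_centers, nuc_radii = _place_nuclei(rng, spec)

    image = np.zeros((len(roles),) + shape, dtype=np.float32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nucleolus_labels = np.zeros(shape, dtype=np.int32)
    dmin = np.full(shape, np.inf, dtype=np.float32)

    centroids: dict[int, tuple[float, ...]] = {}
    boundary: dict[int, BoundaryShape] = {}
    parent: dict[int, int] = {}

    next_label = 1
    for nuc_id, (nc, nr) in enumerate(zip(nuc_centers, nuc_radii), start=1):
        # nucleus body, rendered within its bounding box only
        nbox = []
        for ax, n in enumerate(shape):
            e = nr / zscale if (spec.is_3d and ax == 0) else nr
            nbox.append(
                slice(max(0, int(math.floor(nc[ax] - e)) - 1),
                      min(n, int(math.ceil(nc[ax] + e)) + 2))
            )
        nbox = tuple(nbox)
        ngrids = np.ogrid[nbox]
        sq = 0.0
        for ax, (g, c) in enumerate(zip(ngrids, nc)):
            scale = zscale if (spec.is_3d and ax == 0) else 1.0
            sq = sq + ((g - c) * scale) ** 2
        inside_box = sq <= nr**2
        nucleus_labels[nbox][inside_box] = nuc_id
        img_view = image[(slice(None),) + nbox]
        img_view[:, inside_box] = np.array(
            [law.baseline for law in laws], dtype=np.float32
        )[:, None]
        inside_nuc_of = lambda sl: nucleus_labels[sl] == nuc_id  # noqa: E731

        for (center, radius) in _place_nucleoli(rng, spec, nc, nr):
            shape_fn = BoundaryShape(radius=radius, harmonics=_harmonic_phases(rng, spec))
            label = next_label
            next_label += 1
            centroids[label] = tuple(float(v) for v in center)
            boundary[label] = shape_fn
            parent[label] = nuc_id

            # bounding box of the d<=2 annulus
            ext = 2.0 * shape_fn.max_radius + 2.0
            sl = []
            for ax, n in enumerate(shape):
                e = ext / zscale if (spec.is_3d and ax == 0) else ext
                lo = max(0, int(math.floor(center[ax] - e)))
                hi = min(n, int(math.ceil(center[ax] + e)) + 1)
                sl.append(slice(lo, hi))
            sl = tuple(sl)
            sub = np.meshgrid(
                *[np.arange(s.start, s.stop, dtype=float) for s in sl], indexing="ij"
            )
            deltas = []
            for ax, (g, c) in enumerate(zip(sub, center)):
                scale = zscale if (spec.is_3d and ax == 0) else 1.0
                deltas.append((g - c) * scale)
            if spec.is_3d:
                dist = np.sqrt(deltas[0] ** 2 + deltas[1] ** 2 + deltas[2] ** 2)
                rho_xy = np.hypot(deltas[1], deltas[2])
                theta = np.arctan2(deltas[0], rho_xy)  # polar angle; harmonics in it
            else:
                dist = np.hypot(deltas[0], deltas[1])
                theta = np.arctan2(deltas[0], deltas[1])
            rb = shape_fn.radius_at(theta)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = dist / rb
            d[~np.isfinite(d)] = np.inf

            inside_nuc_sl = inside_nuc_of(sl)
            body = d <= 1.0
            nucleolus_labels[sl][body & inside_nuc_sl] = label

            update = (d < dmin[sl]) & (d <= laws[0].d_max) & inside_nuc_sl
            for ci, law in enumerate(laws):
                ch = image[ci][sl]
                ch[update] = law(d[update])
                image[ci][sl] = ch
            dm = dmin[sl]
            dm[update] = d[update]
            dmin[sl] = dm

    # optics + noise
    if spec.blur_sigma > 0:
        sigma = (
            (spec.blur_sigma / zscale,) + (spec.blur_sigma,) * 2
            if spec.is_3d
            else spec.blur_sigma
        )
        for ci in range(len(roles)):
            image[ci] = ndimage.gaussian_filter(image[ci], sigma=sigma, truncate=3.0)
    if spec.poisson_scale is not None:
        lam = np.maximum(image * spec.poisson_scale, 0.0)
        pos = lam > 0  # Poisson(0) == 0; draw only where the rate is nonzero
        counts = np.zeros_like(lam)
        counts[pos] = rng.poisson(lam[pos])
        image = counts / np.float32(spec.poisson_scale)
    if spec.gaussian_noise_sd > 0:
        image = image + spec.gaussian_noise_sd * rng.standard_normal(
            image.shape, dtype=np.float32
        )

    fld = ImageField(
        pixels=image,
        pixel_size=spec.pixel_size,
        z_spacing=spec.z_spacing if spec.is_3d else None,
        channel_roles=role_index,
        field_id=f"{spec.condition_label}-seed{spec.seed}",
        condition=spec.condition_label,
        metadata={
            "seed": spec.seed,
            "blur_sigma": spec.blur_sigma,
            "poisson_scale": spec.poisson_scale,
            "gaussian_noise_sd": spec.gaussian_noise_sd,
        },
    )
    truth = SyntheticTruth(
        nucleus_mask=LabeledMask(nucleus_labels, source_role="nucleus_marker"),
        nucleolus_mask=LabeledMask(
            nucleolus_labels, source_role="shell_marker", parent=dict(parent)
        ),
        centroids=centroids,
        boundary=boundary,
        channel_laws=dict(spec.channel_laws),
        parent=parent,
    )
    return fld, truth


# ---------------------------------------------------------------------------
# Synthetic assay tables
# ---------------------------------------------------------------------------

QPCR_REGIONS = ("PQS-1", "PQS-2", "PQS-3", "PQS-4", "Non-PQS")


def generate_gel_table(
    seed: int,
    true_fractions: Mapping[str, float],
    n_replicates: int = 3,
    noise_cv: float = 0.05,
    total_intensity: float = 1000.0,
) -> pd.DataFrame:
    """Synthetic gel-band table for the crosslink-protection assay.

    Each lane carries a non-denatured band and a total band; the true
    protected fraction per condition is ``true_fractions[condition]``, and
    multiplicative log-normal noise of coefficient of variation ``noise_cv``
    is applied to each band independently (``noise_cv = 0`` gives exact
    ratios).
    """
    for cond, f in true_fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"true fraction for {cond!r} must be in [0, 1], got {f}")
    if noise_cv < 0 or total_intensity <= 0:
        raise ValueError("noise_cv must be >= 0 and total_intensity > 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(noise_cv**2))
    rows = []
    for cond, frac in true_fractions.items():
        for rep in range(1, n_replicates + 1):
            noise_t = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0
            noise_n = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0
            total = total_intensity * noise_t
            rows.append(
                {
                    "lane_id": f"{cond}-rep{rep}",
                    "condition": cond,
                    "band_nondenatured": frac * total_intensity * noise_n,
                    "band_total": total,
                }
            )
    return pd.DataFrame(rows)


def default_chip_truth(
    pqs_ratio: float = 0.4, nonpqs_ratio: float = 1.0
) -> dict[tuple[str, str, str], float]:
    """True recovered-chromatin fractions per (region, antibody, condition).

    The shell-marker antibody recovers ~2% of input at its target regions
    under control conditions; under the G4-ligand-like condition the
    recovery at PQS regions drops by ``pqs_ratio`` while the Non-PQS region
    is unchanged.  Histone H3 (positive control) and IgG (negative control)
    are condition-independent.
    """
    truth = {}
    for region in QPCR_REGIONS:
        is_pqs = region != "Non-PQS"
        npm_water = 0.02 if is_pqs else 0.004
        ratio = pqs_ratio if is_pqs else nonpqs_ratio
        truth[(region, "NPM", "water")] = npm_water
        truth[(region, "NPM", "TMPyP4")] = npm_water * ratio
        for cond in ("water", "TMPyP4"):
            truth[(region, "H3", cond)] = 0.10
            truth[(region, "IgG", cond)] = 0.0005
    return truth


def generate_qpcr_table(
    seed: int,
    enrichment: Mapping[tuple[str, str, str], float] | None = None,
    input_fraction: float = 0.02,
    ct_noise_sd: float = 0.15,
    n_replicates: int = 3,
    base_ct: float = 18.0,
) -> pd.DataFrame:
    """Synthetic ChIP-qPCR Ct table.

    For each (condition, replicate) an input aliquot of ``input_fraction``
    of the chromatin is measured alongside each antibody's IP.  Ct values
    follow ideal doubling: ct = C0 - log2(recovered fraction), where C0 is a
    per-replicate chromatin offset, plus Gaussian measurement noise of
    ``ct_noise_sd`` cycles (0.15 is a typical replicate-to-replicate qPCR
    spread).  With noise 0 and enrichment equal to ``input_fraction``,
    Ct_IP equals Ct_input exactly.
    """
    if not (0.0 < input_fraction < 1.0):
        raise ValueError("input_fraction must lie in (0, 1)")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    if enrichment is None:
        enrichment = default_chip_truth()
    for key, e in enrichment.items():
        if e <= 0:
            raise ValueError(f"enrichment for {key} must be positive, got {e}")
    rng = np.random.default_rng(seed)
    conditions = sorted({c for (_, _, c) in enrichment})
    regions = sorted({r for (r, _, _) in enrichment})
    rows = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            c0 = base_ct + (rng.normal(0.0, 0.3) if ct_noise_sd > 0 else 0.0)
            for region in regions:
                ct_input = c0 - math.log2(input_fraction)
                if ct_noise_sd > 0:
                    ct_input += rng.normal(0.0, ct_noise_sd)
                rows.append(
                    {
                        "target_region": region,
                        "antibody": "input",
                        "condition": cond,
                        "replicate": rep,
                        "ct": ct_input,
                        "input_fraction": input_fraction,
                    }
                )
                for (r, ab, c), e in enrichment.items():
                    if r != region or c != cond:
                        continue
                    ct = c0 - math.log2(e)
                    if ct_noise_sd > 0:
                        ct += rng.normal(0.0, ct_noise_sd)
                    rows.append(
                        {
                            "target_region": region,
                            "antibody": ab,
                            "condition": cond,
                            "replicate": rep,
                            "ct": ct,
                            "input_fraction": input_fraction,
                        }
                    )
    return pd.DataFrame(rows)


def generate_assay_tables(
    seed: int,
    gel_fractions: Mapping[str, float] | None = None,
    chip_enrichment: Mapping[tuple[str, str, str], float] | None = None,
    gel_noise_cv: float = 0.05,
    ct_noise_sd: float = 0.15,
    input_fraction: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate both assay fixtures (gel band table, qPCR Ct table)."""
    if gel_fractions is None:
        gel_fractions = {
            "underwound+psoralen+UV": 0.7,
            "relaxed+psoralen+UV": 0.15,
            "underwound-psoralen+UV": 0.02,
            "underwound+psoralen-UV": 0.02,
        }
    ss = np.random.SeedSequence(seed)
    s_gel, s_chip = (int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2))
    gel = generate_gel_table(s_gel, gel_fractions, noise_cv=gel_noise_cv)
    chip = generate_qpcr_table(
        s_chip, chip_enrichment, input_fraction=input_fraction, ct_noise_sd=ct_noise_sd
    )
    return gel, chip
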