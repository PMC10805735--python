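"""Core in-memory containers shared across the pipeline.

Coordinate convention: images and masks are numpy arrays indexed
``(row, col)`` in 2D or ``(plane, row, col)`` in 3D, with pixel centers at
integer 0-based coordinates.  Channels are stored along the leading axis of
:class:`ImageField.pixels`.  ``pixel_size`` is the in-plane pixel pitch in
micrometres; ``z_spacing`` the plane spacing for z-stacks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import MissingLabelError


@dataclass
class ImageField:
    """Multi-channel intensity image with channel-role metadata.

    ``channel_roles`` maps semantic roles (``nucleus_marker``,
    ``shell_marker``, ``target``, ...) to indices along the channel axis.
    """

    pixels: np.ndarray  # (C, H, W) or (C, Z, H, W)
    pixel_size: float
    channel_roles: Mapping[str, int]
    z_spacing: float | None = None
    field_id: str = "field-0"
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (3, 4):
            raise ValueError("pixels must be (C, H, W) or (C, Z, H, W)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        idx = list(self.channel_roles.values())
        if len(set(idx)) != len(idx):
            raise ValueError("channel_roles indices must be distinct")
        for role, i in self.channel_roles.items():
            if not 0 <= i < self.pixels.shape[0]:
                raise ValueError(f"role {role!r} maps to invalid channel {i}")
        if self.is_3d and self.z_spacing is None:
            raise ValueError("z_spacing required for 3D fields")

    @property
    def is_3d(self) -> bool:
        return self.pixels.ndim == 4

    @property
    def frame_shape(self) -> tuple[int, ...]:
        return self.pixels.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(
                f"role {role!r} not present; available: {sorted(self.channel_roles)}"
            )
        return self.pixels[self.channel_roles[role]]


@dataclass
class LabeledMask:
    """Integer-labeled region image: 0 = background, k > 0 = region k.

    ``parent`` optionally maps each (nucleolus) label to the label of the
    nucleus that contains it.  ``border_labels`` flags regions touching the
    image border; they are kept but marked so downstream stages can exclude
    them.
    """

    labels: np.ndarray
    source_role: str = ""
    parent: dict[int, int] | None = None
    border_labels: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        self._region_labels: list[int] | None = None

    @property
    def region_labels(self) -> list[int]:
        # cached: masks are treated as immutable once constructed
        if self._region_labels is None:
            labs = np.unique(self.labels)
            self._region_labels = [int(v) for v in labs if v > 0]
        return self._region_labels

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    def require_label(self, label: int) -> np.ndarray:
        mask = self.labels == label
        if label <= 0 or not mask.any():
            raise MissingLabelError(f"label {label} not present in mask")
        return mask

    def parent_of(self, label: int) -> int | None:
        if self.parent is None:
            return None
        return self.parent.get(int(label))
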