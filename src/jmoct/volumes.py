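"""In-memory containers for Jones-matrix tomograms, scalar contrast volumes
and binary regions of interest.

Axis convention everywhere: depth first, ``(z, x, y)``; Jones data carry a
leading repeat axis and trailing ``(2, 2)`` matrix axes, i.e.
``(repeat, z, x, y, 2, 2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .system import SystemProfile

#: contrast kind -> physical units
KIND_UNITS = {
    "intensity_linear": "a.u.",
    "intensity_db": "dB",
    "attenuation": "mm^-1",
    "birefringence": "",
    "dopu": "",
    "flow": "",
}

ORGAN_LABELS = ("spine", "muscles", "gills", "skin", "other")


@dataclass
class JonesVolume:
    """A measured or simulated complex 2×2 Jones matrix per voxel.

    ``data`` has shape ``(n_repeats, z, x, y, 2, 2)``; the four matrix entries
    are the four polarization channels of a polarization-multiplexed
    acquisition (two illumination states × two detection states).
    """

    data: np.ndarray
    system: SystemProfile
    provenance: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim != 6 or a.shape[-2:] != (2, 2):
            raise ValueError(
                f"JonesVolume data must have shape (repeat, z, x, y, 2, 2); got {a.shape}")
        if a.shape[0] != self.system.n_repeats:
            raise ValueError(
                f"repeat axis length {a.shape[0]} does not match "
                f"system.n_repeats={self.system.n_repeats}")
        if a.shape[1:4] != self.system.grid_shape:
            raise ValueError(
                f"volume grid {a.shape[1:4]} does not match system grid "
                f"{self.system.grid_shape}")
        if not np.iscomplexobj(a):
            raise ValueError("JonesVolume data must be complex")
        if not np.all(np.isfinite(a.view(float))):
            raise ValueError("JonesVolume data contains non-finite entries")
        self.data = a

    @property
    def n_repeats(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:4]


@dataclass
class ContrastVolume:
    """A scalar contrast per voxel, with a validity mask and the estimator
    parameters that produced it."""

    data: np.ndarray
    kind: str
    units: str | None = None
    valid_mask: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.data, dtype=float)
        if a.ndim != 3:
            raise ValueError(f"ContrastVolume data must be (z, x, y); got shape {a.shape}")
        if self.kind not in KIND_UNITS:
            raise ValueError(f"unknown contrast kind {self.kind!r}; "
                             f"expected one of {sorted(KIND_UNITS)}")
        if self.units is None:
            self.units = KIND_UNITS[self.kind]
        if self.valid_mask is None:
            self.valid_mask = np.ones(a.shape, dtype=bool)
        else:
            m = np.asarray(self.valid_mask, dtype=bool)
            if m.shape != a.shape:
                raise ValueError(
                    f"valid_mask shape {m.shape} does not match data shape {a.shape}")
            self.valid_mask = m
        self.data = a
        self._check_range()

    def _check_range(self) -> None:
        v = self.data[self.valid_mask]
        if v.size == 0:
            return
        if self.kind in ("dopu", "flow") and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
            raise ValueError(f"{self.kind} values must lie in [0, 1] where valid")
        if self.kind == "attenuation" and v.min() < -1e-9:
            raise ValueError("attenuation must be non-negative where valid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def valid_values(self) -> np.ndarray:
        """Values at valid voxels, flattened."""
        return self.data[self.valid_mask]


@dataclass
class ROIMask:
    """A binary region of interest aligned to a contrast volume."""

    mask: np.ndarray
    organ_label: str
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError(f"ROIMask must be a (z, x, y) volume; got shape {m.shape}")
        if not m.any():
            raise ValueError(f"ROIMask for {self.organ_label!r} is empty")
        if self.organ_label not in ORGAN_LABELS:
            raise ValueError(
                f"organ_label must be one of {ORGAN_LABELS}, got {self.organ_label!r}")
        self.mask = m

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())
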