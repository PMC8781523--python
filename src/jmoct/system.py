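"""Acquisition-system description for a swept-source Jones-matrix OCT scanner.

The default profile mirrors a 1310 nm polarization-multiplexed prototype:
14 μm axial resolution in tissue, 7.24 μm depth pixel separation, and four
repeated frames per B-scan position for angiography.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace


@dataclass(frozen=True)
class SystemProfile:
    """Optical and sampling parameters of the scanner.

    Lengths are in micrometres.  ``axial_fwhm`` is the full width at half
    maximum of the *intensity* axial point-spread function (the convention in
    which OCT axial resolutions are quoted); the simulator derives the complex
    field kernel from it.  ``noise_floor_db`` is the additive noise power per
    polarization channel relative to the backscattered intensity of a unit
    reflector at the sample surface (so −30 dB means 30 dB SNR there).
    """

    center_wavelength: float = 1.31
    axial_pixel: float = 7.24
    axial_fwhm: float = 14.0
    lateral_pixel: float = 18.1
    lateral_fwhm: float = 18.1
    n_repeats: int = 4
    noise_floor_db: float | None = -30.0
    depth_pixels: int = 400
    x_pixels: int = 64
    y_pixels: int = 64

    def __post_init__(self) -> None:
        for name in ("center_wavelength", "axial_pixel", "axial_fwhm",
                     "lateral_pixel", "lateral_fwhm"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.axial_fwhm < self.axial_pixel:
            raise ValueError(
                f"axial_fwhm ({self.axial_fwhm} um) must be >= axial_pixel "
                f"({self.axial_pixel} um)")
        if self.n_repeats < 1:
            raise ValueError(f"n_repeats must be >= 1, got {self.n_repeats}")
        for name in ("depth_pixels", "x_pixels", "y_pixels"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 1):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")

    @property
    def axial_pixel_mm(self) -> float:
        """Depth pixel pitch in millimetres (attenuation coefficients are mm⁻¹)."""
        return self.axial_pixel * 1e-3

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(z, x, y) voxel grid of one volume."""
        return (self.depth_pixels, self.x_pixels, self.y_pixels)

    @property
    def noise_variance(self) -> float:
        """Linear-scale additive noise power per channel (0 if noise disabled)."""
        if self.noise_floor_db is None:
            return 0.0
        return float(10.0 ** (self.noise_floor_db / 10.0))

    def to_dict(self) -> dict:
        return asdict(self)

    def with_(self, **kwargs) -> "SystemProfile":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


DEFAULT_SYSTEM = SystemProfile()
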