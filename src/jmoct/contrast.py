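"""The five multicontrast estimators computed from a Jones-matrix tomogram:

* scatter intensity (channel-averaged, linear or dB),
* depth-resolved attenuation coefficient (ratio of local intensity to the
  remaining integrated tail),
* local birefringence from a local Jones-matrix eigenvalue analysis,
* degree of polarization uniformity (DOPU),
* complex-correlation angiography over repeated frames,

plus the SNR mask that gates the polarization and flow contrasts.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.ndimage import median_filter, uniform_filter

from .volumes import ContrastVolume, JonesVolume

log = logging.getLogger(__name__)

__all__ = [
    "compute_intensity",
    "compute_attenuation",
    "compute_local_birefringence",
    "compute_dopu",
    "compute_octa",
    "snr_mask",
]


# ---------------------------------------------------------------------------
# intensity

def compute_intensity(jones: JonesVolume,
                      average_repeats: bool = True,
                      kind: str = "intensity_linear") -> ContrastVolume:
    """Channel-averaged backscatter intensity.

    The absolute-squared intensities of the four Jones-matrix entries (the
    four polarization channels) are averaged; with ``average_repeats`` the
    mean over repeated frames is taken as well, otherwise the first repeat is
    used.  ``kind='intensity_db'`` returns ``10·log10(I)`` relative to a unit
    reflector.
    """
    power = np.abs(jones.data) ** 2
    intensity = power.mean(axis=(-2, -1))
    intensity = intensity.mean(axis=0) if average_repeats else intensity[0]
    params = {"average_repeats": average_repeats}
    if kind == "intensity_db":
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(intensity)
        valid = intensity > 0
        db[~valid] = np.finfo(float).min / 4
        return ContrastVolume(db, kind="intensity_db", valid_mask=valid, params=params)
    if kind != "intensity_linear":
        raise ValueError(f"kind must be intensity_linear or intensity_db, got {kind!r}")
    return ContrastVolume(intensity, kind="intensity_linear", params=params)


def to_db(intensity: ContrastVolume) -> ContrastVolume:
    """Convert a linear intensity volume to dB."""
    if intensity.kind == "intensity_db":
        return intensity
    if intensity.kind != "intensity_linear":
        raise ValueError(f"expected an intensity volume, got kind {intensity.kind!r}")
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(intensity.data)
    valid = intensity.valid_mask & (intensity.data > 0)
    db[~(intensity.data > 0)] = np.finfo(float).min / 4
    return ContrastVolume(db, kind="intensity_db", valid_mask=valid,
                          params=dict(intensity.params))


# ---------------------------------------------------------------------------
# attenuation

def compute_attenuation(intensity: ContrastVolume,
                        axial_pixel_mm: float,
                        method: str = "log_corrected",
                        tail_guard: int = 16,
                        noise_floor: float | None = None,
                        background: tuple[int, int] | None = None,
                        tail_fit_pixels: int = 0) -> ContrastVolume:
    """Depth-resolved attenuation coefficient (mm⁻¹).

    For depth index ``i`` with linear intensity ``I`` and tail sum
    ``T[i] = Σ_{j>i} I[j]``:

    * ``method='raw'``:           ``μ̂[i] = I[i] / (2·Δ·T[i])``
    * ``method='log_corrected'``: ``μ̂[i] = ln(1 + I[i]/T[i]) / (2·Δ)``

    The log-corrected form is exact on a discretely sampled exponential and is
    the default.  The noise floor (an explicit linear value, or the mean of a
    designated background depth range) is subtracted before summation;
    negative results are clipped to zero.  The deepest ``tail_guard`` pixels
    are flagged invalid (tail-truncation bias).  With ``tail_fit_pixels > 0``
    the volume-mean tail decay over that many deepest in-guard pixels is
    extrapolated beyond the bottom of the volume and added to every tail sum,
    which removes the truncation bias of slowly decaying media in shallow
    volumes.
    """
    if intensity.kind != "intensity_linear":
        raise ValueError(
            f"compute_attenuation needs linear intensity, got {intensity.kind!r}")
    if method not in ("raw", "log_corrected"):
        raise ValueError(f"method must be 'raw' or 'log_corrected', got {method!r}")
    nz = intensity.shape[0]
    if nz < tail_guard + 2:
        raise ValueError(
            f"depth ({nz} px) must be at least tail_guard + 2 = {tail_guard + 2}")

    I = np.array(intensity.data, dtype=float)
    if background is not None:
        z0, z1 = background
        noise_floor = float(I[z0:z1].mean())
    if noise_floor:
        I -= noise_floor
        n_clipped = int((I < 0).sum())
        if n_clipped:
            log.info("attenuation: clipped %d negative voxels after noise-floor "
                     "subtraction", n_clipped)
        np.clip(I, 0.0, None, out=I)

    # Depth integration stops where the lateral-mean signal has decayed to the
    # noise floor: beyond that point the measured values are clipped noise
    # residue that would otherwise accumulate into every tail sum.
    profile = I.mean(axis=(1, 2))
    cut = nz
    if noise_floor:
        above = np.nonzero(profile >= noise_floor)[0]
        if above.size == 0:
            raise ValueError("mean intensity never exceeds the noise floor")
        cut = int(above[-1]) + 1

    # T[i] = sum over j in (i, cut)
    S = np.zeros_like(I)
    S[:cut] = np.cumsum(I[cut - 1::-1], axis=0)[::-1]
    T = S - I
    T[cut:] = 0.0

    if tail_fit_pixels > 0:
        T = T + _tail_remainder(I, cut, tail_fit_pixels)

    dz = float(axial_pixel_mm)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "raw":
            mu = I / (2.0 * dz * T)
        else:
            mu = np.log1p(I / T) / (2.0 * dz)

    valid = (T > 0) & np.isfinite(mu)
    if tail_guard > 0:
        valid[max(0, cut - tail_guard):] = False
    else:
        valid[cut:] = False
    dead_lines = ~I.any(axis=0)
    if dead_lines.any():
        valid &= ~dead_lines[None, :, :]
    mu = np.where(valid, mu, 0.0)

    params = {"method": method, "axial_pixel_mm": dz, "tail_guard": tail_guard,
              "noise_floor": noise_floor, "tail_fit_pixels": tail_fit_pixels,
              "depth_cut": cut}
    return ContrastVolume(mu, kind="attenuation", valid_mask=valid, params=params)


def _tail_remainder(I: np.ndarray, cut: int, m: int) -> np.ndarray:
    """Estimated signal energy beyond the integration cut, per A-line.

    The per-pixel decay ratio ``r`` is fitted to the lateral-mean intensity
    profile over the last ``m`` pixels before the cut (split-half log-slope,
    robust to speckle); each line's end amplitude is estimated from its last
    pixels decay-compensated to the cut, and the geometric remainder
    ``Â·r/(1−r)`` is returned (0 where the fit finds no decay).
    """
    m = min(m, cut)
    profile = I[cut - m:cut].mean(axis=(1, 2))
    pos = profile > 0
    if pos.sum() < 4:
        return np.zeros(I.shape[1:])
    logp = np.log(np.where(pos, profile, np.nan))
    half = m // 2
    m1 = np.nanmean(logp[:half])
    m2 = np.nanmean(logp[half:])
    slope = (m2 - m1) / (m / 2.0)
    if not np.isfinite(slope) or slope >= 0:
        return np.zeros(I.shape[1:])
    r = float(np.exp(slope))
    k0 = min(16, cut)
    w = r ** np.arange(k0, dtype=float)          # compensate decay to the cut
    amp = np.einsum("k,kxy->xy", w, I[cut - k0:cut][::-1]) / k0
    # smooth the speckled amplitude laterally: the remainder enters the tail
    # sums inside a logarithm, so its noise would otherwise bias the deepest
    # estimates upward (Jensen)
    if min(amp.shape) >= 3:
        amp = uniform_filter(amp, size=3, mode="nearest")
    return amp * r / (1.0 - r)


def attenuation_analysis_window(intensity: ContrastVolume,
                                noise_floor: float,
                                threshold_db: float = 10.0,
                                surface_guard: int = 5) -> np.ndarray:
    """Depth-window mask for attenuation statistics.

    Selects *whole depths* where the lateral-mean linear intensity exceeds the
    noise floor by ``threshold_db``, skipping the top ``surface_guard`` pixels
    (PSF edge).  A per-voxel intensity gate must not be used here: for
    exponentially distributed speckle, conditioning on a voxel being bright
    selects the upper tail of its own intensity and systematically inflates
    the local attenuation estimate, so the gate is a function of depth only.
    """
    if intensity.kind != "intensity_linear":
        raise ValueError(
            f"expected linear intensity, got kind {intensity.kind!r}")
    profile = intensity.data.mean(axis=(1, 2))
    good = profile >= noise_floor * 10.0 ** (threshold_db / 10.0)
    mask = np.zeros(intensity.shape, dtype=bool)
    idx = np.nonzero(good)[0]
    if idx.size:
        mask[:idx[-1] + 1] = True
    mask[:surface_guard] = False
    return mask


# ---------------------------------------------------------------------------
# SNR mask

def snr_mask(intensity: ContrastVolume,
             threshold_db: float,
             noise_floor: float | None = None) -> np.ndarray:
    """Boolean volume, true where intensity exceeds the noise floor by
    ``threshold_db`` dB.

    The floor (linear scale) defaults to the median intensity of the deepest
    5% of pixels — adequate when the signal has decayed below the floor at the
    bottom of the volume; pass it explicitly otherwise.
    """
    if intensity.kind == "intensity_db":
        lin = 10.0 ** (intensity.data / 10.0)
    elif intensity.kind == "intensity_linear":
        lin = intensity.data
    else:
        raise ValueError(f"expected an intensity volume, got kind {intensity.kind!r}")
    if threshold_db == -np.inf:
        return np.ones(lin.shape, dtype=bool)
    if threshold_db == np.inf:
        return np.zeros(lin.shape, dtype=bool)
    if noise_floor is None:
        nz = lin.shape[0]
        noise_floor = float(np.median(lin[nz - max(1, nz // 20):]))
    return lin > noise_floor * 10.0 ** (threshold_db / 10.0)


# ---------------------------------------------------------------------------
# local birefringence

def _eig2x2_ratio_phase(L: np.ndarray) -> np.ndarray:
    """|arg(λ1/λ2)| of 2×2 matrices, wrapped to [0, π]."""
    tr = L[..., 0, 0] + L[..., 1, 1]
    det = L[..., 0, 0] * L[..., 1, 1] - L[..., 0, 1] * L[..., 1, 0]
    disc = np.sqrt(tr * tr - 4.0 * det + 0j)
    lam1 = 0.5 * (tr + disc)
    lam2 = 0.5 * (tr - disc)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.abs(np.angle(lam1 / lam2))
    return delta


def _cond2x2(M: np.ndarray) -> np.ndarray:
    """Condition number of 2×2 matrices from the closed-form singular values."""
    f2 = np.sum(np.abs(M) ** 2, axis=(-2, -1))
    d = np.abs(M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0])
    root = np.sqrt(np.maximum(f2 * f2 - 4.0 * d * d, 0.0))
    s_max2 = 0.5 * (f2 + root)
    s_min2 = 0.5 * (f2 - root)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.sqrt(s_max2 / s_min2)
    cond[s_min2 <= 0] = np.inf
    return cond


def compute_local_birefringence(jones: JonesVolume,
                                lag: int = 3,
                                kernel: tuple[int, int] = (3, 3),
                                snr_threshold_db: float | None = 15.0,
                                noise_floor: float | None = None,
                                cond_cap: float = 1e6,
                                repeat: int | str = "mean",
                                aggregation: str = "trace") -> ContrastVolume:
    """Local (depth-resolved) birefringence Δn from a local Jones analysis.

    The local matrix ``L(z) = M(z+lag·Δ)·M(z)⁻¹`` is similar to the squared
    single-pass retarder of the slab between the two depths, so the phase
    difference of its eigenvalues is the local round-trip retardance
    ``δ(z) = |arg(λ1/λ2)| ∈ [0, π]``, converted to
    ``Δn̂ = δ·λ0/(4π·lag·Δ)``.

    δ is a magnitude, so complex averaging of ``exp(i·δ)`` is not meaningful;
    two kernel aggregations over ``(kz, kx)`` are provided instead:

    * ``'trace'`` (default): the det-normalized trace
      ``tr(L)/√det(L) = ±2·cos(δ/2)`` is intensity-weight averaged over the
      kernel before the arccos — noise enters this statistic linearly, so
      averaging first suppresses the upward folding bias of per-voxel phase
      estimates at low retardance;
    * ``'median'``: per-voxel δ median-filtered over the kernel.

    ``repeat='mean'`` coherently averages the Jones matrices over repeated
    frames first (valid for static tissue, √R noise reduction); pass an int
    to use a single repeat.  Retardances above the wrap limit
    ``Δn = λ0/(4·lag·Δ)`` alias back into range.  Voxels failing the SNR mask
    or the matrix-conditioning cap are flagged invalid.
    """
    nz = jones.grid_shape[0]
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if lag >= nz:
        raise ValueError(f"lag ({lag}) must be smaller than the depth ({nz} px)")
    if aggregation not in ("trace", "median"):
        raise ValueError(f"aggregation must be 'trace' or 'median', got {aggregation!r}")
    kz, kx = kernel

    M = jones.data.mean(axis=0) if repeat == "mean" else jones.data[repeat]
    M1 = M[:-lag]
    M2 = M[lag:]
    cond = _cond2x2(M1)
    invertible = cond < cond_cap
    L = np.einsum("...ij,...jk->...ik", M2,
                  _safe_inv2x2(M1, invertible))

    if aggregation == "median":
        delta = _eig2x2_ratio_phase(L)
        delta = np.where(np.isfinite(delta), delta, 0.0)
        delta = median_filter(delta, size=(kz, kx, 1), mode="nearest")
    else:
        det = L[..., 0, 0] * L[..., 1, 1] - L[..., 0, 1] * L[..., 1, 0]
        tr = L[..., 0, 0] + L[..., 1, 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            u = tr / np.sqrt(det)                 # ±2·cos(δ/2), sign ambiguous
        u = np.where(u.real >= 0, u, -u)
        weight = np.sum(np.abs(M1) ** 2, axis=(-2, -1))
        size = (kz, kx, 1)
        num = uniform_filter(np.nan_to_num(u.real * weight), size=size, mode="nearest")
        den = uniform_filter(np.nan_to_num(weight), size=size, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            ubar = num / den
        delta = 2.0 * np.arccos(np.clip(np.nan_to_num(ubar) / 2.0, -1.0, 1.0))

    sys_ = jones.system
    scale = sys_.center_wavelength / (4.0 * np.pi * lag * sys_.axial_pixel)
    dn = np.zeros(jones.grid_shape)
    dn[:-lag] = delta * scale

    valid = np.zeros(jones.grid_shape, dtype=bool)
    valid[:-lag] = invertible
    if snr_threshold_db is not None:
        intensity = compute_intensity(jones)
        valid &= snr_mask(intensity, snr_threshold_db, noise_floor=noise_floor)
    dn[~valid] = 0.0

    params = {"lag": lag, "kernel": list(kernel), "cond_cap": cond_cap,
              "snr_threshold_db": snr_threshold_db, "repeat": repeat,
              "aggregation": aggregation,
              "wrap_limit": sys_.center_wavelength / (4.0 * lag * sys_.axial_pixel)}
    return ContrastVolume(dn, kind="birefringence", valid_mask=valid, params=params)


def _safe_inv2x2(M: np.ndarray, ok: np.ndarray) -> np.ndarray:
    det = M[..., 0, 0] * M[..., 1, 1] - M[..., 0, 1] * M[..., 1, 0]
    det = np.where(ok & (det != 0), det, 1.0)
    inv = np.empty_like(M)
    inv[..., 0, 0] = M[..., 1, 1]
    inv[..., 1, 1] = M[..., 0, 0]
    inv[..., 0, 1] = -M[..., 0, 1]
    inv[..., 1, 0] = -M[..., 1, 0]
    return inv / det[..., None, None]


# ---------------------------------------------------------------------------
# DOPU

def compute_dopu(jones: JonesVolume,
                 kernel: tuple[int, int] = (3, 3),
                 snr_threshold_db: float | None = None,
                 noise_floor: float | None = None) -> ContrastVolume:
    """Degree of polarization uniformity.

    For each of the two illumination states (the Jones-matrix columns) the
    per-voxel Stokes vector of the detected field pair is computed, each
    component is averaged over the ``(kz, kx)`` kernel (and over repeats), and
    ``DOPU = √(Q̄²+Ū²+V̄²)/Ī``.  The two states are averaged and the result is
    clipped to [0, 1]; 1 means spatially uniform polarization, low values mark
    depolarizing (pigmented) tissue.
    """
    kz, kx = kernel
    if kz < 1 or kx < 1 or kz % 2 == 0 or kx % 2 == 0:
        raise ValueError(f"kernel dims must be odd and >= 1, got {kernel}")
    nz, nx, _ = jones.grid_shape
    if kz > nz or kx > nx:
        raise ValueError(f"kernel {kernel} larger than the volume grid "
                         f"{jones.grid_shape[:2]}")

    dopu_states = []
    for col in (0, 1):
        e1 = jones.data[..., 0, col]
        e2 = jones.data[..., 1, col]
        s0 = (np.abs(e1) ** 2 + np.abs(e2) ** 2).mean(axis=0)
        s1 = (np.abs(e1) ** 2 - np.abs(e2) ** 2).mean(axis=0)
        cross = (e1 * np.conj(e2)).mean(axis=0)
        s2 = 2.0 * cross.real
        s3 = -2.0 * cross.imag
        size = (kz, kx, 1)
        s0m = uniform_filter(s0, size=size, mode="nearest")
        s1m = uniform_filter(s1, size=size, mode="nearest")
        s2m = uniform_filter(s2, size=size, mode="nearest")
        s3m = uniform_filter(s3, size=size, mode="nearest")
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.sqrt(s1m ** 2 + s2m ** 2 + s3m ** 2) / s0m
        dopu_states.append(np.where(np.isfinite(d), d, 0.0))
    dopu = np.clip(0.5 * (dopu_states[0] + dopu_states[1]), 0.0, 1.0)

    valid = np.ones(jones.grid_shape, dtype=bool)
    if snr_threshold_db is not None:
        valid = snr_mask(compute_intensity(jones), snr_threshold_db,
                         noise_floor=noise_floor)
        dopu[~valid] = 0.0
    params = {"kernel": list(kernel), "snr_threshold_db": snr_threshold_db}
    return ContrastVolume(dopu, kind="dopu", valid_mask=valid, params=params)


# ---------------------------------------------------------------------------
# angiography

def compute_octa(jones: JonesVolume,
                 kernel: tuple[int, int] = (3, 3),
                 channels: str = "first",
                 snr_threshold_db: float | None = 10.0,
                 noise_floor: float | None = None) -> ContrastVolume:
    """Complex-correlation angiography over repeated frames.

    The complex correlation of adjacent repeat pairs, aggregated over the
    ``(kz, kx)`` kernel,

    ``ρ = |Σ E_k·E*_{k+1}| / √(Σ|E_k|²·Σ|E_{k+1}|²)``,

    is converted to ``flow = 1 − ρ``.  Static tissue keeps its speckle between
    repeats (ρ→1); moving blood decorrelates (ρ→0).  Pure-noise voxels
    decorrelate like flow, so an intensity mask flags them invalid.
    ``channels='first'`` uses the first Jones entry; ``'all'`` aggregates the
    four entries.
    """
    R = jones.n_repeats
    if R < 2:
        raise ValueError(
            "angiography needs at least 2 repeated frames (4 recommended); "
            "re-simulate or re-acquire with n_repeats >= 2")
    kz, kx = kernel

    if channels == "first":
        E = jones.data[..., 0, 0][..., None]
    elif channels == "all":
        E = jones.data.reshape(jones.data.shape[:4] + (4,))
    else:
        raise ValueError(f"channels must be 'first' or 'all', got {channels!r}")

    num = np.zeros(jones.grid_shape, dtype=complex)
    p1 = np.zeros(jones.grid_shape)
    p2 = np.zeros(jones.grid_shape)
    for k in range(R - 1):
        num += (E[k] * np.conj(E[k + 1])).sum(axis=-1)
        p1 += (np.abs(E[k]) ** 2).sum(axis=-1)
        p2 += (np.abs(E[k + 1]) ** 2).sum(axis=-1)

    size = (kz, kx, 1)
    num_re = uniform_filter(num.real, size=size, mode="nearest")
    num_im = uniform_filter(num.imag, size=size, mode="nearest")
    p1m = uniform_filter(p1, size=size, mode="nearest")
    p2m = uniform_filter(p2, size=size, mode="nearest")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.hypot(num_re, num_im) / np.sqrt(p1m * p2m)
    rho = np.where(np.isfinite(rho), rho, 1.0)
    flow = np.clip(1.0 - rho, 0.0, 1.0)

    valid = np.ones(jones.grid_shape, dtype=bool)
    if snr_threshold_db is not None:
        valid = snr_mask(compute_intensity(jones), snr_threshold_db,
                         noise_floor=noise_floor)
        flow[~valid] = 0.0
    params = {"kernel": list(kernel), "channels": channels,
              "n_repeats": R, "snr_threshold_db": snr_threshold_db}
    return ContrastVolume(flow, kind="flow", valid_mask=valid, params=params)
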