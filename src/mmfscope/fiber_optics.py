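"""Multimode-fiber transmission-matrix model.

The fiber is idealized as a fully scrambling linear medium: a complex
transmission matrix (TM) maps abstract input modes to the optical field on
the output-facet pixel grid.  On top of this the module provides
phase-conjugate focusing, binary (Lee-style) hologram encoding of phase
masks, simulated off-axis interferometric TM calibration, and angular-
spectrum free-space propagation used to extend a facet TM to multiple
axial planes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np

__all__ = [
    "OpticalConfig",
    "TransmissionMatrix",
    "PhaseMask",
    "BinaryHologram",
    "TmEstimate",
    "DemodulationError",
    "estimate_mode_count",
    "generate_tm",
    "focus_mask",
    "apply_mask",
    "focus_enhancement",
    "lee_encode",
    "lee_decode",
    "simulate_offaxis_calibration",
    "propagate_angular_spectrum",
    "save_tm",
    "load_tm",
]


class DemodulationError(ValueError):
    """Raised when off-axis sideband demodulation is geometrically impossible."""


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of the probe and the output-plane sampling.

    Parameters
    ----------
    wavelength : float
        Illumination wavelength in µm.
    na : float
        Numerical aperture, strictly between 0 and 1.
    core_diameter : float
        Fiber core diameter in µm; sets the circular imaging boundary.
    pixel_size : float
        Output-plane sampling in µm.  Must satisfy the PSF Nyquist bound
        ``pixel_size <= wavelength / (2 * na)``.
    grid_shape : tuple of int
        Output-plane pixel grid ``(rows, cols)``; must cover the core.
    """

    wavelength: float
    na: float
    core_diameter: float
    pixel_size: float
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.na < 1:
            raise ValueError("na must be in (0, 1)")
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        nyq = self.wavelength / (2.0 * self.na)
        if self.pixel_size > nyq * (1 + 1e-12):
            raise ValueError(
                f"pixel_size {self.pixel_size} violates Nyquist bound {nyq:.4g}"
            )
        ny, nx = self.grid_shape
        if ny < 2 or nx < 2:
            raise ValueError("grid_shape must be at least 2x2")
        if min(ny, nx) * self.pixel_size < self.core_diameter:
            raise ValueError("grid does not cover the core diameter")

    @property
    def n_pixels(self) -> int:
        return int(self.grid_shape[0] * self.grid_shape[1])

    def aperture_mask(self) -> np.ndarray:
        """Boolean mask of pixels inside the circular core aperture."""
        ny, nx = self.grid_shape
        yy, xx = np.mgrid[:ny, :nx]
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        r = np.hypot(yy - cy, xx - cx) * self.pixel_size
        return r <= self.core_diameter / 2.0

    def to_json(self) -> str:
        d = {
            "wavelength": self.wavelength,
            "na": self.na,
            "core_diameter": self.core_diameter,
            "pixel_size": self.pixel_size,
            "grid_shape": list(self.grid_shape),
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "OpticalConfig":
        d = json.loads(s)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


def estimate_mode_count(config: OpticalConfig) -> int:
    """Rough guided-mode count of a step-index fiber, (pi*d*NA/lambda)^2 / 2."""
    v = np.pi * config.core_diameter * config.na / config.wavelength
    return int(round(v * v / 2.0))


@dataclass
class TransmissionMatrix:
    """Complex map from input modes to output-facet field pixels.

    ``entries`` has shape ``(n_pixels, n_modes)`` and refers to the facet
    plane (z = 0).  ``z_planes`` optionally lists additional axial offsets;
    plane TMs are derived on demand via angular-spectrum propagation.
    """

    entries: np.ndarray
    config: OpticalConfig
    seed: int
    z_planes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=np.complex128)
        if self.entries.ndim != 2:
            raise ValueError("entries must be 2-D (n_pixels, n_modes)")
        if self.entries.shape[0] != self.config.n_pixels:
            raise ValueError("entries row count must equal config.n_pixels")
        if not np.all(np.isfinite(self.entries.view(float))):
            raise ValueError("entries must be finite")
        if self.z_planes is not None:
            self.z_planes = np.asarray(self.z_planes, dtype=float)
            if self.z_planes.ndim != 1 or np.any(np.diff(self.z_planes) <= 0):
                raise ValueError("z_planes must be strictly increasing 1-D")

    @property
    def n_modes(self) -> int:
        return self.entries.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.entries.shape[0]

    def at_plane(self, z: float) -> "TransmissionMatrix":
        """TM at axial offset ``z``: each column propagated from the facet."""
        if z == 0:
            return self
        ny, nx = self.config.grid_shape
        cols = self.entries.T.reshape(self.n_modes, ny, nx)
        out = np.empty_like(cols)
        for k in range(self.n_modes):
            out[k] = propagate_angular_spectrum(cols[k], z, self.config)
        return replace(self, entries=out.reshape(self.n_modes, -1).T, z_planes=None)


@dataclass
class PhaseMask:
    """Per-mode phase control vector, angles wrapped to [0, 2*pi)."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.mod(np.asarray(self.phases, dtype=float), 2 * np.pi)


@dataclass
class BinaryHologram:
    """Binary amplitude pattern carrying a phase map on a linear carrier."""

    pattern: np.ndarray
    carrier_period: float

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern)
        if not np.isin(self.pattern, (0, 1)).all():
            raise ValueError("pattern values must be 0 or 1")
        if self.carrier_period < 4:
            raise ValueError("carrier_period must be >= 4 pixels")


@dataclass
class TmEstimate:
    """Calibrated TM with a diagnostic fidelity against ground truth."""

    entries: np.ndarray
    fidelity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fidelity <= 1.0 + 1e-12:
            raise ValueError("fidelity must lie in [0, 1]")


def generate_tm(
    config: OpticalConfig,
    n_modes: int,
    seed: int,
    z_planes=None,
) -> TransmissionMatrix:
    """Draw a random fully-scrambling TM.

    Entries are i.i.d. circular complex Gaussian, then each column is
    normalized to unit L2 norm (energy-conservation convention).
    Deterministic for a fixed ``seed``.
    """
    if n_modes < 1:
        raise ValueError("n_modes must be >= 1")
    rng = np.random.default_rng(seed)
    shape = (config.n_pixels, n_modes)
    t = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    t /= np.linalg.norm(t, axis=0, keepdims=True)
    return TransmissionMatrix(entries=t, config=config, seed=seed, z_planes=z_planes)


def _check_target(tm: TransmissionMatrix, target_pixel: int) -> None:
    if not 0 <= target_pixel < tm.n_pixels:
        raise ValueError("target_pixel out of range")
    if not tm.config.aperture_mask().ravel()[target_pixel]:
        raise ValueError("target_pixel lies outside the core aperture")


def focus_mask(tm: TransmissionMatrix, target_pixel: int) -> PhaseMask:
    """Phase-conjugation mask focusing at one output pixel."""
    _check_target(tm, target_pixel)
    return PhaseMask(phases=-np.angle(tm.entries[target_pixel, :]))


def apply_mask(tm: TransmissionMatrix, mask: PhaseMask) -> np.ndarray:
    """Output field for a phase-only input ``exp(i*phi)/sqrt(N)``."""
    if mask.phases.shape[0] != tm.n_modes:
        raise ValueError("mask length must equal n_modes")
    a = np.exp(1j * mask.phases) / np.sqrt(tm.n_modes)
    return tm.entries @ a


def focus_enhancement(tm: TransmissionMatrix, target_pixel: int) -> float:
    """Focus intensity over mean speckle background inside the aperture."""
    _check_target(tm, target_pixel)
    intensity = np.abs(apply_mask(tm, focus_mask(tm, target_pixel))) ** 2
    ap = tm.config.aperture_mask().ravel()
    bg = ap.copy()
    bg[target_pixel] = False
    return float(intensity[target_pixel] / intensity[bg].mean())


def lee_encode(phase_grid: np.ndarray, carrier_period: float) -> BinaryHologram:
    """Encode a 2-D phase map as a binary amplitude hologram.

    Pixel (y, x) is on when ``frac(x / T + phi / 2pi) < 1/2``; the first
    diffraction order of this square-wave carries ``exp(i*phi)``.
    """
    if carrier_period < 4:
        raise ValueError("carrier_period < 4 pixels would alias the sideband")
    phase_grid = np.asarray(phase_grid, dtype=float)
    if phase_grid.ndim != 2:
        raise ValueError("phase mask must be arranged on a 2-D grid")
    x = np.arange(phase_grid.shape[1])[None, :]
    u = x / carrier_period + phase_grid / (2 * np.pi)
    pattern = (np.mod(u, 1.0) < 0.5).astype(np.uint8)
    return BinaryHologram(pattern=pattern, carrier_period=carrier_period)


def lee_decode(holo: BinaryHologram) -> np.ndarray:
    """Recover the phase map from the first diffraction order.

    Demodulates at the carrier frequency and low-passes with a circular
    window of half the carrier frequency; corrects the -pi/2 offset of the
    square-wave first harmonic.
    """
    h = holo.pattern.astype(float)
    ny, nx = h.shape
    x = np.arange(nx)[None, :]
    demod = h * np.exp(-2j * np.pi * x / holo.carrier_period)
    spec = np.fft.fft2(demod)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    fc = 1.0 / holo.carrier_period
    window = np.hypot(fy, fx) <= fc / 2.0
    low = np.fft.ifft2(spec * window)
    return np.mod(np.angle(low) + np.pi / 2.0, 2 * np.pi)


def _fourier_upsample(field: np.ndarray, factor: int) -> np.ndarray:
    """Band-limited interpolation by zero-padding the spectrum."""
    ny, nx = field.shape
    spec = np.fft.fftshift(np.fft.fft2(field))
    big = np.zeros((ny * factor, nx * factor), dtype=complex)
    y0 = (ny * factor - ny) // 2
    x0 = (nx * factor - nx) // 2
    big[y0 : y0 + ny, x0 : x0 + nx] = spec
    return np.fft.ifft2(np.fft.ifftshift(big)) * factor**2


def _fourier_downsample(field: np.ndarray, factor: int) -> np.ndarray:
    """Inverse of :func:`_fourier_upsample` for band-limited fields."""
    ny, nx = field.shape
    my, mx = ny // factor, nx // factor
    spec = np.fft.fftshift(np.fft.fft2(field))
    y0 = (ny - my) // 2
    x0 = (nx - mx) // 2
    small = spec[y0 : y0 + my, x0 : x0 + mx]
    return np.fft.ifft2(np.fft.ifftshift(small)) / factor**2


def simulate_offaxis_calibration(
    tm_true: TransmissionMatrix,
    basis: np.ndarray | None = None,
    noise_sd: float = 0.0,
    *,
    upsample: int = 8,
    carrier: tuple[float, float] = (0.0, 0.125),
    ref_ratio: float = 20.0,
    seed: int = 0,
) -> TmEstimate:
    """Estimate the TM from simulated off-axis interferograms.

    For each probe mode the facet field is rendered on a camera grid
    oversampled by ``upsample``, interfered with a tilted plane-wave
    reference (``carrier`` in cycles per camera pixel, amplitude
    ``ref_ratio`` times the field RMS), and the sideband is recovered by
    Fourier filtering with a square window of half-width equal to half the
    carrier frequency.  The global phase is fixed by making the first
    matrix entry real-positive.
    """
    n_pix, n_modes = tm_true.entries.shape
    if basis is None:
        basis = np.eye(n_modes)
    basis = np.asarray(basis, dtype=complex)
    if basis.shape[0] != n_modes or basis.shape[1] < n_modes:
        raise ValueError("basis must have shape (n_modes, n_probes>=n_modes)")
    if np.linalg.matrix_rank(basis) < n_modes:
        raise ValueError("basis does not span the mode space")
    if ref_ratio <= 0:
        raise DemodulationError("reference amplitude must be positive")
    fc = float(np.hypot(*carrier))
    half_width = fc / 2.0
    # object band after upsampling: square of half-width 0.5/upsample
    if half_width < 0.5 / upsample - 1e-12:
        raise DemodulationError(
            "reference tilt too small to separate the sideband from the band"
        )
    if fc + half_width > 0.5 + 1e-12:
        raise DemodulationError("carrier too close to Nyquist for the window")

    rng = np.random.default_rng(seed)
    ny, nx = tm_true.config.grid_shape
    NY, NX = ny * upsample, nx * upsample
    yy = np.arange(NY)[:, None]
    xx = np.arange(NX)[None, :]
    ref_phase = np.exp(2j * np.pi * (carrier[0] * yy + carrier[1] * xx))
    fy = np.fft.fftfreq(NY)[:, None]
    fx = np.fft.fftfreq(NX)[None, :]
    window = (np.abs(fy - carrier[0]) <= half_width) & (
        np.abs(fx - carrier[1]) <= half_width
    )

    fields = tm_true.entries @ basis  # (n_pix, n_probes)
    cols = np.empty((n_pix, basis.shape[1]), dtype=complex)
    for k in range(basis.shape[1]):
        e = _fourier_upsample(fields[:, k].reshape(ny, nx), upsample)
        r_amp = ref_ratio * np.sqrt(np.mean(np.abs(e) ** 2))
        if r_amp == 0:
            raise DemodulationError("zero reference amplitude")
        holo = np.abs(e + r_amp * ref_phase) ** 2
        if noise_sd > 0:
            holo = holo + rng.normal(0.0, noise_sd * holo.mean(), holo.shape)
        spec = np.fft.fft2(holo)
        side = np.fft.ifft2(spec * window)
        # the +carrier sideband is conj(E) * R; divide out R and conjugate
        est = np.conj(side / (r_amp * ref_phase))
        cols[:, k] = _fourier_downsample(est, upsample).ravel()

    entries = cols @ np.linalg.pinv(basis)
    # global-phase convention: first entry real-positive
    ph = np.angle(entries.flat[0])
    entries = entries * np.exp(-1j * ph)
    num = np.abs(np.vdot(entries, tm_true.entries))
    den = np.linalg.norm(entries) * np.linalg.norm(tm_true.entries)
    fid = float(num / den) if den > 0 else 0.0
    return TmEstimate(entries=entries, fidelity=min(fid, 1.0))


def propagate_angular_spectrum(
    field: np.ndarray, dz: float, config: OpticalConfig
) -> np.ndarray:
    """Free-space propagation over ``dz`` µm by the angular-spectrum method.

    Evanescent components are discarded (a warning is emitted when they
    carry noticeable energy); the propagating band is treated unitarily, so
    energy is conserved and propagation is invertible.
    """
    field = np.asarray(field, dtype=complex)
    if dz == 0:
        return field.copy()
    ny, nx = field.shape
    fy = np.fft.fftfreq(ny, d=config.pixel_size)[:, None]
    fx = np.fft.fftfreq(nx, d=config.pixel_size)[None, :]
    arg = 1.0 / config.wavelength**2 - fy**2 - fx**2
    propagating = arg > 0
    spec = np.fft.fft2(field)
    ev_energy = np.sum(np.abs(spec[~propagating]) ** 2)
    tot = np.sum(np.abs(spec) ** 2)
    if tot > 0 and ev_energy / tot > 1e-6:
        warnings.warn(
            "field has energy beyond the evanescent cutoff; it is discarded",
            RuntimeWarning,
            stacklevel=2,
        )
    kz = np.zeros_like(arg)
    kz[propagating] = 2 * np.pi * np.sqrt(arg[propagating])
    h = np.where(propagating, np.exp(1j * kz * dz), 0.0)
    return np.fft.ifft2(spec * h)


def save_tm(tm: TransmissionMatrix, path) -> None:
    """Persist a TM to HDF5 (keys: entries, z_planes, config, seed)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("entries", data=tm.entries)
        if tm.z_planes is not None:
            f.create_dataset("z_planes", data=tm.z_planes)
        f.attrs["config"] = tm.config.to_json()
        f.attrs["seed"] = tm.seed


def load_tm(path) -> TransmissionMatrix:
    with h5py.File(path, "r") as f:
        entries = f["entries"][...]
        z = f["z_planes"][...] if "z_planes" in f else None
        config = OpticalConfig.from_json(f.attrs["config"])
        seed = int(f.attrs["seed"])
    return TransmissionMatrix(entries=entries, config=config, seed=seed, z_planes=z)
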