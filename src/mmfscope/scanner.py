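"""Point-scan image formation, Brenner autofocus, and depth series.

Two image-formation modes are provided.  ``"speckle"`` forms each pixel by
phase-conjugate focusing through the transmission matrix and integrating
the resulting focus intensity against the phantom (single-bucket detection,
so the effective PSF is the illumination focus intensity).  ``"ideal_psf"``
is a fast shortcut that convolves the phantom with the diffraction-limited
Airy intensity pattern of the probe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import fftconvolve
from scipy.special import j1

from .fiber_optics import OpticalConfig, TransmissionMatrix
from .phantoms import Phantom

__all__ = [
    "ScanImage",
    "DepthSeries",
    "airy_psf",
    "psf_first_zero_radius",
    "acquire_scan",
    "reconstruct",
    "brenner_score",
    "autofocus",
    "puncture_series",
    "save_scan",
    "load_scan",
    "save_depth_series",
]


@dataclass
class ScanImage:
    """Reconstructed point-scan image with circular field-of-view mask."""

    pixels: np.ndarray
    pixel_size: float
    fov_mask: np.ndarray
    z: float = 0.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels must be finite")
        if self.pixels.min() < 0:
            raise ValueError("pixels must be non-negative")
        self.fov_mask = np.asarray(self.fov_mask, dtype=bool)
        if self.fov_mask.shape != self.pixels.shape:
            raise ValueError("fov_mask shape must match pixels")


@dataclass
class DepthSeries:
    """Ordered (z, ScanImage) pairs along a puncture trajectory."""

    depths: np.ndarray
    images: list

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if len(self.depths) != len(self.images):
            raise ValueError("depths and images must have equal length")
        if len(self.depths) > 1 and np.any(np.diff(self.depths) <= 0):
            raise ValueError("depths must be strictly increasing")

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(zip(self.depths, self.images))


def airy_psf(config: OpticalConfig, radius_px: int | None = None) -> np.ndarray:
    """Diffraction-limited intensity PSF ``[2 J1(v)/v]^2`` on the pixel grid.

    ``v = 2*pi*NA*r/lambda``; the first zero sits at r = 0.61 lambda/NA.
    """
    if radius_px is None:
        r0 = 0.61 * config.wavelength / config.na
        radius_px = max(int(np.ceil(5 * r0 / config.pixel_size)), 8)
    ax = np.arange(-radius_px, radius_px + 1) * config.pixel_size
    rr = np.hypot(ax[:, None], ax[None, :])
    v = 2 * np.pi * config.na * rr / config.wavelength
    with np.errstate(invalid="ignore", divide="ignore"):
        psf = np.where(v == 0, 1.0, (2 * j1(v) / np.where(v == 0, 1, v)) ** 2)
    return psf / psf.sum()


def psf_first_zero_radius(config: OpticalConfig, dr: float = 0.01) -> float:
    """First radial zero (µm) of the simulated PSF, located numerically."""
    r = np.arange(dr, 4.0 * config.wavelength / config.na, dr)
    v = 2 * np.pi * config.na * r / config.wavelength
    profile = (2 * j1(v) / v) ** 2
    idx = np.nonzero((profile[1:-1] < profile[:-2]) & (profile[1:-1] <= profile[2:]))[0]
    if len(idx) == 0:
        raise RuntimeError("no PSF zero found in search range")
    return float(r[idx[0] + 1])


def _fov_mask(config: OpticalConfig) -> np.ndarray:
    return config.aperture_mask()


def acquire_scan(
    tm: TransmissionMatrix | None,
    phantom: Phantom,
    grid: np.ndarray | None = None,
    *,
    config: OpticalConfig | None = None,
    mode: str = "ideal_psf",
    noise_peak: float | None = None,
    seed: int = 0,
    z: float = 0.0,
) -> ScanImage:
    """Point-scan image of a 2-D phantom (or one slice of a volume).

    The scan grid defaults to the full pixel lattice; every requested
    position must lie inside the core aperture.  ``noise_peak`` applies
    Poisson noise scaled so that the expected peak signal equals that many
    counts.
    """
    if mode not in ("ideal_psf", "speckle"):
        raise ValueError("mode must be 'ideal_psf' or 'speckle'")
    if config is None:
        if tm is None:
            raise ValueError("either tm or config is required")
        config = tm.config
    density = phantom.slice_at(z) if phantom.density.ndim == 3 else phantom.density
    if density.shape != tuple(config.grid_shape):
        raise ValueError("phantom shape must match config.grid_shape")
    if not np.isclose(phantom.pixel_size, config.pixel_size):
        raise ValueError("phantom pixel size must match config.pixel_size")
    mask = _fov_mask(config)
    if grid is not None:
        grid = np.asarray(grid, dtype=int)
        if np.any(~mask[grid[:, 0], grid[:, 1]]):
            raise ValueError("scan grid positions outside the core aperture")

    if mode == "ideal_psf":
        psf = airy_psf(config)
        img = fftconvolve(density, psf, mode="same")
    else:
        if tm is None:
            raise ValueError("speckle mode requires a transmission matrix")
        flat_idx = np.nonzero(mask.ravel())[0]
        n = tm.n_modes
        rows = tm.entries[flat_idx, :]  # (n_pos, n_modes)
        inputs = np.exp(-1j * np.angle(rows)).T / np.sqrt(n)  # (n_modes, n_pos)
        fields = tm.entries @ inputs  # (n_pix, n_pos)
        intensity = np.abs(fields) ** 2
        signals = intensity.T @ density.ravel()
        img = np.zeros(config.n_pixels)
        img[flat_idx] = signals
        img = img.reshape(config.grid_shape)

    img = np.clip(img, 0.0, None)
    if noise_peak is not None:
        rng = np.random.default_rng(seed)
        peak = img.max()
        if peak > 0:
            scale = noise_peak / peak
            img = rng.poisson(img * scale).astype(float) / scale
    img = np.where(mask, img, 0.0)
    if grid is not None:
        keep = np.zeros(config.grid_shape, dtype=bool)
        keep[grid[:, 0], grid[:, 1]] = True
        img = np.where(keep, img, 0.0)
    return ScanImage(pixels=img, pixel_size=config.pixel_size, fov_mask=mask, z=z)


def reconstruct(
    signals: np.ndarray,
    layout: tuple[int, int],
    pixel_size: float,
    fov_mask: np.ndarray | None = None,
    *,
    denoise: str | None = "median",
    denoise_size: int = 3,
    z: float = 0.0,
) -> ScanImage:
    """Reshape raw scan signals to an image, denoise, and circular-crop.

    Pseudocolor display is a plotting concern and never alters the stored
    values.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    ny, nx = layout
    if signals.size != ny * nx:
        raise ValueError("signal count does not match scan layout")
    img = signals.reshape(ny, nx)
    if denoise == "median":
        img = median_filter(img, size=denoise_size)
    elif denoise == "gaussian":
        img = gaussian_filter(img, sigma=denoise_size / 3.0)
    elif denoise is not None:
        raise ValueError("denoise must be 'median', 'gaussian', or None")
    if fov_mask is None:
        yy, xx = np.mgrid[:ny, :nx]
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        fov_mask = np.hypot(yy - cy, xx - cx) <= min(ny, nx) / 2.0
    img = np.where(fov_mask, img, 0.0)
    img = np.clip(img, 0.0, None)
    return ScanImage(pixels=img, pixel_size=pixel_size, fov_mask=fov_mask, z=z)


def brenner_score(
    image: ScanImage | np.ndarray,
    mask: np.ndarray | None = None,
    *,
    normalize: bool = True,
) -> float:
    """Shift-2 squared-difference sharpness, both axes, mask-restricted.

    ``B = sum [I(x+2,y) - I(x,y)]^2 + sum [I(x,y+2) - I(x,y)]^2`` over
    pixel pairs fully inside the mask, divided by the number of
    contributing pairs when ``normalize`` is true.
    """
    if isinstance(image, ScanImage):
        arr = image.pixels
        if mask is None:
            mask = image.fov_mask
    else:
        arr = np.asarray(image, dtype=float)
    if arr.shape[0] < 3 and arr.shape[1] < 3:
        raise ValueError("image must be at least 3 pixels along one axis")
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: Brenner score undefined")
    total = 0.0
    count = 0
    if arr.shape[1] >= 3:
        d = arr[:, 2:] - arr[:, :-2]
        m = mask[:, 2:] & mask[:, :-2]
        total += float(np.sum(d[m] ** 2))
        count += int(m.sum())
    if arr.shape[0] >= 3:
        d = arr[2:, :] - arr[:-2, :]
        m = mask[2:, :] & mask[:-2, :]
        total += float(np.sum(d[m] ** 2))
        count += int(m.sum())
    if count == 0:
        raise ValueError("mask admits no shift-2 pixel pairs")
    return total / count if normalize else total


def autofocus(
    tm: TransmissionMatrix | None,
    phantom_volume: Phantom,
    z_candidates,
    *,
    config: OpticalConfig | None = None,
    mode: str = "ideal_psf",
    noise_peak: float | None = None,
    seed: int = 0,
) -> tuple[float, ScanImage]:
    """Pick the candidate plane maximizing the Brenner score.

    Ties (within 1e-12 relative) break toward the smallest ``|z|``.
    """
    z_candidates = list(z_candidates)
    if len(z_candidates) == 0:
        raise ValueError("need at least one candidate plane")
    best = None
    for z in sorted(z_candidates, key=abs):
        img = acquire_scan(
            tm, phantom_volume, config=config, mode=mode,
            noise_peak=noise_peak, seed=seed, z=z,
        )
        score = brenner_score(img)
        if best is None or score > best[0] * (1 + 1e-12):
            best = (score, z, img)
    return best[1], best[2]


def puncture_series(
    tm: TransmissionMatrix | None,
    phantom_volume: Phantom,
    depths,
    *,
    config: OpticalConfig | None = None,
    mode: str = "ideal_psf",
    focus_halfwidth: float = 0.0,
    focus_steps: int = 1,
    noise_peak: float | None = None,
    seed: int = 0,
) -> DepthSeries:
    """One autofocused image per puncture depth.

    With ``focus_halfwidth > 0`` each depth is refined by autofocusing over
    ``focus_steps`` planes on either side (clipped to the volume range).
    """
    depths = np.asarray(depths, dtype=float)
    if depths.ndim != 1 or len(depths) == 0:
        raise ValueError("depths must be a non-empty 1-D sequence")
    if len(depths) > 1 and np.any(np.diff(depths) <= 0):
        raise ValueError("depths must be strictly increasing")
    if phantom_volume.density.ndim != 3:
        raise ValueError("puncture_series requires a volume phantom")
    lo = phantom_volume.z_positions[0]
    hi = phantom_volume.z_positions[-1]
    if depths[0] < lo or depths[-1] > hi:
        raise ValueError("depth outside the phantom volume range")
    images = []
    for d in depths:
        if focus_halfwidth > 0 and focus_steps > 0:
            cand = np.linspace(d - focus_halfwidth, d + focus_halfwidth,
                               2 * focus_steps + 1)
            cand = np.clip(cand, lo, hi)
        else:
            cand = [d]
        _, img = autofocus(
            tm, phantom_volume, cand, config=config, mode=mode,
            noise_peak=noise_peak, seed=seed,
        )
        img.z = float(d)
        images.append(img)
    return DepthSeries(depths=depths, images=images)


def save_scan(image: ScanImage, path) -> None:
    """16-bit grayscale TIFF plus JSON sidecar (pixel size, z, scale)."""
    import pathlib

    path = pathlib.Path(path)
    scale = float(image.pixels.max()) or 1.0
    tifffile.imwrite(path, np.round(image.pixels / scale * 65535).astype(np.uint16))
    meta = dict(
        pixel_size=image.pixel_size,
        z=image.z,
        scale=scale,
        mask_radius_px=float(np.sqrt(image.fov_mask.sum() / np.pi)),
    )
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_scan(path) -> ScanImage:
    import pathlib

    path = pathlib.Path(path)
    raw = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    pixels = raw / 65535.0 * meta.get("scale", 1.0)
    ny, nx = pixels.shape
    yy, xx = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    mask = np.hypot(yy - cy, xx - cx) <= meta["mask_radius_px"]
    return ScanImage(pixels=pixels, pixel_size=meta["pixel_size"],
                     fov_mask=mask, z=meta.get("z", 0.0))


def save_depth_series(series: DepthSeries, out_dir) -> None:
    """Directory of TIFFs with an index CSV (``z_um,filename``)."""
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (z, img) in enumerate(series):
        fname = f"depth_{i:03d}.tiff"
        save_scan(img, out / fname)
        rows.append(f"{z},{fname}")
    (out / "index.csv").write_text("z_um,filename\n" + "\n".join(rows) + "\n")
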