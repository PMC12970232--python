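"""Per-image texture metrics: GLCM moments and radial-spectrum statistics.

Six metrics per image:

* ``contrast`` and ``homogeneity`` — moments of a symmetric, normalized
  gray-level co-occurrence matrix averaged over four distance-1 offsets;
* ``ams`` — mean non-DC Fourier magnitude;
* ``hfe`` — fraction of non-DC spectral energy above a radius cutoff;
* ``sfc`` — ln(r95/r50) of cumulative radial spectral energy;
* ``sfv`` — log10 of the variance-to-mean-squared ratio of the radial
  spectral-energy profile.

The GLCM is implemented directly (not via a library) so the unit tests can
check it against an independent brute-force pair-enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RadialProfile",
    "DegenerateColumnError",
    "quantize",
    "glcm_features",
    "radial_energy_profile",
    "spectral_metrics",
    "minmax_normalize",
    "feature_table",
    "METRIC_COLUMNS",
    "SPATIAL_METRICS",
    "SPECTRAL_METRICS",
]

METRIC_COLUMNS = ("contrast", "homogeneity", "ams", "hfe", "sfc", "sfv")
SPATIAL_METRICS = ("contrast", "homogeneity")
SPECTRAL_METRICS = ("ams", "hfe", "sfc", "sfv")

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))
SFV_EPS = 1e-12


class DegenerateColumnError(ValueError):
    """A metric column is constant and cannot be min-max normalized."""


@dataclass
class RadialProfile:
    """Spectral energy per integer frequency-pixel radius, DC excluded."""

    radii: np.ndarray
    energy: np.ndarray

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii)
        self.energy = np.asarray(self.energy, dtype=float)
        if np.any(self.energy < 0):
            raise ValueError("profile energy must be non-negative")


def quantize(image: np.ndarray, levels: int, mask: np.ndarray | None = None):
    """Min-max quantize into ``levels`` gray bins inside the mask."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        mask = np.ones(image.shape, dtype=bool)
    vals = image[mask]
    vmin, vmax = vals.min(), vals.max()
    if vmax == vmin:
        return np.zeros(image.shape, dtype=np.intp), mask
    q = np.floor((image - vmin) / (vmax - vmin) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1), mask


def glcm_features(
    image: np.ndarray,
    levels: int = 32,
    offsets=DEFAULT_OFFSETS,
    mask: np.ndarray | None = None,
) -> tuple[float, float]:
    """Contrast and homogeneity of the offset-averaged symmetric GLCM."""
    q, mask = quantize(image, levels, mask)
    glcm_sum = np.zeros((levels, levels))
    total_pairs = 0
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(q.shape[0], q.shape[0] - dr)
        c0, c1 = max(0, -dc), min(q.shape[1], q.shape[1] - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if not m.any():
            continue
        pairs = np.bincount(
            (a[m] * levels + b[m]).ravel(), minlength=levels * levels
        ).reshape(levels, levels)
        g = pairs + pairs.T  # symmetric
        glcm_sum += g / g.sum()
        total_pairs += int(pairs.sum())
    if total_pairs < 2:
        raise ValueError("mask yields fewer than 2 pixel pairs")
    glcm = glcm_sum / glcm_sum.sum()
    i = np.arange(levels)[:, None]
    j = np.arange(levels)[None, :]
    contrast = float(np.sum(glcm * (i - j) ** 2))
    homogeneity = float(np.sum(glcm / (1.0 + np.abs(i - j))))
    return contrast, homogeneity


def _masked_spectrum(image: np.ndarray, mask: np.ndarray | None):
    """FFT of the mean-subtracted image; outside-mask pixels mean-padded."""
    image = np.asarray(image, dtype=float)
    if mask is None:
        work = image - image.mean()
    else:
        m = image[mask].mean()
        work = np.where(mask, image, m) - m
    return np.fft.fft2(work)


def _radius_grid(shape) -> np.ndarray:
    ny, nx = shape
    ky = np.minimum(np.arange(ny), ny - np.arange(ny))[:, None]
    kx = np.minimum(np.arange(nx), nx - np.arange(nx))[None, :]
    return np.hypot(ky, kx)


def radial_energy_profile(
    image: np.ndarray, mask: np.ndarray | None = None
) -> RadialProfile:
    """|FFT|^2 binned by integer frequency-pixel radius, DC excluded."""
    spec = _masked_spectrum(image, mask)
    power = np.abs(spec) ** 2
    r = np.round(_radius_grid(power.shape)).astype(np.intp)
    power_flat = power.ravel()
    r_flat = r.ravel()
    keep = np.ones(power_flat.shape, dtype=bool)
    keep[0] = False  # DC sample at index (0, 0)
    energy = np.bincount(r_flat[keep], weights=power_flat[keep])
    radii = np.arange(len(energy))
    first = 1 if len(energy) > 1 else 0
    return RadialProfile(radii=radii[first:], energy=energy[first:])


def spectral_metrics(
    image: np.ndarray,
    hfe_cutoff_frac: float = 0.25,
    mask: np.ndarray | None = None,
) -> dict:
    """ams / hfe / sfc / sfv from the image spectrum.

    Returns a dict with the four metrics and a ``degenerate`` flag set for
    zero-energy (constant) images, where epsilon-guarded sentinels are
    substituted.
    """
    spec = _masked_spectrum(image, mask)
    mag = np.abs(spec).ravel()[1:]  # drop DC
    total = float(np.sum(mag**2))
    if total <= 0:
        return dict(
            ams=0.0, hfe=0.0, sfc=0.0, sfv=float(np.log10(SFV_EPS)), degenerate=True
        )
    ams = float(mag.mean())
    r = _radius_grid(spec.shape).ravel()[1:]
    nyquist = min(spec.shape) / 2.0
    hfe = float(np.sum(mag[r > hfe_cutoff_frac * nyquist] ** 2) / total)
    prof = radial_energy_profile(image, mask)
    cum = np.cumsum(prof.energy) / prof.energy.sum()
    r50 = float(prof.radii[np.searchsorted(cum, 0.50)])
    r95 = float(prof.radii[np.searchsorted(cum, 0.95)])
    sfc = float(np.log(r95 / r50))
    e = prof.energy
    sfv = float(np.log10(np.var(e) / np.mean(e) ** 2 + SFV_EPS))
    return dict(ams=ams, hfe=hfe, sfc=sfc, sfv=sfv, degenerate=False)


def minmax_normalize(
    table: pd.DataFrame, columns=METRIC_COLUMNS
) -> tuple[pd.DataFrame, dict]:
    """Pooled per-column (x - min)/(max - min); adds ``norm_*`` columns."""
    out = table.copy()
    constants = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise DegenerateColumnError(f"column {col!r} is constant")
        out[f"norm_{col}"] = (x - lo) / (hi - lo)
        constants[col] = (float(lo), float(hi))
    return out, constants


def feature_table(
    images,
    labels,
    ids=None,
    *,
    mask: np.ndarray | None = None,
    levels: int = 32,
    offsets=DEFAULT_OFFSETS,
    hfe_cutoff_frac: float = 0.25,
    normalize: bool = True,
) -> pd.DataFrame:
    """One metric row per image; optionally adds pooled min-max columns."""
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    if ids is None:
        ids = [f"img_{i:04d}" for i in range(len(images))]
    rows = []
    for img_id, img, label in zip(ids, images, labels):
        contrast, homogeneity = glcm_features(img, levels, offsets, mask)
        spectral = spectral_metrics(img, hfe_cutoff_frac, mask)
        rows.append(
            dict(
                id=img_id,
                label=label,
                contrast=contrast,
                homogeneity=homogeneity,
                ams=spectral["ams"],
                hfe=spectral["hfe"],
                sfc=spectral["sfc"],
                sfv=spectral["sfv"],
            )
        )
    table = pd.DataFrame(rows)
    if normalize:
        table, _ = minmax_normalize(table)
    return table


def load_image(path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float; names the file on failure."""
    import imageio.v3 as iio

    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise OSError(f"could not read image file {path}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=-1)
    return arr
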