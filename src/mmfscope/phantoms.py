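"""Synthetic tissue phantoms and optical test targets.

Phantoms are non-negative fluorophore-density images with a ground-truth
class label.  The "normal" generator lays out similarly sized round-to-
oval dark voids on a jittered hexagonal lattice with bright rims (vascular
septa); the "tumor" generator replaces that order with spectrally shaped
correlated noise, broken void remnants, multiplicative intensity
patchiness and an overall brightness shift.  Line-pair and two-point
targets support resolution validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy.ndimage import gaussian_filter

__all__ = [
    "Phantom",
    "alveolar_phantom",
    "tumor_phantom",
    "linepair_target",
    "two_point_target",
    "cohort",
    "Cohort",
    "save_phantom",
    "load_phantom",
]

LABELS = ("normal", "tumor", "target")


@dataclass
class Phantom:
    """Fluorophore-density image (2-D) or volume (3-D) with metadata.

    For a volume, ``density`` has shape ``(nz, ny, nx)`` and ``z_positions``
    gives the axial coordinate (µm) of each slice.
    """

    density: np.ndarray
    pixel_size: float
    label: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    z_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.ndim not in (2, 3):
            raise ValueError("density must be 2-D or 3-D")
        if not np.all(np.isfinite(self.density)):
            raise ValueError("density must be finite")
        if self.density.min() < 0:
            raise ValueError("density must be non-negative")
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}")
        if self.density.ndim == 3:
            if self.z_positions is None:
                raise ValueError("volume phantom requires z_positions")
            self.z_positions = np.asarray(self.z_positions, dtype=float)
            if len(self.z_positions) != self.density.shape[0]:
                raise ValueError("z_positions length must match nz")
            if np.any(np.diff(self.z_positions) <= 0):
                raise ValueError("z_positions must be strictly increasing")

    def slice_at(self, z: float) -> np.ndarray:
        """Nearest axial slice of a volume (a 2-D phantom returns itself)."""
        if self.density.ndim == 2:
            return self.density
        lo, hi = self.z_positions[0], self.z_positions[-1]
        if not lo <= z <= hi:
            raise ValueError(f"z={z} outside volume range [{lo}, {hi}]")
        idx = int(np.argmin(np.abs(self.z_positions - z)))
        return self.density[idx]


def _hex_centers(shape, spacing_px, rng, jitter):
    """Hexagonal lattice centers covering the frame, with uniform jitter."""
    ny, nx = shape
    dy = spacing_px * np.sqrt(3) / 2.0
    centers = []
    row = 0
    y = -spacing_px
    while y < ny + spacing_px:
        x0 = -spacing_px + (spacing_px / 2.0 if row % 2 else 0.0)
        x = x0
        while x < nx + spacing_px:
            centers.append((y, x))
            x += spacing_px
        y += dy
        row += 1
    centers = np.asarray(centers, dtype=float)
    if jitter > 0:
        centers = centers + rng.uniform(
            -jitter * spacing_px / 2.0, jitter * spacing_px / 2.0, centers.shape
        )
    return centers


def _paint_voids(
    shape,
    centers,
    radii_px,
    aspects,
    angles,
    rim_width_frac,
):
    """Union masks for void interiors and rims from elliptical distance maps."""
    ny, nx = shape
    void = np.zeros(shape, dtype=bool)
    rim = np.zeros(shape, dtype=bool)
    for (cy, cx), r, asp, th in zip(centers, radii_px, aspects, angles):
        a, b = r * asp, r / asp
        ext = int(np.ceil(max(a, b) * (1 + rim_width_frac) + 2))
        y0, y1 = max(0, int(cy) - ext), min(ny, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(nx, int(cx) + ext + 1)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = yy - cy, xx - cx
        c, s = np.cos(th), np.sin(th)
        u = (c * dx + s * dy) / a
        v = (-s * dx + c * dy) / b
        rho = np.sqrt(u * u + v * v)
        void[y0:y1, x0:x1] |= rho < 1.0
        rim[y0:y1, x0:x1] |= (rho >= 1.0) & (rho < 1.0 + rim_width_frac)
    return void, rim


def _alveolar_geometry(shape, rng, *, mean_radius_um, radius_cv, jitter,
                       pixel_size, spacing_factor, aspect_max, rim_width_frac):
    """Sample void centers/shapes; shared by the normal and tumor generators.

    Consumes a fixed number of draws from ``rng`` for a given lattice so the
    tumor generator reproduces the normal structure exactly at disorder=0.
    """
    if not 0 <= radius_cv < 0.5:
        raise ValueError("radius_cv must be in [0, 0.5)")
    if not 0 <= jitter <= 1:
        raise ValueError("jitter must be in [0, 1]")
    spacing_px = spacing_factor * mean_radius_um / pixel_size
    max_r_px = mean_radius_um * (1 + 2 * radius_cv) * aspect_max / pixel_size
    if max_r_px * (1 + rim_width_frac) > spacing_px:
        raise ValueError("void radii exceed lattice spacing (voids would overlap)")
    centers = _hex_centers(shape, spacing_px, rng, jitter)
    n = len(centers)
    radii = mean_radius_um / pixel_size * np.clip(
        1 + radius_cv * rng.standard_normal(n), 1 - 2 * radius_cv, 1 + 2 * radius_cv
    )
    aspects = np.sqrt(rng.uniform(1.0, aspect_max, n))
    angles = rng.uniform(0, np.pi, n)
    return centers, radii, aspects, angles


_ALV_DEFAULTS = dict(
    mean_radius_um=8.0,
    radius_cv=0.18,
    rim_brightness=1.0,
    jitter=0.5,
    pixel_size=0.4,
    spacing_factor=2.6,
    aspect_max=1.3,
    rim_width_frac=0.25,
    background=0.35,
    void_level=0.05,
    blur_sigma_px=2.0,
    noise_level=0.01,
)


def _render_alveoli(shape, rng, p, keep=None):
    """Paint voids/rims (optionally a subset) and apply blur and noise."""
    centers, radii, aspects, angles = _alveolar_geometry(
        shape,
        rng,
        mean_radius_um=p["mean_radius_um"],
        radius_cv=p["radius_cv"],
        jitter=p["jitter"],
        pixel_size=p["pixel_size"],
        spacing_factor=p["spacing_factor"],
        aspect_max=p["aspect_max"],
        rim_width_frac=p["rim_width_frac"],
    )
    if keep is not None:
        sel = keep(len(centers))
        centers, radii = centers[sel], radii[sel]
        aspects, angles = aspects[sel], angles[sel]
    void, rim = _paint_voids(
        shape, centers, radii, aspects, angles, p["rim_width_frac"]
    )
    img = np.full(shape, p["background"])
    img[rim] = p["background"] + p["rim_brightness"]
    img[void] = p["void_level"]
    if p["blur_sigma_px"] > 0:
        img = gaussian_filter(img, p["blur_sigma_px"])
    if p["noise_level"] > 0:
        img = img + p["noise_level"] * rng.standard_normal(shape)
    return img


def alveolar_phantom(
    mean_radius_um: float = 8.0,
    radius_cv: float = 0.18,
    rim_brightness: float = 1.0,
    jitter: float = 0.5,
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    *,
    pixel_size: float = 0.4,
    spacing_factor: float = 2.6,
    aspect_max: float = 1.3,
    rim_width_frac: float = 0.25,
    background: float = 0.35,
    void_level: float = 0.05,
    blur_sigma_px: float = 2.0,
    noise_level: float = 0.01,
) -> Phantom:
    """Normal-tissue phantom: ordered dark voids with bright rims."""
    p = dict(
        mean_radius_um=mean_radius_um,
        radius_cv=radius_cv,
        rim_brightness=rim_brightness,
        jitter=jitter,
        pixel_size=pixel_size,
        spacing_factor=spacing_factor,
        aspect_max=aspect_max,
        rim_width_frac=rim_width_frac,
        background=background,
        void_level=void_level,
        blur_sigma_px=blur_sigma_px,
        noise_level=noise_level,
    )
    rng = np.random.default_rng(seed)
    img = np.clip(_render_alveoli(shape, rng, p), 0.0, None)
    params = dict(
        mean_radius_um=mean_radius_um,
        radius_cv=radius_cv,
        rim_brightness=rim_brightness,
        jitter=jitter,
        pixel_size=pixel_size,
        spacing_factor=spacing_factor,
    )
    return Phantom(img, pixel_size, "normal", params, seed)


def _shaped_noise(shape, beta, rng):
    """Isotropic random field with power spectrum ~ 1/f^beta, unit std."""
    ny, nx = shape
    white = rng.standard_normal(shape)
    fy = np.fft.fftfreq(ny)[:, None]
    fx = np.fft.fftfreq(nx)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = f[f > 0].min()
    amp = f ** (-beta / 2.0)
    field = np.fft.ifft2(np.fft.fft2(white) * amp).real
    field -= field.mean()
    sd = field.std()
    return field / sd if sd > 0 else field


def tumor_phantom(
    disorder: float = 1.0,
    blob_scale_um: float = 3.0,
    heterogeneity: float = 0.5,
    # defaults below tuned so that, against the default alveolar phantom,
    # cohort means satisfy: contrast/ams/hfe/sfc/sfv higher, homogeneity lower
    shape: tuple[int, int] = (256, 256),
    seed: int = 0,
    *,
    pixel_size: float = 0.4,
    alveolar_params: dict | None = None,
    beta_ordered: float = 3.0,
    beta_disordered: float = 2.6,
    blob_level: float = 0.45,
    grain_level: float = 0.18,
    grain_sigma_px: float = 0.5,
    brightness_shift: float = 0.25,
    patch_scale_um: float = 10.0,
) -> Phantom:
    """Tumor-tissue phantom: disordered heterogeneous correlated noise.

    The ordered structure decays by remnant thinning: each void of the
    matched alveolar geometry survives with probability ``1 - disorder``
    (surviving remnants keep full amplitude, so their contribution decays
    linearly).  On top of the thinned structure sit a 1/f^beta blob field
    whose exponent drops with ``disorder``, a fine-grained speckle
    component (``grain_level``, correlation ``grain_sigma_px``) modelling
    dense cellular texture, multiplicative patchiness (``heterogeneity``),
    and a brightness shift.  ``disorder=0`` with ``heterogeneity=0``
    reproduces the alveolar phantom at matched parameters exactly.
    """
    if not 0 <= disorder <= 1:
        raise ValueError("disorder must be in [0, 1]")
    if heterogeneity < 0:
        raise ValueError("heterogeneity must be >= 0")
    p = dict(_ALV_DEFAULTS)
    p.update(alveolar_params or {})
    p["pixel_size"] = pixel_size
    rng_alv = np.random.default_rng(seed)  # same stream as alveolar_phantom
    rng_t = np.random.default_rng([seed, 0x7D])  # tumor-specific draws
    keep = None
    if disorder > 0:
        keep = lambda n: rng_t.random(n) >= disorder  # noqa: E731
    img = _render_alveoli(shape, rng_alv, p, keep=keep)
    if disorder > 0:
        beta = beta_ordered + (beta_disordered - beta_ordered) * disorder
        noise = _shaped_noise(shape, beta, rng_t)
        blur = max(blob_scale_um / pixel_size / 8.0, 0.0)
        if blur > 0:
            noise = gaussian_filter(noise, blur)
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        grain = gaussian_filter(rng_t.standard_normal(shape), grain_sigma_px)
        grain /= grain.std()
        img = (
            img
            + disorder * blob_level * noise
            + np.sqrt(disorder) * grain_level * grain
        )
    if heterogeneity > 0 and disorder > 0:
        patch = gaussian_filter(
            rng_t.standard_normal(shape), patch_scale_um / pixel_size
        )
        sd = patch.std()
        if sd > 0:
            patch = patch / sd
        img = img * (1 + heterogeneity * disorder * np.tanh(patch))
    img = img + brightness_shift * disorder
    img = np.clip(img, 0.0, None)
    params = dict(
        disorder=disorder,
        blob_scale_um=blob_scale_um,
        heterogeneity=heterogeneity,
        pixel_size=pixel_size,
    )
    return Phantom(img, pixel_size, "tumor", params, seed)


def linepair_target(
    lp_per_mm: float,
    pixel_size: float,
    shape: tuple[int, int] = (256, 256),
) -> Phantom:
    """Binary bar pattern; bar width = 1000 / (2 * lp_per_mm) µm."""
    if lp_per_mm <= 0:
        raise ValueError("lp_per_mm must be positive")
    period_um = 1000.0 / lp_per_mm
    if period_um / pixel_size < 2:
        raise ValueError("bar pattern below the sampling Nyquist limit")
    x_um = np.arange(shape[1]) * pixel_size
    bars = (np.mod(x_um / period_um, 1.0) < 0.5).astype(float)
    img = np.tile(bars, (shape[0], 1))
    params = dict(lp_per_mm=lp_per_mm, bar_width_um=period_um / 2.0)
    return Phantom(img, pixel_size, "target", params)


def two_point_target(
    separation_um: float,
    pixel_size: float,
    shape: tuple[int, int] = (256, 256),
) -> Phantom:
    """Two unit impulses separated along x, nearest-pixel placement."""
    if separation_um < 0:
        raise ValueError("separation must be non-negative")
    if separation_um > 0 and separation_um < 2 * pixel_size:
        raise ValueError("separation must be at least 2 pixels (or exactly 0)")
    ny, nx = shape
    cy, cx = ny // 2, (nx - 1) / 2.0
    img = np.zeros(shape)
    c1 = int(round(cx - separation_um / 2.0 / pixel_size))
    c2 = int(round(cx + separation_um / 2.0 / pixel_size))
    img[cy, c1] += 1.0
    img[cy, c2] += 1.0
    params = dict(separation_um=separation_um)
    return Phantom(img, pixel_size, "target", params)


@dataclass
class Cohort:
    """Balanced labeled phantom image set with a manifest."""

    images: list
    labels: list
    manifest: pd.DataFrame
    pixel_size: float


def cohort(
    n_per_class,
    image_size: int | tuple[int, int] = (256, 256),
    seed: int = 0,
    mode: str = "direct",
    *,
    pixel_size: float = 0.4,
    normal_kwargs: dict | None = None,
    tumor_kwargs: dict | None = None,
    noise_peak: float | None = None,
    out_dir=None,
) -> Cohort:
    """Generate a labeled normal/tumor image set.

    ``n_per_class`` may be an int (balanced) or a ``(n_normal, n_tumor)``
    pair.  ``mode="direct"`` renders phantom densities as images;
    ``mode="through_fiber"`` images each phantom with the ideal-PSF scanner
    (optionally Poisson noise at ``noise_peak`` expected peak counts).
    """
    if isinstance(n_per_class, (tuple, list)):
        n_normal, n_tumor = map(int, n_per_class)
    else:
        n_normal = n_tumor = int(n_per_class)
    if min(n_normal, n_tumor) < 2:
        raise ValueError("need at least 2 images per class")
    if mode not in ("direct", "through_fiber"):
        raise ValueError("mode must be 'direct' or 'through_fiber'")
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_normal + n_tumor)]

    scanner_ctx = None
    if mode == "through_fiber":
        from . import scanner as _scanner
        from .fiber_optics import OpticalConfig

        cfg = OpticalConfig(
            wavelength=0.785,
            na=0.37,
            core_diameter=min(image_size) * pixel_size * 0.95,
            pixel_size=pixel_size,
            grid_shape=tuple(image_size),
        )
        scanner_ctx = (_scanner, cfg)

    images, labels, rows = [], [], []
    specs = [("normal", s) for s in child_seeds[:n_normal]] + [
        ("tumor", s) for s in child_seeds[n_normal:]
    ]
    for i, (label, s) in enumerate(specs):
        if label == "normal":
            ph = alveolar_phantom(
                shape=image_size, seed=s, pixel_size=pixel_size,
                **(normal_kwargs or {}),
            )
        else:
            ph = tumor_phantom(
                shape=image_size, seed=s, pixel_size=pixel_size,
                **(tumor_kwargs or {}),
            )
        if scanner_ctx is None:
            img = ph.density
        else:
            _scanner, cfg = scanner_ctx
            scan = _scanner.acquire_scan(
                None, ph, config=cfg, mode="ideal_psf",
                noise_peak=noise_peak, seed=s,
            )
            img = scan.pixels
        fname = f"{label}_{i:04d}.tiff"
        images.append(img)
        labels.append(label)
        rows.append({"filename": fname, "label": label, "seed": s})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for img, row in zip(images, rows):
            scale = img.max() if img.max() > 0 else 1.0
            tifffile.imwrite(
                out / row["filename"],
                np.round(img / scale * 65535).astype(np.uint16),
            )
        manifest.to_csv(out / "manifest.csv", index=False)
    return Cohort(images=images, labels=labels, manifest=manifest, pixel_size=pixel_size)


def save_phantom(phantom: Phantom, path) -> None:
    """Write a phantom as 16-bit TIFF plus a JSON parameter sidecar."""
    import pathlib

    path = pathlib.Path(path)
    scale = float(phantom.density.max()) or 1.0
    tifffile.imwrite(
        path, np.round(phantom.density / scale * 65535).astype(np.uint16)
    )
    meta = dict(
        pixel_size=phantom.pixel_size,
        label=phantom.label,
        params=phantom.params,
        seed=phantom.seed,
        scale=scale,
    )
    if phantom.z_positions is not None:
        meta["z_positions"] = list(map(float, phantom.z_positions))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_phantom(path) -> Phantom:
    import pathlib

    path = pathlib.Path(path)
    raw = tifffile.imread(path).astype(float)
    meta = json.loads(path.with_suffix(".json").read_text())
    density = raw / 65535.0 * meta.get("scale", 1.0)
    return Phantom(
        density,
        meta["pixel_size"],
        meta["label"],
        meta.get("params", {}),
        meta.get("seed", 0),
        z_positions=meta.get("z_positions"),
    )
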