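"""Synthetic brightfield bead fields and Z sweeps with a known focal plane.

Renders 8-bit grayscale images of polymer control beads (~19 px diameter at
1.5 um/px) as they appear in transmitted-light viability counters: a dark
annular rim whose center lights up near focus.  The model is
deliberately simple -- a radial template convolved with a defocus disk
kernel -- but reproduces the behaviours the downstream pipeline depends on:

* the bead center is strictly brightest at the true focal plane,
* the radial profile's steepest (most negative) slope occurs at focus,
* defocus blur grows with distance |dZ| from the focal plane,
* beads look different above versus below focus (asymmetric blur growth
  and asymmetric decay of the center brightness), which is what makes the
  *sign* of dZ recoverable from a single image,
* background intensity scales linearly with exposure until the sensor
  clips at 255.

All randomness flows from integer seeds through ``numpy.random.default_rng``;
identical seeds give bitwise-identical images.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve


class PlacementError(RuntimeError):
    """Raised when beads cannot be placed without overlap."""


@dataclass(frozen=True)
class OpticalModel:
    """Parameters of the synthetic bead / camera model.

    Intensities are expressed as fractions of the local background level;
    the background itself is ``background_level`` counts at the reference
    exposure and scales linearly with exposure time.
    """

    bead_radius_px: float = 9.5          # ~19 px diameter at 1.5 um/px
    rim_depth: float = 0.6               # darkness of the annular rim, fraction of background
    rim_sigma_in_px: float = 3.0         # inner width of the rim trough (steep side)
    rim_sigma_out_px: float = 5.0        # outer width (gradual recovery to background)
    center_peak_gain: float = 0.9        # in-focus center brightness above background
    center_sigma_px: float = 2.8         # width of the bright center spot
    background_level: float = 120.0      # counts at the reference exposure
    exposure_ref_ms: float = 12.0
    defocus_blur_rate: float = 0.05      # disk-kernel radius growth, px per um below focus
    blur_asymmetry: float = 1.8          # blur grows faster above focus (rate * asymmetry)
    focus_sharpness_scale: float = 45.0  # um; decay scale of center brightness above focus
    sharpness_asymmetry: float = 24.0 / 45.0  # center brightness decays faster below focus
    noise_sd: float = 2.0                # additive Gaussian read noise, counts
    bit_depth_max: int = 255

    def background(self, exposure_ms: float) -> float:
        """Pre-clipping mean background in counts at the given exposure."""
        return self.background_level * exposure_ms / self.exposure_ref_ms

    def center_focus_factor(self, dz_um: float) -> float:
        """Lorentzian decay of the center brightness, asymmetric about focus."""
        s = self.focus_sharpness_scale
        if dz_um < 0:
            s = s * self.sharpness_asymmetry
        return 1.0 / (1.0 + (dz_um / s) ** 2)

    def blur_radius(self, dz_um: float) -> float:
        """Defocus disk-kernel radius in px at signed distance dz from focus."""
        rate = self.defocus_blur_rate
        if dz_um > 0:
            rate = rate * self.blur_asymmetry
        return rate * abs(dz_um)


@dataclass(frozen=True)
class SweepSpec:
    """Layout of a simulated Z sweep (one experiment on one instrument)."""

    z_min: float
    z_max: float
    z_increment: float
    exposures: tuple = (6.0, 9.0, 12.0)
    n_fov: int = 2
    beads_per_fov: int = 8
    true_refp: float = 1507.5
    distractor_count: int = 0
    field_size: int = 480
    experiment: str = "sim"
    seed: int = 0

    def z_levels(self) -> np.ndarray:
        n = int(round((self.z_max - self.z_min) / self.z_increment)) + 1
        return self.z_min + self.z_increment * np.arange(n)


def _disk_kernel(radius: float) -> np.ndarray | None:
    """Anti-aliased disk kernel of continuous radius; None when negligible."""
    if radius < 0.25:
        return None
    r = int(np.ceil(radius + 1))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    k = np.clip(radius + 0.5 - np.hypot(yy, xx), 0.0, 1.0)
    return k / k.sum()


def _blur(img: np.ndarray, radius: float) -> np.ndarray:
    k = _disk_kernel(radius)
    if k is None:
        return img
    pad = k.shape[0] // 2
    padded = np.pad(img, pad, mode="edge")
    out = fftconvolve(padded, k, mode="same")
    return out[pad:-pad, pad:-pad]


def _bead_template(r: np.ndarray, dz_um: float, model: OpticalModel) -> np.ndarray:
    """Radial intensity template as a fraction of background (pre-blur).

    A dark annular rim at the bead radius (steep on the inside, gradual on
    the outside, as the bead body grades into the background halo) plus a
    bright center spot whose amplitude decays away from focus.
    """
    d = r - model.bead_radius_px
    sigma = np.where(d < 0, model.rim_sigma_in_px, model.rim_sigma_out_px)
    rim = model.rim_depth * np.exp(-(d**2) / (2.0 * sigma**2))
    center = (
        model.center_peak_gain
        * model.center_focus_factor(dz_um)
        * np.exp(-(r**2) / (2.0 * model.center_sigma_px**2))
    )
    return 1.0 - rim + center


def _finalize(img: np.ndarray, model: OpticalModel, rng: np.random.Generator | None) -> np.ndarray:
    if rng is not None and model.noise_sd > 0:
        img = img + rng.normal(0.0, model.noise_sd, img.shape)
    return np.clip(np.rint(img), 0, model.bit_depth_max).astype(np.uint8)


def render_bead(
    dz_um: float,
    exposure_ms: float,
    model: OpticalModel = OpticalModel(),
    tile_size: int = 64,
    center: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one bead tile at signed defocus ``dz_um``.

    ``center`` is the continuous (x, y) bead center in tile coordinates;
    defaults to the tile midpoint.  Returns a uint8 ``tile_size`` square.
    """
    if tile_size <= 0 or exposure_ms <= 0:
        raise ValueError("tile_size and exposure_ms must be positive")
    if tile_size < 4 * model.bead_radius_px:
        raise ValueError("tile_size must be at least 4 bead radii")
    cx, cy = center if center is not None else ((tile_size - 1) / 2.0, (tile_size - 1) / 2.0)
    yy, xx = np.mgrid[0:tile_size, 0:tile_size]
    r = np.hypot(xx - cx, yy - cy)
    bg = model.background(exposure_ms)
    img = bg * _bead_template(r, dz_um, model)
    img = _blur(img, model.blur_radius(dz_um))
    return _finalize(img, model, rng)


def _place_objects(
    n: int, field_size: int, margin: float, min_dist: float, rng: np.random.Generator,
    existing: list | None = None, max_tries: int = 5000,
) -> list[tuple[float, float]]:
    placed: list[tuple[float, float]] = []
    others = list(existing) if existing else []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise PlacementError(
                f"could not place {n} objects in a {field_size} px field without overlap"
            )
        x = rng.uniform(margin, field_size - 1 - margin)
        y = rng.uniform(margin, field_size - 1 - margin)
        if all(np.hypot(x - px, y - py) >= min_dist for px, py in placed + others):
            placed.append((x, y))
    return placed


def render_field(
    dz_um: float,
    exposure_ms: float,
    model: OpticalModel = OpticalModel(),
    field_size: int = 480,
    n_beads: int = 8,
    distractor_count: int = 0,
    rng: np.random.Generator | None = None,
    bead_centers: list[tuple[float, float]] | None = None,
    distractors: list[tuple] | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a field of view with ``n_beads`` beads plus optional debris.

    Distractors are elongated dark ellipses (random orientation, ~4:1 aspect)
    that pass the size filter but fail the 0.9 circularity filter.  Returns
    the uint8 image and a ground-truth table of continuous bead centers.
    Pre-computed ``bead_centers``/``distractors`` may be passed so that the
    same physical layout can be re-imaged at many (Z, exposure) settings.
    """
    if exposure_ms <= 0 or field_size <= 0:
        raise ValueError("field_size and exposure_ms must be positive")
    rng = rng if rng is not None else np.random.default_rng(0)
    margin = model.bead_radius_px + 10
    min_dist = 4.5 * model.bead_radius_px
    if bead_centers is None:
        bead_centers = _place_objects(n_beads, field_size, margin, min_dist, rng)
    if distractors is None:
        dc = _place_objects(
            distractor_count, field_size, margin + 15, min_dist + 15, rng, existing=bead_centers
        )
        distractors = [(x, y, rng.uniform(0, np.pi), rng.uniform(18, 24), rng.uniform(4.5, 5.5))
                       for x, y in dc]

    bg = model.background(exposure_ms)
    img = np.full((field_size, field_size), bg, dtype=float)
    yy, xx = np.mgrid[0:field_size, 0:field_size]
    for cx, cy in bead_centers:
        x0, x1 = int(cx) - 40, int(cx) + 41
        y0, y1 = int(cy) - 40, int(cy) + 41
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, field_size), min(y1, field_size)
        r = np.hypot(xx[y0:y1, x0:x1] - cx, yy[y0:y1, x0:x1] - cy)
        img[y0:y1, x0:x1] += bg * (_bead_template(r, dz_um, model) - 1.0)
    for cx, cy, theta, a, b in distractors:
        x0, x1 = max(int(cx) - 35, 0), min(int(cx) + 36, field_size)
        y0, y1 = max(int(cy) - 35, 0), min(int(cy) + 36, field_size)
        dx = xx[y0:y1, x0:x1] - cx
        dy = yy[y0:y1, x0:x1] - cy
        u = dx * np.cos(theta) + dy * np.sin(theta)
        v = -dx * np.sin(theta) + dy * np.cos(theta)
        q = (u / a) ** 2 + (v / b) ** 2
        img[y0:y1, x0:x1] -= 0.5 * bg / (1.0 + np.exp(np.clip((q - 1.0) * 6.0, -50, 50)))
    img = _blur(img, model.blur_radius(dz_um))
    img = _finalize(img, model, rng)
    truth = pd.DataFrame(bead_centers, columns=["x", "y"])
    return img, truth


def _image_rng(seed: int, fov: int, zi: int, ei: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1000 + fov, 2000 + zi, 3000 + ei])


def simulate_sweep(
    spec: SweepSpec, model: OpticalModel = OpticalModel()
) -> tuple[dict, pd.DataFrame]:
    """Simulate a full Z sweep in memory.

    Returns ``(images, manifest)`` where ``images`` maps
    ``(experiment, exposure_ms, fov, z_um)`` to a uint8 array and the
    manifest carries one row per image with the ground-truth
    ``true_dz_um = z_um - true_refp`` (negative below the focal plane).
    Bead layout is fixed per FOV across the whole sweep, as on a real stage;
    noise is independent per image.
    """
    if not (spec.z_min <= spec.true_refp <= spec.z_max):
        # allowed, but the focal plane is then outside the sweep
        pass
    zs = spec.z_levels()
    images: dict = {}
    rows = []
    for fov in range(spec.n_fov):
        layout_rng = np.random.default_rng([spec.seed, 77, fov])
        margin = model.bead_radius_px + 10
        centers = _place_objects(
            spec.beads_per_fov, spec.field_size, margin, 4.5 * model.bead_radius_px, layout_rng
        )
        dcent = _place_objects(
            spec.distractor_count, spec.field_size, margin + 15,
            4.5 * model.bead_radius_px + 15, layout_rng, existing=centers,
        )
        dist = [
            (x, y, layout_rng.uniform(0, np.pi), layout_rng.uniform(18, 24),
             layout_rng.uniform(4.5, 5.5))
            for x, y in dcent
        ]
        for zi, z in enumerate(zs):
            dz = float(z - spec.true_refp)
            for ei, exp_ms in enumerate(spec.exposures):
                rng = _image_rng(spec.seed, fov, zi, ei)
                img, _ = render_field(
                    dz, exp_ms, model, spec.field_size, spec.beads_per_fov,
                    rng=rng, bead_centers=centers, distractors=dist,
                )
                key = (spec.experiment, float(exp_ms), fov, float(z))
                images[key] = img
                rows.append(
                    {"experiment": spec.experiment, "exposure_ms": float(exp_ms),
                     "fov": fov, "z_um": float(z), "true_dz_um": dz}
                )
    manifest = pd.DataFrame(rows)
    return images, manifest


def generate_sweep(
    spec: SweepSpec, model: OpticalModel = OpticalModel(), outdir: str = "."
) -> str:
    """Write a simulated sweep to disk as TIFFs plus a CSV manifest.

    Returns the manifest path.  File layout:
    ``<outdir>/<experiment>_e<exposure>_f<fov>_z<z>.tif``.
    """
    import tifffile

    os.makedirs(outdir, exist_ok=True)
    images, manifest = simulate_sweep(spec, model)
    paths = []
    for _, row in manifest.iterrows():
        key = (row.experiment, row.exposure_ms, int(row.fov), row.z_um)
        fname = (
            f"{row.experiment}_e{row.exposure_ms:g}_f{int(row.fov)}_z{row.z_um:g}.tif"
        )
        path = os.path.join(outdir, fname)
        tifffile.imwrite(path, images[key])
        paths.append(path)
    manifest = manifest.assign(path=paths)
    mpath = os.path.join(outdir, "manifest.csv")
    manifest.to_csv(mpath, index=False)
    return mpath
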