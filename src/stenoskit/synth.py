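"""Synthetic angiogram-like scenes: dark vessel trees with annotated stenoses.

X-ray coronary angiography shows contrast-filled vessels as dark curvilinear
tubes on a brighter, noisy tissue background.  This generator emulates that
appearance: each scene draws a few smooth random curves (spline centerlines)
as dark tubes of slowly varying width over a low-frequency textured
background, optionally narrows each tube over a short arc — a "stenosis" —
and records a tight bounding box around the narrowed segment in normalized
YOLO coordinates (class 0).  Gaussian pixel noise is added last.  Everything
is deterministic given the seed.

It is a phantom, not a physical simulation: no projection geometry, motion
blur, or contrast-washout dynamics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter

from .boxloss import Box
from .metrics import GroundTruth, write_yolo_labels
from .prep import write_gray

__all__ = ["SceneParams", "VesselTrace", "SyntheticScene",
           "generate_vessel_image", "generate_dataset"]


@dataclass(frozen=True)
class SceneParams:
    """Generation knobs for one scene.

    size            image side length in pixels.
    n_vessels       number of vessel curves drawn.
    width_range     (min, max) vessel half-width in pixels.
    stenosis_prob   per-vessel probability of inserting one stenosis.
    stenosis_factor local width multiplier of the narrowed arc, in (0, 1).
    noise_sd        additive Gaussian pixel-noise standard deviation.
    seed            RNG seed; identical params reproduce the scene bit-exactly.

    Defaults draw tubes of half-width 4–8 px on a 640-px frame, so a stenosis
    box spans roughly 3–8% of the image side — small targets, as in clinical
    frames.
    """

    size: int = 640
    n_vessels: int = 3
    width_range: tuple[float, float] = (4.0, 8.0)
    stenosis_prob: float = 0.7
    stenosis_factor: float = 0.45
    noise_sd: float = 8.0
    seed: int = 0
    background_level: float = 200.0
    vessel_level: float = 70.0

    def __post_init__(self):
        if not (0.0 < self.stenosis_factor < 1.0):
            raise ValueError("stenosis_factor must lie in (0, 1)")
        if not (0.0 <= self.stenosis_prob <= 1.0):
            raise ValueError("stenosis_prob must lie in [0, 1]")
        if self.width_range[0] > self.width_range[1] or self.width_range[0] <= 0:
            raise ValueError("width_range must be a nonempty positive range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.size < 32 or self.size <= 6 * self.width_range[1]:
            raise ValueError("image too small for the requested vessel width")


@dataclass
class VesselTrace:
    """Centerline samples of one drawn vessel (generator bookkeeping)."""

    points: np.ndarray          # (M, 2) x, y in pixels
    radii: np.ndarray           # (M,) drawn half-width (stenosis applied)
    nominal_radii: np.ndarray   # (M,) half-width without the stenosis dip
    stenosis_span: tuple[int, int] | None = None   # sample-index range


@dataclass
class SyntheticScene:
    image: np.ndarray                  # H×W uint8
    annotations: list[GroundTruth]     # class 0, normalized YOLO coords
    params: SceneParams
    vessels: list[VesselTrace] = field(default_factory=list)


def _centerline(rng: np.random.Generator, size: int) -> np.ndarray:
    """Smooth random curve crossing the frame, kept inside a margin."""
    margin = 0.1 * size
    k = 5
    main = np.linspace(margin, size - margin, k)
    cross = rng.uniform(margin, size - margin) + \
        rng.normal(0.0, 0.12 * size, size=k)
    cross = np.clip(cross, margin, size - margin)
    t = np.linspace(0.0, 1.0, k)
    m = int(3 * size)
    ts = np.linspace(0.0, 1.0, m)
    a = CubicSpline(t, main)(ts)
    b = CubicSpline(t, cross)(ts)
    if rng.random() < 0.5:          # horizontal-ish or vertical-ish
        xy = np.stack([a, b], axis=1)
    else:
        xy = np.stack([b, a], axis=1)
    return np.clip(xy, 2.0, size - 3.0)


def _width_profile(rng: np.random.Generator, m: int,
                   width_range: tuple[float, float]) -> np.ndarray:
    r0 = rng.uniform(*width_range)
    knots = rng.uniform(0.85, 1.15, size=4)
    ts = np.linspace(0.0, 1.0, m)
    wiggle = CubicSpline(np.linspace(0, 1, 4), knots)(ts)
    return r0 * np.clip(wiggle, 0.7, 1.3)


def _stenosis_dip(rng: np.random.Generator, ts: np.ndarray,
                  curve_len: float, mean_radius: float,
                  factor: float) -> tuple[np.ndarray, tuple[int, int]]:
    """Multiplier profile dipping to `factor` over a short arc; returns the
    profile and the sample span of the deeper half of the dip."""
    t0 = rng.uniform(0.35, 0.65)
    arc_px = 4.0 * (2.0 * mean_radius)          # ~4 vessel diameters
    ht = 0.5 * arc_px / curve_len               # half-arc in t units
    mult = np.ones_like(ts)
    inside = np.abs(ts - t0) < ht
    # raised-cosine dip: multiplier = factor exactly at the arc center
    mult[inside] = 1.0 - (1.0 - factor) * 0.5 * (
        1.0 + np.cos(np.pi * (ts[inside] - t0) / ht))
    deep = mult < 1.0 - 0.5 * (1.0 - factor)
    idx = np.nonzero(deep)[0]
    return mult, (int(idx[0]), int(idx[-1]))


def _stamp_tube(mask: np.ndarray, pts: np.ndarray, radii: np.ndarray) -> None:
    """Rasterize a tube by stamping disks along the centerline samples."""
    size = mask.shape[0]
    for (x, y), r in zip(pts, radii):
        r = max(r, 0.5)
        x0, x1 = int(np.floor(x - r)), int(np.ceil(x + r)) + 1
        y0, y1 = int(np.floor(y - r)), int(np.ceil(y + r)) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        x1, y1 = min(x1, size), min(y1, size)
        if x0 >= x1 or y0 >= y1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        mask[y0:y1, x0:x1] |= (xx - x) ** 2 + (yy - y) ** 2 <= r * r


def generate_vessel_image(params: SceneParams) -> SyntheticScene:
    """Draw one seeded scene; see the module docstring for the recipe."""
    rng = np.random.default_rng(params.seed)
    size = params.size

    # background: base level + smooth "tissue" blobs
    blobs = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), sigma=size / 16)
    sd = blobs.std()
    if sd > 0:
        blobs *= 15.0 / sd
    background = params.background_level + blobs

    vessel_mask = np.zeros((size, size), dtype=bool)
    vessels: list[VesselTrace] = []
    annotations: list[GroundTruth] = []

    for _ in range(params.n_vessels):
        pts = _centerline(rng, size)
        m = len(pts)
        ts = np.linspace(0.0, 1.0, m)
        nominal = _width_profile(rng, m, params.width_range)
        seg = np.diff(pts, axis=0)
        curve_len = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
        span = None
        mult = np.ones(m)
        if rng.random() < params.stenosis_prob:
            mult, span = _stenosis_dip(rng, ts, curve_len, float(nominal.mean()),
                                       params.stenosis_factor)
        radii = nominal * mult
        _stamp_tube(vessel_mask, pts, radii)
        vessels.append(VesselTrace(points=pts, radii=radii,
                                   nominal_radii=nominal, stenosis_span=span))
        if span is not None:
            i0, i1 = span
            seg_pts = pts[i0:i1 + 1]
            seg_r = nominal[i0:i1 + 1]      # pad by the healthy width
            pad = 2.0
            left = float(np.min(seg_pts[:, 0] - seg_r) - pad)
            right = float(np.max(seg_pts[:, 0] + seg_r) + pad)
            top = float(np.min(seg_pts[:, 1] - seg_r) - pad)
            bottom = float(np.max(seg_pts[:, 1] + seg_r) + pad)
            left, top = max(left, 0.0), max(top, 0.0)
            right, bottom = min(right, float(size)), min(bottom, float(size))
            box = Box((left + right) / 2 / size, (top + bottom) / 2 / size,
                      (right - left) / size, (bottom - top) / size)
            annotations.append(GroundTruth(box, class_id=0))

    if not vessel_mask.any():
        raise ValueError("generation produced no drawable vessel area")

    soft = gaussian_filter(vessel_mask.astype(np.float64), sigma=1.0)
    soft = np.clip(soft, 0.0, 1.0)
    img = background * (1.0 - soft) + params.vessel_level * soft
    img = img + rng.normal(0.0, params.noise_sd, (size, size))
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return SyntheticScene(image=image, annotations=annotations,
                          params=params, vessels=vessels)


def generate_dataset(params: SceneParams, n: int,
                     splits: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     out_dir=None) -> dict:
    """Write n seeded scenes as PNG + YOLO labels under train/val/test.

    Per-image seeds derive from ``params.seed``; rerunning with identical
    arguments reproduces every file.  Returns (and writes) a JSON manifest
    recording the parameters, splits and per-image seeds.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if len(splits) != 3 or any(s < 0 for s in splits) or \
            abs(sum(splits) - 1.0) > 1e-6:
        raise ValueError(f"splits must be three nonnegative fractions "
                         f"summing to 1, got {splits}")
    out_dir = Path(out_dir)
    n_val = int(round(n * splits[1]))
    n_test = int(round(n * splits[2]))
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ValueError("degenerate splits: no training images left")
    assignment = (["train"] * n_train + ["val"] * n_val + ["test"] * n_test)

    records = []
    for i, split in enumerate(assignment):
        seed_i = (params.seed * 1000003 + i) % (2 ** 31)
        p = SceneParams(**{**asdict(params), "seed": seed_i})
        scene = generate_vessel_image(p)
        stem = f"scene_{i:04d}"
        img_path = out_dir / split / "images" / f"{stem}.png"
        lbl_path = out_dir / split / "labels" / f"{stem}.txt"
        write_gray(img_path, scene.image)
        write_yolo_labels(lbl_path, scene.annotations)
        records.append({"stem": stem, "split": split, "seed": seed_i,
                        "n_stenoses": len(scene.annotations)})

    manifest = {"params": asdict(params), "n": n, "splits": list(splits),
                "images": records}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
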