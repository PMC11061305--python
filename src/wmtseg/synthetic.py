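"""Synthetic phantom datasets for segmentation experiments.

Two regimes, mirroring the two kinds of data the method targets:

* ``organ`` — one large foreground region per image with a smooth, closed,
  star-convex boundary (a liver-like structure on a CT slice): the boundary
  is a periodic cubic spline through random control radii around a random
  center.
* ``nuclei`` — many small, non-touching elliptical blobs on a textured
  background (stained-tissue nuclei at high magnification), placed by
  rejection sampling.

Images are mask-driven: a base intensity, plus a smooth random background
texture (zero-mean over the background, absent from the foreground), plus
``contrast`` on the foreground, plus i.i.d. Gaussian noise.  With zero
noise, thresholding at base + contrast/2 recovers the mask exactly.

Intensities are float in [0, 1] in memory; ``save_pairs``/``load_pairs``
use 8-bit grayscale PNG with 0/255 masks, matched by filename stem.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label
from skimage.transform import resize as sk_resize

__all__ = ["PhantomSpec", "generate", "split", "save_pairs", "load_pairs"]


@dataclass
class PhantomSpec:
    """Parameters of one phantom dataset."""

    mode: str = "organ"                 # organ | nuclei
    side: int = 128
    n_images: int = 8
    noise_sd: float = 0.03              # Gaussian pixel noise, intensity units
    contrast: float = 0.45              # foreground-background intensity gap
    blob_count_range: tuple[int, int] = (8, 20)   # nuclei mode
    boundary_smoothness: int = 8        # organ mode: spline control points
    base_intensity: float = 0.35
    texture_amp: float = 0.3            # background texture, fraction of contrast
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("organ", "nuclei"):
            raise ValueError(f"mode must be 'organ' or 'nuclei', got {self.mode!r}")
        if self.side % 4:
            raise ValueError(f"side {self.side} must be divisible by 4")
        if self.contrast <= 0:
            raise ValueError("contrast must be positive")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.boundary_smoothness < 4:
            raise ValueError("boundary_smoothness needs at least 4 control points")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["blob_count_range"] = list(self.blob_count_range)
        return d


# ---------------------------------------------------------------------------
# mask generators
# ---------------------------------------------------------------------------


def _organ_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Star-convex region from a periodic radial spline; one component."""
    s = spec.side
    cy = s * rng.uniform(0.40, 0.60)
    cx = s * rng.uniform(0.40, 0.60)
    k = spec.boundary_smoothness
    radii = s * rng.uniform(0.18, 0.34, size=k)
    theta_ctrl = np.linspace(0, 2 * np.pi, k + 1)
    radii = np.append(radii, radii[0])
    spline = CubicSpline(theta_ctrl, radii, bc_type="periodic")
    theta = np.linspace(0, 2 * np.pi, 16 * k, endpoint=False)
    r = np.clip(spline(theta), 2.0, s / 2 - 2)
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    rr, cc = draw_polygon(rows, cols, shape=(s, s))
    mask = np.zeros((s, s), dtype=np.uint8)
    mask[rr, cc] = 1
    return mask


def _nuclei_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Non-touching elliptical blobs placed by rejection sampling."""
    s = spec.side
    lo, hi = spec.blob_count_range
    target = int(rng.integers(lo, hi + 1))
    mask = np.zeros((s, s), dtype=np.uint8)
    # occupancy with a 1-px dilation margin keeps blobs non-touching
    occupied = np.zeros((s, s), dtype=bool)
    yy, xx = np.mgrid[0:s, 0:s]
    placed = 0
    attempts = 0
    max_attempts = 200 * target
    while placed < target:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {target} non-touching blobs of this size on a "
                f"{s}x{s} image after {max_attempts} attempts; reduce "
                f"blob_count_range or increase side"
            )
        a = rng.uniform(0.015, 0.045) * s   # semi-axes
        b = a * rng.uniform(0.6, 1.0)
        phi = rng.uniform(0, np.pi)
        cy = rng.uniform(a + 2, s - a - 2)
        cx = rng.uniform(a + 2, s - a - 2)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(phi) - dx * np.sin(phi)
        v = dy * np.sin(phi) + dx * np.cos(phi)
        blob = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        margin = (u / (a + 2)) ** 2 + (v / (b + 2)) ** 2 <= 1.0
        if (margin & occupied).any():
            continue
        mask[blob] = 1
        occupied |= margin
        placed += 1
    return mask


def _render_image(mask: np.ndarray, spec: PhantomSpec,
                  rng: np.random.Generator) -> np.ndarray:
    """Mask-driven intensity + background texture + Gaussian noise."""
    s = spec.side
    texture = gaussian_filter(rng.normal(size=(s, s)), sigma=s / 16)
    peak = np.abs(texture).max()
    if peak > 0:
        texture *= (spec.texture_amp * spec.contrast / 2) / peak
    bg = mask == 0
    if bg.any():
        texture -= texture[bg].mean()    # zero-mean over the background
    texture[~bg] = 0.0                   # texture lives on the background only
    img = spec.base_intensity + texture + spec.contrast * mask.astype(float)
    img = img + spec.noise_sd * rng.normal(size=(s, s))
    return img


def generate(spec: PhantomSpec) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate ``spec.n_images`` (image, binary mask) pairs, seeded."""
    rng = np.random.default_rng(spec.seed)
    make_mask = _organ_mask if spec.mode == "organ" else _nuclei_mask
    pairs = []
    for _ in range(spec.n_images):
        mask = make_mask(spec, rng)
        if spec.mode == "organ":
            # the radial polygon fill is star-convex hence one component,
            # but guard against degenerate splines anyway
            while cc_label(mask).max() != 1:
                mask = make_mask(spec, rng)
        pairs.append((_render_image(mask, spec, rng), mask))
    return pairs


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def split(dataset, fractions, seed: int = 0):
    """Disjoint, exhaustive train/val/test partition by shuffled index."""
    dataset = list(dataset)
    fractions = tuple(fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three nonnegative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n = len(dataset)
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    train = [dataset[i] for i in order[:n_train]]
    val = [dataset[i] for i in order[n_train:n_train + n_val]]
    test = [dataset[i] for i in order[n_train + n_val:]]
    return train, val, test


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------


def save_pairs(pairs, out_dir, manifest: bool = True) -> None:
    """Write images/ and masks/ PNG trees with matching stems."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, mask) in enumerate(pairs):
        stem = f"{i:05d}"
        img8 = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        mask8 = (np.asarray(mask) > 0).astype(np.uint8) * 255
        iio.imwrite(out_dir / "images" / f"{stem}.png", img8)
        iio.imwrite(out_dir / "masks" / f"{stem}.png", mask8)
        rows.append([stem, int(mask.sum()), img.shape[0], img.shape[1]])
    if manifest:
        with open(out_dir / "manifest.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stem", "foreground_pixels", "height", "width"])
            writer.writerows(rows)


def load_pairs(image_dir, mask_dir=None, resize_to: int | None = None):
    """Load image/mask PNG pairs matched by filename stem.

    Masks are binarized at 128/255; RGB images are converted to grayscale.
    ``resize_to`` applies the preprocessing convention of resizing both
    rasters to a common square side (512 in the reference configuration).
    """
    image_dir = Path(image_dir)
    if mask_dir is None:
        mask_dir = image_dir.parent / "masks"
        image_dir = image_dir if image_dir.name != "." else image_dir
        if not mask_dir.is_dir() and (image_dir / "masks").is_dir():
            mask_dir = image_dir / "masks"
            image_dir = image_dir / "images"
    mask_dir = Path(mask_dir)
    pairs = []
    stems = sorted(p.stem for p in image_dir.iterdir()
                   if p.suffix.lower() in (".png", ".tif", ".tiff"))
    if not stems:
        raise ValueError(f"no raster images found in {image_dir}")
    for stem in stems:
        img_path = next(image_dir.glob(stem + ".*"))
        candidates = list(mask_dir.glob(stem + ".*"))
        if not candidates:
            raise ValueError(f"no mask found for image stem {stem!r} in {mask_dir}")
        img = np.asarray(iio.imread(img_path), dtype=np.float64)
        if img.ndim == 3:
            img = img[..., :3].mean(axis=-1)
        img /= 255.0
        mask = np.asarray(iio.imread(candidates[0]))
        if mask.ndim == 3:
            mask = mask[..., 0]
        mask = (mask >= 128).astype(np.uint8)
        if resize_to is not None:
            img = sk_resize(img, (resize_to, resize_to), order=1,
                            preserve_range=True, anti_aliasing=True)
            mask = sk_resize(mask.astype(float), (resize_to, resize_to),
                             order=0, preserve_range=True,
                             anti_aliasing=False).astype(np.uint8)
        pairs.append((img, mask))
    return pairs
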