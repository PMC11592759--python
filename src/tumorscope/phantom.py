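"""Synthetic chest-CT phantoms with exact ground truth.

Each phantom emulates the structure of an annotated clinical lung-CT case:
an ordered stack of grayscale slices through a torso-like disk containing two
lung-shaped low-intensity regions, zero or more bright spherical nodules
placed inside lung tissue, per-slice binary lung masks, per-slice nodule
bounding boxes, and the consistent 3-D tumor occupancy volume the slices
sample.  Lung pixels are deliberately a minority of the image (the fraction
is confined to a configured sub-interval of (0, 0.5)), reproducing the class
imbalance that motivates reward-shaped training of the segmentation stage.

Geometry is deliberately simple: lungs are two noisy ellipses (smooth angular
radius perturbation) whose size is calibrated per slice by bisection so the
pixel-counted lung fraction lands inside the configured range; nodules are
spheres in index space, sectioned exactly per slice so that stacking the
per-slice cross-sections reproduces the ground-truth volume voxel for voxel.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import AffineTransform, resize as _sk_resize, rotate as _sk_rotate, warp

from .datatypes import (MaskImage, PhantomCase, PhantomConfig, SliceImage,
                        TumorAnnotation, VoxelVolume)

__all__ = [
    "generate_phantom_case", "generate_phantom_dataset",
    "normalize_intensity", "augment", "resize",
]

# Intensity palette (arbitrary normalized units, darker = more air)
_BG, _BODY, _LUNG, _NODULE = 0.05, 0.45, 0.12, 0.70


def normalize_intensity(raw: np.ndarray) -> np.ndarray:
    """Min-max rescale an arbitrary real-valued image to [0, 1].

    The minimum maps to 0 and the maximum to 1.  A constant image maps to all
    zeros (documented convention, not an error).
    """
    arr = np.asarray(raw, dtype=np.float64)
    if not np.isfinite(arr).all():
        raise ValueError("input intensities must be finite")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _lung_membership(shape: tuple[int, int], centers, axes, wobble,
                     scale: float) -> np.ndarray:
    """Boolean union of two noisy ellipses at a given global scale."""
    H, W = shape
    yy, xx = np.mgrid[0:H, 0:W]
    inside = np.zeros(shape, dtype=bool)
    for (cy, cx), (ay, ax_), (amp, phases) in zip(centers, axes, wobble):
        dy, dx = (yy - cy) / ay, (xx - cx) / ax_
        rho = np.sqrt(dy**2 + dx**2)
        theta = np.arctan2(dy, dx)
        bump = sum(amp * np.cos(k * theta + ph)
                   for k, ph in zip((2, 3, 5), phases))
        inside |= rho <= scale * (1.0 + bump)
    return inside


def _calibrate_lung_mask(shape, centers, axes, wobble,
                         frac_range: tuple[float, float]) -> np.ndarray:
    """Bisect the ellipse scale until the pixel fraction lies in range."""
    lo, hi = frac_range
    target = 0.5 * (lo + hi)
    s_lo, s_hi = 0.05, 4.0
    for _ in range(60):
        s = 0.5 * (s_lo + s_hi)
        mask = _lung_membership(shape, centers, axes, wobble, s)
        frac = mask.mean()
        if lo <= frac <= hi:
            return mask
        if frac < target:
            s_lo = s
        else:
            s_hi = s
    raise ValueError(
        f"could not calibrate lung fraction into {frac_range} on {shape}")


def _sphere_cross_section(shape, zc, yc, xc, r, z) -> np.ndarray:
    """Exact planar section of the sphere at integer slice z (boolean)."""
    H, W = shape
    dz2 = (z - zc) ** 2
    if dz2 > r**2:
        return np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[0:H, 0:W]
    return (yy - yc) ** 2 + (xx - xc) ** 2 + dz2 <= r**2


def generate_phantom_case(config: PhantomConfig) -> PhantomCase:
    """Generate one synthetic patient; bit-identical for identical config."""
    rng = np.random.default_rng(config.seed)
    H = W = config.image_size
    n = config.n_slices
    shape = (H, W)

    # case-level lung geometry: two ellipses left/right of the midline
    cy = H * rng.uniform(0.45, 0.55)
    gap = W * rng.uniform(0.12, 0.18)
    centers = [(cy, W / 2 - gap), (cy, W / 2 + gap)]
    axes = []
    for _ in range(2):
        ecc = rng.uniform(1.2, 1.8)  # lungs are taller than wide
        base = W * rng.uniform(0.10, 0.14)
        axes.append((base * ecc, base))
    wobble = [(rng.uniform(0.02, 0.06), rng.uniform(0, 2 * np.pi, size=3))
              for _ in range(2)]

    # per-slice masks; mild cranio-caudal tapering via per-slice axis scaling
    masks: list[np.ndarray] = []
    taper = 1.0 - 0.15 * np.abs(np.linspace(-1, 1, n))
    for z in range(n):
        axes_z = [(ay * taper[z], ax_ * taper[z]) for ay, ax_ in axes]
        masks.append(_calibrate_lung_mask(shape, centers, axes_z, wobble,
                                          config.lung_fraction_range))

    # nodules: spheres in (z, y, x) index space, strictly inside lung tissue
    n_lo, n_hi = config.n_nodules_range
    n_nodules = int(rng.integers(n_lo, n_hi + 1))
    volume = np.zeros((n, H, W), dtype=np.uint8)
    nodules = []
    for k in range(n_nodules):
        placed = False
        for _ in range(200):
            r = rng.uniform(*config.nodule_radius_range)
            side = int(rng.integers(0, 2))
            (lcy, lcx), (lay, lax) = centers[side], axes[side]
            zc = rng.uniform(max(0.0, r), max(r, n - 1 - r)) if n > 1 else 0.0
            yc = lcy + rng.uniform(-0.4, 0.4) * lay
            xc = lcx + rng.uniform(-0.4, 0.4) * lax
            sections = [_sphere_cross_section(shape, zc, yc, xc, r, z)
                        for z in range(n)]
            if not any(s.any() for s in sections):
                continue
            if all((~masks[z] & sections[z]).sum() == 0 for z in range(n)):
                placed = True
                break
        if not placed:
            raise ValueError(
                "impossible nodule geometry: radius "
                f"{config.nodule_radius_range} does not fit inside the lung "
                "extent; shrink the nodules or enlarge the lungs")
        nodules.append((zc, yc, xc, r, f"nodule-{k}"))
        for z in range(n):
            volume[z][sections[z]] = 1

    # annotations: per-slice tight half-open boxes around each nodule section
    annotations: list[TumorAnnotation] = []
    for zc, yc, xc, r, nid in nodules:
        for z in range(n):
            sect = _sphere_cross_section(shape, zc, yc, xc, r, z)
            if not sect.any():
                continue
            ys, xs = np.nonzero(sect)
            annotations.append(TumorAnnotation(
                slice_index=z,
                box=(int(xs.min()), int(ys.min()),
                     int(xs.max()) + 1, int(ys.max()) + 1),
                nodule_id=nid))

    # render slices: body disk, dark lungs, bright nodules, additive noise
    case_id = f"phantom-{config.seed:08d}"
    yy, xx = np.mgrid[0:H, 0:W]
    body = ((yy - H / 2) / (0.47 * H)) ** 2 + ((xx - W / 2) / (0.45 * W)) ** 2 <= 1.0
    slices: list[SliceImage] = []
    mask_objs: list[MaskImage] = []
    for z in range(n):
        img = np.full(shape, _BG)
        img[body] = _BODY
        img[masks[z]] = _LUNG
        img[volume[z] > 0] = _NODULE
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=shape)
        img = np.clip(img, 0.0, 1.0)
        slices.append(SliceImage(img, case_id=case_id, slice_index=z))
        mask_objs.append(MaskImage(masks[z].astype(np.uint8)))

    return PhantomCase(
        slices=slices, masks=mask_objs, annotations=annotations,
        tumor_volume=VoxelVolume(volume, spacing=config.spacing),
        seed=config.seed)


def generate_phantom_dataset(config: PhantomConfig, n_cases: int,
                             seed: int | None = None) -> list[PhantomCase]:
    """Generate `n_cases` phantoms with per-case seeds derived from `seed`."""
    base = config.seed if seed is None else seed
    cases = []
    for i in range(n_cases):
        case_seed = int((base * 1000003 + i * 7919 + 1) % (2**31 - 1))
        cfg_i = PhantomConfig(**{**vars(config), "seed": case_seed})
        cases.append(generate_phantom_case(cfg_i))
    return cases


# --------------------------------------------------------------------------
# preprocessing: augmentation and resizing
# --------------------------------------------------------------------------

def _paired_transform(image: SliceImage, mask: MaskImage, img_px, mask_px):
    return (SliceImage(np.clip(img_px, 0.0, 1.0), case_id=image.case_id,
                       slice_index=image.slice_index),
            MaskImage((np.asarray(mask_px) > 0.5).astype(np.uint8)))


def augment(image: SliceImage, mask: MaskImage, op: str, *,
            angle: float | None = None, factor: float | None = None,
            ) -> tuple[SliceImage, MaskImage]:
    """Apply one geometric augmentation identically to image and mask.

    ``op`` is one of ``"rotate"`` (counter-clockwise by ``angle`` degrees
    about the image centre), ``"zoom"`` (scale by ``factor`` about the
    centre, same output size) or ``"hflip"``.  The image is resampled
    bilinearly, the mask with nearest neighbour so it stays binary.
    """
    px, mk = image.pixels, mask.labels.astype(float)
    if px.shape != mk.shape:
        raise ValueError("image and mask shapes differ")
    if op == "hflip":
        return _paired_transform(image, mask, px[:, ::-1], mk[:, ::-1])
    if op == "rotate":
        if angle is None:
            raise ValueError("rotate requires an angle")
        img2 = _sk_rotate(px, angle, order=1, preserve_range=True, cval=0.0)
        mk2 = _sk_rotate(mk, angle, order=0, preserve_range=True, cval=0.0)
        return _paired_transform(image, mask, img2, mk2)
    if op == "zoom":
        if factor is None or factor <= 0:
            raise ValueError("zoom requires a positive factor")
        H, W = px.shape
        center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        tf = (AffineTransform(translation=-center)
              + AffineTransform(scale=1.0 / factor)
              + AffineTransform(translation=center))
        img2 = warp(px, tf, order=1, preserve_range=True, cval=0.0)
        mk2 = warp(mk, tf, order=0, preserve_range=True, cval=0.0)
        return _paired_transform(image, mask, img2, mk2)
    raise ValueError(f"unknown augmentation op {op!r}")


def resize(image: SliceImage, mask: MaskImage,
           target_size: tuple[int, int]) -> tuple[SliceImage, MaskImage]:
    """Resize to ``(height, width)``; bilinear image, nearest-neighbour mask."""
    th, tw = target_size
    if th <= 0 or tw <= 0:
        raise ValueError("target size must be positive")
    if (th, tw) == image.pixels.shape:
        return (SliceImage(image.pixels.copy(), case_id=image.case_id,
                           slice_index=image.slice_index),
                MaskImage(mask.labels.copy()))
    img2 = _sk_resize(image.pixels, (th, tw), order=1, preserve_range=True,
                      anti_aliasing=False)
    mk2 = _sk_resize(mask.labels.astype(float), (th, tw), order=0,
                     preserve_range=True, anti_aliasing=False)
    return _paired_transform(image, mask, img2, mk2)
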