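"""Synthetic organoid imagery, annotation handling and preprocessing.

Real datasets in this domain are brightfield micrographs of 3D organoid
cultures with expert polygon annotations; none are bundled here, so a
synthetic generator emulates their salient features: bright, roughly
elliptical organoids of heterogeneous size with a darker rim, on a
textured background with a smooth uneven-illumination field and additive
Gaussian noise.  The preprocessing pipeline mirrors common practice for
such data: non-local-means denoising, expansion to fixed-size tiles by
random flip/crop/scale, and a source-grouped train/val/test split.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.restoration import denoise_nl_means


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _default_meta() -> dict:
    return {"source_id": "", "culture_day": 1, "group_label": "CTR", "pixel_size_um": 1.0}


@dataclass
class AnnotatedImage:
    """An image, its binary organoid mask, and acquisition metadata."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W, values in {0, 1}
    meta: dict = field(default_factory=_default_meta)

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} sizes differ"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must contain only 0/1")
        if self.meta.get("culture_day", 1) < 1:
            raise ValueError("culture_day must be >= 1")


@dataclass
class PolygonAnnotation:
    """Polygon outlines in image coordinates (x = column, origin top-left)."""

    shapes: list[tuple[str, list[tuple[float, float]]]]
    image_height: int
    image_width: int

    def validate(self):
        if self.image_height < 1 or self.image_width < 1:
            raise ValueError("canvas must be positive-sized")
        for label, verts in self.shapes:
            if len(verts) < 3:
                raise ValueError(f"polygon {label!r} has {len(verts)} < 3 vertices")
            for x, y in verts:
                if not (0 <= x < self.image_width and 0 <= y < self.image_height):
                    raise ValueError(f"vertex ({x},{y}) outside canvas in {label!r}")


@dataclass
class SyntheticSceneSpec:
    width: int = 256
    height: int = 256
    n_organoids: int = 8
    radius_range: tuple[float, float] = (8.0, 24.0)
    intensity_contrast: float = 0.5
    noise_sigma: float = 6.0
    illumination_amplitude: float = 0.15
    overlap_allowed: bool = False
    boundary_wobble: float = 0.08
    seed: int = 0

    def validate(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("scene must be positive-sized")
        if self.n_organoids < 0:
            raise ValueError("n_organoids must be >= 0")
        lo, hi = self.radius_range
        if lo > hi:
            raise ValueError("radius_range min must be <= max")
        if hi >= min(self.width, self.height) / 2:
            raise ValueError("max radius must be < min(width,height)/2")
        if not 0 < self.intensity_contrast <= 1:
            raise ValueError("intensity_contrast must be in (0,1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.illumination_amplitude < 1:
            raise ValueError("illumination_amplitude must be in [0,1)")


@dataclass
class AugmentationConfig:
    tile_size: int = 256
    tiles_per_image: int = 32
    allow_hflip: bool = True
    allow_vflip: bool = True
    scale_range: tuple[float, float] = (0.8, 1.25)
    seed: int = 0

    def validate(self):
        if self.tile_size < 32:
            raise ValueError("tile_size must be >= 32")
        if self.tiles_per_image < 1:
            raise ValueError("tiles_per_image must be >= 1")
        lo, hi = self.scale_range
        if not (0 < lo <= hi):
            raise ValueError("scale_range must satisfy 0 < min <= max")


@dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)  # train, val, test
    seed: int = 0

    def validate(self):
        if any(r < 0 for r in self.ratios):
            raise ValueError("ratios must be >= 0")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError(f"ratios must sum to 1, got {sum(self.ratios)}")


# ---------------------------------------------------------------------------
# synthetic scene rendering
# ---------------------------------------------------------------------------


def _render_scene(rng: np.random.Generator, height: int, width: int,
                  radii: np.ndarray, intensity_contrast: float,
                  noise_sigma: float, illumination_amplitude: float,
                  overlap_allowed: bool, boundary_wobble: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Render organoid blobs over a textured, unevenly lit background."""
    H, W = height, width
    base = 70.0 + gaussian_filter(rng.normal(0.0, 12.0, (H, W)), sigma=6.0)
    gy, gx = np.mgrid[0:H, 0:W]
    theta = rng.uniform(0, 2 * np.pi)
    ramp = np.cos(theta) * (gx / max(W - 1, 1) - 0.5) + np.sin(theta) * (
        gy / max(H - 1, 1) - 0.5
    )
    img = base + illumination_amplitude * 255.0 * ramp
    mask = np.zeros((H, W), dtype=bool)

    # place the largest organoids first: rejection sampling then succeeds for
    # the small ones instead of silently dropping the big ones
    order = np.argsort([-max(np.atleast_1d(r)) for r in radii])
    for r in (radii[i] for i in order):
        ab = np.atleast_1d(r)
        placed = False
        for _ in range(100):
            a = float(ab[0])
            b = float(ab[-1])
            ang = rng.uniform(0, np.pi)
            rmax = max(a, b) * (1 + boundary_wobble) + 1
            cy = rng.uniform(rmax, H - rmax) if H > 2 * rmax else H / 2
            cx = rng.uniform(rmax, W - rmax) if W > 2 * rmax else W / 2
            y0, y1 = int(max(0, cy - rmax)), int(min(H, cy + rmax + 1))
            x0, x1 = int(max(0, cx - rmax)), int(min(W, cx + rmax + 1))
            yy, xx = np.mgrid[y0:y1, x0:x1]
            dx, dy = xx - cx, yy - cy
            u = (dx * np.cos(ang) + dy * np.sin(ang)) / a
            v = (-dx * np.sin(ang) + dy * np.cos(ang)) / b
            rho = np.sqrt(u ** 2 + v ** 2)
            if boundary_wobble > 0:
                pol = np.arctan2(v, u)
                k1, k2 = rng.integers(3, 7), rng.integers(7, 12)
                p1, p2 = rng.uniform(0, 2 * np.pi, 2)
                edge = 1.0 + boundary_wobble * 0.6 * np.sin(k1 * pol + p1) \
                    + boundary_wobble * 0.4 * np.sin(k2 * pol + p2)
            else:
                edge = np.ones_like(rho)
            inside = rho <= edge
            if not overlap_allowed and (inside & mask[y0:y1, x0:x1]).any():
                continue
            # bright interior with a mild dome profile, darker rim
            offset = intensity_contrast * 150.0 * rng.uniform(0.75, 1.05)
            rel = np.clip(rho / np.maximum(edge, 1e-9), 0, 1)
            bump = offset * (1.0 - 0.35 * rel ** 2)
            rim = rel > 0.82
            patch = img[y0:y1, x0:x1]
            patch[inside] += bump[inside]
            patch[inside & rim] -= intensity_contrast * 90.0
            mask[y0:y1, x0:x1] |= inside
            placed = True
            break
        if not placed:
            warnings.warn("could not place an organoid without overlap; skipping one")
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, (H, W))
    img8 = np.clip(img, 0, 255).astype(np.uint8)
    return np.repeat(img8[:, :, None], 3, axis=2), mask.astype(np.uint8)


def generate_synthetic_scene(spec: SyntheticSceneSpec) -> AnnotatedImage:
    """Deterministically render one synthetic organoid scene with its mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # each ellipse axis drawn independently from radius_range; a degenerate
    # range therefore yields exact discs (up to boundary wobble)
    radii = rng.uniform(spec.radius_range[0], spec.radius_range[1], (spec.n_organoids, 2))
    image, mask = _render_scene(
        rng, spec.height, spec.width, radii, spec.intensity_contrast,
        spec.noise_sigma, spec.illumination_amplitude, spec.overlap_allowed,
        spec.boundary_wobble,
    )
    meta = _default_meta() | {"source_id": f"synthetic-{spec.seed}"}
    return AnnotatedImage(image, mask, meta)


def generate_drug_screen(seed: int = 0,
                         groups: tuple[str, ...] = ("CTR", "RA", "B0107"),
                         days: tuple[int, ...] = (1, 3, 5, 7),
                         images_per_condition: int = 10,
                         image_size: tuple[int, int] = (192, 192),
                         organoids_per_image: int = 8,
                         base_radius: float = 6.0,
                         growth_per_day: float = 0.18,
                         ctr_boost: float = 1.25,
                         sigma_log: float = 0.2,
                         effect_start_day: int = 5) -> list[AnnotatedImage]:
    """Synthetic drug-screen study: growing organoids under three arms.

    Per-organoid radii are log-normal with a median that grows
    exponentially with culture day.  From ``effect_start_day`` on, the
    untreated arm (first group) gets its median radius multiplied by
    ``ctr_boost`` — i.e. the drugs inhibit growth — while earlier days are
    statistically identical across arms.
    """
    rng = np.random.default_rng(seed)
    H, W = image_size
    out = []
    for day in days:
        for group in groups:
            for rep in range(images_per_condition):
                median_r = base_radius * np.exp(growth_per_day * (day - 1))
                if group == groups[0] and day >= effect_start_day:
                    median_r *= ctr_boost
                radii = np.exp(rng.normal(np.log(median_r), sigma_log, organoids_per_image))
                radii = np.clip(radii, 2.0, min(H, W) / 2 - 2)
                image, mask = _render_scene(
                    rng, H, W, radii, intensity_contrast=0.5, noise_sigma=5.0,
                    illumination_amplitude=0.1, overlap_allowed=False,
                    boundary_wobble=0.06,
                )
                out.append(
                    AnnotatedImage(
                        image, mask,
                        {"source_id": f"{group}-d{day}-r{rep}", "culture_day": int(day),
                         "group_label": group, "pixel_size_um": 1.0},
                    )
                )
    return out


# ---------------------------------------------------------------------------
# polygon annotations
# ---------------------------------------------------------------------------


def rasterize_polygons(ann: PolygonAnnotation) -> np.ndarray:
    """Binary mask: pixel (r,c) is 1 iff its center (x=c, y=r) lies inside
    or on the boundary of any polygon; overlapping polygons union."""
    ann.validate()
    mask = np.zeros((ann.image_height, ann.image_width), dtype=np.uint8)
    for _, verts in ann.shapes:
        poly = shapely.Polygon(verts)
        minx, miny, maxx, maxy = poly.bounds
        c0, c1 = max(0, int(np.floor(minx))), min(ann.image_width - 1, int(np.ceil(maxx)))
        r0, r1 = max(0, int(np.floor(miny))), min(ann.image_height - 1, int(np.ceil(maxy)))
        if c1 < c0 or r1 < r0:
            continue
        yy, xx = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
        hits = shapely.intersects_xy(poly, xx.astype(float), yy.astype(float))
        mask[r0 : r1 + 1, c0 : c1 + 1] |= hits.astype(np.uint8)
    return mask


def read_labelme(path) -> PolygonAnnotation:
    """Read a Labelme-dialect polygon JSON annotation."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except FileNotFoundError:
        raise FileNotFoundError(f"annotation file not found: {path}") from None
    shapes = [
        (s.get("label", ""), [tuple(map(float, p)) for p in s["points"]])
        for s in doc["shapes"]
    ]
    return PolygonAnnotation(shapes, int(doc["imageHeight"]), int(doc["imageWidth"]))


def write_labelme(ann: PolygonAnnotation, path) -> None:
    doc = {
        "shapes": [
            {"label": label, "points": [list(p) for p in verts], "shape_type": "polygon"}
            for label, verts in ann.shapes
        ],
        "imageHeight": ann.image_height,
        "imageWidth": ann.image_width,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------


def denoise_image(image: np.ndarray, strength: float = 10.0,
                  patch_size: int = 7, search_window: int = 21) -> np.ndarray:
    """Non-local-means denoising of an 8-bit image (gray or RGB).

    ``strength`` plays the role of the filtering parameter h on the 0-255
    scale; ``patch_size`` and ``search_window`` are the (odd) patch and
    search-window side lengths.
    """
    if patch_size % 2 == 0 or search_window % 2 == 0:
        raise ValueError("patch_size and search_window must be odd")
    if patch_size > search_window:
        raise ValueError("patch_size must be <= search_window")
    if strength < 0:
        raise ValueError("strength must be >= 0")
    img = np.asarray(image)
    if strength == 0:
        return img.copy()
    x = img.astype(np.float64) / 255.0
    channel_axis = -1 if x.ndim == 3 else None
    den = denoise_nl_means(
        x, h=strength / 255.0, sigma=0.0, patch_size=patch_size,
        patch_distance=(search_window - 1) // 2, channel_axis=channel_axis,
        fast_mode=True,
    )
    return np.clip(np.round(den * 255.0), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------


def _resize_pair(image: np.ndarray, mask: np.ndarray, nh: int, nw: int):
    # image bilinear, mask nearest-neighbour (stays binary); PIL's uint8
    # path is far faster than a float round-trip
    if (nh, nw) == image.shape[:2]:
        return image.copy(), mask.copy()
    img = np.asarray(Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    msk = np.asarray(Image.fromarray(mask.astype(np.uint8)).resize((nw, nh), Image.NEAREST))
    return img, msk


def apply_tile_transform(image: np.ndarray, mask: np.ndarray, log: dict):
    """Re-apply a logged augmentation transform (scale -> crop -> flips).

    The image is resampled bilinearly, the mask nearest-neighbour, so mask
    values stay binary.
    """
    nh, nw = log["scaled_size"]
    img, msk = _resize_pair(image, mask, nh, nw)
    y0, x0 = log["crop"]
    t = log["tile_size"]
    img, msk = img[y0 : y0 + t, x0 : x0 + t], msk[y0 : y0 + t, x0 : x0 + t]
    if log["hflip"]:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if log["vflip"]:
        img, msk = img[::-1, :], msk[::-1, :]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def augment_dataset(samples: list[AnnotatedImage],
                    cfg: AugmentationConfig) -> list[AnnotatedImage]:
    """Expand sources into ``tiles_per_image`` random flip/scale/crop tiles each.

    Every tile records its transform under ``meta['augment']`` so the
    geometry can be re-applied and verified independently.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    t = cfg.tile_size
    out: list[AnnotatedImage] = []
    for s in samples:
        H, W = s.mask.shape
        lo, hi = cfg.scale_range
        min_feasible = t / min(H, W)
        if min_feasible > hi:
            raise ValueError(
                f"source {s.meta.get('source_id', '?')!r} of size {H}x{W} cannot yield a "
                f"{t}x{t} tile under scales in [{lo}, {hi}]"
            )
        lo = max(lo, min_feasible)
        for i in range(cfg.tiles_per_image):
            scale = rng.uniform(lo, hi)
            nh = max(t, int(round(H * scale)))
            nw = max(t, int(round(W * scale)))
            y0 = int(rng.integers(0, nh - t + 1))
            x0 = int(rng.integers(0, nw - t + 1))
            hflip = bool(cfg.allow_hflip and rng.random() < 0.5)
            vflip = bool(cfg.allow_vflip and rng.random() < 0.5)
            log = {
                "scale": scale, "scaled_size": (nh, nw), "crop": (y0, x0),
                "tile_size": t, "hflip": hflip, "vflip": vflip,
            }
            img, msk = apply_tile_transform(s.image, s.mask, log)
            meta = dict(s.meta)
            meta["augment"] = log
            meta["tile_index"] = i
            out.append(AnnotatedImage(img, msk, meta))
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_dataset(samples: list[AnnotatedImage], spec: SplitSpec):
    """Source-grouped train/val/test partition.

    Targets round(ratio*N) for val and test with the remainder in train; all
    tiles sharing a ``source_id`` land in the same partition (so augmented
    copies of one micrograph can never leak across splits).
    """
    spec.validate()
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to split")
    n = len(samples)
    by_source: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        sid = s.meta.get("source_id") or f"__idx{i}"
        by_source.setdefault(sid, []).append(i)
    order = sorted(by_source)
    rng = np.random.default_rng(spec.seed)
    rng.shuffle(order)
    n_val = round(spec.ratios[1] * n)
    n_test = round(spec.ratios[2] * n)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    for sid in order:
        idxs = by_source[sid]
        if len(parts["test"]) + len(idxs) <= n_test:
            parts["test"].extend(idxs)
        elif len(parts["val"]) + len(idxs) <= n_val:
            parts["val"].extend(idxs)
        else:
            parts["train"].extend(idxs)
    return tuple([samples[i] for i in sorted(parts[k])] for k in ("train", "val", "test"))


# ---------------------------------------------------------------------------
# raster I/O and manifests
# ---------------------------------------------------------------------------


def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an H x W x 3 uint8 array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    try:
        with Image.open(path) as im:
            if im.mode in ("I", "I;16", "I;16B", "F"):
                raise ValueError(f"unsupported bit depth ({im.mode}) in {path}")
            return np.asarray(im.convert("RGB"))
    except ValueError:
        raise
    except Exception as e:  # unreadable / corrupt
        raise ValueError(f"could not read image {path}: {e}") from e


def write_mask(path, mask: np.ndarray) -> None:
    """Write a binary mask as single-channel PNG (0/255 on disk)."""
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return (arr > 127).astype(np.uint8)


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


MANIFEST_COLUMNS = [
    "path", "mask_path", "source_id", "split", "culture_day", "group_label", "pixel_size_um",
]


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("path",) if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} lacks required columns: {missing}")
    return df
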