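"""Domain-randomized scene compositing.

Builds synthetic training images by pasting bird sprites onto background
images with three paste operators:

``direct``
    hard alpha copy of the transformed sprite,
``gaussian``
    feathered blend through a Gaussian-blurred binary alpha mask,
``poisson``
    gradient-domain blend solving the discrete Poisson equation with the
    background as Dirichlet boundary condition.

Placement attributes (on-screen area fraction, lighting scalar, 2D pose)
are drawn from uniform distributions; the pasted-object area fraction is
uniform on [0.0004, 0.0056] of the frame area and the light factor uniform
on [0.6, 1.0].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg as _cg, spsolve

__all__ = [
    "Sprite",
    "PlacementSample",
    "CompositorConfig",
    "PlacementError",
    "sample_placement",
    "transform_sprite",
    "direct_paste",
    "gaussian_paste",
    "poisson_paste",
    "poisson_blend_region",
    "compose_scene",
    "generate_dataset",
    "CATEGORY_IDS",
]

CATEGORY_IDS = {"great_egret": 1, "little_egret": 2, "other": 3}


class PlacementError(RuntimeError):
    """Raised when no valid placement can be found under the overlap policy."""


@dataclass
class Sprite:
    """An RGBA cut-out with a species label.

    The array is ``(H, W, 4)`` uint8 with straight (un-premultiplied)
    colour; the opaque bounding box must be non-empty and tight after
    construction (see :func:`egretwatch.synthetic.generate_sprites`).
    """

    rgba: np.ndarray
    species: str

    def __post_init__(self) -> None:
        if self.rgba.ndim != 3 or self.rgba.shape[2] != 4:
            raise ValueError("sprite must be an (H, W, 4) RGBA array")
        if not (self.rgba[..., 3] > 0).any():
            raise ValueError("sprite has an empty opaque region")

    @property
    def opaque_box(self) -> tuple[int, int, int, int]:
        """Tight half-open box ``(x_min, y_min, x_max, y_max)`` of alpha > 0."""
        ys, xs = np.nonzero(self.rgba[..., 3])
        return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


@dataclass
class PlacementSample:
    """One randomized paste decision."""

    center: tuple[float, float]  # (x, y) in frame pixels
    area_fraction: float
    light_factor: float
    rotation_deg: float = 0.0
    flip: bool = False
    shear: float = 0.0

    def mirrored(self, frame_width: int) -> "PlacementSample":
        """The equivalent placement in a horizontally mirrored frame."""
        return PlacementSample(
            center=(frame_width - self.center[0], self.center[1]),
            area_fraction=self.area_fraction,
            light_factor=self.light_factor,
            rotation_deg=-self.rotation_deg,
            flip=not self.flip,
            shear=-self.shear,
        )


@dataclass
class CompositorConfig:
    area_fraction_range: tuple[float, float] = (0.0004, 0.0056)
    light_range: tuple[float, float] = (0.6, 1.0)
    rotation_range: tuple[float, float] = (-15.0, 15.0)
    shear_range: tuple[float, float] = (-0.2, 0.2)
    flip_prob: float = 0.5
    max_overlap_iou: float = 0.3
    max_retries: int = 50
    gaussian_sigma: float = 2.0
    species_mix: dict = field(
        default_factory=lambda: {"great_egret": 0.5, "little_egret": 0.5}
    )


def sample_placement(
    rng: np.random.Generator,
    frame_size: tuple[int, int],
    config: CompositorConfig | None = None,
    allowed_mask: np.ndarray | None = None,
) -> PlacementSample:
    """Draw one placement from the randomization distributions.

    ``frame_size`` is ``(width, height)``.  The centre is uniform over the
    allowed-region mask (whole frame when ``allowed_mask`` is None); the
    remaining attributes are independent uniforms on the configured ranges.
    """
    config = config or CompositorConfig()
    width, height = frame_size
    if allowed_mask is not None:
        ys, xs = np.nonzero(allowed_mask)
        if len(ys) == 0:
            raise PlacementError("allowed-region mask is empty")
        k = rng.integers(len(ys))
        center = (float(xs[k]) + rng.random(), float(ys[k]) + rng.random())
    else:
        center = (rng.uniform(0, width), rng.uniform(0, height))
    return PlacementSample(
        center=center,
        area_fraction=rng.uniform(*config.area_fraction_range),
        light_factor=rng.uniform(*config.light_range),
        rotation_deg=rng.uniform(*config.rotation_range),
        flip=bool(rng.random() < config.flip_prob),
        shear=rng.uniform(*config.shear_range),
    )


def _pose_matrix(placement: PlacementSample, scale: float) -> np.ndarray:
    """Forward 2x2 map in (row, col) coordinates: rotate . shear . scale."""
    theta = np.deg2rad(placement.rotation_deg)
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    shear = np.array([[1.0, 0.0], [placement.shear, 1.0]])
    return rot @ shear @ (scale * np.eye(2))


def transform_sprite(
    sprite: Sprite,
    placement: PlacementSample,
    frame_size: tuple[int, int],
) -> np.ndarray:
    """Scale / rotate / shear / flip the sprite and apply the light factor.

    The sprite is scaled so its opaque bounding box covers
    ``area_fraction`` of the frame area, then the pose transform is applied
    about the sprite centre with bilinear interpolation (colour channels
    premultiplied by alpha during resampling to avoid fringing).

    Returns a float ``(H, W, 4)`` array with straight RGB in [0, 255] x
    light_factor and alpha in [0, 1].
    """
    width, height = frame_size
    x0, y0, x1, y1 = sprite.opaque_box
    box_area = (x1 - x0) * (y1 - y0)
    target_area = placement.area_fraction * width * height
    scale = float(np.sqrt(target_area / box_area))

    rgba = sprite.rgba.astype(np.float64)
    alpha = rgba[..., 3:4] / 255.0
    premult = np.concatenate([rgba[..., :3] * alpha, alpha], axis=2)
    if placement.flip:
        # flip before the affine so mirroring the placement mirrors the output
        premult = premult[:, ::-1]

    fwd = _pose_matrix(placement, scale)
    h, w = premult.shape[:2]
    in_center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    corners = np.array([[0, 0], [0, w - 1], [h - 1, 0], [h - 1, w - 1]], float)
    mapped = (fwd @ (corners - in_center).T).T
    lo, hi = mapped.min(axis=0), mapped.max(axis=0)
    out_h = int(np.ceil(hi[0] - lo[0])) + 1
    out_w = int(np.ceil(hi[1] - lo[1])) + 1
    out_center = np.array([(out_h - 1) / 2.0, (out_w - 1) / 2.0])

    inv = np.linalg.inv(fwd)
    offset = in_center - inv @ out_center
    out = np.empty((out_h, out_w, 4))
    for c in range(4):
        out[..., c] = ndimage.affine_transform(
            premult[..., c], inv, offset=offset, output_shape=(out_h, out_w),
            order=1, mode="constant", cval=0.0,
        )
    a = np.clip(out[..., 3], 0.0, 1.0)
    rgb = np.zeros_like(out[..., :3])
    nz = a > 1e-8
    rgb[nz] = out[..., :3][nz] / a[nz, None]
    rgb = np.clip(rgb * placement.light_factor, 0.0, 255.0)
    return np.concatenate([rgb, a[..., None]], axis=2)


def _paste_window(
    background: np.ndarray, rgba: np.ndarray, center: tuple[float, float]
) -> tuple[slice, slice]:
    """Integer window of the frame covered by the transformed sprite."""
    h, w = rgba.shape[:2]
    x0 = int(np.floor(center[0] - w / 2.0 + 0.5))
    y0 = int(np.floor(center[1] - h / 2.0 + 0.5))
    if x0 < 0 or y0 < 0 or x0 + w > background.shape[1] or y0 + h > background.shape[0]:
        raise PlacementError("sprite does not fit inside the frame at this placement")
    return slice(y0, y0 + h), slice(x0, x0 + w)


def _prepared(background, sprite, placement, frame_size=None):
    frame_size = frame_size or (background.shape[1], background.shape[0])
    rgba = transform_sprite(sprite, placement, frame_size)
    if min(rgba.shape[0], rgba.shape[1]) < 2:
        raise PlacementError("scaled sprite degenerates below 2 px")
    ys, xs = _paste_window(background, rgba, placement.center)
    return rgba, ys, xs


def opaque_box_in_frame(
    background: np.ndarray, sprite: Sprite, placement: PlacementSample
) -> tuple[int, int, int, int]:
    """Half-open pixel box of the pasted sprite's opaque region in the frame."""
    rgba, ys, xs = _prepared(background, sprite, placement)
    mask = rgba[..., 3] >= 0.5
    rr, cc = np.nonzero(mask)
    return (
        int(xs.start + cc.min()),
        int(ys.start + rr.min()),
        int(xs.start + cc.max()) + 1,
        int(ys.start + rr.max()) + 1,
    )


def direct_paste(
    background: np.ndarray, sprite: Sprite, placement: PlacementSample
) -> np.ndarray:
    """Hard alpha copy: opaque sprite pixels replace background pixels."""
    rgba, ys, xs = _prepared(background, sprite, placement)
    out = background.copy()
    mask = rgba[..., 3] >= 0.5
    region = out[ys, xs].astype(np.float64)
    region[mask] = rgba[..., :3][mask]
    out[ys, xs] = np.clip(np.rint(region), 0, 255).astype(np.uint8)
    return out


def gaussian_paste(
    background: np.ndarray,
    sprite: Sprite,
    placement: PlacementSample,
    sigma: float = 2.0,
) -> np.ndarray:
    """Feathered paste: blur the binary alpha mask, blend convexly.

    ``sigma = 0`` reduces exactly to :func:`direct_paste`.  Sprite colour is
    extended outside the opaque region by nearest-neighbour fill so the
    feather fades sprite colour (not black) into the background.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rgba, ys, xs = _prepared(background, sprite, placement)
    mask = (rgba[..., 3] >= 0.5).astype(np.float64)
    premult = rgba[..., :3] * mask[..., None]

    pad = int(np.ceil(3 * sigma)) + 1 if sigma > 0 else 0
    mask_p = np.pad(mask, pad)
    premult_p = np.pad(premult, ((pad, pad), (pad, pad), (0, 0)))
    if sigma > 0:
        # blur mask and premultiplied colour with the same kernel: the
        # result stays a convex combination of background and sprite colours
        mask_p = ndimage.gaussian_filter(mask_p, sigma)
        premult_p = np.stack(
            [ndimage.gaussian_filter(premult_p[..., c], sigma) for c in range(3)],
            axis=2,
        )
    a = np.clip(mask_p, 0.0, 1.0)

    y0 = max(ys.start - pad, 0)
    y1 = min(ys.stop + pad, background.shape[0])
    x0 = max(xs.start - pad, 0)
    x1 = min(xs.stop + pad, background.shape[1])
    py0 = y0 - (ys.start - pad)
    px0 = x0 - (xs.start - pad)
    a = a[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]
    premult_p = premult_p[py0 : py0 + (y1 - y0), px0 : px0 + (x1 - x0)]

    out = background.copy()
    region = out[y0:y1, x0:x1].astype(np.float64)
    blended = region * (1.0 - a[..., None]) + premult_p
    out[y0:y1, x0:x1] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    return out


def _poisson_system(mask: np.ndarray):
    """Sparse 5-point Laplacian over ``mask`` pixels with Dirichlet exterior."""
    h, w = mask.shape
    idx = -np.ones((h, w), dtype=np.int64)
    ys, xs = np.nonzero(mask)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    rows, cols, vals = [], [], []
    for k in range(n):
        rows.append(k)
        cols.append(k)
        vals.append(4.0)
    neighbours = []
    for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        ny, nx = ys + dy, xs + dx
        inside = (ny >= 0) & (ny < h) & (nx >= 0) & (nx < w)
        nidx = np.where(inside, idx[np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)], -1)
        inmask = nidx >= 0
        rows.extend(np.nonzero(inmask)[0].tolist())
        cols.extend(nidx[inmask].tolist())
        vals.extend([-1.0] * int(inmask.sum()))
        neighbours.append((ny, nx, inside, inmask))
    lap = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return lap, (ys, xs), neighbours


def poisson_blend_region(
    background: np.ndarray,
    guide: np.ndarray,
    mask: np.ndarray,
    method: str = "cg",
    tol: float = 1e-10,
) -> np.ndarray:
    """Solve the gradient-domain blend on ``mask`` and return a float image.

    Per channel solves  ``lap f = div(grad guide)``  over masked pixels with
    Dirichlet data from ``background`` on the exterior.  ``method`` selects a
    conjugate-gradient iteration (the matrix is SPD) or a sparse direct
    factorization.
    """
    if not mask.any():
        return background.astype(np.float64)
    lap, (ys, xs), neighbours = _poisson_system(mask)
    bg = background.astype(np.float64)
    gd = guide.astype(np.float64)
    out = bg.copy()
    h, w = mask.shape
    n = len(ys)
    for c in range(bg.shape[2]):
        rhs = np.zeros(n)
        for ny, nx, inside, inmask in neighbours:
            nyc, nxc = np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)
            # guidance gradients (zero across the frame edge)
            g = np.where(inside, gd[..., c][np.clip(ny, 0, h - 1), np.clip(nx, 0, w - 1)], gd[ys, xs, c])
            rhs += gd[ys, xs, c] - g
            # Dirichlet contribution from non-mask neighbours inside the frame
            dir_px = inside & ~inmask
            rhs += np.where(dir_px, bg[nyc, nxc, c], 0.0)
        if method == "cg":
            sol, info = _cg(lap, rhs, rtol=tol, atol=0.0, maxiter=20000)
            if info != 0:
                raise RuntimeError(f"Poisson CG failed to converge (info={info})")
        elif method == "direct":
            sol = spsolve(lap.tocsc(), rhs)
        else:
            raise ValueError(f"unknown solver method {method!r}")
        out[ys, xs, c] = sol
    return out


def poisson_paste(
    background: np.ndarray,
    sprite: Sprite,
    placement: PlacementSample,
    method: str = "cg",
) -> np.ndarray:
    """Gradient-domain paste with seamless boundary.

    The opaque region must lie strictly inside the frame (at least one
    pixel of background margin) so the Dirichlet boundary is well defined.
    """
    rgba, ys, xs = _prepared(background, sprite, placement)
    mask_local = rgba[..., 3] >= 0.5
    h, w = background.shape[:2]
    rr, cc = np.nonzero(mask_local)
    r0, r1 = ys.start + rr.min(), ys.start + rr.max() + 1
    c0, c1 = xs.start + cc.min(), xs.start + cc.max() + 1
    if r0 < 1 or c0 < 1 or r1 > h - 1 or c1 > w - 1:
        raise PlacementError("Poisson paste region must be strictly inside the frame")

    # solve on the opaque box padded by one background pixel; the guidance
    # is the sprite colour extended by nearest-neighbour fill so that
    # boundary-crossing gradients are sprite gradients, not sprite-vs-
    # background jumps (a constant sprite then blends to pure background)
    sub = (slice(r0 - 1, r1 + 1), slice(c0 - 1, c1 + 1))
    bg_sub = background[sub]
    lr0, lc0 = r0 - ys.start, c0 - xs.start
    mask_sub = np.zeros(bg_sub.shape[:2], dtype=bool)
    mask_sub[1:-1, 1:-1] = mask_local[lr0 : lr0 + (r1 - r0), lc0 : lc0 + (c1 - c0)]
    rgb_sub = np.zeros_like(bg_sub, dtype=np.float64)
    rgb_sub[1:-1, 1:-1] = rgba[lr0 : lr0 + (r1 - r0), lc0 : lc0 + (c1 - c0), :3]
    if (~mask_sub).any():
        _, (ir, ic) = ndimage.distance_transform_edt(~mask_sub, return_indices=True)
        guide_sub = rgb_sub[ir, ic]
    else:
        guide_sub = rgb_sub
    blended = poisson_blend_region(bg_sub, guide_sub, mask_sub, method=method)
    out = background.copy()
    out[sub] = np.clip(np.rint(blended), 0, 255).astype(np.uint8)
    return out


_PASTE_FNS = {
    "direct": direct_paste,
    "gaussian": None,  # needs sigma; handled in compose_scene
    "poisson": poisson_paste,
}

PASTE_MODES = ("direct", "gaussian", "poisson")


def _box_iou(a, b) -> float:
    ix0, iy0 = max(a[0], b[0]), max(a[1], b[1])
    ix1, iy1 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0, ix1 - ix0), max(0, iy1 - iy0)
    inter = iw * ih
    if inter == 0:
        return 0.0
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter)


def compose_scene(
    background: np.ndarray,
    sprite_pool: list[Sprite],
    n_birds: int,
    rng: np.random.Generator,
    paste_mode: str = "direct",
    config: CompositorConfig | None = None,
) -> tuple[np.ndarray, list[dict]]:
    """Paste ``n_birds`` sprites back-to-front; return image + annotations.

    Species are drawn from ``config.species_mix``; sprites may overlap up
    to IoU ``config.max_overlap_iou``, beyond which the placement is
    resampled (bounded retries).  Every annotation box lies inside the
    frame.
    """
    config = config or CompositorConfig()
    if n_birds < 0:
        raise ValueError("n_birds must be >= 0")
    by_species: dict[str, list[Sprite]] = {}
    for s in sprite_pool:
        by_species.setdefault(s.species, []).append(s)
    mix_species = [s for s in config.species_mix if s in by_species]
    if n_birds > 0 and not mix_species:
        raise ValueError("sprite pool has no species present in species_mix")
    probs = np.array([config.species_mix[s] for s in mix_species], dtype=float)
    probs = probs / probs.sum() if len(probs) else probs

    image = background.copy()
    annotations: list[dict] = []
    placed_boxes: list[tuple] = []
    for _ in range(n_birds):
        species = mix_species[rng.choice(len(mix_species), p=probs)]
        sprite = by_species[species][rng.integers(len(by_species[species]))]
        for attempt in range(config.max_retries + 1):
            placement = sample_placement(rng, (image.shape[1], image.shape[0]), config)
            try:
                box = opaque_box_in_frame(image, sprite, placement)
            except PlacementError:
                continue
            if paste_mode == "poisson" and (
                box[0] < 1 or box[1] < 1
                or box[2] >= image.shape[1] - 1 or box[3] >= image.shape[0] - 1
            ):
                continue
            if all(_box_iou(box, b) <= config.max_overlap_iou for b in placed_boxes):
                break
        else:
            raise PlacementError("could not place sprite within retry budget")
        if paste_mode == "gaussian":
            image = gaussian_paste(image, sprite, placement, sigma=config.gaussian_sigma)
        elif paste_mode == "poisson":
            image = poisson_paste(image, sprite, placement)
        else:
            image = direct_paste(image, sprite, placement)
        placed_boxes.append(box)
        annotations.append({"species": species, "bbox": box})
    return image, annotations


def generate_dataset(
    out_dir: str | Path,
    sprite_pool: list[Sprite],
    backgrounds: list[np.ndarray],
    n_images: int = 1000,
    seed: int = 0,
    paste_mode: str = "mix",
    birds_per_image: tuple[int, int] = (1, 6),
    config: CompositorConfig | None = None,
    write_images: bool = True,
) -> dict:
    """Write an ``n_images`` synthetic detection dataset with COCO annotations.

    ``paste_mode='mix'`` chooses one of the three operators uniformly per
    image.  Returns the manifest dict (also written as ``manifest.json``).
    """
    config = config or CompositorConfig()
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    images_meta, anns = [], []
    ann_id = 1
    for i in range(n_images):
        bg = backgrounds[rng.integers(len(backgrounds))]
        mode = (
            PASTE_MODES[rng.integers(3)] if paste_mode == "mix" else paste_mode
        )
        n_birds = int(rng.integers(birds_per_image[0], birds_per_image[1] + 1))
        image, ann = compose_scene(bg, sprite_pool, n_birds, rng, mode, config)
        fname = f"im_{i:05d}.png"
        if write_images:
            Image.fromarray(image).save(out_dir / "images" / fname)
        images_meta.append(
            {"id": i + 1, "file_name": fname, "width": image.shape[1],
             "height": image.shape[0]}
        )
        for a in ann:
            x0, y0, x1, y1 = a["bbox"]
            anns.append(
                {"id": ann_id, "image_id": i + 1,
                 "category_id": CATEGORY_IDS[a["species"]],
                 "bbox": [int(x0), int(y0), int(x1 - x0), int(y1 - y0)],
                 "area": int((x1 - x0) * (y1 - y0)), "iscrowd": 0}
            )
            ann_id += 1
    coco = {
        "images": images_meta,
        "annotations": anns,
        "categories": [
            {"id": v, "name": k} for k, v in CATEGORY_IDS.items()
        ],
    }
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(coco, fh)
    cfg_repr = json.dumps(asdict(config), sort_keys=True, default=str)
    manifest = {
        "n_images": n_images,
        "seed": seed,
        "paste_mode": paste_mode,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "n_annotations": len(anns),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
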