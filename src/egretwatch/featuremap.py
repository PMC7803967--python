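"""Feature-map denoising and visualization via row/null-space splitting.

A feature vector x at each grid location is split against the downstream
affine operator A: coordinates x_hat solve A A^T x_hat = A x (minimum-norm
when A A^T is singular), the row-space component is x_r = A^T x_hat and
the null-space remainder x_n = x - x_r is the part the network discards.
The row-space field is reduced to three principal components and combined
with the RGB-to-grayscale weights

    V = 0.7152 V1 + 0.2126 V2 + 0.0722 V3,

then min-max normalized and colormapped over the source image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy import ndimage
from scipy.stats import skew
from sklearn.decomposition import PCA

__all__ = [
    "FeatureStack",
    "SubspaceSplit",
    "COMBINE_WEIGHTS",
    "row_null_split",
    "pca_reduce",
    "weighted_combine",
    "overlay",
    "visualize",
]

COMBINE_WEIGHTS = (0.7152, 0.2126, 0.0722)


@dataclass
class FeatureStack:
    """An (H, W, D) grid of feature vectors plus the (M, D) operator."""

    x: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, float)
        self.A = np.asarray(self.A, float)
        if self.x.ndim != 3 or self.A.ndim != 2:
            raise ValueError("x must be (H, W, D) and A must be (M, D)")
        if self.x.shape[2] != self.A.shape[1]:
            raise ValueError("feature dimension does not match operator columns")
        if not (np.isfinite(self.x).all() and np.isfinite(self.A).all()):
            raise ValueError("non-finite entries")


@dataclass
class SubspaceSplit:
    x_hat: np.ndarray  # (H, W, M) row-space coordinates
    x_r: np.ndarray    # (H, W, D) row-space component
    x_n: np.ndarray    # (H, W, D) null-space component


def row_null_split(stack: FeatureStack) -> SubspaceSplit:
    """Split each feature vector into row- and null-space components of A."""
    A = stack.A
    h, w, d = stack.x.shape
    flat = stack.x.reshape(-1, d)
    gram = A @ A.T
    rhs = flat @ A.T  # (N, M), rows are A x
    x_hat, *_ = np.linalg.lstsq(gram, rhs.T, rcond=None)  # min-norm when singular
    x_hat = x_hat.T
    x_r = x_hat @ A
    x_n = flat - x_r
    return SubspaceSplit(
        x_hat=x_hat.reshape(h, w, -1),
        x_r=x_r.reshape(h, w, d),
        x_n=x_n.reshape(h, w, d),
    )


def pca_reduce(field: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First three principal-component score maps of an (H, W, D) field.

    Features are centred over grid locations; each component's sign is
    fixed so its score distribution has non-negative skewness, making the
    output deterministic.  Returns ``(scores (H, W, 3), explained ratios)``.
    """
    h, w, d = field.shape
    if h * w < 3 or d < 3:
        raise ValueError("need at least 3 locations and 3 feature dimensions")
    flat = field.reshape(-1, d)
    if np.linalg.matrix_rank(flat - flat.mean(axis=0)) < 3:
        raise ValueError("fewer than 3 non-degenerate feature dimensions")
    pca = PCA(n_components=3, svd_solver="full")
    scores = pca.fit_transform(flat)
    for k in range(3):
        if skew(scores[:, k]) < 0:
            scores[:, k] = -scores[:, k]
    return scores.reshape(h, w, 3), pca.explained_variance_ratio_


def weighted_combine(
    v1: np.ndarray, v2: np.ndarray, v3: np.ndarray,
    weights: tuple[float, float, float] = COMBINE_WEIGHTS,
) -> np.ndarray:
    """Pointwise luminance-weighted sum of the three component maps."""
    v1, v2, v3 = (np.asarray(v) for v in (v1, v2, v3))
    if not (v1.shape == v2.shape == v3.shape):
        raise ValueError("component maps must share a shape")
    w1, w2, w3 = weights
    return w1 * v1 + w2 * v2 + w3 * v3


def overlay(
    V: np.ndarray,
    image: np.ndarray,
    colormap: str = "viridis",
    alpha: float = 0.5,
) -> tuple[np.ndarray, bool]:
    """Min-max normalize V, upsample bilinearly, colormap and blend.

    Returns ``(rendered uint8 image, constant_flag)``; a constant V cannot
    be normalized and renders as a uniform mid-colormap wash with the flag
    set.
    """
    V = np.asarray(V, float)
    vmin, vmax = V.min(), V.max()
    constant = bool(vmax - vmin <= 0)
    norm = np.full_like(V, 0.5) if constant else (V - vmin) / (vmax - vmin)
    h, w = image.shape[:2]
    zoomed = ndimage.zoom(norm, (h / V.shape[0], w / V.shape[1]), order=1)
    zoomed = np.clip(zoomed[:h, :w], 0.0, 1.0)
    cmap = colormaps[colormap]
    heat = cmap(zoomed)[..., :3] * 255.0
    base = image.astype(float)
    if base.ndim == 2:
        base = base[..., None].repeat(3, axis=2)
    out = base + alpha * (heat - base)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8), constant


def visualize(
    stack: FeatureStack,
    image: np.ndarray,
    colormap: str = "viridis",
    alpha: float = 0.5,
) -> dict:
    """Full chain: split, PCA to three maps, weighted combine, overlay."""
    split = row_null_split(stack)
    scores, ratios = pca_reduce(split.x_r)
    V = weighted_combine(scores[..., 0], scores[..., 1], scores[..., 2])
    rendered, constant = overlay(V, image, colormap=colormap, alpha=alpha)
    return {
        "split": split,
        "scores": scores,
        "explained_variance_ratio": ratios,
        "V": V,
        "rendered": rendered,
        "constant_flag": constant,
    }
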