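"""Colour Pattern Modelling (CPM).

Categorize wing-image pixels into discrete colour classes, align specimens
to an iteratively estimated average template so that pixel positions become
homologous across individuals, encode each aligned pattern as a per-pixel
feature vector, and measure phenotypic distances in the space of the first
few principal components.

Conventions: images are row-major with 0-based pixel indices; similarity
transforms (translation + rotation + isotropic scale) act on pixel-centre
coordinates in (x, y) = (col, row) order and map the specimen frame to the
template frame. Background / out-of-mask pixels are labelled ``BACKGROUND``
(-1) and encode as all-zeros, so a wing-shape difference costs 1 (not 2)
per pixel in squared binary distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from skimage.transform import SimilarityTransform, warp
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

BACKGROUND = -1

DEFAULT_CLASS_NAMES = ("black", "orange", "yellow", "white")

#: RGB centroids of the four wing colour classes; the synthetic renderer
#: paints with exactly these values.
DEFAULT_CENTROIDS: dict[str, tuple[float, float, float]] = {
    "black": (0.05, 0.05, 0.05),
    "orange": (0.90, 0.45, 0.05),
    "yellow": (0.95, 0.85, 0.10),
    "white": (0.95, 0.95, 0.95),
}

__all__ = [
    "BACKGROUND",
    "DEFAULT_CLASS_NAMES",
    "DEFAULT_CENTROIDS",
    "WingImage",
    "ColorMap",
    "PatternPCA",
    "DistanceSet",
    "categorize_pixels",
    "build_average_template",
    "align_to_template",
    "binary_encode",
    "fit_pattern_pca",
    "pca_distance",
    "distance_set",
]


# --------------------------------------------------------------------------
# Types
# --------------------------------------------------------------------------

@dataclass
class WingImage:
    """An RGB wing photograph (or synthetic render) with its wing mask."""

    rgb: np.ndarray          # H x W x 3, values in [0, 1]
    mask: np.ndarray         # H x W bool, True on the wing
    side: str = "fore"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be H x W x 3")
        if self.mask.shape != self.rgb.shape[:2]:
            raise ValueError("mask shape must match image")
        if not self.mask.any():
            raise ValueError("wing mask is empty")
        if not np.all(np.isfinite(self.rgb)):
            raise ValueError("rgb values must be finite")


@dataclass
class ColorMap:
    """Per-pixel colour-class labels for one wing.

    ``labels`` holds class indices into ``class_names`` with ``BACKGROUND``
    (-1) outside the wing. ``alignment_transform`` is the similarity
    transform mapping the specimen frame into the template frame; ``None``
    until the map has been aligned.
    """

    labels: np.ndarray
    class_names: tuple[str, ...] = DEFAULT_CLASS_NAMES
    alignment_transform: SimilarityTransform | None = None
    side: str = "fore"
    specimen_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.class_names = tuple(self.class_names)
        if not (3 <= len(self.class_names) <= 4):
            raise ValueError("expected 3 or 4 colour classes")
        if self.labels.max() >= len(self.class_names) or self.labels.min() < BACKGROUND:
            raise ValueError("labels out of range for class_names")
        if not (self.labels >= 0).any():
            raise ValueError("colour map has no in-mask pixels")

    @property
    def mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass
class PatternPCA:
    """A fitted pattern-space PCA.

    ``scores`` is specimen x component; distances between specimens use the
    first ``n_components_used`` score columns (all components reproduce the
    raw-space Euclidean distances exactly, since PCA is a rotation).
    """

    basis: np.ndarray                 # k x p
    scores: pd.DataFrame              # specimen x k
    variance_explained: np.ndarray    # length k, non-increasing
    encoding: str                     # "binary" | "quantum_catch"
    n_components_used: int = 8
    mean_: np.ndarray | None = None

    @property
    def specimen_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class DistanceSet:
    """The three phenotypic distances that describe one morph set.

    het_homD: heterozygote to dominant local homozygote (distance to the
    nearest peak); het_homR: heterozygote to the recessive homozygote;
    hom_hom: between the two local homozygotes (distance between peaks).
    """

    het_homD: float
    het_homR: float
    hom_hom: float
    observer: str = ""
    encoding: str = "binary"

    def __post_init__(self) -> None:
        if min(self.het_homD, self.het_homR, self.hom_hom) < 0:
            raise ValueError("distances must be non-negative")


# --------------------------------------------------------------------------
# Pixel categorization
# --------------------------------------------------------------------------

def categorize_pixels(image: WingImage,
                      centroids: dict[str, tuple[float, float, float]] | None = None,
                      ) -> ColorMap:
    """Label every in-mask pixel with the nearest colour-class centroid.

    Nearest in RGB Euclidean distance; exact ties go to the earlier class
    in the centroid ordering. Out-of-mask pixels get ``BACKGROUND``.
    """
    if centroids is None:
        centroids = DEFAULT_CENTROIDS
    names = tuple(centroids)
    if len(names) < 2:
        raise ValueError("need at least two colour-class centroids")
    cents = np.asarray([centroids[c] for c in names], dtype=float)
    if len(np.unique(cents.round(12), axis=0)) != len(names):
        raise ValueError("centroids must be pairwise distinct")
    flat = image.rgb.reshape(-1, 3)
    # squared distances to each centroid; argmin returns the first minimum,
    # which implements the class-order tie-break
    d2 = ((flat[:, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1).reshape(image.mask.shape)
    labels[~image.mask] = BACKGROUND
    return ColorMap(labels=labels, class_names=names, side=image.side,
                    specimen_id=image.specimen_id)


# --------------------------------------------------------------------------
# Similarity registration on categorical label maps
# --------------------------------------------------------------------------

def _centered_similarity(theta: float, scale: float, tx: float, ty: float,
                         center: np.ndarray) -> SimilarityTransform:
    """Similarity about the grid centre, then a translation (specimen->template)."""
    return (SimilarityTransform(translation=-center)
            + SimilarityTransform(rotation=theta, scale=scale)
            + SimilarityTransform(translation=center + np.array([tx, ty])))


def _grid_center(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    return np.array([(w - 1) / 2.0, (h - 1) / 2.0])


def _onehot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """(n_classes + 1, H, W) float one-hot, background as its own channel."""
    chans = [labels == c for c in range(n_classes)]
    chans.append(labels == BACKGROUND)
    return np.stack(chans).astype(float)


def _warp_labels(labels: np.ndarray, tform: SimilarityTransform,
                 output_shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbour resample of labels into the template frame."""
    if tform.scale <= 0:
        raise ValueError("degenerate transform: scale must be positive")
    out = warp(labels.astype(float), tform.inverse, order=0,
               output_shape=output_shape, cval=BACKGROUND, preserve_range=True)
    return np.rint(out).astype(int)


def _hard_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Class agreement over the union of the two masks (background excluded)."""
    union = (a >= 0) | (b >= 0)
    if not union.any():
        return 0.0
    return float(((a == b) & union).sum() / union.sum())


def _soft_agreement(params: np.ndarray, moving_oh: np.ndarray,
                    template_oh: np.ndarray, center: np.ndarray) -> float:
    """Smooth (interpolated) agreement objective for the optimizer.

    Samples the moving specimen's one-hot channels at template pixel
    positions pulled back through the candidate transform and correlates
    with the template's one-hot channels, background channel included so
    that drifting off the wing is penalised.
    """
    theta, log_s, tx, ty = params
    tform = _centered_similarity(theta, float(np.exp(log_s)), tx, ty, center)
    h, w = template_oh.shape[1:]
    rows, cols = np.mgrid[0:h, 0:w]
    pts = tform.inverse(np.column_stack([cols.ravel(), rows.ravel()]))
    coords = np.stack([pts[:, 1].reshape(h, w), pts[:, 0].reshape(h, w)])
    total = 0.0
    for c in range(template_oh.shape[0]):
        sampled = ndimage.map_coordinates(moving_oh[c], coords, order=1,
                                          cval=1.0 if c == template_oh.shape[0] - 1 else 0.0)
        total += float((template_oh[c] * sampled).sum())
    return total / (h * w)


def _register(moving: np.ndarray, template: np.ndarray, n_classes: int,
              init: SimilarityTransform | None = None,
              theta_starts: tuple[float, ...] = (-0.17, 0.0, 0.17),
              ) -> SimilarityTransform:
    """Estimate the similarity transform aligning ``moving`` onto ``template``.

    Maximizes in-mask class agreement: a smooth interpolated objective is
    optimized (Powell, multi-start over initial rotations); the identity
    transform is kept whenever it matches the optimum on the exact
    (hard, nearest-neighbour) agreement, which makes alignment idempotent.
    """
    center = _grid_center(template.shape)
    moving_oh = _onehot(moving, n_classes)
    template_oh = _onehot(template, n_classes)

    if init is None:
        init_t = np.zeros(2)
        init_log_s = 0.0
    else:
        init_t = np.asarray(init.translation, dtype=float)
        init_log_s = float(np.log(init.scale))

    best_params, best_val = None, -np.inf
    for th0 in theta_starts:
        x0 = np.array([th0, init_log_s, init_t[0], init_t[1]])
        res = optimize.minimize(
            lambda p: -_soft_agreement(p, moving_oh, template_oh, center),
            x0, method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 200},
        )
        if -res.fun > best_val:
            best_val, best_params = -res.fun, res.x
    theta, log_s, tx, ty = best_params
    fitted = _centered_similarity(theta, float(np.exp(log_s)), tx, ty, center)

    # prefer the identity if it is at least as good under exact agreement
    ident = SimilarityTransform()
    agree_fit = _hard_agreement(_warp_labels(moving, fitted, template.shape), template)
    agree_id = _hard_agreement(moving, template)
    return ident if agree_id >= agree_fit else fitted


def _compose(first: SimilarityTransform, then: SimilarityTransform) -> SimilarityTransform:
    out = SimilarityTransform(matrix=(first + then).params)
    return out


# --------------------------------------------------------------------------
# Average-template construction and alignment
# --------------------------------------------------------------------------

def _modal_labels(stack: np.ndarray) -> np.ndarray:
    """Per-pixel modal class over specimens; ties go to the lower label
    (background = -1 wins ties, keeping the template mask conservative)."""
    n_spec = stack.shape[0]
    h, w = stack.shape[1:]
    offset = stack + 1  # 0..C
    counts = np.zeros((h, w, offset.max() + 1), dtype=int)
    for s in range(n_spec):
        idx = offset[s]
        np.add.at(counts.reshape(-1, counts.shape[2]),
                  (np.arange(h * w), idx.ravel()), 1)
    return counts.argmax(axis=2) - 1


def _prenormalize(cmap: ColorMap, target_centroid: np.ndarray,
                  target_area: float) -> SimilarityTransform:
    """Translation/scale aligning mask centroid and area to the target.

    The translation is snapped to whole pixels and the scale to 1 when
    within 2%: sub-pixel pre-adjustments are below the label-grid
    resolution and are left to the registration refinement, which keeps
    already-aligned specimens exactly unchanged.
    """
    mask = cmap.mask
    rows, cols = np.nonzero(mask)
    centroid = np.array([cols.mean(), rows.mean()])
    scale = float(np.sqrt(target_area / mask.sum()))
    if abs(scale - 1.0) < 0.02:
        scale = 1.0
    shift = np.rint(target_centroid - centroid)
    return (SimilarityTransform(translation=-centroid)
            + SimilarityTransform(scale=scale)
            + SimilarityTransform(translation=centroid + shift))


def build_average_template(colormaps: list[ColorMap], max_iter: int = 50,
                           tol: int = 0,
                           ) -> tuple[ColorMap, list[SimilarityTransform]]:
    """Iteratively estimate the average colour-pattern template.

    Specimens are first pre-normalized (mask centroid to the grid centre,
    mask area to the median area); the template is initialized as the
    per-pixel modal class and then refined by alternating (a) similarity
    registration of every specimen to the template, maximizing in-mask
    class agreement, and (b) recomputing the modal-class template from the
    aligned maps. Stops when at most ``tol`` template pixels change, or
    after ``max_iter`` sweeps.

    Returns the template ``ColorMap`` and the composite (pre-normalization
    + registration) specimen->template transform for each input.
    """
    if len(colormaps) < 2:
        raise ValueError("need at least two colour maps to build a template")
    sides = {c.side for c in colormaps}
    if len(sides) != 1:
        raise ValueError("all colour maps must be the same wing side")
    names = colormaps[0].class_names
    if any(c.class_names != names for c in colormaps):
        raise ValueError("class_names differ between colour maps")
    shape = colormaps[0].labels.shape
    if any(c.labels.shape != shape for c in colormaps):
        raise ValueError("colour maps must share a pixel grid")

    center = _grid_center(shape)
    target_area = float(np.median([c.mask.sum() for c in colormaps]))
    pre = [_prenormalize(c, center, target_area) for c in colormaps]
    normed = [_warp_labels(c.labels, t, shape) for c, t in zip(colormaps, pre)]

    common = np.logical_and.reduce([lab >= 0 for lab in normed])
    if not common.any():
        raise ValueError("specimen masks do not overlap after pre-normalization")

    template = _modal_labels(np.stack(normed))
    regs = [SimilarityTransform() for _ in normed]
    for _ in range(max_iter):
        regs = [_register(lab, template, len(names)) for lab in normed]
        aligned = [_warp_labels(lab, r, shape) for lab, r in zip(normed, regs)]
        new_template = _modal_labels(np.stack(aligned))
        changed = int((new_template != template).sum())
        template = new_template
        if changed <= tol:
            break

    transforms = [_compose(p, r) for p, r in zip(pre, regs)]
    template_map = ColorMap(labels=template, class_names=names,
                            alignment_transform=SimilarityTransform(),
                            side=colormaps[0].side, specimen_id="template")
    return template_map, transforms


def align_to_template(colormap: ColorMap, template: ColorMap) -> ColorMap:
    """Resample a specimen's labels into the template frame.

    The specimen is pre-normalized to the template's mask centroid and
    area, then registered by the agreement-maximizing similarity
    transform. Labels are resampled with nearest-neighbour interpolation,
    so the class vocabulary is untouched. Aligning an already-aligned map
    is a no-op (the identity wins ties on exact agreement).
    """
    if template.alignment_transform is None:
        raise ValueError("template is not fitted")
    shape = template.labels.shape
    trows, tcols = np.nonzero(template.mask)
    t_centroid = np.array([tcols.mean(), trows.mean()])
    pre = _prenormalize(colormap, t_centroid, float(template.mask.sum()))

    candidates: list[SimilarityTransform] = [SimilarityTransform(), pre]
    normed = _warp_labels(colormap.labels, pre, shape)
    reg = _register(normed, template.labels, colormap.n_classes)
    candidates.append(_compose(pre, reg))

    scored = [
        (_hard_agreement(_warp_labels(colormap.labels, t, shape), template.labels), -i, t)
        for i, t in enumerate(candidates)
    ]
    _, _, best = max(scored, key=lambda s: (s[0], s[1]))
    if best.scale <= 0:
        raise ValueError("degenerate transform: scale must be positive")
    return ColorMap(
        labels=_warp_labels(colormap.labels, best, shape),
        class_names=colormap.class_names,
        alignment_transform=best,
        side=colormap.side,
        specimen_id=colormap.specimen_id,
    )


# --------------------------------------------------------------------------
# Encodings and PCA
# --------------------------------------------------------------------------

def binary_encode(aligned: ColorMap) -> np.ndarray:
    """One-hot presence/absence encoding of an aligned colour map.

    Every template-frame pixel contributes one slot per colour class
    (pixel-major); background pixels are all-zero. Two maps differing by k
    single-class pixel swaps are at squared Euclidean distance 2k.
    """
    if aligned.alignment_transform is None:
        raise ValueError("colour map must be aligned to the template frame")
    labels = aligned.labels
    C = aligned.n_classes
    feat = np.zeros(labels.shape + (C,))
    in_mask = labels >= 0
    feat[in_mask, labels[in_mask]] = 1.0
    return feat.reshape(-1)


def fit_pattern_pca(features: pd.DataFrame | np.ndarray, n_components: int = 8,
                    encoding: str = "binary",
                    specimen_ids: list[str] | None = None) -> PatternPCA:
    """Mean-centred PCA of the specimen x feature matrix.

    All non-trivial components are retained internally (PCA is a rotation:
    scores over all components reproduce raw-space Euclidean distances
    exactly); ``n_components`` only sets how many are *used* for
    distances. If fewer components exist than requested, all are used and
    a warning is logged.
    """
    if isinstance(features, pd.DataFrame):
        ids = list(features.index.astype(str))
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(X.shape[0])] if specimen_ids is None \
            else list(specimen_ids)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two specimens")

    Xc = X - X.mean(axis=0)
    if not np.any(Xc):  # constant matrix: zero components, all distances 0
        scores = pd.DataFrame(np.zeros((X.shape[0], 1)), index=ids)
        return PatternPCA(basis=np.zeros((1, X.shape[1])), scores=scores,
                          variance_explained=np.zeros(1), encoding=encoding,
                          n_components_used=1, mean_=X.mean(axis=0))

    pca = PCA(n_components=min(X.shape[0] - 1, X.shape[1]), svd_solver="full")
    S = pca.fit_transform(X)
    scores = pd.DataFrame(S, index=ids)
    k_avail = S.shape[1]
    k_used = min(n_components, k_avail)
    if k_used < n_components:
        logger.warning("only %d components available; using all of them "
                       "(requested %d)", k_avail, n_components)
    return PatternPCA(basis=pca.components_, scores=scores,
                      variance_explained=pca.explained_variance_ratio_,
                      encoding=encoding, n_components_used=k_used,
                      mean_=pca.mean_)


def pca_distance(pca: PatternPCA, a: str, b: str,
                 n_components: int | None = None) -> float:
    """Euclidean distance between two specimens on the leading PC scores."""
    k = pca.n_components_used if n_components is None else n_components
    if k > pca.scores.shape[1]:
        raise ValueError("requested more components than are available")
    for s in (a, b):
        if s not in pca.scores.index:
            raise KeyError(f"unknown specimen id {s!r}")
    diff = pca.scores.loc[a].to_numpy()[:k] - pca.scores.loc[b].to_numpy()[:k]
    return float(np.linalg.norm(diff))


def distance_set(pca: PatternPCA, het: str, hom_dom: str, hom_rec: str,
                 observer: str = "") -> DistanceSet:
    """The het-homD / het-homR / hom-hom distance triple for one morph set."""
    return DistanceSet(
        het_homD=pca_distance(pca, het, hom_dom),
        het_homR=pca_distance(pca, het, hom_rec),
        hom_hom=pca_distance(pca, hom_dom, hom_rec),
        observer=observer,
        encoding=pca.encoding,
    )
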