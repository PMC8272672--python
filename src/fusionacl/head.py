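"""Feature head: batch normalization, pooling, projection, handcrafted features.

The fused pyramid's finest map passes through batch normalization, ReLU,
adaptive max pooling and an affine projection to produce the deep feature
vector o (default length 1026).  Alongside it, 32 handcrafted "traditional"
features c — intensity histogram statistics, gradient statistics, grey-level
co-occurrence texture summaries and dark-structure shape features — describe
the slice the way a classical radiomics pipeline would.  The two vectors
are later concatenated into the multimodal sample m = (c, o).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import label as cc_label

from .errors import ConfigurationError, SizeError
from .backbone import FeatureMap
from .phantom import LabeledImage

#: default length of the deep feature vector
DEEP_DIM = 1026


# ---------------------------------------------------------------------------
# Batch normalization
# ---------------------------------------------------------------------------

@dataclass
class BNParams:
    """Per-feature scale/shift plus running statistics.

    In train mode the batch mean and biased variance standardize the batch
    and update the running estimates; in eval mode the running estimates are
    used, so single samples normalize consistently at test time.
    """

    scale: np.ndarray
    shift: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1
    running_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    running_var: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, float)
        self.shift = np.asarray(self.shift, float)
        if self.eps <= 0:
            raise ConfigurationError("BN epsilon must be > 0")
        n = self.scale.shape[0]
        if self.running_mean is None:
            self.running_mean = np.zeros(n)
        if self.running_var is None:
            self.running_var = np.ones(n)

    @classmethod
    def identity(cls, n_features: int) -> "BNParams":
        return cls(scale=np.ones(n_features), shift=np.zeros(n_features))


def batch_normalize(x: np.ndarray, params: BNParams, mode: str = "train") -> np.ndarray:
    """Normalize a batch per feature: scale*(x-mean)/sqrt(var+eps)+shift.

    ``x`` is (N, F) or (N, C, H, W); for 4-D input the channel is the
    feature and statistics pool over batch and spatial axes.
    """
    x = np.asarray(x, float)
    if mode not in ("train", "eval"):
        raise ConfigurationError(f"BN mode must be 'train' or 'eval', got {mode!r}")
    if x.ndim == 2:
        axes, shape = (0,), (1, -1)
    elif x.ndim == 4:
        axes, shape = (0, 2, 3), (1, -1, 1, 1)
    else:
        raise ConfigurationError("batch_normalize expects (N,F) or (N,C,H,W)")
    if mode == "train":
        if x.shape[0] < 1:
            raise ConfigurationError("train-mode BN needs batch size >= 1")
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)  # biased
        m = params.momentum
        params.running_mean = (1 - m) * params.running_mean + m * mean
        params.running_var = (1 - m) * params.running_var + m * var
    else:
        mean, var = params.running_mean, params.running_var
    mean_b = mean.reshape(shape)
    var_b = var.reshape(shape)
    return (params.scale.reshape(shape) * (x - mean_b)
            / np.sqrt(var_b + params.eps) + params.shift.reshape(shape))


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(x, 0.0)


# ---------------------------------------------------------------------------
# Adaptive max pooling
# ---------------------------------------------------------------------------

def adaptive_pool_geometry(in_size: int, out_size: int) -> tuple[int, int]:
    """stride = floor(In/Out); kernel = In - (Out-1)*stride; padding 0."""
    if out_size < 1:
        raise SizeError("out_size must be >= 1")
    if out_size > in_size:
        raise SizeError(f"out_size {out_size} exceeds input side {in_size}")
    stride = in_size // out_size
    kernel = in_size - (out_size - 1) * stride
    return stride, kernel


def adaptive_max_pool(fmap, out_size: int):
    """Max pool to an exact output side determined by the input side."""
    is_fm = isinstance(fmap, FeatureMap)
    x = fmap.values if is_fm else np.asarray(fmap, float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None]
    h, w = x.shape[-2:]
    sh, kh = adaptive_pool_geometry(h, out_size)
    sw, kw = adaptive_pool_geometry(w, out_size)
    out = np.empty((x.shape[0], out_size, out_size), dtype=x.dtype)
    for i in range(out_size):
        for j in range(out_size):
            win = x[:, i * sh: i * sh + kh, j * sw: j * sw + kw]
            out[:, i, j] = win.max(axis=(1, 2))
    if squeeze:
        out = out[0]
    return FeatureMap(out, fmap.block_index) if is_fm else out


# ---------------------------------------------------------------------------
# Projection to the deep feature vector
# ---------------------------------------------------------------------------

@dataclass
class ProjectionParams:
    weight: np.ndarray  # (out_dim, in_dim)
    bias: np.ndarray  # (out_dim,)

    @property
    def out_dim(self) -> int:
        return self.weight.shape[0]


def init_projection(in_dim: int, out_dim: int = DEEP_DIM, seed: int = 0) -> ProjectionParams:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    w = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
    return ProjectionParams(weight=w, bias=np.zeros(out_dim))


def project_deep_features(pooled, params: ProjectionParams) -> np.ndarray:
    """Affine map of the flattened pooled map to the deep vector, then ReLU."""
    x = pooled.values if isinstance(pooled, FeatureMap) else np.asarray(pooled, float)
    flat = x.reshape(-1)
    if flat.shape[0] != params.weight.shape[1]:
        raise ConfigurationError(
            f"projection expects input of length {params.weight.shape[1]}, "
            f"got {flat.shape[0]}"
        )
    return relu(params.weight @ flat + params.bias)


# ---------------------------------------------------------------------------
# Traditional (handcrafted) features
# ---------------------------------------------------------------------------

TRADITIONAL_FEATURE_NAMES: tuple[str, ...] = (
    # intensity histogram statistics
    "intensity_mean", "intensity_std", "intensity_skewness", "intensity_kurtosis",
    "intensity_min", "intensity_max", "intensity_median", "intensity_p10",
    "intensity_p90", "intensity_iqr", "intensity_entropy", "intensity_uniformity",
    # gradient statistics (central differences)
    "grad_mag_mean", "grad_mag_std", "grad_mag_max", "grad_mag_p90",
    "grad_row_abs_mean", "grad_col_abs_mean",
    # grey-level co-occurrence texture (32 levels; distances 1 and 3,
    # averaged over 0 and 90 degree offsets)
    "glcm_contrast_d1", "glcm_dissimilarity_d1", "glcm_homogeneity_d1",
    "glcm_energy_d1", "glcm_correlation_d1", "glcm_contrast_d3",
    # low-signal structure shape, computed on a Gaussian-denoised copy:
    # connectivity of the dark (ligament-like) structures is the classic
    # radiological sign of a tear
    "dark_area_fraction", "dark_component_count", "dark_largest_fraction",
    "dark_second_fraction", "dark_largest_eccentricity", "dark_min_intensity",
    "smoothed_p95", "smoothed_p99",
)

#: features unchanged by adding a constant to all pixels (within [0,1]);
#: the dark-structure mask uses a quantile-midpoint threshold, so it shifts
#: with the image and its shape features are offset invariant
OFFSET_INVARIANT_FEATURES: frozenset[str] = frozenset({
    "intensity_std", "intensity_skewness", "intensity_kurtosis", "intensity_iqr",
    "grad_mag_mean", "grad_mag_std", "grad_mag_max", "grad_mag_p90",
    "grad_row_abs_mean", "grad_col_abs_mean",
    "dark_area_fraction", "dark_component_count", "dark_largest_fraction",
    "dark_second_fraction", "dark_largest_eccentricity",
})


@dataclass
class TraditionalFeatureVector:
    values: np.ndarray
    names: tuple[str, ...] = TRADITIONAL_FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _entropy_uniformity(pix: np.ndarray, bins: int = 64) -> tuple[float, float]:
    hist, _ = np.histogram(pix, bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum()), float((p ** 2).sum())


def _glcm_features(pix: np.ndarray) -> list[float]:
    levels = 32
    q = np.clip((pix * levels).astype(np.uint8), 0, levels - 1)
    constant = q.min() == q.max()
    glcm = graycomatrix(q, distances=[1, 3], angles=[0.0, np.pi / 2],
                        levels=levels, symmetric=True, normed=True)
    def prop(name, d):  # averaged over the two offsets
        if name == "correlation" and constant:
            return 0.0  # undefined for a single grey level
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = graycoprops(glcm, name)[d]
        return float(np.nan_to_num(vals, nan=0.0).mean())
    return [prop("contrast", 0), prop("dissimilarity", 0), prop("homogeneity", 0),
            prop("energy", 0), prop("correlation", 0), prop("contrast", 1)]


def _dark_structure_features(pix: np.ndarray) -> list[float]:
    """Shape of the low-signal (ligament/meniscus-like) structures.

    The image is Gaussian-denoised; the dark mask takes pixels below the
    midpoint of the 5th and 60th intensity percentiles.  A torn ligament
    breaks the largest dark component in two, so the component count rises
    and the largest-component area drops.
    """
    from scipy import ndimage
    from skimage.measure import regionprops

    sm = ndimage.gaussian_filter(pix, 1.5)
    thr = 0.5 * (np.percentile(sm, 5) + np.percentile(sm, 60))
    dark = sm < thr
    p95 = float(np.percentile(sm, 95))
    p99 = float(np.percentile(sm, 99))
    if not dark.any():
        return [0.0, 0.0, 0.0, 0.0, 0.0, float(sm.min()), p95, p99]
    lab = cc_label(dark)
    sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1]
    min_size = max(1, int(0.005 * pix.size))
    n_components = float((sizes >= min_size).sum())
    largest = float(sizes[0] / pix.size)
    second = float(sizes[1] / pix.size) if len(sizes) > 1 else 0.0
    ecc = 0.0
    props = regionprops((lab == (np.argmax(np.bincount(lab.ravel())[1:]) + 1)).astype(int))
    if props:
        ecc = float(props[0].eccentricity)
    return [float(dark.mean()), n_components, largest, second, ecc,
            float(sm.min()), p95, p99]


def extract_traditional_features(image) -> TraditionalFeatureVector:
    """Compute the 32 handcrafted features, in the documented fixed order.

    Degenerate (constant) images follow the convention that undefined
    statistics — skewness, kurtosis, entropy, co-occurrence correlation,
    dark-structure shape — are reported as 0.
    """
    pix = image.pixels if isinstance(image, LabeledImage) else np.asarray(image, float)
    if pix.ndim != 2:
        raise ConfigurationError("traditional features expect a 2-D image")
    flat = pix.ravel()
    constant = flat.std() <= 1e-12  # tolerate float roundoff on flat images
    skew = 0.0 if constant else float(sps.skew(flat))
    kurt = 0.0 if constant else float(sps.kurtosis(flat))
    entropy, uniformity = _entropy_uniformity(flat)
    if constant:
        entropy = 0.0
    gr = np.gradient(pix)
    gmag = np.hypot(gr[0], gr[1]).ravel()
    values = np.array([
        flat.mean(), flat.std(), skew, kurt,
        flat.min(), flat.max(), np.median(flat), np.percentile(flat, 10),
        np.percentile(flat, 90),
        np.percentile(flat, 75) - np.percentile(flat, 25),
        entropy, uniformity,
        gmag.mean(), gmag.std(), gmag.max(), np.percentile(gmag, 90),
        np.abs(gr[0]).mean(), np.abs(gr[1]).mean(),
        *_glcm_features(pix),
        *_dark_structure_features(pix),
    ], dtype=float)
    values = np.nan_to_num(values, nan=0.0, posinf=0.0, neginf=0.0)
    return TraditionalFeatureVector(values=values)
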