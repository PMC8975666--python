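"""CT-like image preprocessing, feature extraction, segmentation, measurement.

The chain mirrors a classical lesion-measurement workflow: adaptive Wiener
denoising, fuzzy-set contrast intensification, gray-level co-occurrence
texture features, differential box-counting (DBC) fractal dimension, a
from-scratch backpropagation pixel classifier that separates target from
non-target pixels, largest-connected-component masking, and finally the
longest in-plane diameter (mm) and voxel-count volume (cm³) of the lesion.

Images are float arrays on the 8-bit range [0, 255]; stacks are
(slices, rows, cols).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .synthetic import LesionMeasurement

logger = logging.getLogger(__name__)

__all__ = [
    "wiener_denoise",
    "fuzzy_enhance",
    "glcm",
    "CooccurrenceMatrix",
    "TextureFeatures",
    "texture_features",
    "BoxCountEstimate",
    "fractal_dimension_dbc",
    "PixelClassifier",
    "train_pixel_classifier",
    "pixel_features",
    "segment",
    "measure_lesion",
    "volume_change",
    "tumor_reduction_from_lung",
]

GRAY_LEVELS = 256


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.min() < -1e-9 or img.max() > 255 + 1e-9:
        raise ValueError("pixel values must lie in [0, 255]")
    return img


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def wiener_denoise(img: np.ndarray, window: int = 5) -> np.ndarray:
    """Adaptive local-statistics Wiener filter.

    Per pixel: out = m + max(0, v − v_n) / max(v, v_n) · (x − m), where m, v
    are the local mean and variance in the window and the noise variance
    v_n is estimated as the mean of all local variances.  Uniform-variance
    regions shrink fully toward the local mean.  Stacks are filtered slice
    by slice.
    """
    img = _check_image(img)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and ≥ 3")
    if img.ndim == 3:
        return np.stack([wiener_denoise(s, window) for s in img])
    if window > min(img.shape):
        raise ValueError("window larger than image")
    mean = ndimage.uniform_filter(img, window)
    sq_mean = ndimage.uniform_filter(img * img, window)
    var = np.maximum(sq_mean - mean * mean, 0.0)
    noise = var.mean()
    denom = np.maximum(np.maximum(var, noise), 1e-12)
    out = mean + np.maximum(var - noise, 0.0) / denom * (img - mean)
    return np.clip(out, 0.0, 255.0)


def fuzzy_enhance(img: np.ndarray, crossover: float = 127.5,
                  iterations: int = 1) -> np.ndarray:
    """Fuzzy-set contrast intensification.

    Pixels map to memberships μ = v/255 and the intensification operator
    pushes μ away from the crossover membership μ_c = crossover/255:
    μ ← μ_c·(μ/μ_c)² for μ ≤ μ_c, else 1 − (1−μ_c)·((1−μ)/(1−μ_c))².
    0, 255 and the crossover itself are fixed points.
    """
    img = _check_image(img)
    if not 0 < crossover < 255:
        raise ValueError("crossover must be inside (0, 255)")
    uc = crossover / 255.0
    u = img / 255.0
    for _ in range(iterations):
        low = u <= uc
        u = np.where(low, (u * u) / uc, 1.0 - (1.0 - u) ** 2 / (1.0 - uc))
    return np.clip(u * 255.0, 0.0, 255.0)


# ---------------------------------------------------------------------------
# texture (gray-level co-occurrence)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetrized, normalized joint frequency of level pairs at one offset."""

    p: np.ndarray
    levels: int
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        if abs(self.p.sum() - 1.0) > 1e-9 or (self.p < 0).any():
            raise ValueError("co-occurrence matrix must be a distribution")


def glcm(img: np.ndarray, offset: tuple[int, int] = (0, 1),
         levels: int = 8) -> CooccurrenceMatrix:
    """Gray-level co-occurrence matrix.

    The image is re-quantized to ``levels`` equal-width bins of [0, 256);
    pairs at the given (Δrow, Δcol) offset are counted in both directions
    and normalized to sum to one.
    """
    img = _check_image(img)
    if img.ndim != 2:
        raise ValueError("glcm expects a single 2-D slice")
    if levels < 2:
        raise ValueError("levels must be ≥ 2")
    dr, dc = offset
    h, w = img.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise ValueError("offset beyond image extent")
    q = np.minimum((img * levels / GRAY_LEVELS).astype(int), levels - 1)
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels)
    counts = counts.reshape(levels, levels).astype(float)
    counts = counts + counts.T  # symmetrize: count both directions
    return CooccurrenceMatrix(counts / counts.sum(), levels, (dr, dc))


@dataclass(frozen=True)
class TextureFeatures:
    """Inertia/contrast, mean and entropy of a co-occurrence matrix."""

    inertia: float
    mean: float
    entropy: float
    form: str = "standard"


def texture_features(m: CooccurrenceMatrix, form: str = "standard") -> TextureFeatures:
    """Texture summary in one of two algebraic forms.

    ``standard``: contrast ΣΣ (i−j)²·p, mean ΣΣ i·p, entropy −ΣΣ p·log₂ p
    (bits).  ``printed`` keeps the alternative typeset forms
    ΣΣ (i−j)·p², ΣΣ p/(M·N) and ΣΣ (i−j)·p·log₁₀ p with 0·log 0 = 0; they
    are retained for fidelity but are degenerate on symmetric matrices,
    which is why ``standard`` is the default.
    """
    p = m.p
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("matrix must be normalized")
    i, j = np.meshgrid(np.arange(m.levels), np.arange(m.levels), indexing="ij")
    nz = p > 0
    if form == "standard":
        inertia = float((((i - j) ** 2) * p).sum())
        mean = float((i * p).sum())
        entropy = float(-(p[nz] * np.log2(p[nz])).sum())
    elif form == "printed":
        inertia = float(((i - j) * p ** 2).sum())
        mean = float(p.sum() / (m.levels * m.levels))
        ent = np.zeros_like(p)
        ent[nz] = p[nz] * np.log10(p[nz])
        entropy = float(((i - j) * ent).sum())
    else:
        raise ValueError("form must be 'standard' or 'printed'")
    return TextureFeatures(inertia, mean, entropy, form)


# ---------------------------------------------------------------------------
# fractal (differential box counting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxCountEstimate:
    """Per-scale box counts and the fitted fractal dimension."""

    scales: tuple[tuple[int, float, int], ...]  # (block size s, ratio r, N_r)
    fd: float
    residual: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.fd):
            raise ValueError("fractal dimension must be finite")


def fractal_dimension_dbc(img: np.ndarray, block_sizes=(4, 8, 16)) -> BoxCountEstimate:
    """Differential box-counting fractal dimension of a gray-level surface.

    The N×N image is partitioned into s×s blocks (2 < s < N/2); the gray
    axis is cut into boxes of height h = s·G/N with G = 256 levels; a block
    whose min and max gray values fall in boxes k and l needs
    n_r = l − k + 1 boxes, N_r = Σ n_r, scale ratio r = s/N.  FD is the
    least-squares slope of log N_r against log(1/r) across the scales.
    Block sizes that do not divide N drop the trailing partial blocks.
    """
    img = _check_image(img)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("DBC expects a square 2-D image")
    n = img.shape[0]
    entries = []
    for s in block_sizes:
        if not 2 < s < n / 2:
            logger.warning("block size %d outside (2, N/2); skipped", s)
            continue
        nb = n // s
        if nb * s != n:
            logger.warning("block size %d does not divide N=%d; "
                           "trailing partial blocks dropped", s, n)
        crop = img[:nb * s, :nb * s]
        blocks = crop.reshape(nb, s, nb, s)
        gmin = blocks.min(axis=(1, 3))
        gmax = blocks.max(axis=(1, 3))
        h = s * GRAY_LEVELS / n
        k = np.floor(gmin / h)
        l = np.floor(gmax / h)
        n_r = (l - k + 1).sum()
        entries.append((int(s), s / n, int(n_r)))
    if len(entries) < 2:
        raise ValueError("need at least 2 valid scales")
    x = np.log([1.0 / r for _, r, _ in entries])
    y = np.log([nr for _, _, nr in entries])
    slope, intercept = np.polyfit(x, y, 1)
    residual = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return BoxCountEstimate(tuple(entries), float(slope), residual)


# ---------------------------------------------------------------------------
# backpropagation pixel classifier
# ---------------------------------------------------------------------------

def _sigmoid(h: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-h))


@dataclass
class PixelClassifier:
    """Single-hidden-layer sigmoid network trained by online backprop.

    Layer weights carry an extra column for a constant-one bias input.
    The hidden-layer size must lie between the rounded mean of the input
    and output widths and the overfitting bound N_s / (α·(N_i + N_o)) with
    α in [2, 10] (default 5).
    """

    n_input: int
    n_hidden: int
    n_output: int
    w_hidden: np.ndarray        # (n_hidden, n_input + 1)
    w_output: np.ndarray        # (n_output, n_hidden + 1)
    learning_rate: float
    n_samples: int
    alpha: float = 5.0
    loss_curve: list[float] = field(default_factory=list)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(x)
        xb = np.hstack([x, np.ones((x.shape[0], 1))])
        hid = _sigmoid(xb @ self.w_hidden.T)
        hb = np.hstack([hid, np.ones((hid.shape[0], 1))])
        out = _sigmoid(hb @ self.w_output.T)
        return hid, out

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[1][:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        return (self.predict_proba(x) >= 0.5).astype(int)


def _hidden_bounds(n_input: int, n_output: int, n_samples: int,
                   alpha: float) -> tuple[int, int]:
    lower = int(round((n_input + n_output) / 2))
    upper = int(n_samples / (alpha * (n_input + n_output)))
    return lower, upper


def loss_and_gradients(clf: PixelClassifier, x: np.ndarray, t: float
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """Squared error E = ½ Σ (V − T)² and its analytic weight gradients
    for a single sample (used by the update step and by gradient checks)."""
    x = np.asarray(x, dtype=float).ravel()
    xb = np.append(x, 1.0)
    hid = _sigmoid(clf.w_hidden @ xb)
    hb = np.append(hid, 1.0)
    out = _sigmoid(clf.w_output @ hb)
    err = out - t
    loss = 0.5 * float((err ** 2).sum())
    d_out = err * out * (1.0 - out)                      # output deltas
    g_out = np.outer(d_out, hb)
    d_hid = hid * (1.0 - hid) * (clf.w_output[:, :-1].T @ d_out)
    g_hid = np.outer(d_hid, xb)
    return loss, g_hid, g_out


def train_pixel_classifier(features: np.ndarray, labels: np.ndarray,
                           layout: tuple[int, int, int] | None = None,
                           learning_rate: float = 0.5, epochs: int = 200,
                           seed: int = 0, alpha: float = 5.0) -> PixelClassifier:
    """Train the pixel classifier by per-sample gradient descent.

    Samples are visited in a seeded shuffled order each epoch; each visit
    applies W ← W − ε·∂E/∂W with the sigmoid squared-error gradients.  The
    epoch-mean loss is recorded in ``loss_curve``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float).ravel()
    if features.ndim != 2 or len(features) != len(labels):
        raise ValueError("features must be (n_samples, n_features) matching labels")
    if not 0 <= learning_rate < 1.0 + 1e-12:
        raise ValueError("learning rate must lie in [0, 1]")
    n_samples, n_input = features.shape
    n_output = 1
    if layout is None:
        lower, upper = _hidden_bounds(n_input, n_output, n_samples, alpha)
        n_hidden = max(lower, min(8, upper)) if upper >= lower else lower
        layout = (n_input, n_hidden, n_output)
    n_input_l, n_hidden, n_output = layout
    if n_input_l != n_input:
        raise ValueError("layout input width does not match features")
    lower, upper = _hidden_bounds(n_input, n_output, n_samples, alpha)
    if not lower <= n_hidden <= max(lower, upper):
        raise ValueError(
            f"hidden width {n_hidden} violates the overfitting bound: must lie "
            f"in [{lower}, {max(lower, upper)}] = [mean(N_i,N_o), N_s/(α(N_i+N_o))]")
    rng = np.random.default_rng(seed)
    clf = PixelClassifier(
        n_input, n_hidden, n_output,
        w_hidden=rng.uniform(-0.5, 0.5, size=(n_hidden, n_input + 1)),
        w_output=rng.uniform(-0.5, 0.5, size=(n_output, n_hidden + 1)),
        learning_rate=learning_rate, n_samples=n_samples, alpha=alpha)
    for _ in range(epochs):
        order = rng.permutation(n_samples)
        total = 0.0
        for idx in order:
            loss, g_hid, g_out = loss_and_gradients(clf, features[idx], labels[idx])
            clf.w_hidden -= learning_rate * g_hid
            clf.w_output -= learning_rate * g_out
            total += loss
        clf.loss_curve.append(total / n_samples)
    return clf


# ---------------------------------------------------------------------------
# per-pixel feature channels and segmentation
# ---------------------------------------------------------------------------

def pixel_features(img: np.ndarray, radius: int = 2) -> np.ndarray:
    """Per-pixel feature channels on a single slice, all scaled to ~[0, 1]:
    normalized intensity, local mean, local standard deviation, a local
    entropy texture channel and a local gray-span roughness channel (the
    per-neighborhood ingredient of the box-counting dimension)."""
    img = _check_image(img)
    if img.ndim != 2:
        raise ValueError("pixel_features expects a 2-D slice")
    size = 2 * radius + 1
    mean = ndimage.uniform_filter(img, size)
    sq = ndimage.uniform_filter(img * img, size)
    std = np.sqrt(np.maximum(sq - mean * mean, 0.0))
    # local two-bin entropy of the neighborhood around the global mean
    above = (img > img.mean()).astype(float)
    frac = ndimage.uniform_filter(above, size)
    eps = 1e-12
    entropy = -(frac * np.log2(frac + eps) + (1 - frac) * np.log2(1 - frac + eps))
    span = (ndimage.maximum_filter(img, size) - ndimage.minimum_filter(img, size))
    return np.stack([img / 255.0, mean / 255.0, std / 128.0,
                     entropy, span / 255.0], axis=-1)


def segment(img: np.ndarray, classifier: PixelClassifier,
            radius: int = 2) -> np.ndarray:
    """Classify every pixel and keep the largest connected target component.

    2-D images use 8-connectivity, stacks 26-connectivity.  If no pixel is
    classified as target an empty mask is returned with a warning.
    """
    img = _check_image(img)
    slices = img[None] if img.ndim == 2 else img
    pred = np.zeros(slices.shape, dtype=bool)
    for i, sl in enumerate(slices):
        feats = pixel_features(sl, radius=radius).reshape(-1, classifier.n_input)
        pred[i] = (classifier.predict_proba(feats) >= 0.5).reshape(sl.shape)
    if img.ndim == 2:
        pred = pred[0]
    if not pred.any():
        logger.warning("no pixel classified as target; empty mask")
        return pred
    structure = np.ones((3,) * pred.ndim, dtype=int)
    labels, n = ndimage.label(pred, structure=structure)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep


def measure_lesion(mask: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LesionMeasurement:
    """Longest in-plane diameter and voxel-count volume of a lesion mask.

    The diameter is the maximum pairwise distance between boundary-pixel
    centers within the single slice that maximizes it, in mm; the volume is
    voxel count × voxel volume in cm³.  An empty mask and a single-voxel
    mask are flagged as degenerate.
    """
    mask = np.asarray(mask, dtype=bool)
    stack = mask[None] if mask.ndim == 2 else mask
    sz, sy, sx = spacing if len(spacing) == 3 else (1.0, *spacing)
    voxel_mm3 = sz * sy * sx
    count = int(stack.sum())
    if count == 0:
        logger.warning("empty mask: zero measurement")
        return LesionMeasurement(0.0, 0.0, degenerate=True)
    best = 0.0
    for sl in stack:
        if not sl.any():
            continue
        boundary = sl & ~ndimage.binary_erosion(sl)
        rr, cc = np.nonzero(boundary)
        pts = np.column_stack([rr * sy, cc * sx])
        if len(pts) == 1:
            continue
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
        best = max(best, float(np.sqrt(d2.max())))
    return LesionMeasurement(best, count * voxel_mm3 / 1000.0,
                             degenerate=(count == 1))


# ---------------------------------------------------------------------------
# volume arithmetic
# ---------------------------------------------------------------------------

def volume_change(pre_cm3: float, post_cm3: float) -> float:
    """Tumor volume reduction pre − post, reported to 0.1 cm³."""
    if pre_cm3 < 0 or post_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    return round(pre_cm3 - post_cm3, 1)


def tumor_reduction_from_lung(pre_lung_cm3: float, post_lung_cm3: float) -> float:
    """Tumor reduction inferred from aerated-lung volume gain: post − pre of
    the normal-lung volume equals the tumor volume lost, to 0.1 cm³."""
    if pre_lung_cm3 < 0 or post_lung_cm3 < 0:
        raise ValueError("volumes must be non-negative")
    return round(post_lung_cm3 - pre_lung_cm3, 1)
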