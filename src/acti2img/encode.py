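"""Time-series to image encoders: Markov Transition Field, Gramian
Angular Fields and Recurrence Plots, plus blur pooling and resizing.

MTF is the primary encoder.  A series is discretized into ``Q`` quantile
bins, first-order transitions between consecutive bins are counted and
row-normalized into a transition matrix ``W``, and the field is the n x n
image ``M[i, j] = W[bin(x_i), bin(x_j)]`` - each pixel holds the one-step
transition probability associated with the quantile levels at time stamps
``i`` and ``j``, so the image spreads the Markov statistics back out along
the time axis (the main diagonal carries self-transition probabilities).

Two transition-count orientations are supported, selected by
``orientation``:

* ``"destination"`` (default): ``w[i, j]`` is the normalized frequency
  with which a point in bin ``j`` is *followed* by a point in bin ``i``
  (rows indexed by the destination bin).
* ``"source"``: ``w[i, j]`` is the probability of moving *from* bin ``i``
  *to* bin ``j`` (rows indexed by the source bin; the convention most MTF
  implementations, e.g. pyts, use).

Either way each row sums to one; rows with no observed outgoing/incoming
transitions are set to the uniform distribution ``1/Q``.

Large fields are shrunk by averaging non-overlapping ``m x m`` patches
with the uniform blurring kernel ``{1/m^2}`` before bilinear resizing and
min-max normalization to [0, 1].
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .segment import Segment

logger = logging.getLogger("acti2img")

ORIENTATIONS = ("destination", "source")
ENCODERS = ("mtf", "gasf", "gadf", "rp")


# ---------------------------------------------------------------------------
# quantile binning and the Markov transition model
# ---------------------------------------------------------------------------

@dataclass
class QuantileBinning:
    """Quantile-based discretization of a series into at most Q bins.

    ``edges`` are the interior cut points; intervals are right-closed, so
    a value equal to an edge belongs to the lower bin.  This tie rule
    keeps binning non-degenerate when a quantile coincides with the
    series minimum (ubiquitous in zero-heavy actigraphy: the median of a
    0/1 alternation is 0).  Duplicate or empty-bin edges caused by heavy
    ties are collapsed, so the effective number of bins can be smaller
    than requested.
    """

    q: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.float64)
        if self.q < 2:
            raise ValueError("Q must be >= 2")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def q_effective(self) -> int:
        return int(self.edges.size + 1)

    def assign(self, values: np.ndarray) -> np.ndarray:
        """Bin index in [0, q_effective-1] for every value."""
        return np.searchsorted(self.edges, np.asarray(values), side="left")


def fit_quantile_bins(values: np.ndarray, q: int) -> QuantileBinning:
    """Fit quantile bin edges at levels k/Q, k = 1..Q-1.

    A constant series (all edges tied) degenerates to a single effective
    bin; this is reported with a warning, not an error.
    """
    values = np.asarray(values, dtype=np.float64)
    if q < 2:
        raise ValueError("Q must be >= 2")
    if values.size < 2:
        raise ValueError("need at least 2 values to fit quantile bins")
    levels = np.arange(1, q) / q
    edges = np.unique(np.quantile(values, levels))
    # with right-closed intervals an edge at/above the maximum would leave
    # the top bin empty; drop such edges (constant series -> no edges left)
    edges = edges[edges < values.max()]
    if edges.size == 0:
        warnings.warn(
            "constant or near-constant series: quantile binning degenerates "
            "to a single bin",
            stacklevel=2,
        )
    if edges.size + 1 < q:
        logger.debug(
            "quantile edges collapsed: requested Q=%d, effective Q=%d",
            q,
            edges.size + 1,
        )
    return QuantileBinning(q=q, edges=edges)


@dataclass
class TransitionModel:
    """Row-stochastic Q x Q first-order transition matrix with its binning."""

    binning: QuantileBinning
    w: np.ndarray
    orientation: str = "destination"

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        q = self.w.shape[0]
        if self.w.shape != (q, q):
            raise ValueError("transition matrix must be square")
        if not np.allclose(self.w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.w.min() < -1e-12 or self.w.max() > 1 + 1e-12:
            raise ValueError("transition probabilities must lie in [0, 1]")


def transition_matrix(
    bin_sequence: np.ndarray,
    q: int,
    orientation: str = "destination",
    binning: QuantileBinning | None = None,
) -> TransitionModel:
    """Count first-order bin transitions and row-normalize.

    ``orientation="destination"`` counts ``w[i, j] ~ #(bin j followed by
    bin i)``; ``"source"`` counts ``w[i, j] ~ #(bin i followed by bin j)``.
    Rows without observations become uniform ``1/q``.
    """
    bins = np.asarray(bin_sequence, dtype=np.int64)
    if bins.size < 2:
        raise ValueError("need at least 2 points to count transitions")
    if bins.min() < 0 or bins.max() >= q:
        raise ValueError(f"bin indices must lie in [0, {q - 1}]")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    counts = np.zeros((q, q), dtype=np.float64)
    # counts[source, destination]
    np.add.at(counts, (bins[:-1], bins[1:]), 1.0)
    if orientation == "destination":
        counts = counts.T
    totals = counts.sum(axis=1, keepdims=True)
    w = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0), 1.0 / q)
    if binning is None:
        binning = QuantileBinning(q=max(q, 2), edges=np.arange(1, q))
    return TransitionModel(binning=binning, w=w, orientation=orientation)


# ---------------------------------------------------------------------------
# encoded images
# ---------------------------------------------------------------------------

@dataclass
class EncodedImage:
    """A square real-valued image with provenance."""

    pixels: np.ndarray
    encoder: str
    source: Segment | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("image must be a square 2-D matrix")

    @property
    def size(self) -> int:
        return int(self.pixels.shape[0])


def mtf(
    segment_values: np.ndarray,
    q: int = 8,
    orientation: str = "destination",
    binning: QuantileBinning | None = None,
) -> EncodedImage:
    """Markov Transition Field of a series.

    Bins are fitted on the series itself unless a pre-fitted ``binning``
    (e.g. per-recording) is supplied.  Pixel ``(i, j)`` holds
    ``W[bin(x_i), bin(x_j)]``; all entries lie in [0, 1].
    """
    values = np.asarray(segment_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 points to encode")
    if binning is None:
        binning = fit_quantile_bins(values, q)
    bins = binning.assign(values)
    model = transition_matrix(
        bins, binning.q_effective, orientation=orientation, binning=binning
    )
    pixels = model.w[np.ix_(bins, bins)]
    return EncodedImage(
        pixels=pixels,
        encoder="mtf",
        meta={"q": q, "q_effective": binning.q_effective,
              "orientation": orientation},
    )


def blur_pool(image: EncodedImage | np.ndarray, m: int) -> EncodedImage:
    """Average non-overlapping m x m patches (uniform kernel {1/m^2}).

    Output side is ``floor(n/m)``; trailing rows/columns that do not fill a
    patch are dropped.  ``m = 1`` is the identity.
    """
    img = image.pixels if isinstance(image, EncodedImage) else np.asarray(image)
    img = np.asarray(img, dtype=np.float64)
    n = img.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"pool size m={m} exceeds image side {n}")
    k = n // m
    pooled = img[: k * m, : k * m].reshape(k, m, k, m).mean(axis=(1, 3))
    encoder = image.encoder if isinstance(image, EncodedImage) else "array"
    source = image.source if isinstance(image, EncodedImage) else None
    return EncodedImage(pixels=pooled, encoder=encoder, source=source,
                        meta={"blur_m": m})


def paa(values: np.ndarray, target_length: int) -> np.ndarray:
    """Piecewise Aggregate Approximation: reduce to block means.

    Blocks partition the index range as evenly as possible
    (``[floor(i*n/L), floor((i+1)*n/L))``), matching the exact block-mean
    reduction when ``L`` divides ``n``.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if not 1 <= target_length <= n:
        raise ValueError("target_length must be in [1, len(values)]")
    if target_length == n:
        return values.copy()
    bounds = (np.arange(target_length + 1) * n) // target_length
    return np.array(
        [values[bounds[i]: bounds[i + 1]].mean() for i in range(target_length)]
    )


def _rescale_unit_interval(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1]; a constant series maps to all zeros."""
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        warnings.warn(
            "constant series: rescaling to [-1, 1] is degenerate, mapping "
            "to 0 (angle pi/2)",
            stacklevel=3,
        )
        return np.zeros_like(values)
    return (2.0 * values - hi - lo) / (hi - lo)


def gaf(
    segment_values: np.ndarray,
    target_length: int | None = None,
    variant: str = "gasf",
) -> EncodedImage:
    """Gramian Angular Field (summation or difference variant).

    The series is PAA-reduced to ``target_length`` (default
    ``min(n, 128)``), min-max rescaled to [-1, 1] and mapped to angles
    ``phi = arccos(x)``; pixels are ``cos(phi_i + phi_j)`` (GASF) or
    ``sin(phi_i - phi_j)`` (GADF).
    """
    values = np.asarray(segment_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 points to encode")
    variant = variant.lower()
    if variant not in ("gasf", "gadf"):
        raise ValueError("variant must be 'gasf' or 'gadf'")
    if target_length is None:
        target_length = min(values.size, 128)
    reduced = paa(values, target_length)
    x = np.clip(_rescale_unit_interval(reduced), -1.0, 1.0)
    phi = np.arccos(x)
    if variant == "gasf":
        pixels = np.cos(phi[:, None] + phi[None, :])
    else:
        pixels = np.sin(phi[:, None] - phi[None, :])
    return EncodedImage(pixels=pixels, encoder=variant,
                        meta={"target_length": target_length})


def rp(
    segment_values: np.ndarray, threshold: float | None = None
) -> EncodedImage:
    """Recurrence plot: pairwise distances ``|x_i - x_j|``.

    Unthresholded (default) keeps the raw distance matrix (normalized to
    [0, 1] later in the pipeline); with a threshold ``eps`` the pixel is 1
    when ``|x_i - x_j| <= eps`` and 0 otherwise.
    """
    values = np.asarray(segment_values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 points to encode")
    dist = np.abs(values[:, None] - values[None, :])
    if threshold is None:
        pixels = dist
    else:
        if threshold < 0:
            raise ValueError("threshold must be non-negative")
        pixels = (dist <= threshold).astype(np.float64)
    return EncodedImage(pixels=pixels, encoder="rp",
                        meta={"threshold": threshold})


def normalize_resize(image: EncodedImage | np.ndarray, size: int = 64) -> EncodedImage:
    """Bilinear-resize to ``size x size`` then min-max map to [0, 1].

    A constant image maps to all zeros (with a warning): there is no
    contrast to preserve.
    """
    if size < 8:
        raise ValueError("size must be >= 8")
    img = image.pixels if isinstance(image, EncodedImage) else np.asarray(image)
    img = np.asarray(img, dtype=np.float64)
    if img.shape != (size, size):
        resized = Image.fromarray(img.astype(np.float32), mode="F").resize(
            (size, size), resample=Image.BILINEAR
        )
        img = np.asarray(resized, dtype=np.float64)
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        warnings.warn("constant image: normalized to all zeros", stacklevel=2)
        img = np.zeros_like(img)
    else:
        img = (img - lo) / (hi - lo)
    encoder = image.encoder if isinstance(image, EncodedImage) else "array"
    source = image.source if isinstance(image, EncodedImage) else None
    meta = dict(image.meta) if isinstance(image, EncodedImage) else {}
    meta["size"] = size
    return EncodedImage(pixels=img, encoder=encoder, source=source, meta=meta)


# ---------------------------------------------------------------------------
# the default segment -> model-input pipeline
# ---------------------------------------------------------------------------

def encode_segment(
    segment: Segment,
    encoder: str = "mtf",
    q: int = 8,
    orientation: str = "destination",
    size: int = 64,
    blur_threshold: int = 128,
    rp_threshold: float | None = None,
    binning: QuantileBinning | None = None,
) -> EncodedImage:
    """Encode one segment into a normalized ``size x size`` model input.

    MTF and RP fields larger than ``blur_threshold`` are first shrunk with
    the uniform blurring kernel (``m = ceil(n / blur_threshold)``); GAF
    uses PAA to at most ``blur_threshold`` points instead.  The result is
    bilinear-resized to ``size`` and min-max normalized to [0, 1].

    ``binning`` (MTF only) supplies pre-fitted quantile edges, e.g. fitted
    on the whole source recording, so that windows keep their place in the
    participant's overall intensity range instead of being re-normalized
    individually.
    """
    encoder = encoder.lower()
    if encoder not in ENCODERS:
        raise ValueError(f"encoder must be one of {ENCODERS}")
    values = segment.values
    n = values.size
    if encoder == "mtf":
        image = mtf(values, q=q, orientation=orientation, binning=binning)
    elif encoder in ("gasf", "gadf"):
        image = gaf(values, target_length=min(n, blur_threshold),
                    variant=encoder)
    else:
        image = rp(values, threshold=rp_threshold)
    if encoder in ("mtf", "rp") and image.size > blur_threshold:
        image = blur_pool(image, math.ceil(image.size / blur_threshold))
    out = normalize_resize(image, size=size)
    out.source = segment
    return out


def images_to_array(images: list[EncodedImage]) -> np.ndarray:
    """Stack images into an (N, H, W, 1) float32 batch for the classifier."""
    if not images:
        raise ValueError("no images to stack")
    batch = np.stack([img.pixels for img in images]).astype(np.float32)
    return batch[..., None]


def save_png(image: EncodedImage, path: str | Path) -> Path:
    """Persist an image in [0, 1] as 8-bit grayscale PNG (p -> round(255 p))."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    return path
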