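"""Multivariate multiscale modified-distribution entropy (MM-mDistEn).

The entropy of a multichannel time series is computed in five stages:

1. **Coarse-graining** — the series is replaced, per channel, by the means of
   non-overlapping windows of width ``s`` (the scale factor).  Scale 1 is the
   identity; trailing remainder samples are discarded.
2. **Phase-space reconstruction** — delay vectors of dimension ``m`` with lag
   ``tau`` are built jointly over all channels, giving one ``c x m`` template
   matrix per admissible start index.
3. **Distance matrix** — Euclidean distances between flattened templates,
   divided by the tolerance ``r`` and raised to the power ``n``.
4. **Empirical PDF** — a ``B``-bin equal-width histogram of the pairwise
   distances (upper triangle), normalised to probabilities.
5. **Normalised Shannon entropy** — ``-(1/log2 B) * sum(P * log2 P)``, which
   lies in [0, 1].

The tolerance ``r`` is ``r_coef`` times the pooled standard deviation of the
*original* (pre-coarse-graining) series over all channels and samples, so it
is constant across scales and channel permutations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "MultichannelSeries",
    "CoarseGrainedSeries",
    "EntropyParams",
    "TemplateSet",
    "DistanceMatrix",
    "DistanceHistogram",
    "EntropyCurve",
    "InvalidScaleError",
    "EmbeddingError",
    "DegenerateToleranceError",
    "InvalidBinCountError",
    "coarse_grain",
    "embed",
    "template_distances",
    "distance_epdf",
    "normalized_entropy",
    "mm_mdisten",
    "mm_mdisten_curve",
]


class InvalidScaleError(ValueError):
    """Scale factor incompatible with the series length."""


class EmbeddingError(ValueError):
    """Series too short for the requested embedding."""


class DegenerateToleranceError(ValueError):
    """Tolerance r <= 0 (constant input series)."""


class InvalidBinCountError(ValueError):
    """Histogram bin count below 2."""


@dataclass(frozen=True)
class MultichannelSeries:
    """A ``c x N`` real-valued signal block with an optional sampling rate.

    ``values[c, i]`` is sample ``i`` of channel ``c`` (amplitude units are the
    caller's, typically microvolts for EEG).  Channel order is bookkeeping
    only: every entropy quantity in this module is invariant under channel
    permutation.
    """

    values: np.ndarray
    sampling_rate: float | None = None
    channel_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.values, dtype=float))
        if arr.ndim != 2:
            raise ValueError(f"values must be 1-D or 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(f"need at least 1 channel and 1 sample, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("series contains non-finite values")
        if self.sampling_rate is not None and self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.channel_names is not None and len(self.channel_names) != arr.shape[0]:
            raise ValueError("channel_names length does not match channel count")
        object.__setattr__(self, "values", arr)
        if self.channel_names is not None:
            object.__setattr__(self, "channel_names", tuple(self.channel_names))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float | None:
        if self.sampling_rate is None:
            return None
        return self.n_samples / self.sampling_rate

    def pooled_std(self) -> float:
        """Population standard deviation over all channels and samples."""
        return float(np.std(self.values))


@dataclass(frozen=True)
class CoarseGrainedSeries:
    """Window means of width ``scale``; ``N_s = floor(N / scale)`` samples."""

    values: np.ndarray
    scale: int

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class EntropyParams:
    """Parameter tuple ``(m, tau, r_coef, n, B, scales)``.

    Defaults follow the reference configuration for epileptic EEG analysis:
    embedding dimension ``m=3``, delay ``tau=1``, tolerance coefficient
    ``r_coef=0.2`` (times the pooled SD), distance exponent ``n=2``,
    ``B=64`` histogram bins, and scale factors 1..15.

    ``mode`` selects the phase-space construction: ``"single"`` (default)
    computes distances directly between the ``c x m`` delay matrices;
    ``"nested"`` builds second-level matrices stacking ``m`` consecutive
    delay matrices before the distance step (with the start-index bound
    tightened so all accesses stay in range).
    """

    m: int = 3
    tau: int = 1
    r_coef: float = 0.2
    n: float = 2.0
    B: int = 64
    scales: tuple[int, ...] = tuple(range(1, 16))
    mode: str = "single"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"embedding dimension m must be >= 1, got {self.m}")
        if self.tau < 1:
            raise ValueError(f"time delay tau must be >= 1, got {self.tau}")
        if self.r_coef <= 0:
            raise ValueError(f"r_coef must be > 0, got {self.r_coef}")
        if self.n <= 0:
            raise ValueError(f"distance exponent n must be > 0, got {self.n}")
        if self.B < 2:
            raise InvalidBinCountError(f"bin count B must be >= 2, got {self.B}")
        scales = tuple(int(s) for s in self.scales)
        if len(scales) == 0 or any(s < 1 for s in scales):
            raise ValueError(f"scales must be positive integers, got {self.scales}")
        if self.mode not in ("single", "nested"):
            raise ValueError(f"mode must be 'single' or 'nested', got {self.mode!r}")
        object.__setattr__(self, "scales", scales)


@dataclass(frozen=True)
class TemplateSet:
    """Delay-embedded templates, shape ``(count, c, m_eff)``."""

    templates: np.ndarray

    @property
    def count(self) -> int:
        return self.templates.shape[0]


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise template distances: ``raw`` Euclidean, ``scaled = (raw/r)^n``."""

    raw: np.ndarray
    scaled: np.ndarray

    @property
    def count(self) -> int:
        return self.raw.shape[0]


@dataclass(frozen=True)
class DistanceHistogram:
    """Normalised ``B``-bin histogram of pairwise distances."""

    probabilities: np.ndarray
    bin_edges: np.ndarray


@dataclass(frozen=True)
class EntropyCurve:
    """Entropy value per scale factor."""

    scale_values: tuple[int, ...]
    entropy_values: np.ndarray

    def as_dict(self) -> dict[int, float]:
        return {s: float(e) for s, e in zip(self.scale_values, self.entropy_values)}


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def coarse_grain(series: MultichannelSeries, s: int) -> CoarseGrainedSeries:
    """Average non-overlapping windows of width ``s`` per channel.

    Entry ``j`` of each channel is the mean of parent samples
    ``(j-1)s+1 .. j*s`` (1-based); the ``N mod s`` trailing samples are
    discarded, giving ``N_s = floor(N/s)`` output samples.
    """
    s = int(s)
    N = series.n_samples
    if s < 1 or s > N:
        raise InvalidScaleError(f"scale s={s} invalid for series of length N={N}")
    if s == 1:
        return CoarseGrainedSeries(values=series.values.copy(), scale=1)
    n_s = N // s
    windows = series.values[:, : n_s * s].reshape(series.n_channels, n_s, s)
    return CoarseGrainedSeries(values=windows.mean(axis=2), scale=s)


def _embed_values(values: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embed ``(c, N_s)`` values into ``(count, c, m)`` templates."""
    c, n_s = values.shape
    span = (m - 1) * tau + 1
    if n_s < span:
        raise EmbeddingError(
            f"series of length {n_s} too short for embedding with m={m}, tau={tau}: "
            f"need at least {span} samples"
        )
    # windows: (c, count, span) -> stride by tau along the window axis
    windows = sliding_window_view(values, span, axis=1)[:, :, ::tau]
    return np.ascontiguousarray(windows.transpose(1, 0, 2))


def embed(series: CoarseGrainedSeries, m: int, tau: int) -> TemplateSet:
    """Joint phase-space reconstruction over all channels.

    Template ``j`` (shape ``c x m``) holds, per channel, the samples at
    indices ``j, j+tau, ..., j+(m-1)tau``; there are ``N_s - (m-1)tau``
    templates.
    """
    return TemplateSet(templates=_embed_values(series.values, m, tau))


def embed_nested(series: CoarseGrainedSeries, m: int, tau: int) -> TemplateSet:
    """Second-level reconstruction: stack ``m`` consecutive delay matrices.

    Template ``j`` concatenates the single-level templates at
    ``j, j+tau, ..., j+(m-1)tau`` along the delay axis (shape ``c x m*m``),
    with the start-index bound tightened so every access is in range.
    """
    first = _embed_values(series.values, m, tau)  # (count1, c, m)
    count1 = first.shape[0]
    span = (m - 1) * tau + 1
    if count1 < span:
        raise EmbeddingError(
            f"only {count1} first-level templates: too few for nested embedding "
            f"with m={m}, tau={tau} (need at least {span})"
        )
    count2 = count1 - (m - 1) * tau
    idx = np.arange(count2)[:, None] + np.arange(m)[None, :] * tau
    nested = first[idx]  # (count2, m, c, m)
    nested = nested.transpose(0, 2, 1, 3).reshape(count2, first.shape[1], m * m)
    return TemplateSet(templates=np.ascontiguousarray(nested))


def template_distances(ts: TemplateSet, r: float, n: float) -> DistanceMatrix:
    """Euclidean distances between flattened templates, scaled by ``(d/r)^n``."""
    if ts.count < 2:
        raise EmbeddingError(f"need at least 2 templates for distances, got {ts.count}")
    if r <= 0:
        raise DegenerateToleranceError(
            f"tolerance r={r} is not positive (constant input series)"
        )
    flat = ts.templates.reshape(ts.count, -1)
    raw = squareform(pdist(flat, metric="euclidean"))
    scaled = (raw / r) ** n
    return DistanceMatrix(raw=raw, scaled=scaled)


def _histogram_probs(dists: np.ndarray, B: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width B-bin histogram over [min, max]; degenerate range -> one-hot.

    numpy's half-open bins put a value on an interior edge into the higher
    bin, and the rightmost bin is closed — the documented edge convention.
    """
    lo, hi = float(dists.min()), float(dists.max())
    if hi == lo:
        probs = np.zeros(B)
        probs[0] = 1.0
        edges = lo + np.linspace(0.0, 1.0, B + 1)
        return probs, edges
    counts, edges = np.histogram(dists, bins=B, range=(lo, hi))
    return counts / dists.size, edges


def distance_epdf(dm: DistanceMatrix, B: int) -> DistanceHistogram:
    """Empirical PDF of the scaled pairwise distances.

    Uses the upper triangle (i < j) only; ``B`` equal-width bins span the
    [min, max] of those distances.  When all distances coincide the whole
    mass goes to the first bin.
    """
    B = int(B)
    if B < 2:
        raise InvalidBinCountError(f"bin count B must be >= 2, got {B}")
    if dm.count < 2:
        raise EmbeddingError("distance matrix needs at least 2 templates")
    iu = np.triu_indices(dm.count, k=1)
    probs, edges = _histogram_probs(dm.scaled[iu], B)
    return DistanceHistogram(probabilities=probs, bin_edges=edges)


def normalized_entropy(h: DistanceHistogram) -> float:
    """Shannon entropy of the histogram, normalised by ``log2(B)`` to [0, 1].

    Empty bins contribute zero (the 0*log 0 = 0 convention).
    """
    p = np.asarray(h.probabilities, dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"histogram probabilities sum to {p.sum()}, expected 1")
    B = p.size
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(B))


# ---------------------------------------------------------------------------
# composed entropy
# ---------------------------------------------------------------------------

def _entropy_from_condensed(condensed_raw: np.ndarray, r: float, n: float, B: int) -> float:
    """Fast path: entropy from a condensed (pdist-style) raw distance vector."""
    scaled = (condensed_raw / r) ** n
    probs, _ = _histogram_probs(scaled, B)
    nz = probs[probs > 0]
    return float(-(nz * np.log2(nz)).sum() / np.log2(B))


def _templates_for(cg: CoarseGrainedSeries, params: EntropyParams) -> TemplateSet:
    if params.mode == "nested":
        return embed_nested(cg, params.m, params.tau)
    return embed(cg, params.m, params.tau)


def mm_mdisten(series: MultichannelSeries, params: EntropyParams, s: int) -> float:
    """MM-mDistEn of a multichannel series at one scale factor.

    Chains coarse-graining, joint delay embedding, pairwise template
    distances, the distance ePDF and the normalised Shannon entropy.  The
    tolerance ``r = r_coef * SD`` uses the pooled standard deviation of the
    *original* series, so it is identical across scales.  A constant series
    yields exactly 0 (all distances coincide), not an error.
    """
    sd = series.pooled_std()
    cg = coarse_grain(series, s)
    span = (params.m - 1) * params.tau
    if cg.n_samples < span + 2:
        raise EmbeddingError(
            f"scale s={s}: coarse-grained length {cg.n_samples} supports "
            f"{max(cg.n_samples - span, 0)} template(s); need >= 2 "
            f"(series length N={series.n_samples}, m={params.m}, tau={params.tau})"
        )
    if sd == 0.0:
        return 0.0  # constant series: every template pair at distance zero
    ts = _templates_for(cg, params)
    if ts.count < 2:
        raise EmbeddingError(
            f"scale s={s}: only {ts.count} template(s) in mode={params.mode!r}; need >= 2"
        )
    r = params.r_coef * sd
    flat = ts.templates.reshape(ts.count, -1)
    condensed = pdist(flat, metric="euclidean")
    return _entropy_from_condensed(condensed, r, params.n, params.B)


def mm_mdisten_curve(series: MultichannelSeries, params: EntropyParams) -> EntropyCurve:
    """Entropy at every scale in ``params.scales`` (order preserved).

    An infeasible scale raises (naming the scale); there is no silent
    truncation of the curve.
    """
    values = np.array([mm_mdisten(series, params, s) for s in params.scales])
    return EntropyCurve(scale_values=params.scales, entropy_values=values)


def as_series(
    values: Sequence | np.ndarray,
    sampling_rate: float | None = None,
    channel_names: Sequence[str] | None = None,
) -> MultichannelSeries:
    """Coerce a 1-D or 2-D array-like into a :class:`MultichannelSeries`."""
    return MultichannelSeries(
        values=np.atleast_2d(np.asarray(values, dtype=float)),
        sampling_rate=sampling_rate,
        channel_names=tuple(channel_names) if channel_names is not None else None,
    )
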