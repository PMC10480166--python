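"""Discretized pdfs and cdfs of egonet features in 1, 2 or 3 dimensions.

Feature values live in [0, 1]; the interval is split into ``r = 1/Δ`` bins of
width Δ, with bin ``h`` collecting values in ``[(h-1)Δ, hΔ)`` and the value 1
conventionally counted in the last bin. The cdf is the cumulative mass over
the sub-box of all bin indices up to a multi-index; distances between graphs
are Euclidean norms of cdf differences, optionally truncated at a cap value
``T`` so that only the first ``T/Δ`` bins per axis enter the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = ["Distribution", "joint_histogram", "cumulative", "truncate"]

_TOL = 1e-9
_ONE_EPS = 1e-12


@dataclass(frozen=True)
class Distribution:
    """A discretized feature distribution over [0, 1]^k.

    Either or both of ``pdf`` and ``cdf`` may be present. After truncation
    only the cdf is kept: the retained entries are cumulative masses of the
    untruncated distribution, not a renormalized conditional.
    """

    axes: tuple[str, ...]
    delta: float
    cap: float = 1.0
    pdf: np.ndarray | None = None
    cdf: np.ndarray | None = None

    @property
    def dims(self) -> int:
        return len(self.axes)

    @property
    def r(self) -> int:
        """Bins per axis of the stored grid."""
        arr = self.pdf if self.pdf is not None else self.cdf
        return arr.shape[0]


def _bins_per_axis(value: float, delta: float, what: str) -> int:
    r = value / delta
    r_int = round(r)
    if abs(r - r_int) > _TOL or r_int < 1:
        raise ValueError(f"{what}/delta = {r} is not a positive integer")
    return int(r_int)


def joint_histogram(
    feature_vectors: Sequence[np.ndarray] | np.ndarray,
    delta: float,
    axes: tuple[str, ...] | None = None,
) -> Distribution:
    """Normalized k-dimensional histogram of 1-3 equal-length feature vectors.

    Parameters
    ----------
    feature_vectors
        One to three vectors of values in [0, 1], all of the same length N
        (a single 1-D array is treated as one vector).
    delta
        Bin width Δ; 1/Δ must be an integer.
    axes
        Optional axis names (e.g. ``('d', 'c')``); defaults to positional
        placeholders.
    """
    if isinstance(feature_vectors, np.ndarray) and feature_vectors.ndim == 1:
        feature_vectors = [feature_vectors]
    vectors = [np.asarray(v, dtype=np.float64) for v in feature_vectors]
    k = len(vectors)
    if not 1 <= k <= 3:
        raise ValueError("expected 1 to 3 feature vectors")
    n = vectors[0].shape[0]
    if n == 0:
        raise ValueError("empty feature vectors")
    if any(v.shape != (n,) for v in vectors):
        raise ValueError("feature vectors must share one length")
    r = _bins_per_axis(1.0, delta, "1")
    if axes is None:
        axes = tuple(f"x{i}" for i in range(k))

    # bin h collects [(h-1)Δ, hΔ); values at (or within eps of) 1 go to h=r
    idx = []
    for v in vectors:
        i = np.floor(v / delta).astype(np.int64)
        i[v >= 1.0 - _ONE_EPS] = r - 1
        np.clip(i, 0, r - 1, out=i)
        idx.append(i)
    flat = np.ravel_multi_index(idx, (r,) * k)
    pdf = np.bincount(flat, minlength=r**k).astype(np.float64).reshape((r,) * k) / n
    return Distribution(axes=tuple(axes), delta=float(delta), pdf=pdf)


def cumulative(dist: Distribution) -> Distribution:
    """Fill the cdf: cumulative sums of the pdf along every axis."""
    if dist.pdf is None:
        raise ValueError("distribution has no pdf")
    cdf = dist.pdf
    for ax in range(dist.dims):
        cdf = np.cumsum(cdf, axis=ax)
    return replace(dist, cdf=cdf)


def truncate(dist: Distribution, cap: float) -> Distribution:
    """Cut the cdf at cap value T: keep entries with all indices <= T/Δ.

    The sums defining the cdf are unchanged — only the index range over
    which downstream distances accumulate is reduced — so the retained
    entries are not renormalized.
    """
    if not 0.0 < cap <= 1.0:
        raise ValueError("cap must lie in (0, 1]")
    if dist.cdf is None:
        raise ValueError("distribution has no cdf; call cumulative() first")
    r_cap = _bins_per_axis(cap, dist.delta, "cap")
    if cap == 1.0 or r_cap == dist.r:
        return replace(dist, cap=float(cap))
    sl = (slice(0, r_cap),) * dist.dims
    return replace(dist, cap=float(cap), pdf=None, cdf=dist.cdf[sl])
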