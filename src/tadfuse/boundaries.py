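"""TAD boundary calling on contact matrices via the directionality index.

The directionality index (DI) at bin *i* contrasts the contacts of *i* with
its upstream window A against its downstream window B:

    DI = sign(B - A) * ((A - E)^2 / E + (B - E)^2 / E),   E = (A + B) / 2

Bins inside a domain contact both sides evenly (DI ~ 0); bins just inside a
domain edge contact predominantly inward, so DI swings negative at the end
of one domain and positive at the start of the next.  A boundary is called
where DI crosses from negative to positive with sufficiently strong flanking
extrema.  Because the true domain size is unknown, boundaries are called
iteratively over a ladder of expected TAD sizes (window widths) and only
candidates supported across iterations are kept.  Windows reaching past the
analysed region are filled with the mean of the observed matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactMatrix",
    "DITrack",
    "BoundaryCandidate",
    "BoundaryConsensus",
    "directionality_index",
    "impute_edges",
    "call_boundaries",
    "consensus_boundaries",
    "default_tad_sizes",
]


@dataclass
class ContactMatrix:
    """Square symmetric non-negative contact matrix with genomic anchoring."""

    values: np.ndarray
    bin_size: int
    origin: tuple[str, int] = ("region", 0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(v, v.T, rtol=1e-6, atol=1e-9):
            raise ValueError("contact matrix must be symmetric")
        if (v < 0).any():
            raise ValueError("contact matrix must be non-negative")
        if not np.isfinite(np.diagonal(v)).all():
            raise ValueError("diagonal must be finite")
        self.values = v

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class DITrack:
    di: np.ndarray
    window_bins: int
    A: np.ndarray
    B: np.ndarray


def impute_edges(m: ContactMatrix, window_bins: int):
    """Contact accessor returning the global matrix mean outside the region.

    DI windows near the region borders reach past the data; missing cells
    are simulated with the mean value of the complete observed dataset.
    """
    vals = m.values
    n = m.n_bins
    fill = float(vals.mean())

    def get(i: int, j: int) -> float:
        if 0 <= i < n and 0 <= j < n:
            return float(vals[i, j])
        return fill

    return get


def directionality_index(m: ContactMatrix, window_bins: int) -> DITrack:
    """Per-bin DI with edge imputation; DI = 0 where A == B."""
    if window_bins < 1:
        raise ValueError("window_bins must be >= 1")
    n = m.n_bins
    if n < 2 * window_bins + 1:
        raise ValueError(
            f"matrix of {n} bins too small for window of {window_bins} bins")
    vals = m.values
    fill = float(vals.mean())
    # Pad with the global mean so windows overhanging the region borders use
    # the imputed value.  Direct slice sums keep A == B exact on balanced
    # bins (a cumulative-sum formulation leaks rounding error into the
    # A == B -> DI == 0 rule).
    padded = np.full((n, n + 2 * window_bins), fill)
    padded[:, window_bins:window_bins + n] = vals
    idx = np.arange(n) + window_bins  # column of bin i in padded coords
    A = np.array([padded[i, j - window_bins:j].sum()
                  for i, j in enumerate(idx)])
    B = np.array([padded[i, j + 1:j + 1 + window_bins].sum()
                  for i, j in enumerate(idx)])
    E = (A + B) / 2.0
    di = np.zeros(n)
    nz = (E > 0) & (A != B)
    di[nz] = np.sign(B[nz] - A[nz]) * (
        (A[nz] - E[nz]) ** 2 / E[nz] + (B[nz] - E[nz]) ** 2 / E[nz])
    return DITrack(di=di, window_bins=window_bins, A=A, B=B)


def call_boundaries(track: DITrack, strength: float = 1.0) -> list[int]:
    """Bins where DI crosses from negative to non-negative.

    A crossing at bin b (di[b-1] < 0 <= di[b]) is kept when both the
    upstream negative excursion and the downstream positive excursion reach
    ``strength`` standard deviations of the DI track — a deterministic
    stand-in for the original hidden-Markov segmentation.
    """
    di = track.di
    sd = float(di.std())
    if sd == 0:
        return []
    out = []
    for b in range(1, di.size):
        if di[b - 1] < 0 <= di[b]:
            # upstream negative run ending at b-1
            lo = b - 1
            while lo > 0 and di[lo - 1] < 0:
                lo -= 1
            neg_extreme = di[lo:b].min()
            # downstream non-negative run starting at b
            hi = b
            while hi + 1 < di.size and di[hi + 1] >= 0:
                hi += 1
            pos_extreme = di[b:hi + 1].max()
            if -neg_extreme >= strength * sd and pos_extreme >= strength * sd:
                out.append(b)
    return out


@dataclass(frozen=True)
class BoundaryCandidate:
    bin: int
    support: float
    edge: bool = False


@dataclass
class BoundaryConsensus:
    candidates: list[BoundaryCandidate]
    selected: list[BoundaryCandidate]
    iterations: list[int] = field(default_factory=list)  # window sizes (bins)


def default_tad_sizes(bin_size: int, n: int = 10) -> list[int]:
    """Ladder of expected TAD sizes: log-spaced between 2x and 50x bin size."""
    return [int(round(s)) for s in
            np.geomspace(2 * bin_size, 50 * bin_size, n)]


def consensus_boundaries(
    m: ContactMatrix,
    tad_sizes: list[int],
    min_support: float = 1.0,
    top_k: int | None = None,
    tol_bins: int = 1,
    strength: float = 1.0,
    include_edges: bool = False,
) -> BoundaryConsensus:
    """Iterative DI boundary calling over a ladder of expected TAD sizes.

    Each iteration uses ``window_bins = round(size / bin_size)``; candidate
    bins from all iterations are clustered by single linkage at ``tol_bins``
    and each cluster's support is the fraction of iterations contributing a
    member.  Selected are candidates with support >= ``min_support``, or the
    ``top_k`` by support when given.  Boundaries at the very ends of the
    analysed region are flagged "edge" and excluded from selection by
    default — a border at the extreme of the region may be an artefact of
    truncating the matrix.
    """
    if len(tad_sizes) < 2:
        raise ValueError("need at least 2 expected TAD sizes")
    windows = []
    for size in tad_sizes:
        if size < m.bin_size:
            raise ValueError(f"expected TAD size {size} < bin size {m.bin_size}")
        w = max(1, int(round(size / m.bin_size)))
        if m.n_bins >= 2 * w + 1:
            windows.append(w)
    if len(windows) < 2:
        raise ValueError("fewer than 2 usable window sizes for this matrix")

    per_iter: list[list[int]] = [
        call_boundaries(directionality_index(m, w), strength=strength)
        for w in windows
    ]
    # Single-linkage clustering of candidate bins at tol_bins.
    all_bins = sorted({(b, k) for k, bins in enumerate(per_iter) for b in bins})
    clusters: list[list[tuple[int, int]]] = []
    for b, k in all_bins:
        if clusters and b - clusters[-1][-1][0] <= tol_bins:
            clusters[-1].append((b, k))
        else:
            clusters.append([(b, k)])

    n_iter = len(windows)
    candidates = []
    for cl in clusters:
        bins = [b for b, _ in cl]
        iters = {k for _, k in cl}
        rep = int(round(float(np.median(bins))))
        edge = rep <= 1 or rep >= m.n_bins - 2
        candidates.append(BoundaryCandidate(bin=rep,
                                            support=len(iters) / n_iter,
                                            edge=edge))
    candidates.sort(key=lambda c: c.bin)
    pool = candidates if include_edges else [c for c in candidates if not c.edge]
    if top_k is not None:
        selected = sorted(pool, key=lambda c: (-c.support, c.bin))[:top_k]
        selected.sort(key=lambda c: c.bin)
    else:
        selected = [c for c in pool if c.support >= min_support]
    return BoundaryConsensus(candidates=candidates, selected=selected,
                             iterations=windows)
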