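"""4C interaction-peak calling against a two-sided monotonic background.

The expected 4C signal decays monotonically with genomic distance from the
viewpoint.  The background is therefore modelled as unimodal at the
viewpoint: a least-squares non-decreasing fit on the upstream arm and a
non-increasing fit on the downstream arm, each computed by the pool
adjacent violators algorithm (PAVA).  Fragment ends whose residual
(observed - background) exceeds the Tukey upper fence of the residual
distribution, Q3 + 1.5*IQR, are peak candidates; candidate runs closer than
a merge gap (default 500 bp) are merged into single peaks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression

__all__ = [
    "BackgroundFit",
    "Peak",
    "PeakSet",
    "fit_background",
    "residual_threshold",
    "call_peaks",
    "restrict_to_domain",
]


@dataclass
class BackgroundFit:
    """Unimodal background and residuals for one viewpoint region."""

    values: np.ndarray      # fitted background per end
    residuals: np.ndarray   # observed - fitted
    vp_index: int           # arm split: rising on [0, vp), falling on (vp, n)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    max_residual: float
    n_ends: int


@dataclass
class PeakSet:
    peaks: list[Peak]
    threshold: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


def fit_background(signal: np.ndarray, vp_index: int,
                   mask: np.ndarray | None = None) -> BackgroundFit:
    """Two-sided monotone (PAVA) background split at the viewpoint end.

    The left arm ``signal[:vp_index]`` gets the least-squares non-decreasing
    fit (rising toward the viewpoint), the right arm ``signal[vp_index+1:]``
    the non-increasing fit.  The viewpoint end itself is its own background
    (residual 0) — its self-ligation signal is excluded upstream anyway.
    Masked ends (viewpoint dead zone) are skipped by the fit and keep their
    observed value (residual 0), so their zeros cannot distort the unimodal
    background.  An arm with fewer than 2 ends keeps its observed values.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if not (0 <= vp_index < n):
        raise ValueError(f"vp_index {vp_index} out of range for {n} ends")
    keep = np.ones(n, dtype=bool) if mask is None else ~np.asarray(mask)
    fitted = signal.copy()
    for sl, increasing in (((slice(0, vp_index)), True),
                           (slice(vp_index + 1, n), False)):
        idx = np.arange(n)[sl][keep[sl]]
        if idx.size >= 2:
            fitted[idx] = isotonic_regression(signal[idx],
                                              increasing=increasing).x
    return BackgroundFit(values=fitted, residuals=signal - fitted,
                         vp_index=vp_index)


def residual_threshold(residuals: np.ndarray) -> float:
    """Tukey upper fence Q3 + 1.5*(Q3 - Q1) of the residual distribution.

    Quartiles use linear interpolation between order statistics (the common
    "type 7" convention).  Quartiles are taken over both arms jointly: one
    threshold per viewpoint region.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size < 4:
        raise ValueError("need at least 4 residuals for quartiles")
    q1, q3 = np.percentile(residuals, [25, 75])
    return float(q3 + 1.5 * (q3 - q1))


def call_peaks(
    fit: BackgroundFit,
    ends: np.ndarray,
    frag_bounds: np.ndarray,
    chrom: str = "chr",
    merge_gap: int = 500,
    mask: np.ndarray | None = None,
) -> PeakSet:
    """Threshold residuals and merge candidate runs closer than ``merge_gap``.

    Candidates are ends with residual strictly above the Tukey fence; runs of
    candidates whose genomic gap is < ``merge_gap`` bp form one peak.  Peak
    intervals span the union of the member ends' fragment intervals, giving
    non-degenerate BED intervals.
    """
    ends = np.asarray(ends)
    thr = residual_threshold(fit.residuals if mask is None
                             else fit.residuals[~mask])
    cand = fit.residuals > thr
    if mask is not None:
        cand &= ~mask
    idx = np.flatnonzero(cand)
    peaks: list[Peak] = []
    if idx.size:
        groups: list[list[int]] = [[int(idx[0])]]
        for i in idx[1:]:
            prev = groups[-1][-1]
            gap = int(frag_bounds[i, 0]) - int(frag_bounds[prev, 1])
            if gap < merge_gap:
                groups[-1].append(int(i))
            else:
                groups.append([int(i)])
        for g in groups:
            start = int(frag_bounds[g, 0].min())
            end = int(frag_bounds[g, 1].max())
            peaks.append(Peak(chrom=chrom, start=start, end=end,
                              max_residual=float(fit.residuals[g].max()),
                              n_ends=len(g)))
    return PeakSet(peaks=peaks, threshold=thr)


def restrict_to_domain(pset: PeakSet, interval: tuple[int, int]) -> PeakSet:
    """Drop peaks outside ``interval`` and clip peaks straddling its edges.

    Used when the analysed region has a known boundary (e.g. a TAD border
    from a previous experiment) beyond which calls are not meaningful.
    """
    lo, hi = interval
    kept = []
    for p in pset.peaks:
        if p.end <= lo or p.start >= hi:
            continue
        kept.append(Peak(chrom=p.chrom, start=max(p.start, lo),
                         end=min(p.end, hi), max_residual=p.max_residual,
                         n_ends=p.n_ends))
    return PeakSet(peaks=kept, threshold=pset.threshold)
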