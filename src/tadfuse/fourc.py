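"""Per-viewpoint 4C profiles: fragment-end counting, smoothing, normalisation.

A 4C-seq experiment anchors at one "viewpoint" fragment and reports, for
every other primary-enzyme fragment end, how often it was captured in
ligation with the viewpoint.  The pipeline here follows the conventional
reduction: reads are assigned to valid first-enzyme fragment ends, smoothed
with a running-mean window over fragment ends (default 30), scaled to reads
per million, and standardised to Z-scores for downstream filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragmap import FragmentMap

__all__ = [
    "Viewpoint",
    "FourCProfile",
    "SideFractions",
    "assign_reads",
    "smooth_profile",
    "normalise_rpm",
    "zscore",
    "side_fractions",
]


@dataclass(frozen=True)
class Viewpoint:
    """4C anchor: a named position on a chromosome.

    ``exclusion_radius`` is the number of fragments on either side of the
    viewpoint fragment whose ends are masked — the self-ligation /
    undigested signal around the viewpoint dominates the library and is
    removed before any statistics.
    """

    name: str
    chrom: str
    position: int
    exclusion_radius: int = 2


@dataclass
class FourCProfile:
    """Signal layers over the ordered valid fragment ends of one chromosome.

    ``ends`` are the end coordinates (two per valid fragment: first and last
    base); ``frag_index`` gives the source fragment ordinal for each end and
    ``frag_bounds`` its (start, end) interval.  ``mask`` is True for ends
    excluded around the viewpoint.
    """

    viewpoint: Viewpoint
    ends: np.ndarray                 # (n,) int, strictly increasing
    frag_index: np.ndarray           # (n,) int
    frag_bounds: np.ndarray          # (n, 2) int
    raw: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    rpm: np.ndarray | None = None
    z: np.ndarray | None = None
    mask: np.ndarray | None = None   # True == excluded
    window: int = 30
    n_discarded: int = 0
    derivative_rescaled: bool = False
    side_scalars: tuple[float, float] | None = None

    def copy(self) -> "FourCProfile":
        new = FourCProfile(
            viewpoint=self.viewpoint, ends=self.ends,
            frag_index=self.frag_index, frag_bounds=self.frag_bounds,
            window=self.window, n_discarded=self.n_discarded,
            derivative_rescaled=self.derivative_rescaled,
            side_scalars=self.side_scalars,
        )
        for layer in ("raw", "smoothed", "rpm", "z", "mask"):
            v = getattr(self, layer)
            setattr(new, layer, None if v is None else v.copy())
        return new


def _profile_skeleton(fmap: FragmentMap, vp: Viewpoint) -> FourCProfile:
    frs = fmap.fragments[vp.chrom]
    if not frs:
        raise ValueError(f"no valid fragments on {vp.chrom}")
    ends, fidx, bounds = [], [], []
    for f in frs:
        for e in f.ends:
            ends.append(e)
            fidx.append(f.index)
            bounds.append((f.start, f.end))
    return FourCProfile(
        viewpoint=vp,
        ends=np.asarray(ends, dtype=np.int64),
        frag_index=np.asarray(fidx, dtype=np.int64),
        frag_bounds=np.asarray(bounds, dtype=np.int64),
    )


def assign_reads(
    reads: list[tuple[str, int, int]],
    fmap: FragmentMap,
    vp: Viewpoint,
) -> FourCProfile:
    """Convert (chrom, pos, count) reads to reads-per-fragment-end units.

    ``fmap`` must already be filtered to valid fragments.  A read increments
    the end whose coordinate equals its position exactly; reads matching no
    valid end (or mapping to another chromosome) are tallied as discarded.
    Ends within ``exclusion_radius`` fragments of the viewpoint fragment are
    zeroed and masked.
    """
    prof = _profile_skeleton(fmap, vp)
    n = prof.ends.size
    raw = np.zeros(n, dtype=float)
    end_lookup = {int(e): i for i, e in enumerate(prof.ends)}
    discarded = 0
    for chrom, pos, count in reads:
        if chrom not in fmap.fragments:
            raise ValueError(f"read on unknown chromosome {chrom!r}")
        if count < 0:
            raise ValueError("negative read count")
        if chrom != vp.chrom:
            discarded += count
            continue
        i = end_lookup.get(int(pos))
        if i is None:
            discarded += count
        else:
            raw[i] += count

    # Mask the viewpoint dead zone: the viewpoint fragment +- radius fragments.
    try:
        vp_frag = fmap.fragment_at(vp.chrom, vp.position)
    except ValueError as exc:
        raise ValueError(
            f"viewpoint {vp.name} at {vp.chrom}:{vp.position} is not in a "
            "valid fragment"
        ) from exc
    order = {f.index: k for k, f in enumerate(fmap.fragments[vp.chrom])}
    vp_ord = order[vp_frag.index]
    frag_ord = np.array([order[i] for i in prof.frag_index])
    mask = np.abs(frag_ord - vp_ord) <= vp.exclusion_radius
    raw[mask] = 0.0

    prof.raw = raw
    prof.mask = mask
    prof.n_discarded = discarded
    return prof


def smooth_profile(profile: FourCProfile, window: int = 30) -> FourCProfile:
    """Running-mean smoothing over fragment ends.

    The window is centred: ceil(w/2)-1 ends before, the end itself, and the
    remainder after.  At chromosome edges the window is truncated and the
    mean renormalised by the number of ends actually covered.  Masked ends
    (the viewpoint dead zone) are excluded from the averaging rather than
    contributing zeros, and their own smoothed value stays 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if profile.raw is None:
        raise ValueError("raw layer not filled")
    out = profile.copy()
    out.window = window
    x = profile.raw.astype(float)
    n = x.size
    keep = (~profile.mask if profile.mask is not None
            else np.ones(n, dtype=bool)).astype(float)
    before = int(np.ceil(window / 2)) - 1
    after = window - 1 - before
    csum = np.concatenate([[0.0], np.cumsum(x * keep)])
    cnt = np.concatenate([[0.0], np.cumsum(keep)])
    idx = np.arange(n)
    lo = np.maximum(idx - before, 0)
    hi = np.minimum(idx + after + 1, n)
    denom = cnt[hi] - cnt[lo]
    smoothed = np.zeros(n)
    nz = denom > 0
    smoothed[nz] = (csum[hi] - csum[lo])[nz] / denom[nz]
    smoothed *= keep
    out.smoothed = smoothed
    return out


def normalise_rpm(profile: FourCProfile) -> FourCProfile:
    """Scale the smoothed layer to reads-per-million (sum = 1e6)."""
    if profile.smoothed is None:
        raise ValueError("smoothed layer not filled")
    total = float(profile.smoothed.sum())
    if total <= 0:
        raise ValueError("profile has no signal; cannot normalise")
    out = profile.copy()
    out.rpm = profile.smoothed * (1e6 / total)
    return out


def zscore(profile: FourCProfile) -> FourCProfile:
    """Standardise the rpm layer over unmasked ends (population sd).

    A constant profile gets z = 0 everywhere; masked ends are left at 0.
    """
    if profile.rpm is None:
        raise ValueError("rpm layer not filled")
    out = profile.copy()
    keep = ~profile.mask if profile.mask is not None else np.ones(
        profile.rpm.size, dtype=bool)
    vals = profile.rpm[keep]
    mu = float(vals.mean())
    sd = float(vals.std())  # population (ddof=0)
    z = np.zeros_like(profile.rpm)
    if sd > 0:
        z[keep] = (profile.rpm[keep] - mu) / sd
    out.z = z
    return out


@dataclass(frozen=True)
class SideFractions:
    """Percentages of flank reads upstream/downstream of a centre position."""

    pct_left: float
    pct_right: float
    pct_in_domain: float
    valid: bool = True


def side_fractions(
    profile: FourCProfile,
    center: int,
    flank: int,
    domain: tuple[int, int],
) -> SideFractions:
    """Read-count fractions left/right of ``center`` and inside ``domain``.

    Sums raw counts over ends in ``[center - flank, center)`` versus
    ``[center, center + flank)`` and reports each as a percentage of the
    combined flank counts, plus the percentage falling inside ``domain``.
    With zero flank counts the result is flagged invalid.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if profile.raw is None:
        raise ValueError("raw layer not filled")
    e = profile.ends
    r = profile.raw
    left = float(r[(e >= center - flank) & (e < center)].sum())
    right = float(r[(e >= center) & (e < center + flank)].sum())
    tot = left + right
    if tot <= 0:
        return SideFractions(float("nan"), float("nan"), float("nan"), valid=False)
    in_flanks = (e >= center - flank) & (e < center + flank)
    dom = float(r[in_flanks & (e >= domain[0]) & (e < domain[1])].sum())
    return SideFractions(100.0 * left / tot, 100.0 * right / tot,
                         100.0 * dom / tot)
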