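"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the contact structure 4C analysis assumes: a
polymer-like distance backbone growing as sqrt(genomic separation), TADs
that multiply cross-boundary distances by an insulation factor, planted
loops that shorten specific pairs, and overdispersed (negative-binomial)
4C counts whose expectation decays as a power of distance.  Genomes carry
planted primary/secondary restriction sites so the digestion and
fragment-end machinery runs end to end.  All generators are pure functions
of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .fragmap import FragmentMap, GenomeSequence

__all__ = [
    "LandscapeSpec",
    "GroundTruth",
    "make_genome",
    "make_structure",
    "simulate_4c",
    "counts_to_reads",
    "make_fused_landscape",
]

PRIMARY_SITE = "GATC"
SECONDARY_SITE = "GTAC"


@dataclass(frozen=True)
class LandscapeSpec:
    """Parameters of one synthetic regulatory landscape."""

    n_bins: int
    bin_size: int
    tads: tuple[tuple[int, int], ...]
    insulation: float = 2.0       # cross-boundary distance multiplier (>= 1)
    loops: tuple[tuple[int, int, float], ...] = ()
    alpha: float = 1.0            # counts ~ distance^(-alpha)
    coverage: float = 1e5         # expected total reads per viewpoint
    dispersion: float = 0.1       # NB overdispersion; 0 => noiseless
    bin_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        cur = 0
        for a, b in self.tads:
            if a != cur or b <= a:
                raise ValueError("tads must tile [0, n_bins) in order")
            cur = b
        if cur != self.n_bins:
            raise ValueError("tads must tile [0, n_bins)")
        if self.insulation < 1:
            raise ValueError("insulation must be >= 1")
        for i, j, s in self.loops:
            if not (0 <= i < self.n_bins and 0 <= j < self.n_bins):
                raise ValueError("loop anchors must be inside the region")
            if s <= 1:
                raise ValueError("loop strength must be > 1")

    @property
    def boundaries(self) -> list[int]:
        """Internal TAD junction bins."""
        return [b for _, b in self.tads[:-1]]


@dataclass
class GroundTruth:
    true_boundaries: list[int]
    true_loops: list[tuple[int, int]]
    true_structure: np.ndarray     # (n_bins, 3) least-stress embedding
    true_distance: np.ndarray      # (n_bins, n_bins) target distances
    spec: LandscapeSpec | None = None


_BASES = np.array(list("ACGT"))


def _random_filler(rng: np.random.Generator, n: int) -> str:
    """Random sequence of length n free of primary/secondary sites."""
    if n <= 0:
        return ""
    arr = rng.choice(4, size=n)
    s = "".join(_BASES[arr])
    for site in (PRIMARY_SITE, SECONDARY_SITE):
        while site in s:
            i = s.find(site)
            repl = "A" if s[i + 1] != "A" else "C"
            s = s[: i + 1] + repl + s[i + 2:]
    return s


def make_genome(n_fragments_target: int, mean_fragment_len: float,
                seed: int, name: str = "chrS") -> GenomeSequence:
    """Random chromosome with planted restriction sites.

    Fragments are planted back to back, each opening with the primary site
    and containing one interior secondary site, with lengths spread
    geometrically around ``mean_fragment_len`` (floored so fragments stay
    valid).  Digesting the output therefore yields close to
    ``n_fragments_target`` valid fragments.
    """
    if n_fragments_target < 1:
        raise ValueError("need at least one fragment")
    min_len = 44  # primary + secondary site + margin to stay non-short
    if mean_fragment_len <= 2 * (len(PRIMARY_SITE) + len(SECONDARY_SITE)):
        raise ValueError("mean fragment length infeasibly small")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    spread = max(1.0, mean_fragment_len - min_len)
    for _ in range(n_fragments_target):
        ln = min_len + int(rng.geometric(1.0 / spread)) - 1
        interior = ln - len(PRIMARY_SITE) - len(SECONDARY_SITE)
        cut = int(rng.integers(1, max(2, interior)))  # keep site interior
        chunks.append(PRIMARY_SITE + _random_filler(rng, cut)
                      + SECONDARY_SITE + _random_filler(rng, interior - cut))
    return GenomeSequence(name, "".join(chunks))


def make_structure(spec: LandscapeSpec, embed: bool = True) -> GroundTruth:
    """Target distance matrix and a 3D least-stress embedding.

    d_ij = sqrt(|i-j|) * bin_scale * insulation^(#boundaries crossed),
    divided by the strength of any loop planted on (i, j).  The embedding
    is fitted by SMACOF stress minimisation and is the best 3D realisation
    of the targets, not an exact one; pass ``embed=False`` to skip it when
    only the distance matrix is needed.
    """
    n = spec.n_bins
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    d = np.sqrt(sep, dtype=float) * spec.bin_scale
    bounds = np.asarray(spec.boundaries)
    if bounds.size and spec.insulation > 1:
        # crossings(i,j) = #boundaries b with min(i,j) < b <= max(i,j)
        below = (idx[:, None] < bounds[None, :]).sum(axis=1)
        cross = np.abs(below[:, None] - below[None, :])
        d *= spec.insulation ** cross
    for i, j, s in spec.loops:
        d[i, j] /= s
        d[j, i] /= s
    np.fill_diagonal(d, 0.0)

    if embed:
        from sklearn.manifold import smacof
        emb, _ = smacof(d, n_components=3, random_state=spec.seed,
                        n_init=1, normalized_stress=False)
    else:
        emb = np.zeros((n, 3))
    return GroundTruth(true_boundaries=list(spec.boundaries),
                       true_loops=[(i, j) for i, j, _ in spec.loops],
                       true_structure=emb, true_distance=d, spec=spec)


def simulate_4c(gt: GroundTruth, viewpoints: list[int],
                spec: LandscapeSpec | None = None) -> dict[int, np.ndarray]:
    """Per-viewpoint expected or negative-binomial 4C counts per bin.

    mu_j = coverage * d(vp, j)^(-alpha) / sum_k d(vp, k)^(-alpha); the
    viewpoint bin itself is zero.  With dispersion > 0 counts are drawn
    negative-binomial with var = mu + dispersion * mu^2; dispersion == 0
    returns the expectations (noiseless mode).
    """
    spec = spec or gt.spec
    if spec is None:
        raise ValueError("need a LandscapeSpec")
    n = spec.n_bins
    out: dict[int, np.ndarray] = {}
    for vp in viewpoints:
        if not (0 <= vp < n):
            raise ValueError(f"viewpoint bin {vp} outside region")
        d = gt.true_distance[vp].copy()
        w = np.zeros(n)
        nz = d > 0
        w[nz] = d[nz] ** (-spec.alpha)
        mu = spec.coverage * w / w.sum()
        if spec.dispersion <= 0:
            out[vp] = mu
        else:
            rng = np.random.default_rng([spec.seed, vp])
            r = 1.0 / spec.dispersion
            p = r / (r + mu)
            counts = np.zeros(n)
            pos = mu > 0
            counts[pos] = rng.negative_binomial(r, p[pos])
            out[vp] = counts
    return out


def counts_to_reads(
    bin_counts: np.ndarray,
    fmap: FragmentMap,
    chrom: str,
    bin_size: int,
    seed: int,
    region_start: int = 0,
) -> list[tuple[str, int, int]]:
    """Scatter per-bin counts uniformly over the valid fragment ends in each bin.

    Produces the (chrom, pos, count) read tuples the profile builder
    consumes; positions are fragment-end coordinates.  ``fmap`` must be the
    filtered (valid) fragment map.
    """
    rng = np.random.default_rng(seed)
    ends = np.array([e for f in fmap.fragments[chrom] for e in f.ends])
    bins = (ends - region_start) // bin_size
    reads: list[tuple[str, int, int]] = []
    for b, total in enumerate(np.asarray(bin_counts)):
        total = int(round(float(total)))
        if total <= 0:
            continue
        members = ends[bins == b]
        if members.size == 0:
            continue
        alloc = rng.multinomial(total, np.full(members.size, 1.0 / members.size))
        for pos, c in zip(members, alloc):
            if c > 0:
                reads.append((chrom, int(pos), int(c)))
    return reads


def make_fused_landscape(
    specA: LandscapeSpec,
    specB: LandscapeSpec,
    breakA: int,
    breakB: int,
) -> tuple[LandscapeSpec, GroundTruth]:
    """Fuse two landscapes at intra-TAD breakpoints.

    The fused region is A[0:breakA) + B[breakB:); the junction itself
    carries no insulation penalty, so the fused TAD runs from the last A
    boundary upstream of breakA to the first B boundary downstream of
    breakB.  Breakpoints must fall strictly inside a TAD — a break at an
    existing boundary would not fuse two landscapes into a new domain.
    Landscape-level parameters (insulation, decay, coverage, dispersion)
    are taken from ``specA``; bin sizes must agree.
    """
    if specA.bin_size != specB.bin_size:
        raise ValueError("bin sizes must agree to fuse landscapes")
    for spec, brk, label in ((specA, breakA, "A"), (specB, breakB, "B")):
        if not (0 < brk < spec.n_bins):
            raise ValueError(f"break{label} outside region")
        if brk in spec.boundaries:
            raise ValueError(
                f"break{label} falls on an existing TAD boundary; "
                "breakpoints must be intra-TAD")

    lastA = max([a for a, b in specA.tads if a < breakA])
    firstB = min([b for a, b in specB.tads if b > breakB])
    offset = breakA - breakB

    tads: list[tuple[int, int]] = []
    for a, b in specA.tads:
        if b <= lastA:
            tads.append((a, b))
    tads.append((lastA, firstB + offset))
    for a, b in specB.tads:
        if a >= firstB:
            tads.append((a + offset, b + offset))

    loops = [(i, j, s) for i, j, s in specA.loops if i < breakA and j < breakA]
    loops += [(i + offset, j + offset, s) for i, j, s in specB.loops
              if i >= breakB and j >= breakB]

    fused = LandscapeSpec(
        n_bins=breakA + (specB.n_bins - breakB),
        bin_size=specA.bin_size,
        tads=tuple(tads),
        insulation=specA.insulation,
        loops=tuple(loops),
        alpha=specA.alpha,
        coverage=specA.coverage,
        dispersion=specA.dispersion,
        bin_scale=specA.bin_scale,
        seed=specA.seed,
    )
    return fused, make_structure(fused)
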