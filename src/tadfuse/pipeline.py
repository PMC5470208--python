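"""End-to-end analyses chaining the pipeline stages on synthetic inputs.

Two ready-made experiments cover the package's central claims:

* :func:`loop_recovery_experiment` — plant loops in a landscape, simulate
  overdispersed 4C counts, call peaks against the PAVA background, and
  score recall/precision of the planted loops.

* :func:`fused_tad_experiment` — fuse two multi-TAD landscapes at
  intra-TAD breakpoints, simulate multi-viewpoint 4C on the derivative
  chromosome, build restraint-based 3D models, compute the virtual Hi-C
  and call consensus TAD boundaries; the fused domain should be bounded by
  the parental outer borders with no boundary at the breakpoint itself.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import fourc, model3d, peaks, synthetic
from .boundaries import (BoundaryConsensus, ContactMatrix,
                         consensus_boundaries, default_tad_sizes)
from .fragmap import digest_genome, valid_fragments
from .fusion import BreakpointSpec, build_derivative
from .synthetic import (PRIMARY_SITE, SECONDARY_SITE, LandscapeSpec,
                        counts_to_reads, make_genome, make_structure,
                        simulate_4c)

__all__ = [
    "make_binned_genome",
    "profile_from_counts",
    "loop_recovery_experiment",
    "boundary_recovery_experiment",
    "structure_recovery_experiment",
    "fused_tad_experiment",
    "LoopRecovery",
    "BoundaryRecovery",
    "StructureRecovery",
    "FusedTadResult",
]


def make_binned_genome(n_bins: int, bin_size: int, frags_per_bin: int,
                       seed: int, name: str = "chrS"):
    """Synthetic chromosome of exactly ``n_bins * bin_size`` bp.

    Fragments average ``bin_size / frags_per_bin`` bp; the sequence is
    padded (site-free filler) or truncated to the exact length so bin
    arithmetic stays aligned with the landscape grid.
    """
    target_len = n_bins * bin_size
    mean_len = bin_size / frags_per_bin
    g = make_genome(n_fragments_target=n_bins * frags_per_bin,
                    mean_fragment_len=mean_len, seed=seed, name=name)
    seq = g.seq
    if len(seq) < target_len:
        rng = np.random.default_rng([seed, 1])
        seq = seq + synthetic._random_filler(rng, target_len - len(seq))
    return type(g)(name, seq[:target_len])


def profile_from_counts(bin_counts, fmap, chrom: str, bin_size: int,
                        vp_bin: int, seed, name: str = "VP",
                        window: int = 30) -> fourc.FourCProfile:
    """Scatter bin counts to fragment ends and build the full profile stack."""
    reads = counts_to_reads(bin_counts, fmap, chrom, bin_size, seed=seed)
    ends = np.array([e for f in fmap.fragments[chrom] for e in f.ends])
    in_bin = ends[(ends >= vp_bin * bin_size) & (ends < (vp_bin + 1) * bin_size)]
    if in_bin.size == 0:
        raise ValueError(f"no valid fragment end in viewpoint bin {vp_bin}")
    vp_pos = int(in_bin[in_bin.size // 2])
    vp = fourc.Viewpoint(name=name, chrom=chrom, position=vp_pos)
    prof = fourc.assign_reads(reads, fmap, vp)
    prof = fourc.smooth_profile(prof, window=window)
    prof = fourc.normalise_rpm(prof)
    prof = fourc.zscore(prof)
    return prof


@dataclass
class LoopRecovery:
    recall: float
    precision: float
    n_called: int
    n_planted: int
    peakset: peaks.PeakSet


def loop_recovery_experiment(
    seed: int,
    n_bins: int = 200,
    bin_size: int = 2500,
    frags_per_bin: int = 10,
    n_loops: int = 10,
    loop_strength: float = 4.0,
    coverage: float = 1e5,
    dispersion: float = 0.1,
    merge_gap: int = 500,
) -> LoopRecovery:
    """Plant loops around a central viewpoint and score peak recovery.

    Loop anchors are drawn at least 5 bins from the viewpoint and 3 bins
    apart.  A planted loop counts as recovered when a called peak overlaps
    its bin; a called peak counts as true when it overlaps any planted bin.
    """
    rng = np.random.default_rng([seed, 99])
    vp_bin = n_bins // 2
    candidates = [b for b in range(2, n_bins - 2) if abs(b - vp_bin) >= 5]
    anchors: list[int] = []
    for b in rng.permutation(candidates):
        if all(abs(b - a) >= 3 for a in anchors):
            anchors.append(int(b))
        if len(anchors) == n_loops:
            break
    spec = LandscapeSpec(
        n_bins=n_bins, bin_size=bin_size,
        tads=((0, n_bins),),
        loops=tuple((min(vp_bin, a), max(vp_bin, a), loop_strength)
                    for a in anchors),
        coverage=coverage, dispersion=dispersion, seed=seed,
    )
    gt = make_structure(spec)
    genome = make_binned_genome(n_bins, bin_size, frags_per_bin, seed=seed)
    fmap = valid_fragments(digest_genome({genome.name: genome.seq},
                                         PRIMARY_SITE, SECONDARY_SITE))
    counts = simulate_4c(gt, [vp_bin], spec)[vp_bin]
    prof = profile_from_counts(counts, fmap, genome.name, bin_size, vp_bin,
                               seed=[seed, 7])
    vp_index = int(np.searchsorted(prof.ends, prof.viewpoint.position))
    fit = peaks.fit_background(prof.smoothed, vp_index, mask=prof.mask)
    pset = peaks.call_peaks(fit, prof.ends, prof.frag_bounds,
                            chrom=genome.name, merge_gap=merge_gap,
                            mask=prof.mask)
    loop_ivs = [(a * bin_size, (a + 1) * bin_size) for a in anchors]
    hit = [any(p.start < e and p.end > s for p in pset) for s, e in loop_ivs]
    true_pos = [any(p.start < e and p.end > s for s, e in loop_ivs)
                for p in pset]
    recall = float(np.mean(hit)) if loop_ivs else 1.0
    precision = float(np.mean(true_pos)) if len(pset) else 0.0
    return LoopRecovery(recall=recall, precision=precision,
                        n_called=len(pset), n_planted=len(anchors),
                        peakset=pset)


@dataclass
class BoundaryRecovery:
    recovered: bool
    called_bins: list[int]
    true_boundaries: list[int]


def boundary_recovery_experiment(
    seed: int,
    n_bins: int = 60,
    bin_size: int = 20000,
    insulation: float = 2.0,
    noise_sd: float = 0.2,
    tol_bins: int = 1,
) -> BoundaryRecovery:
    """Boundary calling on a noisy 3-TAD block contact matrix.

    Builds the ground-truth contact matrix 1/d for three equal TADs,
    perturbs every cell with multiplicative log-normal noise of the given
    sd, and asks the iterative consensus caller for the top two boundaries.
    Success = both internal boundaries recovered within ``tol_bins``.
    """
    third = n_bins // 3
    spec = LandscapeSpec(n_bins=n_bins, bin_size=bin_size,
                         tads=((0, third), (third, 2 * third),
                               (2 * third, n_bins)),
                         insulation=insulation, seed=seed)
    gt = make_structure(spec, embed=False)
    d = gt.true_distance
    c = np.zeros_like(d)
    nz = d > 0
    c[nz] = 1.0 / d[nz]
    rng = np.random.default_rng([seed, 5])
    noise = rng.lognormal(0.0, noise_sd, size=c.shape)
    noise = np.sqrt(noise * noise.T)  # keep the matrix symmetric
    c = c * noise
    np.fill_diagonal(c, 0.0)
    np.fill_diagonal(c, c.max())
    m = ContactMatrix(values=c, bin_size=bin_size)
    cons = consensus_boundaries(m, default_tad_sizes(bin_size), top_k=2)
    called = [x.bin for x in cons.selected]
    ok = all(any(abs(b - t) <= tol_bins for b in called)
             for t in gt.true_boundaries)
    return BoundaryRecovery(recovered=bool(ok), called_bins=called,
                            true_boundaries=gt.true_boundaries)


@dataclass
class StructureRecovery:
    spearman_restrained: float
    spearman_all: float
    n_restrained_pairs: int
    vhic: object
    ground_truth: synthetic.GroundTruth


def structure_recovery_experiment(
    seed: int,
    n_bins: int = 100,
    bin_size: int = 5000,
    frags_per_bin: int = 16,
    n_viewpoints: int = 8,
    n_models: int = 2000,
    n_keep: int = 20,
    max_iter: int = 100,
    n_anneal: int = 1,
    d_min: float = 1.0,
    d_max: float = 50.0,
) -> StructureRecovery:
    """Recover a known 3-TAD structure from noiseless synthetic 4C.

    Simulates expectation-level (dispersion 0) 4C for viewpoints spread
    across the region, models the locus and compares the virtual-Hi-C mean
    distances with the ground-truth distances by Spearman rank correlation
    over the harmonically restrained pairs (and over all pairs).
    """
    third = n_bins // 3
    spec = LandscapeSpec(
        n_bins=n_bins, bin_size=bin_size,
        tads=((0, third), (third, 2 * third), (2 * third, n_bins)),
        insulation=2.0, coverage=1e5, dispersion=0.0, seed=seed,
    )
    gt = make_structure(spec)
    genome = make_binned_genome(n_bins, bin_size, frags_per_bin, seed=seed)
    fmap = valid_fragments(digest_genome({genome.name: genome.seq},
                                         PRIMARY_SITE, SECONDARY_SITE))
    vp_bins = np.unique(np.linspace(2, n_bins - 3, n_viewpoints).round()
                        .astype(int))
    counts = simulate_4c(gt, [int(b) for b in vp_bins], spec)
    profiles = [
        profile_from_counts(counts[int(b)], fmap, genome.name, bin_size,
                            int(b), seed=[seed, 13, int(b)], name=f"VP{k}")
        for k, b in enumerate(vp_bins, 1)
    ]
    rs = model3d.build_restraints(profiles, region=(0, n_bins * bin_size),
                                  bin_size=bin_size, d_min=d_min, d_max=d_max)
    er = model3d.run_ensemble(rs, n_models=n_models, n_keep=n_keep,
                              base_seed=seed * 99991 % (2**31 - 1),
                              max_iter=max_iter, n_anneal=n_anneal)
    er = model3d.cluster_mirror(er)
    vhic = model3d.virtual_hic(er, bin_size=bin_size, mode="distance")
    from scipy.stats import spearmanr
    harm = rs.kinds == model3d.HARMONIC
    i, j = rs.pairs[harm, 0], rs.pairs[harm, 1]
    rho_r = float(spearmanr(vhic.values[i, j], gt.true_distance[i, j]).statistic)
    iu = np.triu_indices(n_bins, k=1)
    rho_all = float(spearmanr(vhic.values[iu], gt.true_distance[iu]).statistic)
    return StructureRecovery(spearman_restrained=rho_r, spearman_all=rho_all,
                             n_restrained_pairs=int(harm.sum()), vhic=vhic,
                             ground_truth=gt)


@dataclass
class FusedTadResult:
    fused_spec: LandscapeSpec
    ground_truth: synthetic.GroundTruth
    breakpoint_bin: int
    expected_borders: tuple[int, int]   # fused TAD start/end bins
    consensus: BoundaryConsensus
    called_bins: list[int]
    borders_recovered: bool
    breakpoint_called: bool
    vhic: object
    profiles: list
    ensemble: model3d.EnsembleResult | None = None


def _default_parents() -> tuple[LandscapeSpec, LandscapeSpec, int, int]:
    specA = LandscapeSpec(n_bins=42, bin_size=5000,
                          tads=((0, 10), (10, 32), (32, 42)),
                          insulation=2.0, coverage=1e5, dispersion=0.1)
    specB = LandscapeSpec(n_bins=42, bin_size=5000,
                          tads=((0, 10), (10, 32), (32, 42)),
                          insulation=2.0, coverage=1e5, dispersion=0.1)
    return specA, specB, 22, 20  # breaks inside the central TADs


def fused_tad_experiment(
    seed: int,
    specA: LandscapeSpec | None = None,
    specB: LandscapeSpec | None = None,
    breakA: int | None = None,
    breakB: int | None = None,
    frags_per_bin: int = 16,
    n_viewpoints: int = 9,
    n_models: int = 300,
    n_keep: int = 20,
    max_iter: int = 150,
    n_anneal: int = 1,
    d_min: float = 1.0,
    d_max: float = 30.0,
    tol_bins: int = 1,
) -> FusedTadResult:
    """Full derivative-chromosome analysis on a synthetic translocation.

    Builds native chromosomes for two landscapes, fuses them at intra-TAD
    breakpoints into a derivative chromosome, simulates multi-viewpoint 4C,
    models the locus in 3D, computes the contact-mode virtual Hi-C and
    calls consensus boundaries.  Success is defined as: both fused-TAD
    borders called within ``tol_bins`` and no boundary called at the
    breakpoint bin.
    """
    if specA is None:
        specA, specB, breakA, breakB = _default_parents()
    fused_spec, gt = synthetic.make_fused_landscape(specA, specB, breakA, breakB)
    fused_spec = replace(fused_spec, seed=seed)
    gt.spec = fused_spec
    bin_size = fused_spec.bin_size
    n_bins = fused_spec.n_bins

    gA = make_binned_genome(specA.n_bins, bin_size, frags_per_bin,
                            seed=seed * 2 + 1, name="chrA")
    gB = make_binned_genome(specB.n_bins, bin_size, frags_per_bin,
                            seed=seed * 2 + 2, name="chrB")
    genome = {gA.name: gA.seq, gB.name: gB.seq}
    bp = BreakpointSpec(chromA="chrA", posA=breakA * bin_size,
                        chromB="chrB", posB=breakB * bin_size)
    _, der = build_derivative(genome, bp, name="der")
    fmap = valid_fragments(digest_genome({der.name: der.seq},
                                         PRIMARY_SITE, SECONDARY_SITE))

    # fused TAD borders and breakpoint in fused-bin coordinates
    tad_starts = [a for a, _ in fused_spec.tads]
    fused_start = max(a for a in tad_starts if a < breakA)
    fused_end = dict(fused_spec.tads)[fused_start]
    breakpoint_bin = breakA

    vp_bins = np.unique(np.linspace(2, n_bins - 3, n_viewpoints).round()
                        .astype(int))
    counts = simulate_4c(gt, [int(b) for b in vp_bins], fused_spec)
    profiles = [
        profile_from_counts(counts[int(b)], fmap, der.name, bin_size, int(b),
                            seed=[seed, 11, int(b)], name=f"VP{k}")
        for k, b in enumerate(vp_bins, 1)
    ]

    rs = model3d.build_restraints(profiles, region=(0, n_bins * bin_size),
                                  bin_size=bin_size, d_min=d_min, d_max=d_max)
    er = model3d.run_ensemble(rs, n_models=n_models, n_keep=n_keep,
                              base_seed=seed * 100003 % (2**31 - 1),
                              max_iter=max_iter, n_anneal=n_anneal)
    er = model3d.cluster_mirror(er)
    vhic = model3d.virtual_hic(er, bin_size=bin_size, mode="contact",
                               origin=("der", 0))

    cons = consensus_boundaries(vhic, default_tad_sizes(bin_size),
                                top_k=len(fused_spec.boundaries),
                                tol_bins=1)
    called = [c.bin for c in cons.selected]
    ok = (any(abs(b - fused_start) <= tol_bins for b in called)
          and any(abs(b - fused_end) <= tol_bins for b in called))
    bp_called = any(abs(b - breakpoint_bin) <= 0 for b in called)
    return FusedTadResult(
        fused_spec=fused_spec, ground_truth=gt,
        breakpoint_bin=breakpoint_bin,
        expected_borders=(fused_start, fused_end),
        consensus=cons, called_bins=called,
        borders_recovered=bool(ok), breakpoint_called=bool(bp_called),
        vhic=vhic, profiles=profiles, ensemble=er,
    )
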