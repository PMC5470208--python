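# Methods

## 4C profile construction

4C-seq measures, for one anchor ("viewpoint") restriction fragment, how
often every other fragment end of the genome was ligated to it.  The
pipeline works in the standard reduced representation: each valid
primary-enzyme fragment contributes its two ends, and a read counts toward
the end whose coordinate it matches exactly.

*Fragment validity.*  A fragment is unusable ("blind") when no
secondary-enzyme site starts strictly inside it, and is discarded when
shorter than `min_len` (default 40 bp, strict: a 40 bp fragment is kept).
Cut positions are taken at the first base of each primary-site occurrence;
overlapping occurrences are resolved by a leftmost scan with step 1.  Only
palindromic recognition sites are accepted (forward-strand scan suffices);
N never matches.  End coordinates are the fragment's first and last base
(`start`, `end−1`), which keeps end coordinates unique even when retained
fragments are adjacent.

*Smoothing.*  Profiles are smoothed with a centred running mean over 30
fragment ends (⌈w/2⌉−1 before, self, remainder after), truncated and
renormalised at chromosome edges.  The dead zone around the viewpoint
(viewpoint fragment ± 2 fragments by default) is masked: masked ends are
excluded from the averaging rather than contributing zeros, otherwise the
zeroed dead zone carves an artificial dip into the profile exactly where
the background model assumes its mode.  Smoothing precedes normalisation;
the order is configurable.

*Normalisation and Z-scores.*  The smoothed layer is scaled to reads per
million (Σ = 10⁶), then standardised with the population (n) standard
deviation over unmasked ends; a constant profile gets z = 0 everywhere.

*Side fractions.*  Read percentages in the two flanking windows of a centre
position (e.g. 1 Mb either side of a promoter) and within a stated domain
are computed on raw counts, relative to the combined flank counts; a zero
flank yields a flagged, NaN result rather than an exception.

## Derivative chromosomes

A breakpoint specification `chromA[0:posA] + insertion + chromB[posB:]`
(posA exclusive, posB inclusive; micro-homology attributed to chromA)
defines the derivative.  The segment table supports exact bidirectional
coordinate lifting; positions inside the insertion map to the pseudo-source
`"insertion"`.

*Copy-number duplication.*  In a cell with one derivative and intact
homologs, signal on the viewpoint's native chromosome comes from two
alleles, while signal beyond the breakpoint is derivative-unique; those raw
counts are doubled (factor fixed at 2) before smoothing.  The operation
records a flag and refuses re-application, and is undefined (error) for a
viewpoint on the junction fragment or inside the insertion.

*Side balancing.*  Smoothed signal on the two sides of the breakpoint is
rescaled so the mean in the two flanking windows matches; both sides move
toward the geometric mean of the two flank means, making the operation
symmetric and order-independent.  The two scalars are recorded; their ratio
equals the inverse flank-mean ratio.

## Peak calling

The expected 4C background decays monotonically with genomic distance from
the viewpoint, so it is modelled as unimodal at the viewpoint: the
least-squares non-decreasing fit on the upstream arm and non-increasing fit
on the downstream arm, each computed by the pool adjacent violators
algorithm (unit weights; `scipy.optimize.isotonic_regression`).  Masked
ends are skipped by the fit and keep residual 0.  The viewpoint end itself
is its own background.  Peaks are ends with residual strictly above the
Tukey fence Q3 + 1.5·IQR of the residual distribution — quartiles by
linear interpolation ("type 7"), computed jointly over both arms — with
candidate runs merged when the genomic gap between their fragment
intervals is < 500 bp (strictly).  Peak intervals are unions of member
fragment intervals.  Calls are invariant under adding a constant to the
signal (the monotone background absorbs it).  Peaks can be restricted to a
known domain, dropping outside peaks and clipping straddlers.

## Restraint-based 3D modelling and virtual Hi-C

Binned multi-viewpoint profiles (per-bin mean of the smoothed layer over
unmasked ends) define target distances under the assumption that 4C signal
is inversely related to spatial distance.  The default map is the literal
inverse, anchored at the strongest bin and clipped:

    d_target(b) = clip(d_min · s_max / s(b),  d_min,  d_max)

Because every viewpoint shares the genome-wide coverage scale, targets from
different viewpoints are mutually consistent up to one factor, which makes
the joint optimisation well posed.  An affine alternative
(d = d_max − ŝ·(d_max − d_min) on the min-max-normalised signal) is kept as
`mapping="affine"`; it is bounded by construction but compresses the
heavy-tailed 4C signal toward d_max and yields visibly worse geometry, so
it is not the default.  An optional Z-score cut (`z_cut`) restricts
restraints to significant bins; by default all bins with signal are
restrained — dropping sub-mean bins leaves distal regions geometrically
underdetermined.  Consecutive bins are chained at d_min (connectivity);
all remaining pairs get an excluded-volume lower bound at 2·d_min.
Defaults: d_min = 1, d_max region-scale (30–50), all force constants 1
(arbitrary units).

*Optimisation.*  Coordinates start uniformly random in a cube of side
d_max·∛n from the model seed; the energy Σ k·(d − d_target)² (lower-bound
restraints active only when violated) is minimised by L-BFGS descent with
analytic gradients, plus seeded annealing perturbation restarts that keep
the best state seen; the result never scores worse than the start and is
deterministic given (restraints, seed).  Ensembles use the seed ladder
`base_seed + i`, so they are reproducible regardless of execution order.
The top-scoring `n_keep` of `n_models` are retained (the full-scale
configuration 200/50,000 is available; desk-scale runs here use
300–2,000 models keeping 20).

*Mirror clustering.*  Distance restraints cannot distinguish a structure
from its mirror image, so kept models split into two enantiomeric
populations.  Pairwise RMSD uses optimal translation + proper rotation only
(Kabsch with determinant correction — no reflections), average-linkage
clustering is cut at two clusters, and the mirror relation is verified by
reflecting one cluster medoid through a coordinate plane: re-superposition
must reduce the medoid RMSD by ≥ 50%.  The most populated cluster is kept
(ties: lower medoid score); identical models collapse to one cluster with
the check skipped.

*Virtual Hi-C.*  Entry (i, j) is the mean Euclidean distance over the kept
cluster's models ("distance" mode), or its reciprocal with the diagonal set
to the maximum off-diagonal contact ("contact" mode, the DI input).  The
matrix is symmetric, rigid-motion invariant, and reduces to the single
model's own distances for a one-model cluster.

## Directionality index and boundary consensus

For bin i with upstream window sum A and downstream sum B over
`window_bins` bins, E = (A+B)/2 and

    DI(i) = sign(B − A) · ((A − E)²/E + (B − E)²/E),   DI = 0 when A = B.

Windows that reach past the analysed region are filled with the mean of
the observed matrix (the analysis is restricted to a region of interest,
so border bins are missing data, not zeros).  A boundary is called where
DI crosses from negative to non-negative and both the upstream negative
and downstream positive excursions reach `strength`·sd(DI) (default 1) —
a deterministic stand-in for the original hidden-Markov segmentation,
adequate at these resolutions.  Scaling the matrix scales DI magnitudes
but not signs, so boundary calls are scale-invariant.

Because the result depends on the expected TAD size, boundaries are called
iteratively over a ladder of sizes (default 10 sizes log-spaced between 2×
and 50× the bin size, `window_bins = round(size / bin_size)`), candidate
bins are clustered across iterations by single linkage at ± 1 bin, and each
cluster's support is the fraction of iterations contributing a member.
Selection takes either all candidates with support ≥ `min_support`
(default 1.0 — present in every iteration) or the `top_k` by support.
Candidates at the extreme bins of the region are flagged `edge` and
excluded from selection by default: a border at the end of the analysed
region is likely an artefact of truncation.

## Synthetic data generator

The generator emulates the features of real 4C/Hi-C data that the analysis
depends on:

* **Distance backbone** d_ij = √|i−j| · bin_scale — an
  equilibrium-globule-like growth; any monotone kernel would do, the square
  root keeps distances bounded over desk-scale regions.
* **TAD insulation** multiplies d_ij by `insulation` (default 2) per
  boundary crossed; **loops** (i, j, strength) divide d_ij by their
  strength.
* **3D ground truth**: a SMACOF least-stress 3D embedding of the target
  distances (the formula matrix itself is not exactly Euclidean-embeddable;
  the formula matrix is the reference for recovery comparisons).
* **4C counts**: μ_j = coverage · d(vp, j)^(−α) / Σ_k d(vp, k)^(−α) with
  α = 1 by default (the inverse-proportionality assumption), drawn
  negative-binomial with var = μ + dispersion·μ² (dispersion 0.1 default;
  0 returns expectations — "noiseless" mode).  Counts are scattered
  multinomially over the valid fragment ends of each bin.
* **Genomes**: fragments planted back to back, each opening with the
  primary site and containing one interior secondary site, lengths spread
  geometrically around the requested mean; digesting the output recovers
  the requested valid-fragment count within ~10%.
* **Fusion**: `make_fused_landscape` joins A[0:breakA) to B[breakB:) at
  intra-TAD breakpoints (a break at an existing boundary is rejected); the
  junction itself carries no insulation, so the fused TAD spans from the
  last A boundary before the break to the first B boundary after it.

What the generator does **not** model: mappability and GC biases, PCR
duplicates, undigested/self-ligation background beyond the masked dead
zone, trans contacts, or cell-to-cell heterogeneity.  Passing tests
demonstrate the pipeline's internal correctness and its behaviour under
the stated noise model, not performance on any particular real library.

## Study-scale choices

The bundled experiments run at desk scale, sized to finish in minutes on
one CPU while keeping every stage of the real pipeline:

* *Loop recovery*: 200 bins × 2.5 kb, ~2,000 fragments, 10 loops of
  strength 4 anchored at a central viewpoint, coverage 10⁵, dispersion 0.1.
* *Boundary recovery*: 60-bin 3-TAD matrices, 20% multiplicative
  log-normal noise, top-2 consensus.
* *Structure recovery*: 100-bin 3-TAD landscape, noiseless counts, 8
  viewpoints, 2,000 models keeping 20.
* *Fused-TAD closure*: two 42-bin landscapes (5 kb bins) broken inside
  their central TADs, 9 viewpoints on the derivative, ~16 fragments per bin
  (~310 bp mean fragment, typical 4-cutter density), 300 models keeping 20,
  top-2 consensus with edge candidates excluded.

## Numerical notes and limitations

* Isotonic fits delegate to `scipy.optimize.isotonic_regression`; the test
  suite checks them against an exact brute-force block-enumeration oracle.
* DI window sums use direct slice summation so that exactly balanced bins
  give exactly DI = 0.
* Kabsch RMSD is computed from the explicitly rotated coordinates rather
  than the singular-value shortcut, avoiding cancellation near zero.
* The optimizer is a generic restraint minimiser, not a polymer-physics
  model: no persistence length, confinement or volume interactions beyond
  the pairwise lower bound; coordinates are in arbitrary units.
* Boundary localisation on virtual Hi-C is accurate to ~±1 bin; profile
  smoothing wider than a bin blurs insulation steps and can displace a
  called border by an additional bin.
* `side_fractions` measures the domain percentage within the flank window,
  keeping all percentages in [0, 100].
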