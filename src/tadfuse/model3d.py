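"""Restraint-based 3D modelling of a binned locus from 4C profiles.

Under the assumption that 4C-seq read counts are inversely related to the
spatial distance between the viewpoint and a fragment, multi-viewpoint 4C
profiles define a set of target distances.  Each significant bin receives a
harmonic restraint to its viewpoint bin, with the target mapped affinely
from the min-max-normalised binned signal s in [0, 1]:

    d_target = d_max - s * (d_max - d_min)

so the strongest signal maps to the closest distance.  Adjacent bins are
chained by connectivity restraints at d_min and all other pairs carry an
excluded-volume lower bound.  An ensemble of models is optimised from
random seeded starts, the top-scoring fraction is kept, the kept models are
clustered into the two mirror-image populations that distance-only
restraints cannot distinguish, and the most populated cluster yields the
"virtual Hi-C" mean-distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.optimize import minimize
from scipy.spatial.distance import squareform

from .boundaries import ContactMatrix

__all__ = [
    "RestraintSet",
    "Model3D",
    "EnsembleResult",
    "build_restraints",
    "optimize_model",
    "run_ensemble",
    "cluster_mirror",
    "virtual_hic",
    "kabsch_rmsd",
]

HARMONIC = "harmonic"
CONNECTIVITY = "connectivity"
EXCLUDED = "excluded"


@dataclass
class RestraintSet:
    """Pairwise restraints over ``n_particles`` bins.

    ``pairs`` columns: (i, j); ``targets`` is the harmonic/connectivity
    target distance or the excluded-volume lower bound; ``kinds`` per pair;
    ``k`` force constants.
    """

    n_particles: int
    pairs: np.ndarray       # (m, 2) int
    targets: np.ndarray     # (m,) float
    kinds: np.ndarray       # (m,) object/str
    k: np.ndarray           # (m,) float
    d_min: float = 1.0
    d_max: float = 100.0

    def __post_init__(self):
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        if not ((0 <= i) & (i < j) & (j < self.n_particles)).all():
            raise ValueError("restraint pairs must satisfy 0 <= i < j < n")


@dataclass
class Model3D:
    coords: np.ndarray      # (n, 3)
    score: float
    seed: int
    converged: bool = True


@dataclass
class EnsembleResult:
    models: list[Model3D]
    selected: list[int] = field(default_factory=list)
    clusters: dict[int, list[int]] = field(default_factory=dict)
    kept_cluster: int | None = None
    mirror_checked: bool = False
    vhic: ContactMatrix | None = None


def bin_profile(profile, region_start: int, region_end: int,
                bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Average a profile layer (smoothed, fallback raw) into bins.

    Returns (binned signal, binned max z); masked ends are skipped.
    """
    n_bins = int(np.ceil((region_end - region_start) / bin_size))
    sig = profile.smoothed if profile.smoothed is not None else profile.raw
    z = profile.z if profile.z is not None else np.zeros_like(sig)
    keep = ~profile.mask if profile.mask is not None else np.ones(
        sig.size, dtype=bool)
    e = profile.ends
    inside = keep & (e >= region_start) & (e < region_end)
    bins = (e[inside] - region_start) // bin_size
    out = np.zeros(n_bins)
    zmax = np.full(n_bins, -np.inf)
    cnt = np.zeros(n_bins)
    np.add.at(out, bins, sig[inside])
    np.add.at(cnt, bins, 1.0)
    np.maximum.at(zmax, bins, z[inside])
    nz = cnt > 0
    out[nz] /= cnt[nz]
    return out, zmax


def build_restraints(
    profiles: list,
    region: tuple[int, int],
    bin_size: int,
    d_min: float = 1.0,
    d_max: float = 100.0,
    z_cut: float | None = None,
    mapping: str = "inverse",
    k_harmonic: float = 1.0,
    k_connectivity: float = 1.0,
    k_excluded: float = 1.0,
    d_excluded: float | None = None,
) -> RestraintSet:
    """Turn binned multi-viewpoint 4C signal into a pairwise restraint set.

    Per viewpoint, every non-viewpoint bin with signal (optionally filtered
    by a Z-score cut when ``z_cut`` is given) gets a harmonic restraint to
    the viewpoint bin.  Two signal-to-distance maps are available:

    * ``"inverse"`` (default): d = clip(d_min * s_max / s, d_min, d_max) —
      the literal reading of counts being inversely proportional to
      distance, anchored so the strongest bin sits at d_min.  Targets from
      different viewpoints are mutually consistent up to the common
      coverage scale.
    * ``"affine"``: d = d_max - s_norm * (d_max - d_min) with s_norm the
      min-max-normalised signal — bounded by construction but compresses
      the heavy-tailed 4C signal toward d_max.

    Consecutive bins get connectivity restraints at d_min; all remaining
    pairs get the excluded-volume lower bound (default 2 * d_min).
    """
    start, end = region
    n_bins = int(np.ceil((end - start) / bin_size))
    if n_bins < 3:
        raise ValueError("region must span at least 3 bins")
    if mapping not in ("inverse", "affine"):
        raise ValueError("mapping must be 'inverse' or 'affine'")
    if d_excluded is None:
        d_excluded = 2.0 * d_min

    pairs: list[tuple[int, int]] = []
    targets: list[float] = []
    kinds: list[str] = []
    ks: list[float] = []
    restrained: set[tuple[int, int]] = set()

    for prof in profiles:
        vp = prof.viewpoint
        if not (start <= vp.position < end):
            raise ValueError(f"viewpoint {vp.name} outside modelled region")
        vp_bin = (vp.position - start) // bin_size
        sig, zmax = bin_profile(prof, start, end, bin_size)
        sel = (sig > 0) & (np.arange(n_bins) != vp_bin)
        if z_cut is not None:
            sel &= zmax > z_cut
        if not sel.any():
            continue
        smin, smax = sig[sel].min(), sig[sel].max()
        span = smax - smin
        for b in np.flatnonzero(sel):
            if mapping == "inverse":
                d = min(d_max, max(d_min, d_min * smax / sig[b]))
            else:
                s = (sig[b] - smin) / span if span > 0 else 1.0
                d = d_max - s * (d_max - d_min)
            i, j = (vp_bin, b) if vp_bin < b else (b, vp_bin)
            # Multiple viewpoints can restrain the same pair; energies add.
            pairs.append((i, j))
            targets.append(float(d))
            kinds.append(HARMONIC)
            ks.append(k_harmonic)
            restrained.add((int(i), int(j)))

    for b in range(n_bins - 1):
        pairs.append((b, b + 1))
        targets.append(d_min)
        kinds.append(CONNECTIVITY)
        ks.append(k_connectivity)
        restrained.add((b, b + 1))

    iu = np.triu_indices(n_bins, k=1)
    for i, j in zip(*iu):
        if (int(i), int(j)) not in restrained:
            pairs.append((int(i), int(j)))
            targets.append(float(d_excluded))
            kinds.append(EXCLUDED)
            ks.append(k_excluded)

    return RestraintSet(
        n_particles=n_bins,
        pairs=np.asarray(pairs, dtype=int),
        targets=np.asarray(targets, dtype=float),
        kinds=np.asarray(kinds, dtype=object),
        k=np.asarray(ks, dtype=float),
        d_min=d_min, d_max=d_max,
    )


def _energy_grad(x: np.ndarray, rs: RestraintSet,
                 harm: np.ndarray) -> tuple[float, np.ndarray]:
    n = rs.n_particles
    X = x.reshape(n, 3)
    i, j = rs.pairs[:, 0], rs.pairs[:, 1]
    diff = X[i] - X[j]
    d = np.sqrt((diff ** 2).sum(axis=1))
    d = np.maximum(d, 1e-12)
    delta = d - rs.targets
    # excluded-volume restraints only act when violated (d < lower bound)
    active = np.where(harm, True, delta < 0)
    w = rs.k * active
    energy = float((w * delta ** 2).sum())
    coef = (2.0 * w * delta / d)[:, None]
    g_pairs = coef * diff
    grad = np.empty_like(X)
    for dim in range(3):  # bincount is much faster than np.add.at here
        grad[:, dim] = (np.bincount(i, weights=g_pairs[:, dim], minlength=n)
                        - np.bincount(j, weights=g_pairs[:, dim], minlength=n))
    return energy, grad.ravel()


def optimize_model(rs: RestraintSet, seed: int, max_iter: int = 300,
                   n_anneal: int = 2) -> Model3D:
    """Minimise the restraint energy from a seeded random start.

    Coordinates start uniform in a cube of side ~ d_max * n^(1/3); the
    energy is minimised by L-BFGS descent with seeded annealing
    perturbation restarts, keeping the best state seen.  Deterministic
    given (restraints, seed).
    """
    rng = np.random.default_rng(seed)
    n = rs.n_particles
    side = rs.d_max * n ** (1.0 / 3.0)
    x0 = rng.uniform(-side / 2, side / 2, size=n * 3)
    harm = rs.kinds != EXCLUDED

    best_x, best_e = None, np.inf
    x = x0
    converged = False
    for round_ in range(n_anneal + 1):
        res = minimize(_energy_grad, x, args=(rs, harm), jac=True,
                       method="L-BFGS-B",
                       options={"maxiter": max_iter, "gtol": 1e-10,
                                "ftol": 1e-14})
        if res.fun < best_e:
            best_e, best_x = float(res.fun), res.x.copy()
            converged = bool(res.success) or res.status == 1
        if round_ < n_anneal:
            scale = rs.d_min * (0.5 ** round_)
            x = best_x + rng.normal(0.0, scale, size=best_x.shape)
    e0, _ = _energy_grad(x0, rs, harm)
    if best_e > e0:  # optimizer never worsens the starting state
        best_e, best_x = e0, x0
    return Model3D(coords=best_x.reshape(n, 3), score=best_e, seed=seed,
                   converged=converged)


def run_ensemble(rs: RestraintSet, n_models: int = 2000, n_keep: int = 20,
                 base_seed: int = 0, max_iter: int = 300,
                 n_anneal: int = 2) -> EnsembleResult:
    """Optimise ``n_models`` seeded models and keep the lowest-score subset.

    Seeds run base_seed .. base_seed + n_models - 1, so ensembles are
    reproducible regardless of execution order.
    """
    if n_keep > n_models:
        raise ValueError("n_keep must be <= n_models")
    models = [optimize_model(rs, base_seed + i, max_iter=max_iter,
                             n_anneal=n_anneal)
              for i in range(n_models)]
    order = np.argsort([m.score for m in models], kind="stable")
    selected = [int(i) for i in order[:n_keep]]
    return EnsembleResult(models=models, selected=selected)


def kabsch_rmsd(P: np.ndarray, Q: np.ndarray,
                allow_reflection: bool = False) -> float:
    """RMSD after optimal translation + proper rotation superposition.

    With ``allow_reflection`` the optimal improper rotation (mirror) is
    permitted — used only for the mirror diagnostic, never for clustering.
    """
    P = P - P.mean(axis=0)
    Q = Q - Q.mean(axis=0)
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    D = np.eye(3)
    if not allow_reflection and np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    resid = P @ R.T - Q
    return float(np.sqrt((resid ** 2).sum() / P.shape[0]))


def cluster_mirror(er: EnsembleResult) -> EnsembleResult:
    """Split the kept models into the two mirror-image populations.

    Pairwise RMSD uses proper-rotation superposition only, so enantiomers
    stay far apart; average-linkage clustering is cut at two clusters and
    the most populated kept (ties broken by lower medoid score).  The mirror
    relationship is verified by reflecting one medoid and re-superposing
    onto the other: the RMSD must drop by at least half.
    """
    sel = er.selected
    if len(sel) < 2:
        raise ValueError("need at least 2 selected models to cluster")
    coords = [er.models[i].coords for i in sel]
    m = len(sel)
    D = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            D[a, b] = D[b, a] = kabsch_rmsd(coords[a], coords[b])

    if D.max() < 1e-12:
        er.clusters = {0: list(sel)}
        er.kept_cluster = 0
        er.mirror_checked = False
        return er

    Z = average(squareform(D, checks=False))
    labels = fcluster(Z, t=2, criterion="maxclust") - 1
    clusters: dict[int, list[int]] = {}
    medoids: dict[int, int] = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        sub = D[np.ix_(members, members)]
        med_local = members[int(np.argmin(sub.sum(axis=1)))]
        clusters[int(lab)] = [sel[i] for i in members]
        medoids[int(lab)] = int(med_local)

    def keep_key(lab):
        med = er.models[sel[medoids[lab]]]
        return (-len(clusters[lab]), med.score)

    kept = min(clusters, key=keep_key)
    er.clusters = clusters
    er.kept_cluster = int(kept)

    if len(clusters) == 2:
        la, lb = sorted(clusters)
        A = coords[medoids[la]]
        B = coords[medoids[lb]]
        direct = kabsch_rmsd(A, B)
        reflected = kabsch_rmsd(A * np.array([1.0, 1.0, -1.0]), B)
        er.mirror_checked = direct > 0 and reflected <= 0.5 * direct
    return er


def virtual_hic(er: EnsembleResult, bin_size: int = 1,
                mode: str = "distance",
                origin: tuple[str, int] = ("region", 0)) -> ContactMatrix:
    """Mean pairwise-distance (or inverse-distance contact) matrix.

    Averaged over the kept cluster's models.  Contact mode returns
    1 / mean distance with the diagonal set to the maximum off-diagonal
    contact, suitable as DI input.
    """
    if er.kept_cluster is None or not er.clusters:
        raise ValueError("kept cluster not set; run cluster_mirror first")
    members = er.clusters[er.kept_cluster]
    if not members:
        raise ValueError("kept cluster is empty")
    mats = []
    for i in members:
        X = er.models[i].coords
        diff = X[:, None, :] - X[None, :, :]
        mats.append(np.sqrt((diff ** 2).sum(axis=2)))
    mean_d = np.mean(mats, axis=0)
    if mode == "distance":
        vals = mean_d
    elif mode == "contact":
        with np.errstate(divide="ignore"):
            vals = 1.0 / mean_d
        np.fill_diagonal(vals, 0.0)
        off_max = vals.max() if vals.size else 0.0
        np.fill_diagonal(vals, off_max)
    else:
        raise ValueError("mode must be 'distance' or 'contact'")
    er.vhic = ContactMatrix(values=vals, bin_size=bin_size, origin=origin)
    return er.vhic
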