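"""Per-term outlier scoring: distance matrix, spectral structure, scores.

For one ontology term, every pair of genomes gets a genetic distance by
summing zygosity-scaled functional distances over the term's profile
sites.  The resulting distance matrix is converted to a Gaussian-kernel
similarity graph; the spectrum of the symmetric normalised graph Laplacian
reveals whether the term's genetic landscape has hidden structure (the
largest eigengap), and if so K-means on the top Laplacian eigenvectors
recovers the clusters.

An individual's raw outlier score is the mean distance to everyone else
when the landscape has no structure.  With structure, the score is the sum
of a local term (mean distance to cluster co-members) and a global term
(mean distance to non-members) down-weighted by a cluster-size penalty

    mu = (exp(((n_cohort - n_cluster)/n_cohort) * gamma) - 1) / (exp(gamma) - 1)

so that large clusters contribute almost nothing globally (gamma = 9 gives
a >99% penalty for clusters holding over half the cohort).  Raw scores are
finally mapped to a universal [0, 1] scale comparable across terms:

    s_trans(p) = cbrt( exp(-phi * rank(p)/N)
                       * s(p)/sum(s)
                       * (s(p) - min s)/(max s - min s) )

with rank 0 for the top score, so the rank factor rewards the top ~2% when
phi = 150.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .functional_model import InputError, ZYGOSITY_FACTOR
from .term_profiles import TermProfile


@dataclass(frozen=True)
class ScoreParams:
    """Tunable scoring parameters.

    gamma
        Cluster-size penalty strength (dimensionless, > 0); default 9.
    phi
        Rank-contribution strength of the score transform (> 0); default 150.
    threshold
        Outlier-call threshold on the transformed score; default 0.022.
    rho
        Eigengap dominance ratio required to declare hidden structure.
    max_k
        Number of leading Laplacian eigenvalues inspected for the gap.
    bandwidth_rule
        Gaussian kernel bandwidth policy; only ``"median"`` (median
        off-diagonal distance) is currently implemented.
    min_cluster_size
        Clusters smaller than this are treated as stray outliers rather
        than structure and absorbed into the nearest remaining cluster
        before scoring.
    """

    gamma: float = 9.0
    phi: float = 150.0
    threshold: float = 0.022
    rho: float = 3.0
    max_k: int = 10
    bandwidth_rule: str = "median"
    min_cluster_size: int = 2

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.phi <= 0:
            raise InputError("gamma and phi must be > 0")
        if not (0.0 < self.threshold < 1.0):
            raise InputError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric all-vs-all genetic distances for one term."""

    individuals: tuple[str, ...]
    D: np.ndarray
    degenerate: bool = False  # empty profile -> all-zero matrix

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        n = len(self.individuals)
        if D.shape != (n, n):
            raise InputError(f"matrix shape {D.shape} != ({n}, {n})")
        if not np.all(np.isfinite(D)):
            raise InputError("distance matrix has non-finite entries")
        if not np.allclose(D, D.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise InputError("distance matrix diagonal is not zero")
        object.__setattr__(self, "D", D)

    @property
    def n(self) -> int:
        return len(self.individuals)

    def save(self, path) -> None:
        """Cache the matrix as a compressed npz container (one per term)."""
        np.savez_compressed(
            path, individuals=np.array(self.individuals), D=self.D,
            degenerate=self.degenerate,
        )

    @classmethod
    def load(cls, path) -> "DistanceMatrix":
        with np.load(path, allow_pickle=False) as data:
            return cls(
                individuals=tuple(str(i) for i in data["individuals"]),
                D=data["D"],
                degenerate=bool(data["degenerate"]),
            )


@dataclass(frozen=True)
class ClusterAssignment:
    """Outcome of spectral structure detection (and clustering if found)."""

    has_structure: bool
    eigenvalues: np.ndarray
    k: Optional[int] = None
    labels: Optional[np.ndarray] = None
    embedding: Optional[np.ndarray] = None

    def cluster_sizes(self) -> dict[int, int]:
        if self.labels is None:
            return {}
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))


@dataclass(frozen=True)
class OutlierScoreSet:
    """Raw and transformed per-individual scores for one term."""

    term_id: str
    individuals: tuple[str, ...]
    raw: np.ndarray
    local: np.ndarray
    global_: np.ndarray
    combinatorial: np.ndarray
    rank: np.ndarray
    transformed: np.ndarray
    has_structure: bool
    k: Optional[int] = None
    labels: Optional[np.ndarray] = None
    degenerate: bool = False

    @property
    def n(self) -> int:
        return len(self.individuals)

    def score_of(self, individual: str) -> float:
        return float(self.transformed[self.individuals.index(individual)])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def _factor_codes(g: np.ndarray) -> np.ndarray:
    """Normalise genotype codes: missing (-1) behaves as hom_ref (0)."""
    g = np.asarray(g)
    return np.where(g < 0, 0, g).astype(np.int8)


def pairwise_profile_distance(
    ga: np.ndarray, gb: np.ndarray, profile: TermProfile
) -> float:
    """Summed zygosity-scaled distance between two genotype vectors.

    Vectors hold dosage codes (0 hom_ref, 1 het, 2 hom_alt, -1 missing)
    aligned to ``profile.sites``.
    """
    ga, gb = _factor_codes(ga), _factor_codes(gb)
    if ga.shape != gb.shape or len(ga) != profile.n_sites:
        raise InputError(
            f"genotype vectors must both have length {profile.n_sites}"
        )
    d = np.asarray(profile.distances)
    return float(np.sum(d * ZYGOSITY_FACTOR[ga, gb]))


def build_distance_matrix(
    genotypes: np.ndarray,
    profile: TermProfile,
    individuals: Sequence[str],
) -> DistanceMatrix:
    """All-vs-all distance matrix from an (n individuals, n sites) matrix."""
    genotypes = np.asarray(genotypes)
    n = len(individuals)
    if n < 2:
        raise InputError("need at least 2 individuals")
    if genotypes.shape != (n, profile.n_sites):
        raise InputError(
            f"genotype matrix shape {genotypes.shape} != ({n}, {profile.n_sites})"
        )
    if profile.is_empty:
        return DistanceMatrix(tuple(individuals), np.zeros((n, n)), degenerate=True)
    g = _factor_codes(genotypes)
    d = np.asarray(profile.distances)
    D = np.zeros((n, n))
    for s in range(profile.n_sites):
        D += d[s] * ZYGOSITY_FACTOR[g[:, s][:, None], g[:, s][None, :]]
    return DistanceMatrix(tuple(individuals), D, degenerate=bool(np.all(D == 0)))


# ---------------------------------------------------------------------------
# Spectral structure
# ---------------------------------------------------------------------------

def gaussian_similarity(
    dm: DistanceMatrix, params: ScoreParams = ScoreParams()
) -> Optional[np.ndarray]:
    """Gaussian-kernel similarity ``exp(-D^2 / (2 sigma^2))``.

    The bandwidth sigma is the median off-diagonal distance (falling back
    to the mean when the median is zero).  Returns ``None`` when every
    off-diagonal distance is zero — the degenerate case in which the
    no-structure path applies and all scores vanish.
    """
    if params.bandwidth_rule != "median":
        raise InputError(f"unknown bandwidth rule {params.bandwidth_rule!r}")
    D = dm.D
    off = D[~np.eye(dm.n, dtype=bool)]
    sigma = float(np.median(off))
    if sigma == 0.0:
        sigma = float(np.mean(off))
    if sigma == 0.0:
        return None
    S = np.exp(-(D ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(S, 1.0)
    return S


def laplacian_spectrum(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the symmetric normalised graph Laplacian.

    Returns eigenvalues ascending and the matching eigenvectors as columns.
    """
    deg = S.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(S)) - (inv_sqrt[:, None] * S * inv_sqrt[None, :])
    L = (L + L.T) / 2.0  # enforce exact symmetry against roundoff
    eigvals, eigvecs = np.linalg.eigh(L)
    if not np.all(np.isfinite(eigvals)):
        raise ArithmeticError("non-finite Laplacian spectrum")
    return eigvals, eigvecs


def detect_structure(
    S: np.ndarray, params: ScoreParams = ScoreParams()
) -> tuple[bool, Optional[int], np.ndarray]:
    """Decide whether the similarity graph has hidden cluster structure.

    A disconnected similarity graph is structure by itself: the Laplacian
    eigenvalue zero has one multiplicity per connected component, so two or
    more near-zero eigenvalues fix ``k`` directly (capped at ``max_k``).
    Otherwise the gaps between consecutive eigenvalues among the first
    ``max_k`` are inspected: the candidate cluster number ``k`` is the
    position of the largest gap at ``k >= 2``, and structure is declared
    when that gap dominates — exceeds ``rho`` times the mean of the other
    gaps.  Cohorts below 6 individuals are never declared structured.

    Returns ``(has_structure, k, eigenvalues)``.
    """
    n = len(S)
    eigvals, _ = laplacian_spectrum(S)
    if n < 6:
        return False, None, eigvals
    n_components = int(np.sum(eigvals < 1e-8))
    if n_components >= 2:
        return True, min(n_components, params.max_k), eigvals
    K = min(params.max_k, n)
    lam = eigvals[:K]
    gaps = np.diff(lam)  # gaps[j] separates eigenvalues j+1 and j+2 => k = j+1
    if len(gaps) < 2:
        return False, None, eigvals
    candidate_j = 1 + int(np.argmax(gaps[1:]))  # restrict to k >= 2
    k = candidate_j + 1
    others = np.delete(gaps, candidate_j)
    mean_others = float(np.mean(others))
    dominant = gaps[candidate_j] > params.rho * mean_others
    if not dominant:
        return False, None, eigvals
    return True, k, eigvals


def _elbow_m(eigvals: np.ndarray, k: int, max_k: int) -> int:
    """Embedding dimension: elbow (max second difference) of the sorted
    eigenvalue curve, floored at k so K-means has enough coordinates."""
    lam = eigvals[: min(max_k, len(eigvals))]
    if len(lam) < 3:
        return k
    second = lam[2:] - 2.0 * lam[1:-1] + lam[:-2]  # index i covers eigenvalue i+1
    elbow = 1 + int(np.argmax(second))
    return max(k, elbow)


def embed_and_cluster(
    S: np.ndarray,
    k: int,
    params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> ClusterAssignment:
    """Spectral embedding plus K-means labels for ``k`` clusters.

    The embedding uses the eigenvectors of the ``m`` smallest Laplacian
    eigenvalues (``m`` by the elbow rule, at least ``k``), rows normalised
    to unit length.  K-means runs with 10 restarts from the given seed; in
    the (theoretical) event of an empty cluster the fit is repeated once
    with seed + 1.  Deterministic given the seed.
    """
    from sklearn.cluster import KMeans

    eigvals, eigvecs = laplacian_spectrum(S)
    m = _elbow_m(eigvals, k, params.max_k)
    X = eigvecs[:, :m]
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    X = X / norms

    labels: Optional[np.ndarray] = None
    for attempt_seed in (seed, seed + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=attempt_seed % (2**31))
        fit_labels = km.fit_predict(X)
        if len(np.unique(fit_labels)) == k:
            labels = fit_labels
            break
    if labels is None:
        labels = fit_labels  # accept the relocated solution
    return ClusterAssignment(
        has_structure=True, eigenvalues=eigvals, k=k, labels=labels, embedding=X
    )


def absorb_small_clusters(
    assignment: ClusterAssignment,
    dm: DistanceMatrix,
    min_size: int = 2,
) -> ClusterAssignment:
    """Fold below-minimum clusters into their nearest neighbour cluster.

    K-means on the spectral embedding can isolate single extreme genomes
    in clusters of their own; a lone genome is an outlier, not hidden
    structure.  Members of clusters smaller than ``min_size`` are
    reassigned to the cluster with the smallest mean distance to them (in
    the original distance space).  If fewer than two adequately sized
    clusters remain, the assignment degrades to no-structure.
    """
    if not assignment.has_structure or assignment.labels is None:
        return assignment
    labels = np.array(assignment.labels)
    values, counts = np.unique(labels, return_counts=True)
    keep = values[counts >= min_size]
    if len(keep) == len(values):
        return assignment
    if len(keep) < 2:
        return ClusterAssignment(
            has_structure=False, eigenvalues=assignment.eigenvalues
        )
    stray = np.flatnonzero(~np.isin(labels, keep))
    for i in stray:
        mean_dist = [dm.D[i, labels == c].mean() for c in keep]
        labels[i] = keep[int(np.argmin(mean_dist))]
    relabel = {c: j for j, c in enumerate(sorted(np.unique(labels).tolist()))}
    labels = np.array([relabel[c] for c in labels])
    return ClusterAssignment(
        has_structure=True,
        eigenvalues=assignment.eigenvalues,
        k=len(relabel),
        labels=labels,
        embedding=assignment.embedding,
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def size_penalty(size_cohort: int, size_cluster: int, gamma: float = 9.0) -> float:
    """Cluster-size penalty ``mu`` in [0, 1].

    mu = (exp(((size_cohort - size_cluster)/size_cohort) * gamma) - 1)
         / (exp(gamma) - 1)

    Strictly decreasing in the cluster size, with mu = 1 for an empty
    cluster and mu = 0 for a cluster spanning the whole cohort.
    """
    if gamma <= 0:
        raise InputError("gamma must be > 0")
    if not (0 <= size_cluster <= size_cohort):
        raise InputError(
            f"size_cluster {size_cluster} outside [0, size_cohort={size_cohort}]"
        )
    frac = (size_cohort - size_cluster) / size_cohort
    return float(np.expm1(frac * gamma) / np.expm1(gamma))


def raw_outlier_scores(
    dm: DistanceMatrix,
    assignment: Optional[ClusterAssignment],
    params: ScoreParams = ScoreParams(),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Raw scores with their local/global/combinatorial decomposition.

    Without structure the score of individual ``i`` is the arithmetic mean
    of its distances to everyone else (the batch is part of the background
    for each other).  With structure, ``score = local + mu * global`` where
    local is the mean distance to cluster co-members, global the mean
    distance to non-members and mu the size penalty of the individual's
    cluster.  The combinatorial component is the (clipped) excess of the
    clustered score over the unclustered mean-distance score: extra score
    an individual gains only because clustering reveals a variant rare
    within its own cluster.

    Returns ``(score, local, global, combinatorial)`` arrays.
    """
    D = dm.D
    n = dm.n
    if n < 2:
        raise InputError("need at least 2 individuals to score")
    mean_to_others = D.sum(axis=1) / (n - 1)

    if assignment is None or not assignment.has_structure:
        zeros = np.zeros(n)
        return mean_to_others, mean_to_others.copy(), zeros, zeros.copy()

    labels = assignment.labels
    local = np.zeros(n)
    global_ = np.zeros(n)
    score = np.zeros(n)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        outsiders = np.flatnonzero(labels != c)
        mu = size_penalty(n, len(members), params.gamma)
        for i in members:
            co = members[members != i]
            local[i] = D[i, co].mean() if len(co) else 0.0
            global_[i] = D[i, outsiders].mean() if len(outsiders) else 0.0
            score[i] = local[i] + mu * global_[i]
    combinatorial = np.maximum(0.0, score - mean_to_others)
    return score, local, global_, combinatorial


def transform_scores(
    term_id: str,
    individuals: Sequence[str],
    raw: np.ndarray,
    params: ScoreParams = ScoreParams(),
    *,
    local: Optional[np.ndarray] = None,
    global_: Optional[np.ndarray] = None,
    combinatorial: Optional[np.ndarray] = None,
    has_structure: bool = False,
    k: Optional[int] = None,
    labels: Optional[np.ndarray] = None,
) -> OutlierScoreSet:
    """Map raw scores to the universal [0, 1] scale.

    Ranks are 0-based descending (rank 0 = top raw score, rank factor 1),
    ties sharing the mean of their rank range.  If all scores are equal the
    min-max factor is zero for everyone: no one is an outlier.  An all-zero
    raw vector is flagged degenerate.
    """
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if n < 2:
        raise InputError("need at least 2 scores to transform")
    if np.any(raw < 0):
        raise InputError("raw scores must be nonnegative")
    zeros = np.zeros(n)
    local = zeros.copy() if local is None else np.asarray(local, float)
    global_ = zeros.copy() if global_ is None else np.asarray(global_, float)
    combinatorial = (
        zeros.copy() if combinatorial is None else np.asarray(combinatorial, float)
    )

    # descending 0-based mean-tie ranks
    rank = float(n) - rankdata(raw, method="average")

    total = raw.sum()
    degenerate = total == 0.0
    if degenerate:
        trans = zeros.copy()
    else:
        # exp(-(1 + r/N) phi) / exp(-phi) == exp(-phi r / N)
        rank_factor = np.exp(-params.phi * rank / n)
        share = raw / total
        spread = raw.max() - raw.min()
        minmax = (raw - raw.min()) / spread if spread > 0 else zeros.copy()
        trans = np.cbrt(rank_factor * share * minmax)

    return OutlierScoreSet(
        term_id=term_id,
        individuals=tuple(individuals),
        raw=raw,
        local=local,
        global_=global_,
        combinatorial=combinatorial,
        rank=rank,
        transformed=trans,
        has_structure=has_structure,
        k=k,
        labels=None if labels is None else np.asarray(labels),
        degenerate=degenerate,
    )


def score_term(
    profile: TermProfile,
    genotypes: np.ndarray,
    individuals: Sequence[str],
    params: ScoreParams = ScoreParams(),
    seed: int = 0,
) -> OutlierScoreSet:
    """Full per-term pipeline: distances -> spectrum -> clusters -> scores.

    Every individual in ``genotypes`` is scored against all the others, so
    a batch of subjects appended to a background cohort effectively joins
    the background.  Deterministic given the seed.
    """
    dm = build_distance_matrix(genotypes, profile, individuals)
    if dm.degenerate:
        n = dm.n
        return OutlierScoreSet(
            term_id=profile.term_id,
            individuals=tuple(individuals),
            raw=np.zeros(n),
            local=np.zeros(n),
            global_=np.zeros(n),
            combinatorial=np.zeros(n),
            rank=float(n) - rankdata(np.zeros(n), method="average"),
            transformed=np.zeros(n),
            has_structure=False,
            degenerate=True,
        )
    S = gaussian_similarity(dm, params)
    assignment: Optional[ClusterAssignment] = None
    if S is not None:
        has, k, _ = detect_structure(S, params)
        if has:
            assignment = embed_and_cluster(S, k, params, seed=seed)
            assignment = absorb_small_clusters(
                assignment, dm, params.min_cluster_size
            )
            if not assignment.has_structure:
                assignment = None
    score, local, global_, comb = raw_outlier_scores(dm, assignment, params)
    return transform_scores(
        profile.term_id,
        individuals,
        score,
        params,
        local=local,
        global_=global_,
        combinatorial=comb,
        has_structure=assignment is not None,
        k=None if assignment is None else assignment.k,
        labels=None if assignment is None else assignment.labels,
    )
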