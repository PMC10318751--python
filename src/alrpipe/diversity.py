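"""Alpha and beta diversity with group tests.

Alpha: Shannon H' and inverse Simpson per sample, compared between the two
populations with a Mann-Whitney U test (exact by enumeration for small
groups, midrank/tie-corrected normal approximation otherwise).  Beta:
Bray-Curtis dissimilarity, nonmetric multidimensional scaling (Kruskal
stress-1 minimized by isotonic regression + SMACOF updates over random
restarts), and PERMANOVA on the first two ordination dimensions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata


class DiversityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# alpha diversity


def _proportions(abundances: np.ndarray) -> np.ndarray:
    x = np.asarray(abundances, dtype=float)
    if x.ndim != 1:
        raise DiversityError("expected a 1-D abundance vector")
    if np.any(x < 0):
        raise DiversityError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise DiversityError("all-zero abundance vector")
    return x / total


def shannon(abundances: np.ndarray) -> float:
    """Shannon H' = -sum p_i ln p_i over positive proportions."""
    p = _proportions(abundances)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def inv_simpson(abundances: np.ndarray) -> float:
    """Inverse Simpson index 1 / sum p_i^2."""
    p = _proportions(abundances)
    return float(1.0 / (p ** 2).sum())


def mann_whitney_u(group_a: np.ndarray, group_b: np.ndarray,
                   exact_limit: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact p by full enumeration of the C(n, n_a) group assignments when
    both groups have at most ``exact_limit`` members; otherwise a normal
    approximation with tie and continuity corrections.  Returns
    ``(U_a, p)`` where ``U_a`` is the statistic for the first group.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise DiversityError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    mu = na * nb / 2.0

    if na <= exact_limit and nb <= exact_limit:
        # null distribution of U_a over all assignments of pooled ranks
        n = na + nb
        obs_dev = abs(u_a - mu)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            u = ranks[list(combo)].sum() - na * (na + 1) / 2
            total += 1
            if abs(u - mu) >= obs_dev - 1e-9:
                count += 1
        return u_a, count / total

    # tie-corrected normal approximation with continuity correction
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
    var = na * nb / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / np.sqrt(var)
    return u_a, float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


@dataclass
class AlphaResult:
    index_name: str
    per_sample_index: np.ndarray
    group_test_statistic: float
    group_test_pvalue: float


def alpha_diversity(abundance_matrix: np.ndarray, labels: np.ndarray,
                    index: str = "shannon") -> AlphaResult:
    """Per-sample alpha index plus the between-population rank-sum test."""
    fn = {"shannon": shannon, "inv_simpson": inv_simpson}.get(index)
    if fn is None:
        raise DiversityError(f"unknown index {index!r}")
    X = np.asarray(abundance_matrix, dtype=float)
    vals = np.array([fn(row) for row in X])
    labels = np.asarray(labels)
    la, lb = sorted(set(map(str, labels)))
    u, p = mann_whitney_u(vals[labels.astype(str) == la],
                          vals[labels.astype(str) == lb])
    return AlphaResult(index_name=index, per_sample_index=vals,
                       group_test_statistic=u, group_test_pvalue=p)


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(X: np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity matrix: sum|x-y| / sum(x+y) per pair."""
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise DiversityError("abundances must be non-negative")
    if np.any(X.sum(axis=1) <= 0):
        raise DiversityError("all-zero sample row")
    return squareform(pdist(X, metric="braycurtis"))


def pava(y: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators: weighted least-squares non-decreasing fit."""
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    means: list[float] = []
    wsums: list[float] = []
    sizes: list[int] = []
    for yi, wi in zip(y, w):
        means.append(yi)
        wsums.append(wi)
        sizes.append(1)
        while len(means) > 1 and means[-2] >= means[-1]:
            m1, w1, s1 = means.pop(), wsums.pop(), sizes.pop()
            m0, w0, s0 = means.pop(), wsums.pop(), sizes.pop()
            means.append((m0 * w0 + m1 * w1) / (w0 + w1))
            wsums.append(w0 + w1)
            sizes.append(s0 + s1)
    return np.repeat(means, sizes)


_pava_blocks = pava


@dataclass
class NMDSConfig:
    coordinates: np.ndarray
    stress: float
    converged: bool
    n_restarts_used: int


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[idx], 0, None)
    return vecs[:, idx] * np.sqrt(lam)


def stress1(D: np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Disparities are the isotonic regression of configuration distances on
    the rank order of the dissimilarities.
    """
    delta = squareform(np.asarray(D, dtype=float), checks=False)
    d = pdist(np.asarray(coordinates, dtype=float))
    order = np.argsort(delta, kind="stable")
    dhat = np.empty_like(d)
    dhat[order] = _pava_blocks(d[order])
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dhat - d) ** 2).sum() / denom))


def nmds(D: np.ndarray, k: int = 2, max_iter: int = 300, n_restarts: int = 20,
         seed: int = 0, tol: float = 1e-6) -> NMDSConfig:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Restart 0 starts from the classical-scaling configuration; further
    restarts start from random Gaussian configurations.  Each iteration
    computes disparities by isotonic regression of configuration distances
    on the dissimilarity ranks and applies a Guttman (SMACOF) update.
    The best configuration across restarts is returned.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise DiversityError("D must be square")
    if k < 1:
        raise DiversityError("k must be >= 1")
    delta = squareform(D, checks=False)
    order = np.argsort(delta, kind="stable")
    rng = np.random.default_rng(seed)

    best: NMDSConfig | None = None
    for restart in range(max(1, n_restarts)):
        if restart == 0:
            X = _classical_mds(D, k)
            if np.allclose(X, 0):
                X = rng.normal(size=(n, k))
        else:
            X = rng.normal(size=(n, k))
        prev_stress = np.inf
        converged = False
        for _ in range(max_iter):
            d = pdist(X)
            d = np.where(d == 0, 1e-12, d)
            dhat = np.empty_like(d)
            dhat[order] = _pava_blocks(d[order])
            # scale disparities to the configuration's size
            scale = np.sqrt((d ** 2).sum() / max((dhat ** 2).sum(), 1e-300))
            dhat_s = dhat * scale
            stress = np.sqrt(((dhat_s - d) ** 2).sum() / (d ** 2).sum())
            if prev_stress - stress < tol * max(prev_stress, 1e-12):
                converged = True
                break
            prev_stress = stress
            # Guttman transform with disparities dhat_s
            ratio = squareform(dhat_s / d, checks=False)
            B = -ratio
            np.fill_diagonal(B, ratio.sum(axis=1))
            X = B @ X / n
        final_stress = stress1(D, X)
        cand = NMDSConfig(coordinates=X, stress=final_stress,
                          converged=converged, n_restarts_used=restart + 1)
        if best is None or final_stress < best.stress:
            best = cand
    best.n_restarts_used = max(1, n_restarts)
    return best


@dataclass
class PermanovaResult:
    pseudo_f: float
    p_value: float
    n_permutations: int


def permanova(coords: np.ndarray, labels: np.ndarray,
              n_permutations: int = 999, seed: int = 0) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean coordinates (e.g. NMDS loadings).

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)); the p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)`` over random label
    permutations.
    """
    import warnings as _warnings
    X = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(map(str, labels)))
    if len(levels) != 2:
        raise DiversityError("exactly two groups required")
    g1 = labels.astype(str) == levels[0]
    n1, n = int(g1.sum()), X.shape[0]
    if n1 < 2 or n - n1 < 2:
        raise DiversityError("each group needs at least 2 samples")
    if n_permutations < 99:
        _warnings.warn("fewer than 99 permutations gives poor p-value "
                       "resolution", stacklevel=2)
    Xc = X - X.mean(axis=0)
    total = (Xc ** 2).sum()
    colsum = Xc.sum(axis=0)  # = 0 after centering

    def _ss_between(mask_sum: np.ndarray) -> float:
        s1 = mask_sum
        s2 = colsum - s1
        return (s1 ** 2).sum() / n1 + (s2 ** 2).sum() / (n - n1)

    def _f(ssb: float) -> float:
        ssw = total - ssb
        if ssw <= 1e-300:
            return 0.0 if ssb <= 1e-300 else np.inf
        return (ssb / 1.0) / (ssw / (n - 2))

    obs_ssb = _ss_between(Xc[g1].sum(axis=0))
    f_obs = _f(obs_ssb)
    if total <= 1e-300:
        return PermanovaResult(pseudo_f=0.0, p_value=1.0,
                               n_permutations=n_permutations)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        idx = rng.permutation(n)[:n1]
        if _f(_ss_between(Xc[idx].sum(axis=0))) >= f_obs - 1e-12:
            count += 1
    return PermanovaResult(pseudo_f=float(f_obs),
                           p_value=(1 + count) / (1 + n_permutations),
                           n_permutations=n_permutations)
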