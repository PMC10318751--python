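"""From-scratch two-class PLS-DA with Mahalanobis-distance classification.

Implements the NIPALS component extraction on a centered dummy-coded
response, nearest-centroid classification in score space under the pooled
within-class score covariance, the balanced error rate, repeated stratified
cross-validation for component tuning, VIP scoring, the iterative
VIP-threshold feature-selection loop, and the two confusion-matrix
validations (plain and label-permuted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


class PLSDAError(ValueError):
    pass


@dataclass
class PLSDAFit:
    """Fitted PLS-DA model for two classes."""

    classes: np.ndarray                 # the two labels, sorted
    n_components: int
    x_mean: np.ndarray                  # training column means (p,)
    x_weights: np.ndarray               # W, (p, k)
    x_scores: np.ndarray                # T, (n, k)
    x_loadings: np.ndarray              # P, (p, k)
    y_loadings: np.ndarray              # C, (2, k)
    rotations: np.ndarray               # R = W (P'W)^-1, (p, k)
    explained_y_variance: np.ndarray    # SS_h per component, (k,)
    class_centroids: np.ndarray         # (2, k) mean scores per class
    within_class_score_covariance: np.ndarray  # (k, k) pooled
    training_feature_ids: list[str] | None = None
    training_scale_state: str = "autoscaled"


@dataclass
class CVResult:
    ber_by_component: np.ndarray
    chosen_components: int
    fold_count: int
    repeat_count: int
    per_class_classification_rate: np.ndarray  # (2,), class order = sorted labels


@dataclass
class ConfusionSummary:
    """Mean 2x2 confusion counts over CV repeats (rows true, cols predicted,
    positive class first)."""

    matrix: np.ndarray
    accuracy: float
    precision: float
    true_positive_class: str
    per_class_rate: np.ndarray  # correct-classification rate per true class


# ---------------------------------------------------------------------------
# fitting


def _dummy_code(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes = np.unique(np.asarray(y))
    if classes.size != 2:
        raise PLSDAError(f"exactly two classes required, got {classes.size}")
    Y = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
    return classes, Y


def fit_plsda(X: np.ndarray, y: np.ndarray, n_components: int,
              feature_ids: list[str] | None = None) -> PLSDAFit:
    """Fit a two-class PLS-DA model by NIPALS.

    ``y`` is dummy-coded into one centered indicator column per class;
    components are extracted iteratively as the dominant covariance
    direction between the deflated X and Y blocks.  Class centroids and
    the pooled within-class covariance of training scores are stored for
    Mahalanobis classification; per-component explained Y variance feeds
    the VIP computation.  If X runs out of rank before ``n_components``
    the fit stops early with a warning.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components < 1:
        raise PLSDAError("n_components must be >= 1")
    if n_components > min(n - 1, p):
        raise PLSDAError(f"n_components={n_components} exceeds min(n-1, p)="
                         f"{min(n - 1, p)}")
    classes, Y = _dummy_code(y)
    x_mean = X.mean(axis=0)
    Xd = X - x_mean
    Yd = Y - Y.mean(axis=0)

    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    C = np.zeros((2, n_components))
    ss = np.zeros(n_components)
    k = 0
    for h in range(n_components):
        M = Xd.T @ Yd                       # (p, 2)
        u, s, _ = np.linalg.svd(M, full_matrices=False)
        if s[0] < 1e-12:
            warnings.warn(f"rank deficiency: only {k} components extractable",
                          stacklevel=2)
            break
        w = u[:, 0]
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            warnings.warn(f"rank deficiency: only {k} components extractable",
                          stacklevel=2)
            break
        c = Yd.T @ t / tt
        pl = Xd.T @ t / tt
        Xd = Xd - np.outer(t, pl)
        Yd = Yd - np.outer(t, c)
        W[:, h], T[:, h], P[:, h], C[:, h] = w, t, pl, c
        ss[h] = tt * (c @ c)                # Y variance captured by component h
        k += 1
    W, T, P, C, ss = W[:, :k], T[:, :k], P[:, :k], C[:, :k], ss[:k]
    R = W @ np.linalg.inv(P.T @ W)

    centroids = np.vstack([T[np.asarray(y) == cls].mean(axis=0) for cls in classes])
    cov = _pooled_within_cov(T, np.asarray(y), classes)
    return PLSDAFit(classes=classes, n_components=k, x_mean=x_mean,
                    x_weights=W, x_scores=T, x_loadings=P, y_loadings=C,
                    rotations=R, explained_y_variance=ss,
                    class_centroids=centroids,
                    within_class_score_covariance=cov,
                    training_feature_ids=feature_ids)


def _pooled_within_cov(T: np.ndarray, y: np.ndarray, classes: np.ndarray
                       ) -> np.ndarray:
    n, k = T.shape
    S = np.zeros((k, k))
    for cls in classes:
        Tc = T[y == cls]
        S += (Tc - Tc.mean(axis=0)).T @ (Tc - Tc.mean(axis=0))
    dof = max(n - classes.size, 1)
    return S / dof


def _regularized_inverse(S: np.ndarray) -> np.ndarray:
    k = S.shape[0]
    ridge = 1e-8 * np.trace(S) / k
    try:
        cond = np.linalg.cond(S)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e10:
        S = S + max(ridge, 1e-12) * np.eye(k)
    return np.linalg.inv(S)


def predict(fit: PLSDAFit, X_new: np.ndarray, n_components: int | None = None
            ) -> np.ndarray:
    """Assign each row of ``X_new`` to the Mahalanobis-nearest class centroid.

    Ties break deterministically to the first class in sorted label order.
    ``n_components`` truncates the fitted model (used during CV tuning).
    """
    k = fit.n_components if n_components is None else n_components
    if not 1 <= k <= fit.n_components:
        raise PLSDAError("invalid component truncation")
    T = (np.asarray(X_new, dtype=float) - fit.x_mean) @ fit.rotations[:, :k]
    Sinv = _regularized_inverse(fit.within_class_score_covariance[:k, :k])
    d = np.empty((T.shape[0], 2))
    for g in range(2):
        diff = T - fit.class_centroids[g, :k]
        d[:, g] = np.einsum("ij,jk,ik->i", diff, Sinv, diff)
    # argmin returns the first (sorted-order) class on exact ties
    return fit.classes[np.argmin(d, axis=1)]


def balanced_error_rate(true_labels: np.ndarray, predicted_labels: np.ndarray
                        ) -> float:
    """Mean over classes of the per-class misclassification proportion."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise PLSDAError("label vectors must have equal length")
    classes = np.unique(t)
    if classes.size != 2:
        raise PLSDAError("both classes must be present in true_labels")
    errs = [np.mean(p[t == cls] != cls) for cls in classes]
    return float(np.mean(errs))


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator
                      ) -> np.ndarray:
    """Fold assignment per sample; every class spread across all folds."""
    y = np.asarray(y)
    assign = np.empty(y.shape[0], dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if idx.size < folds:
            raise PLSDAError(
                f"class {cls!r} has {idx.size} samples; cannot stratify "
                f"into {folds} folds")
        rng.shuffle(idx)
        assign[idx] = np.arange(idx.size) % folds
    return assign


def cross_validate(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                   folds: int = 4, repeats: int = 100, seed: int = 0
                   ) -> CVResult:
    """Mean out-of-fold BER per candidate component count.

    Each repeat draws fresh stratified folds; models are refit inside every
    training fold with the maximal component count and evaluated at every
    truncation 1..max.  The chosen component count minimizes the mean BER,
    ties going to fewer components.  Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise PLSDAError("folds must be >= 2")
    n, p = X.shape
    kmax = min(max_components, n - int(np.ceil(n / folds)) - 1, p)
    kmax = max(kmax, 1)
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(repeats)]
    ber = np.zeros((repeats, kmax))
    correct = np.zeros((repeats, kmax, 2))
    classes = np.unique(y)
    for r, rng in enumerate(rngs):
        assign = _stratified_folds(y, folds, rng)
        pred = np.empty((kmax, n), dtype=object)
        for f in range(folds):
            test = assign == f
            fit = fit_plsda(X[~test], y[~test],
                            min(kmax, (~test).sum() - 1, p))
            for h in range(kmax):
                pred[h, test] = predict(fit, X[test], min(h + 1, fit.n_components))
        for h in range(kmax):
            ber[r, h] = balanced_error_rate(y, pred[h].astype(y.dtype))
            for g, cls in enumerate(classes):
                correct[r, h, g] = np.mean(pred[h][y == cls] == cls)
    mean_ber = ber.mean(axis=0)
    chosen = int(np.argmin(mean_ber))       # first minimum = fewest components
    return CVResult(ber_by_component=mean_ber, chosen_components=chosen + 1,
                    fold_count=folds, repeat_count=repeats,
                    per_class_classification_rate=correct[:, chosen].mean(axis=0))


# ---------------------------------------------------------------------------
# VIP and the selection loop


def vip(fit: PLSDAFit) -> np.ndarray:
    """Variable importance in projection; satisfies sum(VIP^2) == p."""
    if fit.n_components < 1:
        raise PLSDAError("fit has no components")
    ss = fit.explained_y_variance
    if ss.sum() <= 0:
        raise PLSDAError("zero total explained Y variance")
    W = fit.x_weights
    wn2 = (W / np.linalg.norm(W, axis=0)) ** 2
    p = W.shape[0]
    return np.sqrt(p * (wn2 @ ss) / ss.sum())


@dataclass
class IterationRecord:
    iteration: int
    n_features: int
    n_components: int
    ber: float


def iterative_selection(X: np.ndarray, y: np.ndarray, feature_ids: list[str],
                        ber_target: float = 0.02, max_components: int = 10,
                        folds: int = 4, repeats: int = 100, seed: int = 0,
                        vip_threshold: float = 1.0, max_iterations: int = 50,
                        ) -> tuple[PLSDAFit, list[str], list[IterationRecord]]:
    """The iterative VIP-based feature-selection loop.

    Per iteration: tune the component count by repeated stratified CV, fit
    the full-data model at that count, and retain features with VIP above
    ``vip_threshold``.  Stops when the CV BER drops below ``ber_target``,
    when it fails to improve on the previous iteration (the previous
    model is returned), or when the selected set stops changing.
    """
    if not 0.0 <= ber_target < 1.0:
        raise PLSDAError("ber_target must lie in [0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    ids = list(feature_ids)
    seeds = np.random.SeedSequence(seed).spawn(max_iterations)
    log: list[IterationRecord] = []
    prev: tuple[PLSDAFit, list[str], float] | None = None
    for it in range(max_iterations):
        kmax = min(max_components, X.shape[0] - 1, X.shape[1])
        cv = cross_validate(X, y, kmax, folds, repeats,
                            seed=seeds[it].generate_state(1)[0])
        fit = fit_plsda(X, y, cv.chosen_components, feature_ids=ids)
        ber = float(cv.ber_by_component[cv.chosen_components - 1])
        log.append(IterationRecord(it, len(ids), fit.n_components, ber))
        if prev is not None and ber >= prev[2]:
            return prev[0], prev[1], log       # no improvement: keep previous
        prev = (fit, ids, ber)
        if ber < ber_target:
            return fit, ids, log
        scores = vip(fit)
        keep = scores > vip_threshold
        if not keep.any():
            warnings.warn("VIP selection emptied the feature set; "
                          "returning the current model", stacklevel=2)
            return fit, ids, log
        if keep.all():
            return fit, ids, log               # selected set unchanged
        X = X[:, keep]
        ids = [f for f, k_ in zip(ids, keep) if k_]
    return prev[0], prev[1], log


# ---------------------------------------------------------------------------
# confusion-matrix validations


def _confusion_over_repeats(X: np.ndarray, y: np.ndarray, n_components: int,
                            positive_class: str, folds: int, repeats: int,
                            seed: int, permute: bool) -> ConfusionSummary:
    X = np.asarray(X, dtype=float)
    y_true = np.asarray(y)
    classes = np.unique(y_true)
    if positive_class not in classes:
        raise PLSDAError(f"positive class {positive_class!r} not present")
    order = [positive_class] + [c for c in classes if c != positive_class]
    rngs = [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(repeats)]
    total = np.zeros((2, 2))
    for rng in rngs:
        y_fit = rng.permutation(y_true) if permute else y_true
        assign = _stratified_folds(y_fit, folds, rng)
        pred = np.empty(y_fit.shape[0], dtype=object)
        for f in range(folds):
            test = assign == f
            k = min(n_components, (~test).sum() - 1, X.shape[1])
            fit = fit_plsda(X[~test], y_fit[~test], k)
            pred[test] = predict(fit, X[test])
        for i, ti in enumerate(order):
            for j, pj in enumerate(order):
                total[i, j] += np.sum((y_fit == ti) & (pred == pj))
    mean_mat = total / repeats
    n = mean_mat.sum()
    accuracy = float(np.trace(mean_mat) / n)
    denom = mean_mat[:, 0].sum()
    precision = float(mean_mat[0, 0] / denom) if denom > 0 else 0.0
    row = mean_mat.sum(axis=1)
    per_class = np.divide(np.diag(mean_mat), row, out=np.zeros(2),
                          where=row > 0)
    return ConfusionSummary(matrix=mean_mat, accuracy=accuracy,
                            precision=precision,
                            true_positive_class=positive_class,
                            per_class_rate=per_class)


def confusion_matrix_cv(X, y, n_components: int, positive_class: str,
                        folds: int = 4, repeats: int = 10_000, seed: int = 0
                        ) -> ConfusionSummary:
    """Mean out-of-fold confusion matrix over repeated stratified CV."""
    return _confusion_over_repeats(X, y, n_components, positive_class,
                                   folds, repeats, seed, permute=False)


def permuted_confusion(X, y, n_components: int, positive_class: str,
                       folds: int = 4, repeats: int = 10_000,
                       permutation_seed: int = 0) -> ConfusionSummary:
    """Confusion matrix with the class labels permuted once per repeat.

    A non-spurious model scores near the two-class chance level (50%)
    here; class counts are preserved exactly by the permutation.
    """
    return _confusion_over_repeats(X, y, n_components, positive_class,
                                   folds, repeats, permutation_seed,
                                   permute=True)
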