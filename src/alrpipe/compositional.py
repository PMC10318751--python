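"""Count table -> analysis-ready additive log-ratio (ALR) matrix.

Stages: PCA-based outlier-sample removal, zero-fraction feature filtering
with a presence/absence exception, pseudocount, automatic reference-feature
selection (lowest CV of log-counts among high-abundance candidates, gated
by a Procrustes isometry check against the full log-ratio geometry), the
ALR transform itself, and per-column auto-scaling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .tables import ALRTable, CountTable, TableError


class CompositionError(ValueError):
    pass


@dataclass
class ReferenceDiagnostics:
    """Per-candidate evidence gathered during reference selection."""

    candidate_id: str
    cv_log_abundance: float
    total_abundance: float
    procrustes_correlation: float  # NaN when the candidate was not examined


# ---------------------------------------------------------------------------
# filtering


def filter_features(table: CountTable, zero_fraction_threshold: float = 0.2,
                    zero_diff_threshold: float = 0.5) -> CountTable:
    """Drop features with too many zeros, keeping presence/absence signals.

    A feature is removed when its zero-fraction is at least
    ``zero_fraction_threshold`` within either population or overall, unless
    the absolute between-population difference in zero-fraction exceeds
    ``zero_diff_threshold`` (such features carry group signal in their
    zeros and are retained).  Feature order is preserved.
    """
    for thr in (zero_fraction_threshold, zero_diff_threshold):
        if not 0.0 <= thr <= 1.0:
            raise CompositionError("thresholds must lie in [0, 1]")
    zero = table.counts == 0
    masks = table.group_masks()
    (la, ma), (lb, mb) = sorted(masks.items())
    zf_total = zero.mean(axis=0)
    zf_a = zero[ma].mean(axis=0)
    zf_b = zero[mb].mean(axis=0)
    too_many = ((zf_total >= zero_fraction_threshold)
                | (zf_a >= zero_fraction_threshold)
                | (zf_b >= zero_fraction_threshold))
    informative = np.abs(zf_a - zf_b) > zero_diff_threshold
    keep = ~too_many | informative
    if not keep.any():
        raise CompositionError(
            "zero-filtering removed every feature; relax the thresholds")
    return table.select_features(keep)


def add_pseudocount(table: CountTable, c: int = 1) -> CountTable:
    """Add ``c`` (>= 1) to every entry so no zeros remain."""
    if c < 1:
        raise CompositionError("pseudocount must be >= 1")
    return dataclasses.replace(table, counts=table.counts + int(c))


# ---------------------------------------------------------------------------
# outlier removal


def _pc_scores(counts: np.ndarray, k: int = 2) -> np.ndarray:
    """First ``k`` principal-component scores of log(counts + 1)."""
    X = np.log(counts + 1.0)
    Xc = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return (u * s)[:, :k]


def pca_outlier_removal(table: CountTable, sd_multiplier: float = 3.0
                        ) -> tuple[CountTable, list[str]]:
    """Remove samples far from their own population's PC1/PC2 centroid.

    A sample is flagged when its score on either of the first two principal
    components of the log-count matrix lies more than ``sd_multiplier``
    within-population SDs from the population centroid.  One repeat pass is
    run if the first pass removed anything.
    """
    for lvl, m in table.group_masks().items():
        if m.sum() < 3:
            raise CompositionError(f"population {lvl!r} has fewer than 3 samples")
    removed: list[str] = []
    current = table
    for _ in range(2):
        scores = _pc_scores(current.counts)
        flag = np.zeros(current.n_samples, dtype=bool)
        for _, mask in current.group_masks().items():
            centroid = scores[mask].mean(axis=0)
            sd = scores[mask].std(axis=0, ddof=1)
            sd[sd == 0] = np.inf
            dev = np.abs(scores - centroid) / sd
            flag |= mask & (dev > sd_multiplier).any(axis=1)
        if not flag.any():
            break
        keep = ~flag
        for lvl, mask in current.group_masks().items():
            if (mask & keep).sum() < 3:
                raise CompositionError(
                    f"outlier removal would leave fewer than 3 samples in {lvl!r}")
        removed += [s for s, f in zip(current.sample_ids, flag) if f]
        current = current.select_samples(keep)
    return current, removed


# ---------------------------------------------------------------------------
# Procrustes isometry diagnostic


def procrustes_correlation(config_a: np.ndarray, config_b: np.ndarray) -> float:
    """Similarity of two point configurations after optimal superposition.

    Both configurations are centered and unit-normalized; ``config_b`` is
    then optimally rotated/scaled onto ``config_a``.  The statistic is
    ``sqrt(1 - m2)`` where ``m2`` is the normalized residual sum of
    squares, i.e. the sum of singular values of the cross-product matrix;
    1 means perfectly isometric.  Symmetric in its arguments.
    """
    a = np.atleast_2d(np.asarray(config_a, dtype=float))
    b = np.atleast_2d(np.asarray(config_b, dtype=float))
    if a.shape[0] != b.shape[0]:
        raise CompositionError("configurations must have the same number of points")
    width = max(a.shape[1], b.shape[1])
    a = np.pad(a, ((0, 0), (0, width - a.shape[1])))
    b = np.pad(b, ((0, 0), (0, width - b.shape[1])))
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise CompositionError("degenerate configuration: all points identical")
    s = np.linalg.svd(a.T @ b / (na * nb), compute_uv=False).sum()
    return float(min(1.0, s))


def _pcoa_config(values: np.ndarray) -> np.ndarray:
    """Principal-coordinate configuration (PCA scores) of a real matrix."""
    vc = values - values.mean(axis=0)
    u, s, _ = np.linalg.svd(vc, full_matrices=False)
    return u * s


def _clr(counts: np.ndarray) -> np.ndarray:
    logx = np.log(counts)
    return logx - logx.mean(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# reference selection and the transform


def select_reference(table: CountTable, abundance_quantile: float = 0.75,
                     procrustes_threshold: float = 0.9,
                     force: str | None = None,
                     ) -> tuple[str, list[ReferenceDiagnostics]]:
    """Pick the ALR reference feature.

    Candidates are features whose total abundance reaches the
    ``abundance_quantile`` of the per-feature abundance distribution,
    ranked by ascending coefficient of variation of log-counts.  The
    best-ranked candidate whose ALR geometry has Procrustes correlation
    above ``procrustes_threshold`` with the centered log-ratio geometry of
    the same data is returned, along with diagnostics for every candidate
    (unexamined candidates carry a NaN correlation).  Passing ``force``
    skips the search and reports diagnostics for that feature only.
    """
    counts = table.counts
    if np.any(counts <= 0):
        raise CompositionError("reference selection requires a zero-free table "
                               "(apply add_pseudocount first)")
    logx = np.log(counts.astype(float))
    mean_log = logx.mean(axis=0)
    sd_log = logx.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_log > 0, sd_log / mean_log, np.inf)
    total = counts.sum(axis=0).astype(float)
    clr_config = _pcoa_config(_clr(counts))

    def _corr_for(j: int) -> float:
        alr = logx - logx[:, [j]]
        alr = np.delete(alr, j, axis=1)
        return procrustes_correlation(_pcoa_config(alr), clr_config)

    if force is not None:
        j = table.feature_ids.index(force)
        diag = ReferenceDiagnostics(force, float(cv[j]), float(total[j]), _corr_for(j))
        return force, [diag]

    cutoff = np.quantile(total, abundance_quantile)
    candidates = [j for j in np.argsort(cv, kind="stable") if total[j] >= cutoff]
    if not candidates:
        raise CompositionError("no high-abundance candidate features")

    diagnostics = [ReferenceDiagnostics(table.feature_ids[j], float(cv[j]),
                                        float(total[j]), np.nan)
                   for j in candidates]
    chosen: str | None = None
    best_corr = -np.inf
    for rank, j in enumerate(candidates):
        corr = _corr_for(j)
        diagnostics[rank] = dataclasses.replace(diagnostics[rank],
                                                procrustes_correlation=corr)
        best_corr = max(best_corr, corr)
        if corr > procrustes_threshold:
            chosen = table.feature_ids[j]
            break
    if chosen is None:
        raise CompositionError(
            f"no candidate passed the Procrustes requirement "
            f"(best correlation {best_corr:.4f} <= {procrustes_threshold})")
    return chosen, diagnostics


def alr_transform(table: CountTable, reference_id: str) -> ALRTable:
    """Additive log-ratio transform against ``reference_id``.

    ``values[i, j] = ln(x[i, j]) - ln(x[i, ref])``; the reference column is
    dropped, so the output has one column fewer than the input.
    """
    if reference_id not in table.feature_ids:
        raise TableError(f"reference {reference_id!r} not in table")
    if np.any(table.counts <= 0):
        raise CompositionError("zero counts present: apply add_pseudocount first")
    ref = table.feature_ids.index(reference_id)
    logx = np.log(table.counts.astype(float))
    values = np.delete(logx - logx[:, [ref]], ref, axis=1)
    feature_ids = [f for i, f in enumerate(table.feature_ids) if i != ref]
    return ALRTable(sample_ids=list(table.sample_ids), feature_ids=feature_ids,
                    values=values, reference_id=reference_id,
                    population=table.population.copy(), scaled=False)


def autoscale(table: ALRTable) -> ALRTable:
    """Center each column to mean 0 and scale to SD 1, recording the stats."""
    if table.scaled:
        raise CompositionError("table is already scaled")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    if np.any(sds == 0):
        bad = table.feature_ids[int(np.argmax(sds == 0))]
        raise CompositionError(f"column {bad!r} has zero SD; cannot auto-scale")
    return dataclasses.replace(table, values=(table.values - means) / sds,
                               scaled=True, scale_means=means, scale_sds=sds)


def unscale(table: ALRTable) -> ALRTable:
    """Invert :func:`autoscale` using the recorded statistics."""
    if not table.scaled:
        raise CompositionError("table is not scaled")
    values = table.values * table.scale_sds + table.scale_means
    return dataclasses.replace(table, values=values, scaled=False,
                               scale_means=None, scale_sds=None)


def alr_to_proportions(table: ALRTable) -> np.ndarray:
    """Back-transform ALR values to closed proportions (reference included).

    Columns are ordered as ``feature_ids + [reference_id]``.
    """
    src = unscale(table) if table.scaled else table
    expd = np.exp(np.hstack([src.values, np.zeros((src.n_samples, 1))]))
    return expd / expd.sum(axis=1, keepdims=True)
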