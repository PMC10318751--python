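"""Flat-prior Bayesian two-group comparison, one model per feature.

Model: ``y_i = mu + delta * 1[group_i = g1] + e_i`` with
``e_i ~ N(0, sigma^2)``, improper uniform priors on the location
parameters and a flat prior on ``sigma^2``.  A Gibbs sampler alternates
the normal full conditionals of ``mu`` and ``delta`` with the scaled
inverse-chi-square conditional of ``sigma^2``.  Under these priors the
marginal posterior of ``delta`` is a scaled t distribution centered at the
difference of group means, which the test suite uses as a closed-form
oracle.  Convergence is checked with the split-chain potential scale
reduction factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class BayesError(ValueError):
    pass


@dataclass(frozen=True)
class McmcSettings:
    chains: int = 4
    iterations: int = 50_000
    thinning_lag: int = 10
    burn_in: int = 1_000
    seed: int = 0

    def validate(self) -> None:
        if self.chains < 2:
            raise BayesError("at least 2 chains are required (for R-hat)")
        if self.thinning_lag < 1:
            raise BayesError("thinning_lag must be >= 1")
        if not 0 <= self.burn_in < self.iterations:
            raise BayesError("burn_in must be < iterations")

    @property
    def n_kept(self) -> int:
        return -(-(self.iterations - self.burn_in) // self.thinning_lag)


@dataclass
class GibbsDraws:
    """Thinned post-burn-in draws, shape (chains, kept[, features])."""

    mu: np.ndarray
    delta: np.ndarray
    sigma2: np.ndarray

    def pooled_delta(self) -> np.ndarray:
        return self.delta.reshape(self.delta.shape[0] * self.delta.shape[1], -1)


@dataclass
class PosteriorSummary:
    feature_id: str
    mean_diff_sd_units: float
    p0: float
    hpd95: tuple[float, float]
    rhat: float
    relevant: bool
    converged: bool = True


def _gibbs_matrix(Y: np.ndarray, z: np.ndarray, settings: McmcSettings
                  ) -> GibbsDraws:
    """Vectorized Gibbs sampler over chains and feature columns.

    ``Y`` is (n_samples, n_features); ``z`` the 0/1 group-1 indicator.
    """
    settings.validate()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, F = Y.shape
    z = np.asarray(z, dtype=float)
    n1 = z.sum()
    n0 = n - n1
    if n1 < 2 or n0 < 2:
        raise BayesError("each group needs at least 2 samples")
    C = settings.chains
    rng = np.random.default_rng(settings.seed)

    ybar = Y.mean(axis=0)                       # (F,)
    ybar1 = Y[z == 1].mean(axis=0)
    ybar0 = Y[z == 0].mean(axis=0)
    mu = np.broadcast_to(ybar0, (C, F)).copy()
    delta = np.broadcast_to(ybar1 - ybar0, (C, F)).copy()
    sigma2 = np.broadcast_to(Y.var(axis=0, ddof=1) + 1e-12, (C, F)).copy()

    kept = settings.n_kept
    out_mu = np.empty((C, kept, F))
    out_delta = np.empty((C, kept, F))
    out_sigma2 = np.empty((C, kept, F))

    Ysum = Y.sum(axis=0)
    Y1sum = Y[z == 1].sum(axis=0)
    k = 0
    for it in range(settings.iterations):
        # mu | delta, sigma2  ~  N(mean(y - delta z), sigma2 / n)
        m_mu = (Ysum - delta * n1) / n
        mu = rng.normal(m_mu, np.sqrt(sigma2 / n))
        # delta | mu, sigma2  ~  N(mean_{g1}(y - mu), sigma2 / n1)
        m_d = Y1sum / n1 - mu
        delta = rng.normal(m_d, np.sqrt(sigma2 / n1))
        # sigma2 | mu, delta  ~  SSE / chi2(n - 2)   (flat prior on sigma2)
        resid = Y - mu[:, None, :] - delta[:, None, :] * z[None, :, None]
        sse = np.einsum("cnf,cnf->cf", resid, resid)
        sigma2 = sse / rng.chisquare(n - 2, size=(C, F))
        if it >= settings.burn_in and (it - settings.burn_in) % settings.thinning_lag == 0:
            out_mu[:, k] = mu
            out_delta[:, k] = delta
            out_sigma2[:, k] = sigma2
            k += 1
    return GibbsDraws(mu=out_mu[:, :k], delta=out_delta[:, :k],
                      sigma2=out_sigma2[:, :k])


def gibbs_two_group(y: np.ndarray, labels: np.ndarray, settings: McmcSettings,
                    group_order: tuple[str, str] | None = None) -> GibbsDraws:
    """Sample the posterior of (mu, delta, sigma2) for one feature.

    ``delta`` is the mean of ``group_order[0]`` minus that of
    ``group_order[1]`` (sorted label order by default).  Deterministic
    given ``settings.seed``.
    """
    labels = np.asarray(labels)
    levels = sorted(set(map(str, labels)))
    if group_order is None:
        group_order = (levels[0], levels[1])
    if sorted(group_order) != levels:
        raise BayesError("group_order must name the two observed labels")
    z = (labels.astype(str) == group_order[0]).astype(float)
    draws = _gibbs_matrix(np.asarray(y, dtype=float)[:, None], z, settings)
    return GibbsDraws(mu=draws.mu[..., 0], delta=draws.delta[..., 0],
                      sigma2=draws.sigma2[..., 0])


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor for one parameter.

    Each chain is split in half; the statistic is
    ``sqrt(((n-1)/n W + B/n) / W)`` with ``W`` the mean within-chain
    variance and ``B`` the between-chain variance of the split-chain means.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise BayesError("need >= 2 chains of equal length")
    m, n = chains.shape
    if n < 10:
        raise BayesError("chains too short for a split R-hat")
    half = n // 2
    split = np.vstack([chains[:, :half], chains[:, half:2 * half]])
    W = split.var(axis=1, ddof=1).mean()
    if W <= 0:
        raise BayesError("zero within-chain variance: degenerate chains")
    B = half * split.mean(axis=1).var(ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws."""
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n == 0:
        raise BayesError("empty sample set")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    lo = int(np.argmin(widths))
    return float(x[lo]), float(x[lo + m])


def summarize_posterior(samples: np.ndarray, feature_sd: float = 1.0,
                        sd_threshold: float = 0.5, p0_threshold: float = 0.9,
                        feature_id: str = "", rhat_value: float = np.nan,
                        rhat_limit: float = 1.05) -> PosteriorSummary:
    """Posterior mean difference (SD units), P0, HPD95 and relevance flag.

    ``p0`` is one-sided in the direction of the posterior mean:
    ``max(P(delta > 0), P(delta < 0))``, so it lies in [0.5, 1] up to the
    point mass at zero.  ``relevant`` requires ``|mean| > sd_threshold``,
    ``p0 > p0_threshold`` and, when an R-hat is supplied, convergence.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise BayesError("empty sample set")
    if feature_sd <= 0:
        raise BayesError("feature_sd must be positive")
    mean_diff = float(x.mean() / feature_sd)
    p_pos = float(np.mean(x > 0))
    p0 = max(p_pos, 1.0 - p_pos)
    lo, hi = hpd_interval(x / feature_sd, 0.95)
    converged = bool(np.isnan(rhat_value) or rhat_value < rhat_limit)
    relevant = bool(abs(mean_diff) > sd_threshold and p0 > p0_threshold
                    and converged)
    return PosteriorSummary(feature_id=feature_id,
                            mean_diff_sd_units=mean_diff, p0=p0,
                            hpd95=(lo, hi), rhat=float(rhat_value),
                            relevant=relevant, converged=converged)


def run_bayes_screen(X: np.ndarray, labels: np.ndarray,
                     feature_ids: list[str], settings: McmcSettings,
                     sd_threshold: float = 0.5, p0_threshold: float = 0.9,
                     rhat_limit: float = 1.05,
                     feature_sds: np.ndarray | None = None,
                     group_order: tuple[str, str] | None = None
                     ) -> list[PosteriorSummary]:
    """Per-feature Gibbs screen over the columns of ``X``.

    Features whose difference parameter fails the R-hat bound are flagged
    non-converged and excluded from the relevant set.  The output is
    sorted by ``|mean_diff_sd_units|`` descending.  When ``X`` is
    auto-scaled each feature's SD is 1 (the default).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    levels = sorted(set(map(str, labels)))
    if group_order is None:
        group_order = (levels[0], levels[1])
    z = (labels.astype(str) == group_order[0]).astype(float)
    if feature_sds is None:
        feature_sds = np.ones(X.shape[1])
    draws = _gibbs_matrix(X, z, settings)
    out: list[PosteriorSummary] = []
    for j, fid in enumerate(feature_ids):
        try:
            rv = rhat(draws.delta[:, :, j])
        except BayesError:
            rv = np.inf
        out.append(summarize_posterior(draws.delta[:, :, j],
                                       feature_sd=float(feature_sds[j]),
                                       sd_threshold=sd_threshold,
                                       p0_threshold=p0_threshold,
                                       feature_id=fid, rhat_value=rv,
                                       rhat_limit=rhat_limit))
    out.sort(key=lambda s: abs(s.mean_diff_sd_units), reverse=True)
    return out


def summaries_to_rows(summaries: list[PosteriorSummary], kind: str = "synthetic"
                      ) -> list[dict]:
    """Rows shaped like the per-variable report table (delimited output)."""
    return [{"variable": s.feature_id, "type": kind,
             "meanDiff": s.mean_diff_sd_units, "P0": s.p0,
             "HPD95_low": s.hpd95[0], "HPD95_high": s.hpd95[1],
             "rhat": s.rhat, "relevant": s.relevant, "converged": s.converged}
            for s in summaries]
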