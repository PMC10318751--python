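"""Synthetic two-population compositional count tables with planted truth.

The generator follows a logistic-normal-multinomial scheme: per-feature
baseline log-abundances define an abundance spectrum with a handful of
dominant features; a chosen subset of features receives a signed
between-population shift expressed in units of the within-group
log-abundance SD; per-sample compositions are the closure of the
exponentiated noisy log-abundances; counts are multinomial draws with
overdispersed (gamma-Poisson) library sizes.  A designated high-abundance,
low-noise "reference-like" feature is always present so that downstream
log-ratio reference selection has a valid target, and the planted feature
set is returned as ground truth for recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import CountTable


class DesignError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one synthetic two-population dataset.

    ``effect_sizes`` is either a scalar applied to every planted feature or
    a sequence of length ``n_differential``; each value is the log-scale
    group shift in units of the within-group log-abundance SD
    (``within_sd``).  Signs of planted shifts alternate so that roughly
    half the planted features are enriched in each population.
    """

    n_pop1: int = 34
    n_pop2: int = 28
    n_features: int = 200
    n_differential: int = 0
    effect_sizes: float | Sequence[float] = 1.0
    library_size_mean: float = 50_000.0
    library_size_dispersion: float = 0.3
    zero_inflation: float = 0.0
    seed: int = 0
    within_sd: float = 0.5
    baseline_sd: float = 1.5
    n_dominant: int = 5
    plant_reference: bool = True

    def validate(self) -> None:
        if self.n_pop1 < 1 or self.n_pop2 < 1:
            raise DesignError("each population needs at least one sample")
        if self.n_features < 2:
            raise DesignError("need at least two features")
        if not 0 <= self.n_differential <= self.n_features - int(self.plant_reference):
            raise DesignError("n_differential must fit among non-reference features")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise DesignError("zero_inflation must lie in [0, 1]")
        if self.library_size_mean < 1:
            raise DesignError("library_size_mean must be >= 1")
        if self.library_size_dispersion < 0:
            raise DesignError("library_size_dispersion must be >= 0")
        if self.within_sd <= 0:
            raise DesignError("within_sd must be positive")
        eff = self.effect_vector()
        if not np.all(np.isfinite(eff)):
            raise DesignError("effect_sizes must be finite")

    def effect_vector(self) -> np.ndarray:
        """Per-planted-feature effect sizes, broadcast from a scalar."""
        eff = np.atleast_1d(np.asarray(self.effect_sizes, dtype=float))
        if eff.size == 1:
            eff = np.repeat(eff, self.n_differential)
        if eff.size != self.n_differential:
            raise DesignError("effect_sizes length must equal n_differential")
        return eff


@dataclass
class SimulationTruth:
    """Ground truth of one simulated table."""

    differential_feature_ids: list[str]
    true_shifts: np.ndarray          # signed, natural-log units
    baseline_log_abundances: np.ndarray
    reference_feature_id: str | None = None
    composition: np.ndarray | None = None  # per-sample closed generative composition

    def write(self, path: str | Path) -> None:
        shifts = dict(zip(self.differential_feature_ids, self.true_shifts))
        pd.DataFrame({"feature_id": self.differential_feature_ids,
                      "true_shift": [shifts[f] for f in self.differential_feature_ids]}
                     ).to_csv(path, sep="\t", index=False)


def generate_counts(design: SimulationDesign) -> tuple[CountTable, SimulationTruth]:
    """Draw one two-population count table under the generative model.

    Deterministic given ``design.seed``.  The returned truth records the
    planted feature identifiers, their signed log-scale shifts and the
    baseline log-abundance vector.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n = design.n_pop1 + design.n_pop2
    p = design.n_features

    feature_ids = [f"feat_{j:05d}" for j in range(p)]
    sample_ids = [f"sample_{i:03d}" for i in range(n)]
    population = np.array(["pop1"] * design.n_pop1 + ["pop2"] * design.n_pop2,
                          dtype=object)
    in_pop1 = (population == "pop1").astype(float)

    # abundance spectrum: normal bulk plus a long right tail of dominants
    baseline = rng.normal(0.0, design.baseline_sd, size=p)
    dominant = rng.choice(p, size=min(design.n_dominant, p), replace=False)
    baseline[dominant] += rng.uniform(2.0, 4.0, size=dominant.size)

    noise_sd = np.full(p, design.within_sd)
    ref_id: str | None = None
    ref_idx = -1
    if design.plant_reference:
        # high abundance + tiny per-sample noise => minimal CV(log counts)
        ref_idx = int(np.argmax(baseline))
        baseline[ref_idx] = baseline.max() + 1.0
        noise_sd[ref_idx] = design.within_sd * 0.05
        ref_id = feature_ids[ref_idx]

    eligible = np.setdiff1d(np.arange(p), [ref_idx] if ref_idx >= 0 else [])
    diff_idx = np.sort(rng.choice(eligible, size=design.n_differential, replace=False))
    signs = np.where(np.arange(design.n_differential) % 2 == 0, 1.0, -1.0)
    shifts = np.zeros(p)
    shifts[diff_idx] = signs * design.effect_vector() * design.within_sd

    # per-sample log-abundance: baseline +- half-shift by population + noise
    group_term = np.outer(in_pop1 - 0.5, shifts)
    log_abund = baseline[None, :] + group_term + rng.normal(0.0, noise_sd, size=(n, p))
    # closure
    log_abund -= log_abund.max(axis=1, keepdims=True)
    comp = np.exp(log_abund)
    comp /= comp.sum(axis=1, keepdims=True)

    # overdispersed library sizes (gamma-Poisson), at least 1
    if design.library_size_dispersion > 0:
        shape = 1.0 / design.library_size_dispersion
        lam = rng.gamma(shape, design.library_size_mean / shape, size=n)
    else:
        lam = np.full(n, design.library_size_mean)
    libsizes = np.maximum(rng.poisson(lam), 1)

    counts = np.empty((n, p), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(libsizes[i], comp[i])

    if design.zero_inflation > 0:
        low = baseline < np.median(baseline)
        drop = rng.random(size=(n, p)) < design.zero_inflation
        counts[drop & low[None, :]] = 0

    table = CountTable(sample_ids=sample_ids, feature_ids=feature_ids,
                       counts=counts, population=population,
                       feature_kind="synthetic")
    truth = SimulationTruth(
        differential_feature_ids=[feature_ids[j] for j in diff_idx],
        true_shifts=shifts[diff_idx].copy(),
        baseline_log_abundances=baseline.copy(),
        reference_feature_id=ref_id,
        composition=comp,
    )
    return table, truth
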