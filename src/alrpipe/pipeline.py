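"""End-to-end protocol orchestration under one structured config.

Stage order (default): simulate/ingest -> PCA outlier removal -> zero
filtering -> pseudocount -> reference selection -> ALR -> auto-scaling ->
iterative PLS-DA selection -> confusion and permuted-confusion validation
-> per-feature Bayesian screen -> alpha/beta diversity.  Outlier-removal
placement is a switch (``outlier_first``) since the source protocol lists
it before filtering.  All randomness derives from one root seed through a
fixed-order seed-spawning scheme, so a rerun with the same config
reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import bayes, compositional, diversity, plsda, simulate
from .tables import ALRTable, CountTable


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All pipeline parameters, defaulting to the protocol's values."""

    # input: either file paths or a simulation design
    counts_path: str | None = None
    metadata_path: str | None = None
    feature_kind: str = "synthetic"
    simulation: dict | None = None

    # compositional stage
    outlier_first: bool = True
    outlier_sd_multiplier: float = 3.0
    zero_fraction_threshold: float = 0.2
    zero_diff_threshold: float = 0.5
    pseudocount: int = 1
    abundance_quantile: float = 0.75
    procrustes_threshold: float = 0.9
    forced_reference: str | None = None

    # PLS-DA stage
    max_components: int = 10
    folds: int = 4
    tuning_repeats: int = 100
    confusion_repeats: int = 10_000
    permutation_repeats: int = 10_000
    ber_target: float = 0.02
    vip_threshold: float = 1.0
    positive_class: str | None = None

    # Bayesian stage
    chains: int = 4
    iterations: int = 50_000
    thinning_lag: int = 10
    burn_in: int = 1_000
    rhat_limit: float = 1.05
    sd_threshold: float = 0.5
    p0_threshold: float = 0.9

    # diversity stage
    alpha_level: float = 0.05
    nmds_restarts: int = 20
    n_permutations: int = 999

    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None and (self.counts_path is None
                                        or self.metadata_path is None):
            raise PipelineError("provide either a simulation design or "
                                "counts_path + metadata_path")
        for name, lo, hi in [("zero_fraction_threshold", 0, 1),
                             ("zero_diff_threshold", 0, 1),
                             ("ber_target", 0, 1), ("vip_threshold", 0, np.inf),
                             ("sd_threshold", 0, np.inf),
                             ("p0_threshold", 0.5, 1),
                             ("alpha_level", 0, 1)]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PipelineError(f"{name}={v} outside [{lo}, {hi}]")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class RunReport:
    """Per-stage record of one pipeline execution."""

    stages: list[dict] = field(default_factory=list)
    relevant_features: list[dict] = field(default_factory=list)
    artifacts: dict[str, Any] = field(default_factory=dict, repr=False)

    def add_stage(self, name: str, params: dict, outputs: dict,
                  warnings_: list[str] | None = None) -> None:
        self.stages.append({"stage": name, "params": params,
                            "outputs": outputs,
                            "warnings": warnings_ or []})

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, np.bool_):
                return bool(o)
            raise TypeError(f"not serializable: {type(o)}")
        return json.dumps({"stages": self.stages,
                           "relevant_features": self.relevant_features},
                          indent=2, default=_default)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _spawn_seeds(root: int, n: int = 8) -> list[int]:
    """Child seeds in fixed stage order from one root seed."""
    return [int(s.generate_state(1)[0])
            for s in np.random.SeedSequence(root).spawn(n)]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None
                 ) -> RunReport:
    """Execute all stages in protocol order; deterministic given the seed."""
    config.validate()
    report = RunReport()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    (seed_sim, seed_cv, seed_conf, seed_perm,
     seed_bayes, seed_nmds, seed_permanova, _extra) = _spawn_seeds(config.seed)

    # -- ingest / simulate -------------------------------------------------
    truth = None
    if config.simulation is not None:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", seed_sim)
        design = simulate.SimulationDesign(**sim_kwargs)
        table, truth = simulate.generate_counts(design)
        report.add_stage("simulate", dataclasses.asdict(design),
                         {"n_samples": table.n_samples,
                          "n_features": table.n_features,
                          "planted": truth.differential_feature_ids})
    else:
        table = CountTable.read(config.counts_path, config.metadata_path,
                                feature_kind=config.feature_kind)
        report.add_stage("ingest", {"counts_path": config.counts_path},
                         {"n_samples": table.n_samples,
                          "n_features": table.n_features})
    if out is not None:
        table.write(out / "counts.tsv", out / "metadata.tsv")
        if truth is not None:
            truth.write(out / "truth.tsv")

    # -- compositional -----------------------------------------------------
    removed: list[str] = []

    def _outliers(t: CountTable) -> CountTable:
        nonlocal removed
        t, removed = compositional.pca_outlier_removal(
            t, config.outlier_sd_multiplier)
        report.add_stage("pca_outlier_removal",
                         {"sd_multiplier": config.outlier_sd_multiplier},
                         {"removed_samples": removed,
                          "n_samples": t.n_samples})
        return t

    if config.outlier_first:
        table = _outliers(table)
    filtered = compositional.filter_features(table,
                                             config.zero_fraction_threshold,
                                             config.zero_diff_threshold)
    report.add_stage("filter_features",
                     {"zero_fraction_threshold": config.zero_fraction_threshold,
                      "zero_diff_threshold": config.zero_diff_threshold},
                     {"n_features": filtered.n_features})
    filtered = compositional.add_pseudocount(filtered, config.pseudocount)
    report.add_stage("add_pseudocount", {"c": config.pseudocount},
                     {"min_count": int(filtered.counts.min())})
    if not config.outlier_first:
        filtered = _outliers(filtered)

    ref_id, diagnostics = compositional.select_reference(
        filtered, config.abundance_quantile, config.procrustes_threshold,
        force=config.forced_reference)
    examined = [d for d in diagnostics if not np.isnan(d.procrustes_correlation)]
    report.add_stage("select_reference",
                     {"abundance_quantile": config.abundance_quantile,
                      "procrustes_threshold": config.procrustes_threshold,
                      "forced": config.forced_reference},
                     {"reference_id": ref_id,
                      "procrustes_correlation":
                          examined[-1].procrustes_correlation if examined else None})
    alr = compositional.alr_transform(filtered, ref_id)
    scaled = compositional.autoscale(alr)
    report.add_stage("alr_and_scale", {"reference_id": ref_id},
                     {"n_features": scaled.n_features})
    if out is not None:
        scaled.write(out / "alr_scaled.tsv")

    # -- PLS-DA ------------------------------------------------------------
    y = np.asarray([str(x) for x in scaled.population])
    positive = config.positive_class or sorted(set(y))[0]
    fit, selected, itlog = plsda.iterative_selection(
        scaled.values, y, scaled.feature_ids, ber_target=config.ber_target,
        max_components=config.max_components, folds=config.folds,
        repeats=config.tuning_repeats, seed=seed_cv,
        vip_threshold=config.vip_threshold)
    report.add_stage("iterative_selection",
                     {"ber_target": config.ber_target,
                      "max_components": config.max_components,
                      "folds": config.folds,
                      "repeats": config.tuning_repeats},
                     {"n_selected": len(selected),
                      "n_components": fit.n_components,
                      "final_ber": itlog[-1].ber if itlog else None,
                      "iterations": [dataclasses.asdict(r) for r in itlog]})
    sel_table = scaled.select_features(selected)
    confusion = plsda.confusion_matrix_cv(
        sel_table.values, y, fit.n_components, positive,
        folds=config.folds, repeats=config.confusion_repeats, seed=seed_conf)
    permuted = plsda.permuted_confusion(
        sel_table.values, y, fit.n_components, positive,
        folds=config.folds, repeats=config.permutation_repeats,
        permutation_seed=seed_perm)
    report.add_stage("validation",
                     {"confusion_repeats": config.confusion_repeats,
                      "permutation_repeats": config.permutation_repeats,
                      "positive_class": positive},
                     {"confusion_matrix": confusion.matrix,
                      "accuracy": confusion.accuracy,
                      "precision": confusion.precision,
                      "per_class_rate": confusion.per_class_rate,
                      "permuted_positive_rate": permuted.per_class_rate[0]})

    # -- Bayesian screen ---------------------------------------------------
    settings = bayes.McmcSettings(chains=config.chains,
                                  iterations=config.iterations,
                                  thinning_lag=config.thinning_lag,
                                  burn_in=config.burn_in, seed=seed_bayes)
    summaries = bayes.run_bayes_screen(
        sel_table.values, y, sel_table.feature_ids, settings,
        sd_threshold=config.sd_threshold, p0_threshold=config.p0_threshold,
        rhat_limit=config.rhat_limit)
    relevant = [s for s in summaries if s.relevant]
    report.relevant_features = bayes.summaries_to_rows(summaries,
                                                       scaled_kind(table))
    report.add_stage("bayes_screen",
                     {"chains": config.chains, "iterations": config.iterations,
                      "thinning_lag": config.thinning_lag,
                      "burn_in": config.burn_in,
                      "sd_threshold": config.sd_threshold,
                      "p0_threshold": config.p0_threshold},
                     {"n_screened": len(summaries),
                      "n_relevant": len(relevant),
                      "relevant_ids": [s.feature_id for s in relevant]})

    # -- diversity ---------------------------------------------------------
    props = filtered.counts / filtered.counts.sum(axis=1, keepdims=True)
    alpha = {name: diversity.alpha_diversity(props, y, index=name)
             for name in ("shannon", "inv_simpson")}
    D = diversity.bray_curtis(props)
    config_nmds = diversity.nmds(D, k=2, n_restarts=config.nmds_restarts,
                                 seed=seed_nmds)
    perma = diversity.permanova(config_nmds.coordinates, y,
                                n_permutations=config.n_permutations,
                                seed=seed_permanova)
    report.add_stage("diversity",
                     {"n_permutations": config.n_permutations,
                      "nmds_restarts": config.nmds_restarts},
                     {"alpha": {k: {"U": a.group_test_statistic,
                                    "p": a.group_test_pvalue}
                                for k, a in alpha.items()},
                      "nmds_stress": config_nmds.stress,
                      "permanova_f": perma.pseudo_f,
                      "permanova_p": perma.p_value})

    report.artifacts.update({
        "count_table": table, "filtered": filtered, "alr": scaled,
        "truth": truth, "fit": fit, "selected": selected,
        "iteration_log": itlog, "confusion": confusion, "permuted": permuted,
        "summaries": summaries, "alpha": alpha, "nmds": config_nmds,
        "permanova": perma,
    })
    if out is not None:
        pd.DataFrame(report.relevant_features).to_csv(
            out / "bayes_screen.tsv", sep="\t", index=False)
        report.write(out / "report.json")
    return report


def scaled_kind(table: CountTable) -> str:
    return table.feature_kind
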