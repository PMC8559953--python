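"""End-to-end experiment execution and report generation.

Stages: generate -> reconstruct (reference + perturbed) -> stability ->
discriminability -> features -> phenotype model.  Each stage writes CSV
or JSON outputs tagged with the configuration hash; a failing stage is
logged and skipped, and downstream stages that depend on it are marked
unavailable.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import io as nio
from .cohort import (
    REFERENCE_SIM,
    Cohort,
    Connectome,
    SampleKey,
    generate_cohort,
    run_sample_simulations,
)
from .config import ExperimentConfig, count_executions, count_tests
from .discrim import HYPOTHESIS_COMPARISONS, results_table, run_hypothesis
from .phenotype import resampled_performance
from .stability import COMPARISON_LEVELS, group_stability

__all__ = ["run_experiment", "reconstruct_cohort", "count_executions", "count_tests"]

log = logging.getLogger("netstab")


def reconstruct_cohort(
    cohort: Cohort,
    config: ExperimentConfig,
    pipelines: tuple[str, ...] | None = None,
    modes: tuple[str, ...] | None = None,
    n_sims: int | None = None,
) -> dict[SampleKey, Connectome]:
    """Reference plus perturbed reconstructions for every sample."""
    d = cohort.design
    pipelines = pipelines or d.pipelines
    modes = modes or tuple(m for m in d.modes if m in config.densities)
    n_sims = d.n_sims if n_sims is None else n_sims
    out: dict[SampleKey, Connectome] = {}
    for sample_id in cohort.sample_ids():
        for pipeline in pipelines:
            for mode in modes:
                out.update(
                    run_sample_simulations(
                        cohort, sample_id, pipeline, mode,
                        n_sims=n_sims, t=config.t,
                        mca_mode=config.mca_mode, base_seed=config.seed,
                    )
                )
    return out


def _write_json(path: Path, payload: dict, config: ExperimentConfig) -> None:
    payload = {"config_hash": config.config_hash, **payload}
    path.write_text(json.dumps(payload, indent=2, default=float))


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis described by ``config``.

    Returns a report bundle (dict of stage results); all tabular outputs
    are also written under the output directory together with a run log.
    Reruns with an identical config are bit-identical for the reference
    (density=off) stages.
    """
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_hash": config.config_hash, "stages": {}}
    timings: dict[str, float] = {}
    failed: set[str] = set()

    def stage(name: str, fn, *deps: str):
        if any(d in failed for d in deps):
            bundle["stages"][name] = "unavailable (failed dependency)"
            failed.add(name)
            return None
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # partial-failure isolation
            log.exception("stage %s failed", name)
            bundle["stages"][name] = f"failed: {exc}"
            failed.add(name)
            return None
        timings[name] = time.perf_counter() - t0
        bundle["stages"][name] = "ok"
        return result

    design = config.study_design()
    bundle["n_executions"] = count_executions(design)
    bundle["n_tests"] = count_tests(
        {h: HYPOTHESIS_COMPARISONS[h] for h in config.hypotheses},
        n_pipelines=len(design.pipelines),
        n_modes=len(config.densities),
    )

    cohort = stage(
        "generate",
        lambda: generate_cohort(design, config.effect_sizes(), seed=config.seed),
    )

    def _reconstruct():
        conns = reconstruct_cohort(cohort, config)
        conn_dir = out / "connectomes"
        conn_dir.mkdir(exist_ok=True)
        for key, c in conns.items():
            nio.write_matrix(conn_dir / nio.key_to_filename(key), c.weights)
        nio.write_manifest(out / "manifest.tsv", conns)
        return conns

    conns = stage("reconstruct", _reconstruct, "generate")

    def _stability():
        reports = {}
        for level in COMPARISON_LEVELS:
            try:
                rep = group_stability(conns, level)
            except ValueError as exc:
                log.info("stability level %s skipped: %s", level, exc)
                continue
            rep.pairs.to_csv(out / f"stability_{level}_pairs.csv", index=False)
            rep.edge_digits.to_csv(out / f"stability_{level}_digits.csv", index=False)
            reports[level] = rep
        _write_json(
            out / "stability_summary.json",
            {"levels": {k: v.to_json_summary() for k, v in reports.items()}},
            config,
        )
        return reports

    stability_reports = stage("stability", _stability, "reconstruct")

    def _discrim():
        results = []

        def _one(hyp, comparison, pipeline, mode, source):
            try:
                results.append(
                    run_hypothesis(
                        conns, hyp, pipeline, mode,
                        comparison=comparison, source=source,
                        n_perm=config.n_perm, seed=config.seed,
                    )
                )
            except ValueError as exc:
                log.info(
                    "discriminability %s/%s (%s,%s,%s) skipped: %s",
                    hyp, comparison, pipeline, mode, source, exc,
                )

        for hyp in config.hypotheses:
            for comparison in HYPOTHESIS_COMPARISONS[hyp]:
                for pipeline in design.pipelines:
                    # every comparison setting runs on perturbed data per mode
                    for mode in config.densities:
                        _one(hyp, comparison, pipeline, mode, "mca")
                    # reference-capable settings also run once per pipeline
                    if comparison != "mca":
                        _one(hyp, comparison, pipeline, config.densities[0],
                             "reference")
        table = results_table(results) if results else pd.DataFrame()
        table.to_csv(out / "discriminability.csv", index=False)
        return results

    stage("discrim", _discrim, "reconstruct")

    def _features():
        rows = []
        fpr_inputs: dict[str, dict] = {f: {} for f in feat.UNIVARIATE_FEATURES}
        for key, c in conns.items():
            if key.pipeline != design.pipelines[0] or key.mode != config.densities[0]:
                continue
            uni = feat.univariate_features(c.weights, seed=config.seed)
            rows.append({**dict(zip(nio.KEY_FIELDS, key)), **uni})
            if key.sim != REFERENCE_SIM:
                for f, v in uni.items():
                    fpr_inputs[f].setdefault(key.sample_id, []).append(v)
        pd.DataFrame(rows).to_csv(out / "univariate_features.csv", index=False)
        fprs = {
            f: feat.univariate_zscore_fpr(groups, feature=f).proportion
            for f, groups in fpr_inputs.items()
            if groups and all(len(v) >= 2 for v in groups.values())
        }
        _write_json(out / "univariate_fpr.json", {"zscore_fpr": fprs}, config)
        return fprs

    stage("features", _features, "reconstruct")

    def _model():
        # cross-sectional style: one sample per subject (first session/subsample)
        pipeline, mode = design.pipelines[0], config.densities[0]
        refs, sims = [], []
        for subject in range(design.n_subjects):
            sid = (subject, 0, 0)
            ref_key = SampleKey(*sid, pipeline=pipeline, mode=mode)
            refs.append(conns[ref_key].weights)
            sims.append(
                [
                    conns[k].weights
                    for k in sorted(conns)
                    if k.sample_id == sid and k.pipeline == pipeline
                    and k.mode == mode and k.sim != REFERENCE_SIM
                ]
            )
        labels = cohort.labels
        k = config.model_k[0]
        summary = resampled_performance(
            refs, sims, labels, k=min(k, int(np.bincount(labels).min())),
            n_repeats=config.n_repeats,
            threshold=config.pca_threshold, seed=config.seed,
        )
        _write_json(out / "phenotype_model.json", summary.to_json_summary(), config)
        pd.DataFrame(
            [
                {
                    "sampling_index": r.sampling_index,
                    "k": r.k,
                    "n_components": r.n_components,
                    "explained_variance": r.explained_variance,
                    "accuracy": r.accuracy,
                    "f1": r.f1,
                }
                for r in [summary.reference, *summary.runs]
            ]
        ).to_csv(out / "phenotype_runs.csv", index=False)
        return summary

    stage("model", _model, "reconstruct")

    bundle["timings_s"] = timings
    _write_json(
        out / "run_log.json",
        {
            "config": config.to_dict(),
            "stages": bundle["stages"],
            "timings_s": timings,
            "n_executions": bundle["n_executions"],
            "n_tests": bundle["n_tests"],
        },
        config,
    )
    bundle["stability"] = stability_reports
    return bundle
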