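"""End-to-end orchestration on a synthetic cohort.

A single declarative config drives every stage; unknown keys are rejected
up front and the resolved config (with every seed explicit) is written next
to the outputs so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import io as dkio
from .benchmark import run_fraction_scan
from .imputation import impute_celltype_expression, validate_marker_enrichment
from .pathway import GeneSet, compare_groups, score_matrix
from .signature import (
    build_signature,
    choose_secondfc_threshold,
    compute_marker_stats,
    select_markers,
)
from .solvers import SolverConfig, deconvolve_cohort
from .stats import SvmConfig, compare_group_proportions, test_clinical_association, train_eval_svm
from .subtyping import HvgConfig, build_integrated_profile, choose_k, nmf_consensus
from .synthetic import CohortSpec, ReferenceSpec, generate_cohort, generate_reference

__all__ = ["PipelineConfig", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticStage(_Strict):
    n_cell_types: int = 5
    n_genes: int = 1200
    cells_per_type: int = 40
    markers_per_type: int = 25
    marker_log2fc: float = 4.0
    dropout_rate: float = 0.1
    n_samples_per_group: int = 40
    noise_log_sd: float = 0.2
    platform_bias_sd: float = 0.3
    n_subtypes: int = 2
    pathway_log2fc: float = 1.5
    pathway_size: int = 30
    proportion_shift: float = 0.08
    clinical_effect_size: float = 2.0
    seed: int = 0


class SignatureStage(_Strict):
    logfc_min: float = 1.0
    logcpm_min: float = 1.0
    secondfc: float | str = "auto"  # numeric threshold or "auto" for the plateau scan
    min_frac_expressed: float = 0.30
    plateau_tol: float = 0.05


class DeconvStage(_Strict):
    method: str = "nnls"


class BenchStage(_Strict):
    enabled: bool = False
    methods: list[str] = ["nnls", "ols"]
    fractions: list[float] = [0.25, 0.5, 0.75, 1.0]


class PathwayStage(_Strict):
    top_fraction: float = 0.05


class ClassifyStage(_Strict):
    enabled: bool = True
    logcpm_min: float = 1.0
    de_alpha: float = 0.10
    seed: int = 0


class SubtypeStage(_Strict):
    enabled: bool = True
    k_min: int = 2
    k_max: int = 6
    n_runs: int = 20
    dispersion_cutoff: float = 1.0
    mean_cutoff: float = 0.0
    seed: int = 0


class PipelineConfig(_Strict):
    synthetic: SyntheticStage = SyntheticStage()
    signature: SignatureStage = SignatureStage()
    deconvolution: DeconvStage = DeconvStage()
    benchmark: BenchStage = BenchStage()
    pathway: PathwayStage = PathwayStage()
    classify: ClassifyStage = ClassifyStage()
    subtype: SubtypeStage = SubtypeStage()


def _log(records: list[dict], stage: str, message: str) -> None:
    records.append({"stage": stage, "message": message})


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute every enabled stage in order and persist all outputs.

    Returns the run directory. A stage failure raises with the stage name;
    outputs of completed stages stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.json").write_text(config.model_dump_json(indent=2))
    log: list[dict] = []

    def _run_stage(name, fn):
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                result = fn()
            for w in caught:
                _log(log, name, str(w.message))
            return result
        except Exception as exc:
            pd.DataFrame(log).to_csv(out / "warnings.tsv", sep="\t", index=False)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- synthetic cohort -------------------------------------------------
    sc = config.synthetic

    def _synth():
        ref_spec = ReferenceSpec(
            n_cell_types=sc.n_cell_types,
            n_genes=sc.n_genes,
            cells_per_type=sc.cells_per_type,
            markers_per_type=sc.markers_per_type,
            marker_log2fc=sc.marker_log2fc,
            dropout_rate=sc.dropout_rate,
            seed=sc.seed,
        )
        ref = generate_reference(ref_spec)
        types = ref.cell_types
        shift_type, target_type = types[0], types[1]
        rng_genes = [g for g in ref.gene_ids if g not in ref.planted_markers.get(target_type, [])]
        pathways = {
            st: (
                target_type,
                tuple(rng_genes[st * sc.pathway_size : (st + 1) * sc.pathway_size]),
                sc.pathway_log2fc,
            )
            for st in range(sc.n_subtypes)
        }
        cohort_spec = CohortSpec(
            n_samples_per_group=sc.n_samples_per_group,
            group_proportion_shift={shift_type: sc.proportion_shift},
            noise_log_sd=sc.noise_log_sd,
            platform_bias_sd=sc.platform_bias_sd,
            n_subtypes=sc.n_subtypes,
            subtype_pathway_genes=pathways,
            clinical_effect_size=sc.clinical_effect_size,
            seed=sc.seed + 1,
        )
        cohort = generate_cohort(ref, cohort_spec)
        dkio.write_reference(ref, out / "reference")
        dkio.write_expression_tsv(cohort.bulk, out / "bulk.tsv")
        dkio.write_proportions_tsv(cohort.true_proportions, out / "true_proportions.tsv")
        cohort.clinical_table.to_csv(out / "clinical.tsv", sep="\t", index_label="sample_id")
        cohort.group_labels.to_frame().to_csv(out / "groups.tsv", sep="\t", index_label="sample_id")
        gene_sets = [GeneSet(f"planted_subtype_{st}", genes) for st, (_, genes, _) in pathways.items()]
        dkio.write_gmt(gene_sets, out / "pathways.gmt")
        return ref, cohort, gene_sets

    ref, cohort, gene_sets = _run_stage("synthetic", _synth)

    # -- signature --------------------------------------------------------
    sg = config.signature

    def _signature():
        stats = compute_marker_stats(ref)
        if sg.secondfc == "auto":
            scan = choose_secondfc_threshold(
                ref,
                plateau_tol=sg.plateau_tol,
                logfc_min=sg.logfc_min,
                logcpm_min=sg.logcpm_min,
                min_frac_expressed=sg.min_frac_expressed,
            )
            threshold = scan.chosen_threshold
            pd.DataFrame(
                {"threshold": scan.thresholds, "avg_correlation": scan.avg_correlation}
            ).to_csv(out / "secondfc_scan.tsv", sep="\t", index=False)
        else:
            threshold = float(sg.secondfc)
        markers = select_markers(
            stats,
            logfc_min=sg.logfc_min,
            logcpm_min=sg.logcpm_min,
            secondfc_min=threshold,
            min_frac_expressed=sg.min_frac_expressed,
        )
        sig = build_signature(ref, markers)
        sig.values.to_csv(out / "signature.tsv", sep="\t", index_label="gene_id")
        return sig, markers

    sig, markers = _run_stage("signature", _signature)

    # -- deconvolution + group proportion tests ---------------------------
    def _deconv():
        props = deconvolve_cohort(sig, cohort.bulk, SolverConfig(method=config.deconvolution.method))
        dkio.write_proportions_tsv(props.values, out / "proportions.tsv")
        tests = compare_group_proportions(props, cohort.group_labels)
        tests.to_csv(out / "proportion_group_tests.tsv", sep="\t", index_label="cell_type")
        return props

    props = _run_stage("deconvolution", _deconv)

    # -- optional benchmark scan -----------------------------------------
    if config.benchmark.enabled:
        def _bench():
            recs = run_fraction_scan(
                sig,
                cohort.bulk,
                cohort.true_proportions,
                config.benchmark.methods,
                config.benchmark.fractions,
            )
            pd.DataFrame([r.__dict__ for r in recs]).to_csv(
                out / "benchmark_records.tsv", sep="\t", index=False
            )

        _run_stage("benchmark", _bench)

    # -- imputation + marker validation ----------------------------------
    def _impute():
        cube = impute_celltype_expression(cohort.bulk, props.values)
        heat = validate_marker_enrichment(cube, markers)
        heat.to_csv(out / "marker_enrichment.tsv", sep="\t", index_label="profile")
        cube_dir = out / "cube"
        cube_dir.mkdir(exist_ok=True)
        for ct in cube.cell_type_ids:
            dkio.write_expression_tsv(cube.slice_type(ct), cube_dir / f"{ct}.tsv")
        return cube

    cube = _run_stage("imputation", _impute)

    # -- pathway activity -------------------------------------------------
    def _pathway():
        rows = []
        scores_bulk = score_matrix(cohort.bulk, gene_sets, config.pathway.top_fraction)
        for gs in gene_sets:
            stat, p = compare_groups(scores_bulk[gs.name], cohort.group_labels)
            rows.append({"profile": "bulk", "gene_set": gs.name, "statistic": stat, "p": p})
        for ct in cube.cell_type_ids:
            sl = cube.slice_type(ct).dropna(axis=1, how="any")
            if sl.shape[1] < 4:
                _log(log, "pathway", f"profile {ct} mostly missing; skipped")
                continue
            scores = score_matrix(sl, gene_sets, config.pathway.top_fraction)
            for gs in gene_sets:
                stat, p = compare_groups(scores[gs.name], cohort.group_labels.loc[sl.columns])
                rows.append({"profile": ct, "gene_set": gs.name, "statistic": stat, "p": p})
        pd.DataFrame(rows).to_csv(out / "pathway_group_tests.tsv", sep="\t", index=False)

    _run_stage("pathway", _pathway)

    # -- SVM classification ----------------------------------------------
    if config.classify.enabled:
        def _classify():
            log_bulk = cohort.bulk.apply(lambda c: (c / c.sum() * 1e6)).apply(lambda c: np.log2(c + 1))
            cost, auc, _ = train_eval_svm(
                log_bulk,
                cohort.group_labels,
                SvmConfig(logcpm_min=config.classify.logcpm_min,
                          de_alpha=config.classify.de_alpha, seed=config.classify.seed),
            )
            pd.DataFrame([{"input": "bulk", "best_cost": cost, "test_auc": auc}]).to_csv(
                out / "svm_results.tsv", sep="\t", index=False
            )

        _run_stage("classify", _classify)

    # -- subtyping + clinical association --------------------------------
    if config.subtype.enabled:
        st = config.subtype

        def _subtype():
            case_ids = [s for s in cube.sample_ids if cohort.group_labels[s] == "case"]
            prof = build_integrated_profile(
                cube.subset_samples(case_ids),
                cube.cell_type_ids,
                hvg_cfg=None,
                exclusivity_ratio=2.0,
            )
            cc_by_k, results = {}, {}
            for k in range(st.k_min, min(st.k_max, prof.shape[1] - 1) + 1):
                res = nmf_consensus(prof, k, n_runs=st.n_runs, seed=st.seed)
                cc_by_k[k] = res.cophenetic_cc
                results[k] = res
            k_star = choose_k(cc_by_k)
            best = results[k_star]
            pd.DataFrame({"k": list(cc_by_k), "cophenetic": list(cc_by_k.values())}).to_csv(
                out / "cophenetic_by_k.tsv", sep="\t", index=False
            )
            best.labels.to_frame().to_csv(out / "subtype_labels.tsv", sep="\t", index_label="sample_id")
            best.consensus.to_csv(out / "consensus.tsv", sep="\t", index_label="sample_id")
            assoc = test_clinical_association(best.labels, cohort.clinical_table.loc[best.labels.index])
            pd.DataFrame(
                [
                    {"feature": a.feature, "test": a.test_name, "statistic": a.statistic, "p": a.p}
                    for a in assoc
                ]
            ).to_csv(out / "clinical_association.tsv", sep="\t", index=False)

        _run_stage("subtype", _subtype)

    pd.DataFrame(log, columns=["stage", "message"]).to_csv(out / "warnings.tsv", sep="\t", index=False)
    return out
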