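"""End-to-end orchestration: simulate or ingest cohorts, then run every
analysis stage in dependency order and write a machine-readable report.

A manifest (YAML or dict) either names cohort files (matrix + clinical TSV
per cohort) or embeds a synthetic design. Stage outputs are pure functions
of (inputs, thresholds, seed); re-running the same manifest reproduces the
report byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bimodal, correlate, enrichment, grade, signatures, survival
from .io import (ClinicalTable, ExpressionCohort, SignatureCollection,
                 intersect_probes, read_clinical_table,
                 read_expression_matrix, read_gene_sets_gmt,
                 write_clinical_table, write_expression_matrix)
from .simulate import (SimulationDesign, signature_gene_sets,
                       simulate_multi_cohort, simulate_training_cohort)

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineManifest:
    """Everything a pipeline run needs: inputs, thresholds, seed."""

    target_probe: str
    cohorts: list[dict] = field(default_factory=list)  # matrix/clinical/cohort_id
    design: SimulationDesign | None = None
    gmt_paths: list[str] = field(default_factory=list)
    fdr_max: float = 0.05
    fc_min: float = 2.0
    min_cohorts: int = 4
    strata_method: str = "bimodal_fit"   # or "median"
    variant: str = "auto"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max < 1):
            raise ValueError("fdr_max must be in (0, 1)")
        if self.fc_min <= 0:
            raise ValueError("fc_min must be positive")
        if self.min_cohorts < 1:
            raise ValueError("min_cohorts must be >= 1")
        if self.design is None and not self.cohorts:
            raise ValueError("manifest needs either cohort files or a design")
        for entry in self.cohorts:
            for key in ("matrix", "clinical", "cohort_id"):
                if key not in entry:
                    raise ValueError(f"cohort entry missing {key!r}")
                if key != "cohort_id" and not Path(entry[key]).exists():
                    raise ValueError(f"missing input file {entry[key]}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        design = raw.pop("design", None)
        if design is not None:
            for key in ("sample_counts", "p_true", "mes_corr"):
                if key in design:
                    design[key] = tuple(design[key])
            design = SimulationDesign(**design)
        return cls(design=design, **raw)


def _load_cohorts(manifest: PipelineManifest):
    if manifest.design is not None:
        design = manifest.design
        if design.seed != manifest.seed:
            design = SimulationDesign(**{**_design_dict(design),
                                         "seed": manifest.seed})
        result = simulate_multi_cohort(design)
        return result.cohorts, result.truth, design
    cohorts = []
    for entry in manifest.cohorts:
        expr = read_expression_matrix(entry["matrix"], entry["cohort_id"],
                                      probe_map_path=entry.get("probe_map"))
        clin = read_clinical_table(entry["clinical"])
        cohorts.append((expr, clin))
    return cohorts, None, None


def _design_dict(design: SimulationDesign) -> dict:
    from dataclasses import asdict
    return asdict(design)


def run_pipeline(manifest: PipelineManifest) -> dict:
    """Execute all stages; return (and optionally write) the report dict."""
    report: dict = {"schema_version": REPORT_SCHEMA_VERSION,
                    "seed": manifest.seed,
                    "target_probe": manifest.target_probe,
                    "stages": {}}
    t0 = time.time()

    def stage(name):
        logger.info("stage %-22s start", name)
        return time.time()

    def done(name, started):
        logger.info("stage %-22s done in %.2fs", name, time.time() - started)

    # -- cohorts ------------------------------------------------------------
    ts = stage("cohorts")
    try:
        cohorts, truth, design = _load_cohorts(manifest)
    except Exception as exc:
        raise PipelineError("cohorts", exc) from exc
    report["stages"]["cohorts"] = {
        "n_cohorts": len(cohorts),
        "samples": {expr.cohort_id: expr.n_samples for expr, _ in cohorts},
    }
    done("cohorts", ts)

    # -- bimodal fits -------------------------------------------------------
    ts = stage("bimodal")
    try:
        fits = {}
        for expr, _ in cohorts:
            values = expr.expression(manifest.target_probe)
            fits[expr.cohort_id] = bimodal.fit_expression_values(
                values, variant=manifest.variant)
        p_hat = {cid: fit.p for cid, fit in fits.items()}
        report["stages"]["bimodal"] = {
            "per_cohort": {cid: fit.to_dict() for cid, fit in fits.items()},
            "mean_p": float(np.mean(list(p_hat.values()))),
        }
    except Exception as exc:
        raise PipelineError("bimodal", exc) from exc
    done("bimodal", ts)

    # -- signature collections ---------------------------------------------
    ts = stage("signatures")
    try:
        if manifest.gmt_paths:
            collection = read_gene_sets_gmt(manifest.gmt_paths[0])
        elif design is not None:
            collection = SignatureCollection(
                name="planted", sets=signature_gene_sets(design))
        else:
            collection = None
        validated = None
        if design is not None and collection is not None:
            training, labels = simulate_training_cohort(design)
            _, validated = signatures.validate_signature_probes(
                training, labels, collection,
                fc_min=manifest.fc_min, fdr_max=manifest.fdr_max)
        if validated is not None:
            probe_sets = {s: p for s, p in validated.probes.items() if p}
        elif collection is not None:
            # no labeled training data: take every probe of each set's genes
            probe_sets = {}
            gene_to_probes: dict[str, list[str]] = {}
            expr0 = cohorts[0][0]
            for probe in expr0.probe_ids:
                gene_to_probes.setdefault(expr0.gene_of(probe), []).append(probe)
            for s, genes in collection.sets.items():
                probe_sets[s] = [p for g in genes
                                 for p in gene_to_probes.get(g, [])]
        else:
            probe_sets = {}
        report["stages"]["signatures"] = {
            "validated_per_subtype": {s: len(p) for s, p in probe_sets.items()},
        }
    except Exception as exc:
        raise PipelineError("signatures", exc) from exc
    done("signatures", ts)

    # -- signature-average correlations ------------------------------------
    ts = stage("signature_corr")
    try:
        pooled = {}
        if probe_sets:
            for subtype, probes in probe_sets.items():
                data = []
                for expr, _ in cohorts:
                    present = [p for p in probes if p in expr.matrix.index]
                    if not present:
                        break
                    score = signatures.average_signature_score(expr, present)
                    data.append((expr, score))
                if len(data) != len(cohorts):
                    continue
                r, p, per_cohort, n = correlate.correlate_signature_averages(
                    data, manifest.target_probe)
                pooled[subtype] = {"r": r, "p": p, "n": n,
                                   "per_cohort_r": per_cohort}
        report["stages"]["signature_corr"] = pooled
    except Exception as exc:
        raise PipelineError("signature_corr", exc) from exc
    done("signature_corr", ts)

    # -- per-probe correlation atlas ----------------------------------------
    ts = stage("correlations")
    try:
        all_records = []
        for expr, _ in cohorts:
            recs = correlate.correlate_probes(
                expr, manifest.target_probe, signatures=collection)
            all_records.extend(recs)
        gene_list = correlate.genes_correlated_in_min_cohorts(
            all_records, min_cohorts=min(manifest.min_cohorts, len(cohorts)),
            fdr_max=manifest.fdr_max)
        fractions = correlate.subtype_flagged_fractions(
            all_records, fdr_max=manifest.fdr_max)
        report["stages"]["correlations"] = {
            "n_records": len(all_records),
            "genes_in_min_cohorts": len(gene_list),
            "flagged_fraction_per_subtype": {
                row["subtype"]: float(row["fraction"])
                for _, row in fractions.iterrows()},
        }
    except Exception as exc:
        raise PipelineError("correlations", exc) from exc
    done("correlations", ts)

    # -- grade association ---------------------------------------------------
    ts = stage("grade")
    try:
        grades_present = set()
        for _, clin in cohorts:
            grades_present |= set(clin.table["grade"]) - {"unknown"}
        if len(grades_present) >= 2:
            res = grade.fit_grade_model(cohorts, manifest.target_probe,
                                        contrast="IV_vs_rest")
            report["stages"]["grade"] = {
                "contrast": res.contrast, "fold_change": res.fold_change,
                "p_value": res.p_value, "ls_means": res.ls_means,
            }
        else:
            report["stages"]["grade"] = {"skipped": "single grade level"}
    except Exception as exc:
        raise PipelineError("grade", exc) from exc
    done("grade", ts)

    # -- survival -----------------------------------------------------------
    ts = stage("survival")
    try:
        times, events, labels = [], [], []
        for expr, clin in cohorts:
            meta = clin.for_samples(expr.sample_ids)
            keep = meta["os_months"].notna() & meta["event"].notna()
            values = expr.expression(manifest.target_probe)[keep.to_numpy()]
            if manifest.strata_method == "bimodal_fit":
                lab = survival.stratify_by_expression(
                    values, "bimodal_fit", fit=fits[expr.cohort_id])
            else:
                lab = survival.stratify_by_expression(values, "median")
            times.append(meta.loc[keep, "os_months"].to_numpy(float))
            events.append(meta.loc[keep, "event"].to_numpy(int))
            labels.append(lab)
        comparison = survival.compare_survival(
            np.concatenate(times), np.concatenate(events),
            np.concatenate(labels))
        report["stages"]["survival"] = {
            "median_high": comparison.curves["high"].median,
            "median_low": comparison.curves["low"].median,
            "median_ci_high": comparison.curves["high"].median_ci,
            "median_ci_low": comparison.curves["low"].median_ci,
            "hazard_ratio": comparison.hazard_ratio,
            "hr_ci": comparison.hr_ci,
            "logrank_p": comparison.logrank_p,
            "n_per_group": comparison.n_per_group,
        }
    except Exception as exc:
        raise PipelineError("survival", exc) from exc
    done("survival", ts)

    # -- genome-wide screen ---------------------------------------------------
    ts = stage("screen")
    try:
        probes = intersect_probes([c for c, _ in cohorts])
        screen = survival.genome_wide_screen(cohorts, probes=probes)
        report["stages"]["screen"] = {
            "n_probes": len(screen.table),
            "target_rank": screen.rank_of(manifest.target_probe),
            "target_percentile": screen.percentile_of(manifest.target_probe),
        }
    except Exception as exc:
        raise PipelineError("screen", exc) from exc
    done("screen", ts)

    # -- enrichment -----------------------------------------------------------
    ts = stage("enrichment")
    try:
        if collection is not None and gene_list:
            expr0 = cohorts[0][0]
            universe = sorted({expr0.gene_of(p) for p in probes})
            results = enrichment.fisher_enrichment(gene_list, collection,
                                                   universe)
            report["stages"]["enrichment"] = {
                r.set_name: {"overlap": r.overlap, "p": r.p_value,
                             "fdr": r.fdr}
                for r in results}
        else:
            report["stages"]["enrichment"] = {"skipped": "no gene sets or "
                                                         "empty query"}
    except Exception as exc:
        raise PipelineError("enrichment", exc) from exc
    done("enrichment", ts)

    report["elapsed_s"] = round(time.time() - t0, 2)
    if manifest.out_dir:
        out = Path(manifest.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_report(report, out / "report.json")
        if truth is not None:
            truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return report


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: dict, path) -> None:
    """Stable JSON serialization (sorted keys, rounded floats); identical
    inputs produce identical bytes."""
    clean = _round_floats(report)
    # elapsed time is wall clock and would break byte-identity
    clean.pop("elapsed_s", None)
    with open(path, "w") as fh:
        json.dump(clean, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def write_simulated_cohorts(design: SimulationDesign, out_dir) -> list[dict]:
    """Materialize a synthetic design to cohort_io files + truth sidecar.

    Returns manifest-style cohort entries pointing at the written files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate_multi_cohort(design)
    entries = []
    probe_map_path = out / "probe_map.tsv"
    first_expr = result.cohorts[0][0]
    with open(probe_map_path, "w") as fh:
        for probe, gene in first_expr.probe_to_gene.items():
            fh.write(f"{probe}\t{gene}\n")
    for expr, clin in result.cohorts:
        mpath = out / f"{expr.cohort_id}_expression.tsv"
        cpath = out / f"{expr.cohort_id}_clinical.tsv"
        write_expression_matrix(expr, mpath)
        write_clinical_table(clin, cpath)
        entries.append({"matrix": str(mpath), "clinical": str(cpath),
                        "cohort_id": expr.cohort_id,
                        "probe_map": str(probe_map_path)})
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return entries
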