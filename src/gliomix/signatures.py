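"""Subtype signature-probe validation, signature scores and PCA distances.

Signature probes are validated on a labeled training cohort using a
linear-scale subtype ratio: for each probe assigned to subtype S, the ratio
is (mean linear expression in S) / (sum of the other subtypes' mean linear
expressions). The signed fold change follows the negative-inverse
convention (ratio < 1 maps to -1/ratio) so magnitudes are symmetric around
±1. A probe is validated when fold change > 2 and Welch-t BH FDR < 0.05.
Validated probes are averaged (log2 scale) into per-sample subtype scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCohort, SignatureCollection

logger = logging.getLogger(__name__)


class DesignError(ValueError):
    pass


@dataclass
class ProbeValidationRecord:
    probe_id: str
    gene: str
    subtype: str
    subtype_ratio: float
    fold_change: float
    t_p_value: float
    fdr: float
    validated: bool


@dataclass
class ValidatedProbeSet:
    """Validated probes per subtype; a probe belongs to at most one subtype."""

    probes: dict[str, list[str]]
    provenance: dict = field(default_factory=dict)

    def all_probes(self) -> list[str]:
        return [p for probes in self.probes.values() for p in probes]


def signed_fold_change(subtype_ratio: float) -> float:
    """Negative-inverse convention: ratio >= 1 -> ratio, ratio < 1 -> -1/ratio.

    The boundary ratio = 1.0 maps to +1.0 (assigned to the >= 1 branch).
    """
    if not subtype_ratio > 0:
        raise ValueError(f"subtype ratio must be positive, got {subtype_ratio}")
    if subtype_ratio >= 1.0:
        return float(subtype_ratio)
    return float(-1.0 / subtype_ratio)


def validate_signature_probes(training: ExpressionCohort,
                              labels: pd.Series,
                              signatures: SignatureCollection,
                              fc_min: float = 2.0,
                              fdr_max: float = 0.05
                              ) -> tuple[list[ProbeValidationRecord],
                                         ValidatedProbeSet]:
    """Validate signature probes against subtype labels on a training cohort.

    For each signature gene's probes: unlog (2^x), per-subtype linear means,
    subtype ratio = own / sum(others), signed fold change; Welch two-sample
    t-test (own subtype vs all others) on log2 values; one BH family over
    all probes tested in this run. A probe passing the gates for two
    subtypes is assigned to the one with larger fold change.
    """
    labels = labels.reindex(training.sample_ids)
    if labels.isna().any():
        raise DesignError("every training sample needs a subtype label")
    counts = labels.value_counts()
    for subtype in signatures.set_names():
        if counts.get(subtype, 0) < 2:
            raise DesignError(f"subtype {subtype!r} has "
                              f"{counts.get(subtype, 0)} samples (need >= 2)")
    gene_to_probes: dict[str, list[str]] = {}
    for probe in training.probe_ids:
        gene_to_probes.setdefault(training.gene_of(probe), []).append(probe)

    subtype_masks = {s: (labels == s).to_numpy()
                     for s in signatures.set_names()}
    linear = np.exp2(training.matrix.to_numpy())
    probe_index = {p: i for i, p in enumerate(training.probe_ids)}

    rows = []  # (probe, gene, subtype, ratio, fc, p)
    for subtype, genes in signatures.sets.items():
        own = subtype_masks[subtype]
        others = [m for s, m in subtype_masks.items() if s != subtype]
        for gene in genes:
            probes = gene_to_probes.get(gene)
            if not probes:
                logger.warning("signature gene %s has no probe on platform; "
                               "skipped", gene)
                continue
            for probe in probes:
                i = probe_index[probe]
                own_mean = linear[i, own].mean()
                others_sum = sum(linear[i, m].mean() for m in others)
                ratio = own_mean / others_sum
                fc = signed_fold_change(ratio)
                log2_row = training.matrix.iloc[i].to_numpy(dtype=float)
                other_all = ~own & np.logical_or.reduce(others) \
                    if others else ~own
                _, p = stats.ttest_ind(log2_row[own], log2_row[other_all],
                                       equal_var=False)
                rows.append((probe, gene, subtype, ratio, fc, float(p)))

    if not rows:
        raise DesignError("no signature gene mapped to any probe")
    pvals = np.array([r[5] for r in rows])
    fdr = multipletests(pvals, method="fdr_bh")[1]

    records = []
    for (probe, gene, subtype, ratio, fc, p), q in zip(rows, fdr):
        records.append(ProbeValidationRecord(
            probe_id=probe, gene=gene, subtype=subtype,
            subtype_ratio=float(ratio), fold_change=float(fc),
            t_p_value=p, fdr=float(q),
            validated=bool(fc > fc_min and q < fdr_max)))

    # one subtype per probe: keep the larger fold change
    best: dict[str, ProbeValidationRecord] = {}
    for rec in records:
        if rec.validated:
            prev = best.get(rec.probe_id)
            if prev is None or rec.fold_change > prev.fold_change:
                if prev is not None:
                    logger.warning("probe %s validated for %s and %s; "
                                   "assigned to %s", rec.probe_id,
                                   prev.subtype, rec.subtype, rec.subtype)
                best[rec.probe_id] = rec
    per_subtype: dict[str, list[str]] = {s: [] for s in signatures.set_names()}
    for rec in best.values():
        per_subtype[rec.subtype].append(rec.probe_id)
    probe_set = ValidatedProbeSet(
        probes=per_subtype,
        provenance={"training_cohort": training.cohort_id,
                    "fc_min": fc_min, "fdr_max": fdr_max})
    return records, probe_set


def records_to_frame(records: list[ProbeValidationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def average_signature_score(cohort: ExpressionCohort, probes: list[str],
                            scale: str = "log2") -> pd.Series:
    """Per-sample mean expression over a probe list (the subtype score index).

    Averaging is on the log2 scale by default; ``scale='linear'`` averages
    2^x instead. Probes missing from the platform are skipped with a warning.
    """
    present = [p for p in probes if p in cohort.matrix.index]
    missing = set(probes) - set(present)
    if missing:
        logger.warning("%d probes absent from cohort %s skipped",
                       len(missing), cohort.cohort_id)
    if not present:
        raise ValueError("no signature probes present in cohort "
                         f"{cohort.cohort_id}")
    sub = cohort.matrix.loc[present]
    if scale == "linear":
        return np.exp2(sub).mean(axis=0)
    return sub.mean(axis=0)


def pca_signature_distances(cohort: ExpressionCohort,
                            signature_probes: dict[str, list[str]],
                            target_probe: str,
                            n_components: int = 2
                            ) -> tuple[dict[str, float], pd.DataFrame]:
    """Distances between signature probes and the target in PCA space.

    PCA of the probes-as-observations correlation matrix: probes are
    projected onto the leading eigenvectors scaled by sqrt(eigenvalue)
    (normalized eigenvector scaling), and each probe's Euclidean distance
    to the target probe is computed in that plane. Returns per-subtype mean
    distances and the per-probe coordinate/distance table.
    """
    probe_list = [target_probe]
    tags = {target_probe: "target"}
    for subtype, probes in signature_probes.items():
        for p in probes:
            if p not in tags:
                probe_list.append(p)
                tags[p] = subtype
    present = [p for p in probe_list if p in cohort.matrix.index]
    if len(present) < 3:
        raise ValueError("need >= 3 probes for PCA distances")
    if target_probe not in present:
        raise ValueError(f"target probe {target_probe!r} absent from cohort")
    data = cohort.matrix.loc[present].to_numpy(dtype=float)
    if data.shape[1] < 2:
        raise ValueError("need >= 2 samples for PCA distances")
    keep = data.std(axis=1) > 0
    if not keep.all():
        for p, k in zip(present, keep):
            if not k:
                logger.warning("constant probe %s dropped from PCA", p)
        present = [p for p, k in zip(present, keep) if k]
        data = data[keep]
    corr = np.corrcoef(data)
    eigval, eigvec = np.linalg.eigh(corr)
    idx = np.argsort(eigval)[::-1][:n_components]
    coords = eigvec[:, idx] * np.sqrt(np.maximum(eigval[idx], 0.0))
    table = pd.DataFrame(coords, index=present,
                         columns=[f"PC{i + 1}" for i in range(len(idx))])
    table["subtype"] = [tags[p] for p in present]
    target_xy = table.loc[target_probe, table.columns[:-1]].to_numpy(dtype=float)
    diffs = table[table.columns[:-1]].to_numpy(dtype=float) - target_xy
    table["distance_to_target"] = np.sqrt((diffs ** 2).sum(axis=1))
    means = (table[table["subtype"] != "target"]
             .groupby("subtype")["distance_to_target"].mean().to_dict())
    return means, table


def differential_expression(groups_a: ExpressionCohort | pd.DataFrame,
                            mask_a: np.ndarray, mask_b: np.ndarray,
                            fc_min: float = 1.5, fdr_max: float = 0.05
                            ) -> pd.DataFrame:
    """Two-group differential expression with the |linear FC| and FDR gates.

    Used for e.g. receptor-positive vs receptor-negative cell-line panels:
    per probe, linear fold change between group means (signed by the
    negative-inverse convention), Welch t on log2 values, BH FDR, and a
    ``selected`` flag for |fold change| > fc_min and FDR < fdr_max.
    """
    matrix = groups_a.matrix if isinstance(groups_a, ExpressionCohort) \
        else groups_a
    values = matrix.to_numpy(dtype=float)
    linear = np.exp2(values)
    ratio = linear[:, mask_a].mean(axis=1) / linear[:, mask_b].mean(axis=1)
    fc = np.array([signed_fold_change(r) for r in ratio])
    _, p = stats.ttest_ind(values[:, mask_a], values[:, mask_b],
                           axis=1, equal_var=False)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        "probe_id": matrix.index,
        "ratio": ratio,
        "fold_change": fc,
        "p_value": p,
        "fdr": fdr,
        "selected": (np.abs(fc) > fc_min) & (fdr < fdr_max),
    })
    return out.reset_index(drop=True)
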