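"""Per-probe Pearson correlations with a target probe across cohorts.

Correlations are computed per probe, per array, per cohort; each cohort's
tested probes form one BH FDR family. Significant records (FDR < 0.05) are
assembled into silhouette tables (sorted by subtype block, then increasing
r), aggregated to gene level through an at-least-one-significant-probe rule,
and filtered to genes significant in a minimum number of cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionCohort, SignatureCollection

BACKGROUND = "background"


@dataclass
class CorrelationRecord:
    cohort_id: str
    probe_id: str
    gene: str
    subtype: str
    r: float
    p_value: float
    fdr: float
    n: int
    degenerate: bool = False


@dataclass
class SilhouetteTable:
    """Significant correlations in display order (subtype block, r ascending)."""

    records: list[CorrelationRecord]
    subtype_order: list[str]
    fdr_max: float

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def adjust_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _subtype_of(gene: str, signatures: SignatureCollection | None) -> str:
    if signatures is None:
        return BACKGROUND
    for name, genes in signatures.sets.items():
        if gene in genes:
            return name
    return BACKGROUND


def correlate_probes(cohort: ExpressionCohort, target_probe: str,
                     probes: list[str] | None = None,
                     signatures: SignatureCollection | None = None
                     ) -> list[CorrelationRecord]:
    """Pearson r (and two-sided test p) of every probe against the target.

    Degenerate probes (zero variance or < 3 paired values) are flagged and
    excluded from the BH family; all other probes of the call form one
    family.
    """
    if target_probe not in cohort.matrix.index:
        raise ValueError(f"target probe {target_probe!r} not in cohort "
                         f"{cohort.cohort_id}")
    if probes is None:
        probes = [p for p in cohort.probe_ids if p != target_probe]
    y = cohort.expression(target_probe)
    records: list[CorrelationRecord] = []
    testable: list[CorrelationRecord] = []
    for probe in probes:
        x = cohort.expression(probe)
        ok = np.isfinite(x) & np.isfinite(y)
        n = int(ok.sum())
        rec = CorrelationRecord(
            cohort_id=cohort.cohort_id, probe_id=probe,
            gene=cohort.gene_of(probe),
            subtype=_subtype_of(cohort.gene_of(probe), signatures),
            r=np.nan, p_value=np.nan, fdr=np.nan, n=n)
        if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            rec.degenerate = True
        else:
            r, p = stats.pearsonr(x[ok], y[ok])
            rec.r, rec.p_value = float(r), float(p)
            testable.append(rec)
        records.append(rec)
    if testable:
        q = adjust_fdr([rec.p_value for rec in testable])
        for rec, qi in zip(testable, q):
            rec.fdr = float(qi)
    return records


def build_silhouette(records: list[CorrelationRecord],
                     subtype_order: list[str] | None = None,
                     fdr_max: float = 0.05) -> SilhouetteTable:
    """Filter to FDR < fdr_max and sort by (subtype block, r ascending).

    Ties on r break lexicographically by probe_id; an empty result is valid.
    """
    kept = [r for r in records
            if not r.degenerate and np.isfinite(r.fdr) and r.fdr < fdr_max]
    if subtype_order is None:
        seen: dict[str, None] = {}
        for r in kept:
            seen.setdefault(r.subtype, None)
        subtype_order = list(seen)
    rank = {s: i for i, s in enumerate(subtype_order)}
    kept.sort(key=lambda r: (rank.get(r.subtype, len(rank)), r.r, r.probe_id))
    return SilhouetteTable(records=kept, subtype_order=subtype_order,
                           fdr_max=fdr_max)


def aggregate_gene_level(records: list[CorrelationRecord],
                         direction: str = "positive",
                         fdr_max: float = 0.05) -> pd.DataFrame:
    """Per-gene counts of significant (probe, cohort) records in a direction.

    A gene is flagged when at least one of its probe-cohort records is
    significant (FDR < fdr_max) with the requested sign. Returns one row
    per gene: gene, subtype, n_records, n_significant, n_cohorts_significant,
    flagged.
    """
    if direction not in ("positive", "negative"):
        raise ValueError(f"direction must be positive/negative, got {direction!r}")
    sign = 1.0 if direction == "positive" else -1.0
    rows: dict[str, dict] = {}
    for rec in records:
        if rec.degenerate:
            continue
        row = rows.setdefault(rec.gene, {
            "gene": rec.gene, "subtype": rec.subtype, "n_records": 0,
            "n_significant": 0, "cohorts": set()})
        row["n_records"] += 1
        if np.isfinite(rec.fdr) and rec.fdr < fdr_max and sign * rec.r > 0:
            row["n_significant"] += 1
            row["cohorts"].add(rec.cohort_id)
    out = pd.DataFrame([
        {"gene": v["gene"], "subtype": v["subtype"],
         "n_records": v["n_records"], "n_significant": v["n_significant"],
         "n_cohorts_significant": len(v["cohorts"]),
         "flagged": v["n_significant"] >= 1}
        for v in rows.values()
    ])
    return out.sort_values("gene").reset_index(drop=True)


def subtype_flagged_fractions(records: list[CorrelationRecord],
                              direction: str = "positive",
                              fdr_max: float = 0.05) -> pd.DataFrame:
    """Fraction of genes per subtype with >= 1 significant record."""
    genes = aggregate_gene_level(records, direction=direction, fdr_max=fdr_max)
    if genes.empty:
        return pd.DataFrame(columns=["subtype", "n_genes", "n_flagged",
                                     "fraction"])
    grp = genes.groupby("subtype").agg(
        n_genes=("gene", "size"), n_flagged=("flagged", "sum")).reset_index()
    grp["fraction"] = grp["n_flagged"] / grp["n_genes"]
    return grp


def genes_correlated_in_min_cohorts(records: list[CorrelationRecord],
                                    min_cohorts: int = 4,
                                    fdr_max: float = 0.05) -> list[str]:
    """Genes with significant positive correlations in >= min_cohorts cohorts.

    Any probe counts toward a cohort; the gene must reach the cohort quorum
    (e.g. at least 4 of 8 studies).
    """
    available = {rec.cohort_id for rec in records}
    if min_cohorts > len(available):
        raise ValueError(f"min_cohorts={min_cohorts} exceeds the "
                         f"{len(available)} cohorts present")
    genes = aggregate_gene_level(records, direction="positive",
                                 fdr_max=fdr_max)
    if genes.empty:
        return []
    hit = genes.loc[genes["n_cohorts_significant"] >= min_cohorts, "gene"]
    return sorted(hit)


def correlate_signature_averages(cohort_data: list[tuple[ExpressionCohort,
                                                         pd.Series]],
                                 target_probe: str,
                                 center: bool = False
                                 ) -> tuple[float, float, dict[str, float], int]:
    """Target-vs-signature-score correlation, pooled and per cohort.

    ``cohort_data`` pairs each cohort with its per-sample signature score
    vector (aligned to the cohort's samples). Pooling concatenates samples
    across cohorts; with ``center=True`` target and scores are mean-centered
    per cohort first (guards against batch-driven inflation), while the
    default pools raw values.

    Returns (pooled r, pooled p, per-cohort r, pooled n).
    """
    xs, ys, per_cohort = [], [], {}
    for cohort, scores in cohort_data:
        y = cohort.expression(target_probe)
        x = scores.reindex(cohort.sample_ids).to_numpy(dtype=float)
        if x.size != y.size:
            raise ValueError("scores not aligned with cohort samples")
        r, _ = stats.pearsonr(x, y)
        per_cohort[cohort.cohort_id] = float(r)
        if center:
            x = x - x.mean()
            y = y - y.mean()
        xs.append(x)
        ys.append(y)
    x_all = np.concatenate(xs)
    y_all = np.concatenate(ys)
    r, p = stats.pearsonr(x_all, y_all)
    return float(r), float(p), per_cohort, int(x_all.size)
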