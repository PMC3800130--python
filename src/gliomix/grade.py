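"""Association of target-gene expression with WHO grade or histology.

Pooled cohorts are modelled with an additive two-factor linear model,
expression ~ biological factor + study, so that between-study batch offsets
are absorbed by the study term. Group summaries are least-squares means
(model-predicted level means averaged with equal weight over study levels);
contrasts are tested with the linear-contrast t statistic and reported as
linear-scale fold changes, 2^(LS-mean difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ClinicalTable, ExpressionCohort

#: contrast name -> (numerator levels, denominator levels) on the grade factor
GRADE_CONTRASTS = {
    "IV_vs_I-III": (("IV",), ("I", "II", "III")),
    "III+IV_vs_I+II": (("III", "IV"), ("I", "II")),
    "IV_vs_III": (("IV",), ("III",)),
    "IV_vs_rest": (("IV",), ("I", "II", "III")),
}


class RankDeficiencyError(ValueError):
    """A factor level is confounded with the study term."""


@dataclass
class GradeAssociationResult:
    contrast: str
    factor: str
    ls_means: dict[str, float]          # log2 scale, per level
    fold_change: float                  # 2^(LS-mean difference), linear scale
    estimate_log2: float
    p_value: float
    n_per_level: dict[str, int]
    model_terms: list[str] = field(default_factory=list)


def _assemble(cohorts: list[tuple[ExpressionCohort, ClinicalTable]],
              probe: str, factor: str) -> pd.DataFrame:
    frames = []
    for expr, clin in cohorts:
        values = expr.expression(probe)
        meta = clin.for_samples(expr.sample_ids)
        frames.append(pd.DataFrame({
            "expression": values,
            "level": meta[factor].astype(str).to_numpy(),
            "study": expr.cohort_id,
        }))
    df = pd.concat(frames, ignore_index=True)
    return df[df["level"] != "unknown"].reset_index(drop=True)


def fit_grade_model(cohorts: list[tuple[ExpressionCohort, ClinicalTable]],
                    probe: str,
                    factor: str = "grade",
                    contrast: str | tuple = "IV_vs_rest",
                    weighted_ls_means: bool = False) -> GradeAssociationResult:
    """Two-factor ANOVA (factor + study, no interaction) with an LS-mean
    contrast.

    ``contrast`` is a named grade contrast (see :data:`GRADE_CONTRASTS`) or
    an explicit (numerator levels, denominator levels) pair of level tuples.
    With ``weighted_ls_means`` the study averaging uses study sample sizes
    instead of equal weights.
    """
    if isinstance(contrast, str):
        if contrast not in GRADE_CONTRASTS:
            raise ValueError(f"unknown contrast {contrast!r}")
        num_levels, den_levels = GRADE_CONTRASTS[contrast]
        contrast_name = contrast
    else:
        num_levels, den_levels = contrast
        contrast_name = f"{'+'.join(num_levels)}_vs_{'+'.join(den_levels)}"

    df = _assemble(cohorts, probe, factor)
    levels = sorted(df["level"].unique())
    studies = sorted(df["study"].unique())
    if len(levels) < 2:
        raise ValueError(f"need >= 2 {factor} levels, found {levels}")
    used = [lv for lv in (*num_levels, *den_levels) if lv in levels]
    missing = [lv for lv in (*num_levels, *den_levels) if lv not in levels]
    if missing:
        raise ValueError(f"contrast levels absent from data: {missing}")
    counts = df["level"].value_counts().to_dict()
    for lv in used:
        if counts.get(lv, 0) < 2:
            raise ValueError(f"level {lv!r} has {counts.get(lv, 0)} samples")

    # dummy-coded design: intercept + level dummies (ref=first) + study dummies
    level_dummies = pd.get_dummies(df["level"], prefix="lv",
                                   drop_first=True, dtype=float)
    study_dummies = pd.get_dummies(df["study"], prefix="st",
                                   drop_first=True, dtype=float)
    x = pd.concat([pd.Series(1.0, index=df.index, name="intercept"),
                   level_dummies, study_dummies], axis=1)
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # locate a level confined to a single study
        tab = pd.crosstab(df["level"], df["study"])
        for lv in levels:
            if (tab.loc[lv] > 0).sum() == 1:
                raise RankDeficiencyError(
                    f"{factor} level {lv!r} occurs in a single study; "
                    "contrast not estimable")
        raise RankDeficiencyError("design matrix is rank deficient")
    model = sm.OLS(df["expression"].to_numpy(dtype=float), x).fit()

    if weighted_ls_means:
        study_w = df["study"].value_counts(normalize=True)
        weights = np.array([study_w.get(s, 0.0) for s in studies])
    else:
        weights = np.full(len(studies), 1.0 / len(studies))

    def ls_row(level: str) -> np.ndarray:
        """Design row predicting the level mean, averaged over studies."""
        row = pd.Series(0.0, index=x.columns)
        row["intercept"] = 1.0
        col = f"lv_{level}"
        if col in row.index:
            row[col] = 1.0
        for s, w in zip(studies, weights):
            col = f"st_{s}"
            if col in row.index:
                row[col] = w
        return row.to_numpy()

    ls_means = {lv: float(model.predict(ls_row(lv)[None, :])[0])
                for lv in levels}
    c = (np.mean([ls_row(lv) for lv in num_levels], axis=0)
         - np.mean([ls_row(lv) for lv in den_levels], axis=0))
    test = model.t_test(c)
    estimate = float(np.atleast_1d(test.effect)[0])
    return GradeAssociationResult(
        contrast=contrast_name, factor=factor, ls_means=ls_means,
        fold_change=float(2.0 ** estimate), estimate_log2=estimate,
        p_value=float(test.pvalue),
        n_per_level={lv: int(counts.get(lv, 0)) for lv in levels},
        model_terms=[factor, "study"])


def histology_association(cohorts, probe: str,
                          levels: tuple = ("astrocytoma", "oligoastrocytoma",
                                           "oligodendroglioma")
                          ) -> GradeAssociationResult:
    """Overall histology effect (F test) adjusted for study.

    Reports the omnibus p for the histology factor (the 'no discernible
    differences between the three histological subtypes' check); ls_means
    and fold_change compare the first level against the mean of the rest.
    """
    df = _assemble(cohorts, probe, "histology")
    df = df[df["level"].isin(levels)].reset_index(drop=True)
    present = [lv for lv in levels if (df["level"] == lv).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need >= 2 histology levels with >= 2 samples")
    level_dummies = pd.get_dummies(df["level"], prefix="lv",
                                   drop_first=True, dtype=float)
    study_dummies = pd.get_dummies(df["study"], prefix="st",
                                   drop_first=True, dtype=float)
    x = pd.concat([pd.Series(1.0, index=df.index, name="intercept"),
                   level_dummies, study_dummies], axis=1)
    model = sm.OLS(df["expression"].to_numpy(dtype=float), x).fit()
    level_cols = [c for c in x.columns if c.startswith("lv_")]
    restriction = np.zeros((len(level_cols), x.shape[1]))
    for i, col in enumerate(level_cols):
        restriction[i, x.columns.get_loc(col)] = 1.0
    ftest = model.f_test(restriction)
    rest = [lv for lv in present[1:]]
    result = fit_grade_model_from_frame(df, present[0], rest, x, model)
    result.contrast = "histology_3way"
    result.p_value = float(ftest.pvalue)
    return result


def fit_grade_model_from_frame(df, num_level, den_levels, x, model
                               ) -> GradeAssociationResult:
    """Internal: LS-mean summary for an already-fitted additive model."""
    studies = sorted(df["study"].unique())
    weights = np.full(len(studies), 1.0 / len(studies))

    def ls_row(level):
        row = pd.Series(0.0, index=x.columns)
        row["intercept"] = 1.0
        if f"lv_{level}" in row.index:
            row[f"lv_{level}"] = 1.0
        for s, w in zip(studies, weights):
            if f"st_{s}" in row.index:
                row[f"st_{s}"] = w
        return row.to_numpy()

    levels = sorted(df["level"].unique())
    ls_means = {lv: float(model.predict(ls_row(lv)[None, :])[0])
                for lv in levels}
    c = ls_row(num_level) - np.mean([ls_row(lv) for lv in den_levels], axis=0)
    test = model.t_test(c)
    estimate = float(np.atleast_1d(test.effect)[0])
    counts = df["level"].value_counts().to_dict()
    return GradeAssociationResult(
        contrast="custom", factor="histology", ls_means=ls_means,
        fold_change=float(2.0 ** estimate), estimate_log2=estimate,
        p_value=float(test.pvalue),
        n_per_level={lv: int(counts.get(lv, 0)) for lv in levels},
        model_terms=["histology", "study"])


def recurrence_association(cohorts, probe: str) -> GradeAssociationResult:
    """Primary vs recurrent comparison; same additive model with the
    recurrence factor in place of grade."""
    return fit_grade_model(cohorts, probe, factor="recurrence_status",
                           contrast=(("recurrent",), ("primary",)))
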