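"""Synthetic multi-cohort expression + clinical data generator.

Emulates the statistical structure the downstream analyses assume, so the
whole pipeline is testable without microarray downloads:

* a target gene whose per-sample log2 expression is a two-component Gaussian
  mixture (per-cohort mixing fraction ``p_true``, 2–4 log2-unit separation);
* subtype signature-gene blocks (MES, PN, CL, NL, PROLIF) tied to the target
  through a single latent "mesenchymal" factor per sample, with signed
  per-block correlation targets between the target gene and the block
  average;
* per-cohort batch shifts on every probe;
* WHO grade labels with multiplicative (linear-scale) target-gene effects;
* right-censored survival times with an elevated hazard for samples drawn
  from the high-expression mixture component (Weibull proportional hazards;
  shape 1 recovers the exponential special case).

Defaults follow the eight-cohort glioblastoma compendium the pipeline was
designed around: cohort sizes (50, 159, 191, 70, 35, 56, 59, 339) totalling
959 samples, over-expression fractions averaging 0.58 with one low outlier
at 0.37, a mesenchymal correlation near 0.4, and a high-vs-low hazard ratio
of 1.34.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize
from scipy.integrate import quad

from .io import ClinicalTable, ExpressionCohort

DEFAULT_SAMPLE_COUNTS = (50, 159, 191, 70, 35, 56, 59, 339)
#: per-cohort mixing fractions; one deliberately low cohort, mean 0.58
DEFAULT_P_TRUE = (0.53, 0.73, 0.37, 0.63, 0.57, 0.66, 0.55, 0.60)
#: per-cohort target-vs-MES-average correlation targets (range 0.2-0.46)
DEFAULT_MES_CORR = (0.30, 0.46, 0.20, 0.42, 0.35, 0.44, 0.38, 0.43)

DEFAULT_BLOCK_SIZES = {"MES": 25, "PN": 25, "CL": 15, "NL": 15, "PROLIF": 5}
#: canonical signed target-vs-block-average correlations at mes_corr = 0.4
DEFAULT_BLOCK_CORR = {"MES": 0.40, "PN": -0.30, "CL": 0.15, "NL": 0.05,
                      "PROLIF": 0.30}

DEFAULT_GRADE_FOLDS = {"IV_vs_I-III": 3.5, "III+IV_vs_I+II": 2.8,
                       "IV_vs_III": 2.5}
DEFAULT_GRADE_FRACTIONS = {"I": 0.02, "II": 0.19, "III": 0.29, "IV": 0.50}


class DesignError(ValueError):
    """Invalid simulation design."""


def _attenuation(rho: float, k: int) -> float:
    """corr(block average, latent) for k probes each with loading |rho|."""
    return abs(rho) / np.sqrt(rho * rho + (1.0 - rho * rho) / k)


def _loading_for(c: float, k: int) -> float:
    """Per-probe loading giving block-average-vs-latent correlation |c|."""
    c2 = c * c
    return float(np.sqrt(c2 / (k * (1.0 - c2) + c2)))


def grade_shifts_from_folds(folds: dict[str, float]) -> dict[str, float]:
    """log2 target-gene shifts per grade that jointly approximate the three
    grade-contrast fold targets (least squares; the system is slightly
    over-determined so the fit is the closest compromise)."""
    y = np.log2([folds["IV_vs_I-III"], folds["III+IV_vs_I+II"],
                 folds["IV_vs_III"]])
    # unknowns: shifts for II, III, IV relative to grade I = 0
    a = np.array([[-1 / 3, -1 / 3, 1.0],
                  [-1 / 2, 1 / 2, 1 / 2],
                  [0.0, -1.0, 1.0]])
    m2, m3, m4 = np.linalg.lstsq(a, y, rcond=None)[0]
    return {"I": 0.0, "II": float(m2), "III": float(m3), "IV": float(m4)}


@dataclass
class SimulationDesign:
    """Full specification of a synthetic multi-cohort study."""

    sample_counts: tuple = DEFAULT_SAMPLE_COUNTS
    p_true: tuple = DEFAULT_P_TRUE
    mes_corr: tuple = DEFAULT_MES_CORR
    target_gene: str = "IL13RA2"
    mu1: float = 9.0          # high-component mean, log2 units
    mu2: float = 6.0          # low-component mean
    sigma1: float = 0.8
    sigma2: float = 0.8
    block_sizes: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_SIZES))
    block_corr: dict = field(default_factory=lambda: dict(DEFAULT_BLOCK_CORR))
    mes_probe_loading: float = 0.9   # within-block coherence of MES probes
    block_scale: float = 1.0         # log2 SD of signature probes
    n_background_probes: int = 500
    background_sd: float = 0.8
    batch_sd: float = 0.3            # per-cohort, per-probe log2 shift SD
    grade_scheme: str = "gbm_only"   # or "mixed"
    grade_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_GRADE_FRACTIONS))
    grade_folds: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_FOLDS))
    hazard_ratio: float = 1.34       # high vs low component
    median_survival_low: float = 15.6   # months
    weibull_shape: float = 1.68      # 1.0 = exponential
    censoring_fraction: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.sample_counts)
        if len(self.p_true) != n or len(self.mes_corr) != n:
            raise DesignError("sample_counts, p_true and mes_corr must have "
                              "equal length")
        if any(c < 2 for c in self.sample_counts):
            raise DesignError("every cohort needs >= 2 samples")
        if any(not (0.0 <= p <= 1.0) for p in self.p_true):
            raise DesignError("p_true values must lie in [0, 1]")
        if self.mu1 <= self.mu2:
            raise DesignError("mu1 (high component) must exceed mu2")
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise DesignError("component SDs must be positive")
        if self.hazard_ratio <= 0:
            raise DesignError("hazard_ratio must be positive")
        if not (0.0 <= self.censoring_fraction < 1.0):
            raise DesignError("censoring_fraction must be in [0, 1)")
        if self.grade_scheme not in ("gbm_only", "mixed"):
            raise DesignError(f"unknown grade_scheme {self.grade_scheme!r}")
        c_mes = _attenuation(self.mes_probe_loading, self.block_sizes["MES"])
        if any(r >= c_mes for r in self.mes_corr):
            raise DesignError("mes_corr targets must be below the MES block "
                              f"coherence limit {c_mes:.3f}")
        r_mes = self.block_corr["MES"]
        for name, r in self.block_corr.items():
            if abs(r) * c_mes / r_mes >= 1.0:
                raise DesignError(f"block_corr[{name!r}] unreachable under the "
                                  "single-latent-factor construction")

    @property
    def n_cohorts(self) -> int:
        return len(self.sample_counts)

    @property
    def target_probe(self) -> str:
        return f"{self.target_gene}_at"

    def cohort_ids(self) -> list[str]:
        return [f"C{i + 1:02d}" for i in range(self.n_cohorts)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sample_counts"] = list(self.sample_counts)
        d["p_true"] = list(self.p_true)
        d["mes_corr"] = list(self.mes_corr)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationDesign":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("sample_counts", "p_true", "mes_corr"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# probe universe (shared across cohorts so cross-cohort analyses line up)


def probe_universe(design: SimulationDesign) -> pd.DataFrame:
    """Deterministic probe table: probe_id, gene, block tag, baseline log2."""
    rng = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(900_001,)))
    rows = []
    rows.append((design.target_probe, design.target_gene, "target", 0.0))
    for block, size in design.block_sizes.items():
        for i in range(size):
            gene = f"{block}{i + 1:03d}"
            rows.append((f"{gene}_at", gene, block,
                         float(rng.normal(7.0, 1.0))))
    for i in range(design.n_background_probes):
        gene = f"BG{i + 1:04d}"
        rows.append((f"{gene}_at", gene, "background",
                     float(rng.normal(6.5, 1.2))))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "block", "baseline"])


def signature_gene_sets(design: SimulationDesign) -> dict[str, list[str]]:
    """The planted signature gene lists, one entry per block."""
    return {
        block: [f"{block}{i + 1:03d}" for i in range(size)]
        for block, size in design.block_sizes.items()
    }


# ---------------------------------------------------------------------------
# survival machinery


def _weibull_scale(design: SimulationDesign) -> float:
    """Rate parameter lambda with S_low(median_survival_low) = 1/2."""
    return np.log(2.0) / design.median_survival_low ** design.weibull_shape


def _survival_function(design: SimulationDesign, p_high: float):
    lam, k, hr = _weibull_scale(design), design.weibull_shape, design.hazard_ratio

    def s_mix(t):
        return (p_high * np.exp(-lam * hr * t ** k)
                + (1 - p_high) * np.exp(-lam * t ** k))

    return s_mix


def censoring_window(design: SimulationDesign, p_high: float) -> float:
    """Upper end c of the Uniform(0, c) censoring window that yields the
    design censoring fraction in expectation."""
    if design.censoring_fraction == 0.0:
        return np.inf
    s_mix = _survival_function(design, p_high)

    def expected_censoring(c):
        integral, _ = quad(s_mix, 0.0, c, limit=200)
        return integral / c - design.censoring_fraction

    return float(optimize.brentq(expected_censoring, 1e-3, 1e4))


def draw_survival(design: SimulationDesign, high: np.ndarray,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(os_months, event) under Weibull PH with uniform censoring."""
    n = high.size
    lam, k = _weibull_scale(design), design.weibull_shape
    rate = lam * np.where(high, design.hazard_ratio, 1.0)
    t = (-np.log(rng.uniform(size=n)) / rate) ** (1.0 / k)
    c = censoring_window(design, float(high.mean()) if n else 0.0)
    cens = rng.uniform(0.0, c, size=n) if np.isfinite(c) else np.full(n, np.inf)
    event = (t <= cens).astype(int)
    os_months = np.minimum(t, cens)
    return np.round(os_months, 2), event


# ---------------------------------------------------------------------------
# cohort simulation


def _block_loadings(design: SimulationDesign) -> dict[str, float]:
    """Signed per-probe loadings on the latent factor, per block."""
    c_mes = _attenuation(design.mes_probe_loading, design.block_sizes["MES"])
    r_mes = design.block_corr["MES"]
    loadings = {}
    for block, r in design.block_corr.items():
        if block == "MES":
            loadings[block] = design.mes_probe_loading
            continue
        c_b = abs(r) * c_mes / r_mes
        rho = _loading_for(c_b, design.block_sizes[block])
        loadings[block] = float(np.sign(r) * rho)
    return loadings


def _simulate_cohort_arrays(design: SimulationDesign, cohort_index: int):
    if not (0 <= cohort_index < design.n_cohorts):
        raise DesignError(f"cohort_index {cohort_index} out of range")
    n = design.sample_counts[cohort_index]
    rng = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(cohort_index,)))
    universe = probe_universe(design)
    p = design.p_true[cohort_index]

    high = rng.uniform(size=n) < p
    target = np.where(high,
                      rng.normal(design.mu1, design.sigma1, size=n),
                      rng.normal(design.mu2, design.sigma2, size=n))

    # grades (and their multiplicative effect on the target gene)
    if design.grade_scheme == "mixed":
        grades = list(design.grade_fractions)
        probs = np.array([design.grade_fractions[g] for g in grades])
        grade = rng.choice(grades, size=n, p=probs / probs.sum())
        shifts = grade_shifts_from_folds(design.grade_folds)
        target = target + np.array([shifts[g] for g in grade])
    else:
        grade = np.full(n, "IV")

    # single latent factor tied to the (grade-free bimodal part of the)
    # standardized target; drives every signature block
    z = (target - target.mean()) / target.std()
    c_mes = _attenuation(design.mes_probe_loading, design.block_sizes["MES"])
    alpha = design.mes_corr[cohort_index] / c_mes
    latent = alpha * z + np.sqrt(1.0 - alpha * alpha) * rng.normal(size=n)

    loadings = _block_loadings(design)
    rows = []
    order = []
    for _, probe in universe.iterrows():
        order.append(probe.probe_id)
        if probe.block == "target":
            rows.append(target)
        elif probe.block == "background":
            rows.append(probe.baseline
                        + rng.normal(0.0, design.background_sd, size=n))
        else:
            rho = loadings[probe.block]
            noise = rng.normal(size=n)
            rows.append(probe.baseline + design.block_scale
                        * (rho * latent + np.sqrt(1.0 - rho * rho) * noise))
    matrix = np.vstack(rows)

    # cohort batch effect: one log2 shift per probe
    if design.batch_sd > 0:
        matrix = matrix + rng.normal(0.0, design.batch_sd,
                                     size=(matrix.shape[0], 1))

    # survival gets its own stream: outcomes must not depend on how many
    # probes the expression panel happens to carry
    rng_surv = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(cohort_index, 1)))
    os_months, event = draw_survival(design, high, rng_surv)
    age = np.clip(rng_surv.normal(54.0, 14.0, size=n), 18.0, 90.0)
    sex = rng_surv.choice(["male", "female"], size=n)
    return universe, order, matrix, high, latent, grade, os_months, event, age, sex


def simulate_cohort(design: SimulationDesign, cohort_index: int
                    ) -> tuple[ExpressionCohort, ClinicalTable]:
    """One cohort's expression matrix and clinical table.

    Deterministic under (design.seed, cohort_index).
    """
    expr, clin, _ = simulate_cohort_with_truth(design, cohort_index)
    return expr, clin


def simulate_cohort_with_truth(design: SimulationDesign, cohort_index: int
                               ) -> tuple[ExpressionCohort, ClinicalTable, pd.DataFrame]:
    """As :func:`simulate_cohort`, plus the ground-truth sidecar rows."""
    (universe, order, matrix, high, latent, grade,
     os_months, event, age, sex) = _simulate_cohort_arrays(design, cohort_index)
    cohort_id = design.cohort_ids()[cohort_index]
    n = matrix.shape[1]
    sample_ids = [f"{cohort_id}_s{j + 1:04d}" for j in range(n)]
    frame = pd.DataFrame(np.round(matrix, 4), index=order, columns=sample_ids)
    probe_to_gene = dict(zip(universe.probe_id, universe.gene))
    expr = ExpressionCohort(cohort_id=cohort_id, matrix=frame,
                            probe_to_gene=probe_to_gene,
                            platform_tag="synthetic")
    histology = np.where(grade == "IV", "GBM", "astrocytoma")
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "cohort_id": cohort_id,
        "grade": grade,
        "histology": histology,
        "recurrence_status": "primary",
        "age_years": np.round(age, 1),
        "sex": sex,
        "os_months": os_months,
        "event": event,
    }))
    truth = pd.DataFrame({
        "cohort_id": cohort_id,
        "sample_id": sample_ids,
        "component": np.where(high, "high", "low"),
        "latent": np.round(latent, 6),
        "p_true": design.p_true[cohort_index],
    })
    return expr, clin, truth


@dataclass
class MultiCohortResult:
    cohorts: list  # list of (ExpressionCohort, ClinicalTable)
    truth: pd.DataFrame
    design: SimulationDesign


def simulate_multi_cohort(design: SimulationDesign) -> MultiCohortResult:
    """All cohorts of the design plus the pooled ground-truth sidecar."""
    cohorts, truths = [], []
    for i in range(design.n_cohorts):
        expr, clin, truth = simulate_cohort_with_truth(design, i)
        cohorts.append((expr, clin))
        truths.append(truth)
    return MultiCohortResult(cohorts=cohorts,
                             truth=pd.concat(truths, ignore_index=True),
                             design=design)


def simulate_training_cohort(design: SimulationDesign, n_per_subtype: int = 40,
                             effect_log2: float = 3.5, noise_sd: float = 0.8
                             ) -> tuple[ExpressionCohort, pd.Series]:
    """Labeled training cohort for signature-probe validation.

    Each sample carries a known subtype label; each block probe is shifted up
    by ``effect_log2`` log2 units in its own subtype only. The default effect
    clears the own/(sum of others) > 2 linear-ratio validation gate with
    margin, emulating strongly subtype-specific signature genes.
    """
    if n_per_subtype < 2:
        raise DesignError("need >= 2 samples per subtype")
    rng = np.random.default_rng(
        np.random.SeedSequence(design.seed, spawn_key=(900_002,)))
    universe = probe_universe(design)
    subtypes = list(design.block_sizes)
    labels = np.repeat(subtypes, n_per_subtype)
    n = labels.size
    rows, order = [], []
    for _, probe in universe.iterrows():
        order.append(probe.probe_id)
        base = probe.baseline + rng.normal(0.0, noise_sd, size=n)
        if probe.block in design.block_sizes:
            base = base + np.where(labels == probe.block, effect_log2, 0.0)
        elif probe.block == "target":
            base = design.mu2 + rng.normal(0.0, design.sigma2, size=n) \
                + np.where(labels == "MES", design.mu1 - design.mu2, 0.0)
        rows.append(base)
    cohort_id = "TRAIN"
    sample_ids = [f"{cohort_id}_s{j + 1:04d}" for j in range(n)]
    frame = pd.DataFrame(np.round(np.vstack(rows), 4), index=order,
                         columns=sample_ids)
    expr = ExpressionCohort(cohort_id=cohort_id, matrix=frame,
                            probe_to_gene=dict(zip(universe.probe_id,
                                                   universe.gene)),
                            platform_tag="synthetic-training")
    return expr, pd.Series(labels, index=sample_ids, name="subtype")
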