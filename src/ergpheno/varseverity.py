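"""Elastic-net scoring of genetic variant severity from ERG amplitudes.

For each ERG amplitude component, an elastic-net regression maps per-variant
allele counts (plus age, sex, and pupil class) to the z-scored component
value. Known cis pairs are collapsed into complex-allele columns; patients
without exactly two recognized alleles are excluded. Standardized variant
coefficients act as a severity score: higher values indicate milder
variants. Models are evaluated by leave-one-out cross-validation r² on
pooled out-of-sample predictions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV

from ergpheno.config import RunConfig
from ergpheno.errors import ValidationError
from ergpheno.signal import COMPONENT_COLUMNS

#: Cis pairs treated as one complex allele when carried together.
DEFAULT_CIS_PAIRS = (
    ("c.5603A>T", "c.2588G>C"),
    ("c.5603A>T", "c.5461-10T>C"),
)

OTHER_COLUMN = "other"
COVARIATE_COLUMNS = ("age_years", "sex_male", "pupil_ge7mm")


def parse_alleles(
    variant_a: str | None,
    variant_b: str | None,
    cis_pairs=DEFAULT_CIS_PAIRS,
) -> list[str]:
    """Resolve a patient's genotype strings into a list of alleles.

    Each slot may itself be a complex allele ``"v1;v2"``. Any known cis
    pair present in the combined variant multiset is merged into a single
    complex allele (named ``"v1;v2"`` in the declared pair order).
    """
    variants: list[str] = []
    for slot in (variant_a, variant_b):
        if isinstance(slot, str) and slot:
            variants.extend(v for v in slot.split(";") if v)
    for p, q in cis_pairs:
        while p in variants and q in variants:
            variants.remove(p)
            variants.remove(q)
            variants.append(f"{p};{q}")
    return variants


@dataclass
class DesignMatrix:
    """Regression design for one ERG component."""

    X: pd.DataFrame
    y: np.ndarray  # z-scored response
    variant_cols: list[str]
    covariate_cols: list[str]
    patients: list[str]
    response_mean: float
    response_sd: float
    component: str


def build_design_matrix(
    cohort: pd.DataFrame,
    components: pd.DataFrame,
    component: str,
    cis_pairs=DEFAULT_CIS_PAIRS,
    min_count: int = 2,
    pool_other: bool = True,
) -> DesignMatrix:
    """Allele-count design matrix with z-scored component response.

    ``components`` is a wide component matrix indexed by patient. Retains
    patients with exactly two alleles (after cis merging) and a finite
    response. Variants carried by fewer than ``min_count`` retained
    patients are pooled into an ``"other"`` column (or dropped from the
    panel when ``pool_other`` is False).
    """
    if component not in components.columns:
        raise ValidationError(f"unknown component {component!r}")
    rows = []
    for _, rec in cohort.iterrows():
        pid = rec["patient_id"]
        alleles = parse_alleles(rec.get("variant_a"), rec.get("variant_b"), cis_pairs)
        if len(alleles) != 2:
            continue  # one recognized variant, or more than two
        if pid not in components.index or not np.isfinite(components.at[pid, component]):
            continue
        rows.append((pid, alleles, rec))
    if not rows:
        raise ValidationError("no eligible patients for the design matrix")

    carrier_count: dict[str, int] = {}
    for _, alleles, _ in rows:
        for v in set(alleles):
            carrier_count[v] = carrier_count.get(v, 0) + 1
    panel = sorted(v for v, c in carrier_count.items() if c >= min_count)
    pooled = sorted(set(carrier_count) - set(panel))
    if pooled:
        warnings.warn(
            f"{len(pooled)} sub-threshold variant(s) pooled into {OTHER_COLUMN!r}",
            stacklevel=2,
        )

    variant_cols = panel + ([OTHER_COLUMN] if pool_other and pooled else [])
    data, y, patients = [], [], []
    for pid, alleles, rec in rows:
        counts = dict.fromkeys(variant_cols, 0.0)
        for v in alleles:
            col = v if v in panel else (OTHER_COLUMN if pool_other else None)
            if col is not None:
                counts[col] += 1.0
        covs = {
            "age_years": float(rec["age_years"]),
            "sex_male": 1.0 if rec["sex"] == "M" else 0.0,
            "pupil_ge7mm": 1.0 if rec["pupil_class"] == ">=7mm" else 0.0,
        }
        data.append({**counts, **covs})
        y.append(float(components.at[pid, component]))
        patients.append(pid)

    X = pd.DataFrame(data, index=patients)[variant_cols + list(COVARIATE_COLUMNS)]
    y = np.asarray(y)
    mean, sd = float(y.mean()), float(y.std(ddof=0))
    yz = (y - mean) / sd if sd > 0 else np.zeros_like(y)
    return DesignMatrix(
        X=X,
        y=yz,
        variant_cols=variant_cols,
        covariate_cols=list(COVARIATE_COLUMNS),
        patients=patients,
        response_mean=mean,
        response_sd=sd,
        component=component,
    )


def _select_alpha(design: DesignMatrix, config: RunConfig) -> float:
    if config.enet_alpha is not None:
        return float(config.enet_alpha)
    cv = ElasticNetCV(
        l1_ratio=config.enet_l1_ratio,
        alphas=config.enet_n_alphas,
        cv=config.enet_cv_folds,
        max_iter=50000,
    )
    cv.fit(design.X.to_numpy(), design.y)
    return float(cv.alpha_)


@dataclass
class ElasticNetFit:
    coefficients: pd.Series  # indexed by design column
    intercept: float
    alpha: float

    @property
    def variant_coefficients(self) -> pd.Series:
        return self.coefficients.drop(list(COVARIATE_COLUMNS), errors="ignore")


def fit_elastic_net(design: DesignMatrix, config: RunConfig) -> ElasticNetFit:
    """Fit the elastic net at the configured (or CV-selected) penalty."""
    if design.response_sd == 0:
        warnings.warn("constant response: returning all-zero coefficients", stacklevel=2)
        return ElasticNetFit(
            pd.Series(0.0, index=design.X.columns), intercept=0.0, alpha=0.0
        )
    alpha = _select_alpha(design, config)
    model = ElasticNet(
        alpha=alpha, l1_ratio=config.enet_l1_ratio, max_iter=200000, tol=1e-10
    )
    model.fit(design.X.to_numpy(), design.y)
    return ElasticNetFit(
        pd.Series(model.coef_, index=design.X.columns),
        intercept=float(model.intercept_),
        alpha=alpha,
    )


def loocv_r2(design: DesignMatrix, config: RunConfig) -> float:
    """Leave-one-out r² on pooled out-of-sample predictions.

    The penalty strength is fixed once (configured value, or internal CV on
    the full design) and reused in every fold.
    """
    n = len(design.y)
    if n < 10:
        raise ValidationError(f"LOOCV requires n >= 10, got {n}")
    alpha = _select_alpha(design, config)
    X = design.X.to_numpy()
    y = design.y
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = ElasticNet(
            alpha=alpha, l1_ratio=config.enet_l1_ratio, max_iter=200000, tol=1e-10
        )
        model.fit(X[mask], y[mask])
        preds[i] = model.predict(X[i : i + 1])[0]
    ss_res = float(np.sum((y - preds) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def coefficient_concordance(coef_table: pd.DataFrame) -> float:
    """Mean pairwise Pearson correlation between component coefficient vectors."""
    coef_table = coef_table.dropna()
    cols = list(coef_table.columns)
    if len(cols) < 2 or len(coef_table) < 3:
        raise ValidationError("concordance needs >= 2 components and >= 3 variants")
    corrs = []
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            a = coef_table[cols[i]].to_numpy()
            b = coef_table[cols[j]].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                warnings.warn(
                    f"constant coefficient vector; skipping pair ({cols[i]}, {cols[j]})",
                    stacklevel=2,
                )
                continue
            corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        raise ValidationError("no non-degenerate component pairs")
    return float(np.mean(corrs))


def rank_variants(coef_table: pd.DataFrame) -> pd.DataFrame:
    """Variants ordered mild to severe by mean standardized coefficient."""
    out = coef_table.copy()
    out["mean_beta"] = out.mean(axis=1)
    return out.sort_values("mean_beta", ascending=False, kind="mergesort")


@dataclass
class SeverityResult:
    coefficients: pd.DataFrame  # variants x components
    covariates: pd.DataFrame  # covariates x components
    loocv_r2: dict[str, float]
    mean_r2: float
    concordance: float

    def ranked(self) -> pd.DataFrame:
        return rank_variants(self.coefficients)


def severity_table(
    cohort: pd.DataFrame,
    components: pd.DataFrame,
    config: RunConfig,
    cis_pairs=DEFAULT_CIS_PAIRS,
    min_count: int | None = None,
    run_loocv: bool = True,
) -> SeverityResult:
    """Fit per-component elastic nets and assemble the severity table."""
    min_count = config.min_variant_count if min_count is None else min_count
    comp_cols = [c for c in COMPONENT_COLUMNS if c in components.columns]
    coef_cols, cov_cols, r2 = {}, {}, {}
    for comp in comp_cols:
        design = build_design_matrix(
            cohort, components, comp, cis_pairs=cis_pairs, min_count=min_count
        )
        fit = fit_elastic_net(design, config)
        coef_cols[comp] = fit.variant_coefficients
        cov_cols[comp] = fit.coefficients[list(COVARIATE_COLUMNS)]
        if run_loocv:
            r2[comp] = loocv_r2(design, config)
    coefficients = pd.DataFrame(coef_cols)
    covariates = pd.DataFrame(cov_cols)
    mean_r2 = float(np.mean(list(r2.values()))) if r2 else float("nan")
    return SeverityResult(
        coefficients=coefficients,
        covariates=covariates,
        loocv_r2=r2,
        mean_r2=mean_r2,
        concordance=coefficient_concordance(coefficients),
    )
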