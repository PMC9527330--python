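"""Cohort-level descriptive statistics and classifier summary metrics."""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from ergpheno.errors import ValidationError

GROUPS = (1, 2, 3)


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def prevalence(labels) -> pd.DataFrame:
    """Per-group counts and percentages (half-up rounded to one decimal)."""
    labels = list(labels)
    if not labels:
        raise ValidationError("prevalence requires at least one label")
    bad = sorted({l for l in labels if l not in GROUPS})
    if bad:
        raise ValidationError(f"unknown group labels: {bad}")
    total = len(labels)
    rows = []
    for g in GROUPS:
        count = sum(1 for l in labels if l == g)
        rows.append(
            {"group": g, "count": count, "percent": round_half_up(100.0 * count / total)}
        )
    return pd.DataFrame(rows).set_index("group")


def eye_accounting(
    cohort: pd.DataFrame, traces: pd.DataFrame
) -> dict[str, int]:
    """Patient/eye bookkeeping: ``eyes = 2*bilateral + unilateral``."""
    known = set(cohort["patient_id"])
    eye_sets = traces.groupby("patient_id")["eye"].agg(lambda s: frozenset(s))
    unknown = sorted(set(eye_sets.index) - known)
    if unknown:
        raise ValidationError(f"trace patients missing from cohort table: {unknown[:5]}")
    bilateral = int(sum(len(e) == 2 for e in eye_sets))
    unilateral = int(sum(len(e) == 1 for e in eye_sets))
    return {
        "patients": int(len(eye_sets)),
        "bilateral": bilateral,
        "unilateral": unilateral,
        "eyes": 2 * bilateral + unilateral,
    }


def through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Least-squares slope of y on x with intercept fixed at zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.sum(x * y) / np.sum(x * x))


def interocular_symmetry(eye_components: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and through-origin slope of right on left eye, per component.

    ``eye_components`` is a wide component matrix indexed by
    (patient_id, eye), e.g. from :func:`ergpheno.signal.component_matrix`.
    """
    rows = []
    for comp in eye_components.columns:
        wide = eye_components[comp].unstack("eye")
        if not {"L", "R"}.issubset(wide.columns):
            continue
        pair = wide[["L", "R"]].dropna()
        if len(pair) < 3:
            raise ValidationError(
                f"interocular symmetry for {comp} needs >= 3 bilateral patients"
            )
        r, _ = stats.pearsonr(pair["L"], pair["R"])
        rows.append(
            {
                "component": comp,
                "n_pairs": len(pair),
                "pearson_r": float(r),
                "slope": through_origin_slope(pair["L"].to_numpy(), pair["R"].to_numpy()),
            }
        )
    return pd.DataFrame(rows).set_index("component")


def age_trends(
    components: pd.DataFrame,
    cohort: pd.DataFrame,
    min_patients: int = 5,
    strict: bool = True,
) -> pd.DataFrame:
    """Per (group, component) ordinary least-squares trend of amplitude on age.

    The ``nd`` ("no decline detected") flag is set when the Pearson
    correlation is not significant at p < 0.05. Cells with fewer than
    ``min_patients`` patients raise (``strict``) or are skipped.
    """
    meta = cohort.set_index("patient_id")[["age_years", "group_label"]]
    joined = components.join(meta, how="inner")
    rows = []
    for group, grp in joined.groupby("group_label", sort=True):
        for comp in components.columns:
            sub = grp[[comp, "age_years"]].dropna()
            if len(sub) < min_patients:
                if strict:
                    raise ValidationError(
                        f"age trend for group {group}/{comp} needs >= {min_patients} "
                        f"patients, got {len(sub)}"
                    )
                continue
            if sub["age_years"].nunique() < 2:
                raise ValidationError(f"degenerate (constant) age in group {group}")
            fit = stats.linregress(sub["age_years"], sub[comp])
            rows.append(
                {
                    "group": group,
                    "component": comp,
                    "slope": float(fit.slope),
                    "intercept": float(fit.intercept),
                    "pearson_r": float(fit.rvalue),
                    "p_value": float(fit.pvalue),
                    "nd": bool(fit.pvalue >= 0.05),
                }
            )
    return pd.DataFrame(rows)


def confusion_counts(y_true, y_pred, classes) -> np.ndarray:
    classes = list(classes)
    idx = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[idx[t], idx[p]] += 1
    return cm


def normalize_confusion(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm, dtype=float)
    sums = cm.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = cm / sums
    return np.where(sums > 0, out, 0.0)


def cohen_kappa(cm: np.ndarray) -> float:
    """Cohen's kappa from a square confusion-count matrix.

    Returns NaN (with a warning) when the expected agreement is 1, which
    makes kappa undefined.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError("confusion matrix must be square")
    total = cm.sum()
    if total == 0:
        raise ValidationError("empty confusion matrix")
    p_o = np.trace(cm) / total
    p_e = float(np.sum(cm.sum(axis=0) * cm.sum(axis=1)) / total**2)
    if abs(1.0 - p_e) < 1e-12:
        warnings.warn("expected agreement is 1; kappa undefined", stacklevel=2)
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def _rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    # Mann-Whitney formulation with midranks for ties
    scores = np.concatenate([pos_scores, neg_scores])
    ranks = stats.rankdata(scores)
    n_pos, n_neg = pos_scores.size, neg_scores.size
    rank_sum = ranks[:n_pos].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def ovr_auc(labels, probs: np.ndarray, classes) -> dict:
    """One-vs-rest AUC per class from predicted probability columns."""
    labels = np.asarray(labels)
    probs = np.asarray(probs, dtype=float)
    classes = list(classes)
    if probs.shape != (labels.size, len(classes)):
        raise ValidationError("probability matrix shape mismatch")
    if np.any(probs < -1e-9) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-6):
        raise ValidationError("invalid probability vectors")
    out = {}
    for j, c in enumerate(classes):
        mask = labels == c
        if mask.all() or not mask.any():
            out[c] = float("nan")
            continue
        out[c] = _rank_auc(probs[mask, j], probs[~mask, j])
    return out


def _carried_variants(row) -> set[str]:
    out = set()
    for col in ("variant_a", "variant_b"):
        val = row.get(col, "")
        if isinstance(val, str) and val:
            out.update(v for v in val.split(";") if v)
    return out


def variant_group_profile(
    cohort: pd.DataFrame,
    predictions: pd.DataFrame | None = None,
    min_patients: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-variant percentage of carriers in each phenotype group.

    Returns the expert-label table and, when ``predictions`` (columns
    ``patient_id``, ``predicted``) are given, an aligned model table.
    """
    carriers: dict[str, list[str]] = {}
    for _, row in cohort.iterrows():
        for v in _carried_variants(row):
            carriers.setdefault(v, []).append(row["patient_id"])
    panel = sorted(v for v, pats in carriers.items() if len(pats) >= min_patients)

    expert = cohort.set_index("patient_id")["group_label"]
    pred = (
        predictions.set_index("patient_id")["predicted"]
        if predictions is not None
        else None
    )

    def table(label_map) -> pd.DataFrame:
        rows = []
        for v in panel:
            labs = [label_map[p] for p in carriers[v] if p in label_map.index]
            n = len(labs)
            rows.append(
                {
                    "variant_id": v,
                    "n_patients": n,
                    **{
                        f"group{g}_pct": 100.0 * sum(1 for l in labs if l == g) / n
                        for g in GROUPS
                    },
                }
            )
        return pd.DataFrame(rows).set_index("variant_id")

    expert_tbl = table(expert)
    model_tbl = table(pred) if pred is not None else None
    return expert_tbl, model_tbl
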