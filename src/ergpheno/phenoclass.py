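"""Hierarchical soft-voting phenotype classifier and its nested cross-validation.

Architecture: per stimulus, an ensemble of an RBF SVM, AdaBoost over shallow
decision trees, and logistic regression is fitted on single-trace features
(standard-grid voltages plus age and pupil class); the ensemble probability
is the arithmetic mean of the three calibrated outputs. Single-trace
probabilities are averaged within each eye, then across available eyes, and
the three per-stimulus probability vectors are concatenated as input to a
final SVM that predicts the patient's phenotype group.

Evaluation uses repeated nested five-fold cross-validation at the patient
level: each outer training set is split 80:20 into inner training and
validation (64:16:20 overall), hyperparameters are chosen on inner
validation accuracy only, and all reported metrics come from the untouched
outer test folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from ergpheno import metrics
from ergpheno.config import STIMULI, RunConfig
from ergpheno.errors import ValidationError
from ergpheno.signal import N_STD_SAMPLES, SelectedTraces

logger = logging.getLogger(__name__)

VOLTAGE_COLS = [f"v{i}" for i in range(N_STD_SAMPLES)]
FEATURE_COLS = VOLTAGE_COLS + ["age_years", "pupil"]

BINARY_MAP = {1: "R", 2: "G", 3: "G"}  # restricted vs generalized disease


def combine_groups(labels) -> list[str]:
    """Map 3-class labels to binary: group 1 -> 'R', groups 2/3 -> 'G'."""
    out = []
    for l in labels:
        if l not in BINARY_MAP:
            raise ValidationError(f"unknown group label {l!r}")
        out.append(BINARY_MAP[l])
    return out


def encode_pupil(pupil_class: str) -> float:
    if pupil_class == ">=7mm":
        return 1.0
    if pupil_class == "<7mm":
        return 0.0
    raise ValidationError(f"unknown pupil class {pupil_class!r}")


def build_features(
    selected: list[SelectedTraces], cohort: pd.DataFrame
) -> pd.DataFrame:
    """One row per selected trace: 161 grid voltages + age + pupil class.

    Patients with missing age or pupil metadata are excluded with a log entry.
    """
    meta = cohort.set_index("patient_id")[["age_years", "pupil_class"]]
    rows, mats = [], []
    excluded = set()
    for sel in selected:
        if sel.patient_id not in meta.index:
            excluded.add(sel.patient_id)
            continue
        age = meta.at[sel.patient_id, "age_years"]
        pupil = meta.at[sel.patient_id, "pupil_class"]
        if pd.isna(age) or not isinstance(pupil, str) or not pupil:
            excluded.add(sel.patient_id)
            continue
        for rep, v in zip(sel.repeats, sel.voltages):
            rows.append(
                {
                    "patient_id": sel.patient_id,
                    "eye": sel.eye,
                    "stimulus": sel.stimulus,
                    "repeat": rep,
                    "age_years": float(age),
                    "pupil": encode_pupil(pupil),
                }
            )
            mats.append(v)
    for pid in sorted(excluded):
        logger.info("excluding patient %s: missing age/pupil metadata", pid)
    if not rows:
        raise ValidationError("no usable feature rows")
    feats = pd.DataFrame(rows)
    volt = pd.DataFrame(np.asarray(mats), columns=VOLTAGE_COLS, index=feats.index)
    return pd.concat([feats, volt], axis=1)


def _calibrated_svc(C: float, gamma, seed: int, class_weight=None) -> CalibratedClassifierCV:
    # Platt-style sigmoid calibration of an RBF SVM
    return CalibratedClassifierCV(
        SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight,
            random_state=seed),
        method="sigmoid",
        ensemble=False,
    )


def _make_svm(params: dict, seed: int, class_weight) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", _calibrated_svc(params["C"], params["gamma"], seed, class_weight)),
        ]
    )


def _make_ada(params: dict, seed: int, class_weight) -> AdaBoostClassifier:
    return AdaBoostClassifier(
        estimator=DecisionTreeClassifier(
            max_depth=params["max_depth"], class_weight=class_weight, random_state=seed
        ),
        n_estimators=params["n_estimators"],
        random_state=seed,
    )


def _make_lr(params: dict, seed: int, class_weight) -> Pipeline:
    return Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "clf",
                LogisticRegression(
                    C=params["C"], max_iter=2000, class_weight=class_weight
                ),
            ),
        ]
    )

_BUILDERS = {"svm": _make_svm, "ada": _make_ada, "lr": _make_lr}


@dataclass
class StimulusEnsemble:
    """Soft-voting ensemble of SVM, AdaBoost-DT, and logistic regression."""

    params: dict[str, dict]
    seed: int = 0
    class_weight: str | None = None
    models: dict = field(default_factory=dict)
    classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StimulusEnsemble":
        if np.unique(y).size < 2:
            raise ValidationError("single-class training set")
        for name, builder in _BUILDERS.items():
            model = builder(self.params[name], self.seed, self.class_weight)
            model.fit(X, y)
            self.models[name] = model
        self.classes_ = self.models["svm"].classes_
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        probs = [m.predict_proba(X) for m in self.models.values()]
        return np.mean(probs, axis=0)


def soft_vote(prob_vectors: list[np.ndarray]) -> np.ndarray:
    """Arithmetic mean of calibrated class-probability vectors."""
    return np.mean(np.asarray(prob_vectors, dtype=float), axis=0)


def aggregate_probs(
    prob_df: pd.DataFrame, classes, stimuli=STIMULI
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-trace probabilities -> one concatenated vector per patient.

    Averages within each eye, then over available eyes, per stimulus; a
    stimulus with no traces for a patient is imputed with uniform
    probabilities and the patient flagged.
    """
    classes = list(classes)
    prob_cols = [f"p_{c}" for c in classes]
    eye_mean = prob_df.groupby(["patient_id", "stimulus", "eye"], sort=True)[
        prob_cols
    ].mean()
    stim_mean = eye_mean.groupby(["patient_id", "stimulus"], sort=True).mean()

    patients = sorted(prob_df["patient_id"].unique())
    uniform = np.full(len(classes), 1.0 / len(classes))
    vectors, imputed = [], []
    for pid in patients:
        parts, was_imputed = [], False
        for stim in stimuli:
            try:
                part = stim_mean.loc[(pid, stim)].to_numpy()
            except KeyError:
                part = uniform
                was_imputed = True
            parts.append(part)
        vectors.append(np.concatenate(parts))
        imputed.append(was_imputed)
    cols = [f"{stim}_p_{c}" for stim in stimuli for c in classes]
    out = pd.DataFrame(vectors, index=pd.Index(patients, name="patient_id"), columns=cols)
    return out, pd.Series(imputed, index=out.index, name="imputed")


@dataclass
class HierarchicalModel:
    """Fitted two-level classifier: per-stimulus ensembles + final SVM."""

    ensembles: dict[str, StimulusEnsemble]
    final_svm: CalibratedClassifierCV
    classes: list

    def _trace_probs(self, features: pd.DataFrame) -> pd.DataFrame:
        frames = []
        for stim, ens in self.ensembles.items():
            sub = features[features["stimulus"] == stim]
            if sub.empty:
                continue
            probs = ens.predict_proba(sub[FEATURE_COLS].to_numpy())
            # align ensemble class order onto the global class list
            aligned = np.zeros((len(sub), len(self.classes)))
            for j, c in enumerate(ens.classes_):
                aligned[:, self.classes.index(c)] = probs[:, j]
            frame = sub[["patient_id", "eye", "stimulus"]].copy()
            for j, c in enumerate(self.classes):
                frame[f"p_{c}"] = aligned[:, j]
            frames.append(frame)
        if not frames:
            raise ValidationError("no stimulus data to predict from")
        return pd.concat(frames, ignore_index=True)

    def predict_proba(self, features: pd.DataFrame) -> pd.DataFrame:
        trace_probs = self._trace_probs(features)
        vecs, _ = aggregate_probs(trace_probs, self.classes)
        probs = self.final_svm.predict_proba(vecs.to_numpy())
        aligned = np.zeros((len(vecs), len(self.classes)))
        for j, c in enumerate(self.final_svm.classes_):
            aligned[:, self.classes.index(c)] = probs[:, j]
        return pd.DataFrame(aligned, index=vecs.index, columns=self.classes)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        probs = self.predict_proba(features)
        return probs.idxmax(axis=1)


def _tune_base(
    name: str,
    grid: list[dict],
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    seed: int,
    class_weight,
) -> dict:
    if len(grid) == 1:
        return grid[0]
    best, best_acc = grid[0], -1.0
    for params in grid:
        model = _BUILDERS[name](params, seed, class_weight)
        model.fit(X_tr, y_tr)
        acc = float(np.mean(model.predict(X_val) == y_val))
        if acc > best_acc:
            best, best_acc = params, acc
    return best


def fit_fold(
    features: pd.DataFrame,
    labels: pd.Series,
    train_patients,
    config: RunConfig,
    seed: int,
) -> HierarchicalModel:
    """Fit the full hierarchy on one outer-training set.

    Only the labels of ``train_patients`` are ever read, so outer-test
    labels cannot leak into any fitted parameter.
    """
    train_patients = list(train_patients)
    y_train = labels.loc[train_patients]
    classes = sorted(labels.unique())
    class_weight = "balanced" if config.class_weighted else None

    inner_tr, inner_val = train_test_split(
        train_patients,
        test_size=config.inner_val_fraction,
        stratify=y_train,
        random_state=seed,
    )
    tr_feats = features[features["patient_id"].isin(inner_tr)]
    val_feats = features[features["patient_id"].isin(inner_val)]
    all_feats = features[features["patient_id"].isin(train_patients)]

    grids = {"svm": config.svm_grid, "ada": config.ada_grid, "lr": config.lr_grid}
    ensembles: dict[str, StimulusEnsemble] = {}
    inner_ensembles: dict[str, StimulusEnsemble] = {}
    for stim in STIMULI:
        tr_s = tr_feats[tr_feats["stimulus"] == stim]
        val_s = val_feats[val_feats["stimulus"] == stim]
        all_s = all_feats[all_feats["stimulus"] == stim]
        X_tr = tr_s[FEATURE_COLS].to_numpy()
        y_tr = labels.loc[tr_s["patient_id"]].to_numpy()
        X_val = val_s[FEATURE_COLS].to_numpy()
        y_val = labels.loc[val_s["patient_id"]].to_numpy()
        best = {
            name: _tune_base(name, grids[name], X_tr, y_tr, X_val, y_val, seed, class_weight)
            for name in _BUILDERS
        }
        inner_ensembles[stim] = StimulusEnsemble(best, seed, class_weight).fit(X_tr, y_tr)
        ensembles[stim] = StimulusEnsemble(best, seed, class_weight).fit(
            all_s[FEATURE_COLS].to_numpy(), labels.loc[all_s["patient_id"]].to_numpy()
        )

    # final-SVM C tuned on inner validation patients
    inner_model_stub = HierarchicalModel(inner_ensembles, SVC(), classes)
    tr_vecs, _ = aggregate_probs(inner_model_stub._trace_probs(tr_feats), classes)
    val_vecs, _ = aggregate_probs(inner_model_stub._trace_probs(val_feats), classes)
    best_c, best_acc = config.final_svm_c_grid[0], -1.0
    if len(config.final_svm_c_grid) > 1:
        for c in config.final_svm_c_grid:
            svm = _calibrated_svc(c, "scale", seed)
            svm.fit(tr_vecs.to_numpy(), labels.loc[tr_vecs.index].to_numpy())
            acc = float(
                np.mean(svm.predict(val_vecs.to_numpy()) == labels.loc[val_vecs.index])
            )
            if acc > best_acc:
                best_c, best_acc = c, acc

    stub = HierarchicalModel(ensembles, SVC(), classes)
    full_vecs, _ = aggregate_probs(stub._trace_probs(all_feats), classes)
    final = _calibrated_svc(best_c, "scale", seed)
    final.fit(full_vecs.to_numpy(), labels.loc[full_vecs.index].to_numpy())
    return HierarchicalModel(ensembles, final, classes)


@dataclass
class CVReport:
    """Aggregated results of the repeated nested cross-validation."""

    mode: str
    classes: list
    fold_accuracies: list[float]
    mean_accuracy: float
    se_accuracy: float
    confusion_counts: np.ndarray
    confusion_normalized: np.ndarray
    per_class_accuracy: dict
    kappa: float
    auc: dict
    predictions: pd.DataFrame
    sensitivity: float | None = None
    specificity: float | None = None

    def to_dict(self) -> dict:
        out = {
            "mode": self.mode,
            "classes": [str(c) for c in self.classes],
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "se_accuracy": float(self.se_accuracy),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "per_class_accuracy": {str(k): float(v) for k, v in self.per_class_accuracy.items()},
            "kappa": float(self.kappa),
            "auc": {str(k): float(v) for k, v in self.auc.items()},
        }
        if self.sensitivity is not None:
            out["sensitivity"] = float(self.sensitivity)
            out["specificity"] = float(self.specificity)
        return out


def run_nested_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    config: RunConfig,
    mode: Literal["3class", "binary"] = "3class",
) -> CVReport:
    """Repeated nested five-fold cross-validation at the patient level."""
    labels = labels.copy()
    if mode == "binary":
        labels = pd.Series(
            combine_groups(labels.to_numpy()), index=labels.index, name=labels.name
        )
    patients = np.array(sorted(labels.index))
    labels = labels.loc[patients]
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < config.cv_folds).any():
        raise ValidationError(
            f"each class needs >= {config.cv_folds} patients for stratified folds"
        )

    accs, preds_rows = [], []
    all_true, all_pred = [], []
    prob_rows = []
    for rep in range(config.cv_repeats):
        skf = StratifiedKFold(
            n_splits=config.cv_folds, shuffle=True, random_state=config.seed + 1000 * rep
        )
        for fold, (tr_idx, te_idx) in enumerate(skf.split(patients, labels)):
            fold_seed = config.seed + 1000 * rep + fold
            train_p = patients[tr_idx]
            test_p = patients[te_idx]
            model = fit_fold(features, labels, train_p, config, fold_seed)
            te_feats = features[features["patient_id"].isin(test_p)]
            probs = model.predict_proba(te_feats)
            pred = probs.idxmax(axis=1)
            true = labels.loc[probs.index]
            accs.append(float(np.mean(pred == true)))
            all_true.extend(true.tolist())
            all_pred.extend(pred.tolist())
            prob_rows.append(probs)
            for pid in probs.index:
                preds_rows.append(
                    {
                        "patient_id": pid,
                        "repeat": rep,
                        "fold": fold,
                        "true": true.loc[pid],
                        "predicted": pred.loc[pid],
                        **{f"p_{c}": float(probs.at[pid, c]) for c in classes},
                    }
                )

    cm = metrics.confusion_counts(all_true, all_pred, classes)
    cm_norm = metrics.normalize_confusion(cm)
    pooled_probs = pd.concat(prob_rows).to_numpy()
    auc = metrics.ovr_auc(all_true, pooled_probs, classes)
    report = CVReport(
        mode=mode,
        classes=classes,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        se_accuracy=float(np.std(accs, ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0,
        confusion_counts=cm,
        confusion_normalized=cm_norm,
        per_class_accuracy={c: float(cm_norm[i, i]) for i, c in enumerate(classes)},
        kappa=metrics.cohen_kappa(cm),
        auc=auc,
        predictions=pd.DataFrame(preds_rows),
    )
    if mode == "binary":
        g = classes.index("G")
        r = classes.index("R")
        report.sensitivity = float(cm_norm[g, g])
        report.specificity = float(cm_norm[r, r])
    return report
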