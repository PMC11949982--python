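"""Severity classification experiments: feature assembly, SMOTE balancing,
random-forest cross-validation, AUROC inference and feature ranking.

The workflow mirrors a clinical screening study design:

1. one feature row per subject — the mean of each HRV index over the six
   hourly 15-minute segments, the two oximetry indices (SatMin, T90) and
   five anthropometric attributes;
2. stratified 10-fold cross-validation of a 100-tree random forest without
   depth limit, with SMOTE applied to the *training folds only* so that no
   synthetic row ever reaches a validation fold;
3. per-class one-vs-rest AUROC (multiclass) or a single AUROC (binary) on
   the pooled out-of-fold class probabilities, with subject-level bootstrap
   confidence intervals;
4. impurity-decrease feature importances from a forest fit on the full
   SMOTE-balanced table;
5. DeLong tests between models sharing the same subjects, with
   Benjamini-Hochberg correction across the comparison family.

SMOTE is implemented here directly from its interpolation definition:
synthetic minority rows lie on the segment between a real minority row and
one of its k nearest same-class neighbors (Euclidean distance computed on
standardized features).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .hrv_linear import LINEAR_COLUMNS, SpectralConfig, spectral, time_domain
from .hrv_nonlinear import (EntropyParams, NONLINEAR_COLUMNS, PRSAParams,
                            nonlinear_indices)
from .rri_preprocess import (CorrectionParams, IneligibleSeriesError,
                             InsufficientDataError, correct_rri,
                             select_segments)
from .spo2_metrics import sat_min, t90
from .synthetic_cohort import SubjectRecord, binary_label

__all__ = [
    "HRV_COLUMNS", "SPO2_COLUMNS", "ANTHRO_COLUMNS", "FEATURE_SETS",
    "ExperimentSpec", "ModelReport",
    "segment_features", "subject_features", "build_feature_table",
    "smote_oversample", "run_experiment", "delong_test", "compare_models",
    "benjamini_hochberg",
]

HRV_COLUMNS = LINEAR_COLUMNS + NONLINEAR_COLUMNS        # 34 indices
SPO2_COLUMNS = ["SatMin", "T90"]
ANTHRO_COLUMNS = ["Gender", "Age", "Height", "Weight", "BMI"]

FEATURE_SETS = {
    "hrv": HRV_COLUMNS + ANTHRO_COLUMNS,
    "spo2": SPO2_COLUMNS + ANTHRO_COLUMNS,
    "all": HRV_COLUMNS + SPO2_COLUMNS + ANTHRO_COLUMNS,
}


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one classification experiment."""

    feature_set: str = "all"          # "hrv" | "spo2" | "all"
    task: str = "binary"              # "binary" | "multiclass"
    n_trees: int = 100
    max_depth: int | None = None
    cv_folds: int = 10
    smote_k: int = 5
    seed: int = 0
    bootstrap_reps: int = 2000

    def __post_init__(self) -> None:
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.task not in ("binary", "multiclass"):
            raise ValueError(f"unknown task {self.task!r}")


@dataclass
class ModelReport:
    """Out-of-fold scores and the inference built on them."""

    spec: ExperimentSpec
    classes: list[str]
    subject_ids: list[str]
    y_true: np.ndarray                 # encoded labels, one per subject
    oof_scores: np.ndarray             # (n_subjects, n_classes) probabilities
    auroc: dict[str, float]
    ci: dict[str, tuple[float, float]]
    importances: pd.DataFrame          # feature, pct, rank

    def to_dict(self) -> dict:
        return {
            "feature_set": self.spec.feature_set,
            "task": self.spec.task,
            "auroc": {
                cls: {"point": self.auroc[cls],
                      "ci_low": self.ci[cls][0], "ci_high": self.ci[cls][1]}
                for cls in self.auroc
            },
            "importances": self.importances.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# feature extraction
# ---------------------------------------------------------------------------

def segment_features(
    values: np.ndarray,
    spectral_cfg: SpectralConfig = SpectralConfig(),
    entropy_params: EntropyParams = EntropyParams(),
    prsa_params: PRSAParams = PRSAParams(),
) -> dict[str, float]:
    """All 34 HRV indices of one corrected 15-minute segment."""
    from .rri_preprocess import RRiSeries

    series = RRiSeries(values=np.asarray(values, dtype=float))
    out = time_domain(series)
    out.update(spectral(series, spectral_cfg))
    out.update(nonlinear_indices(series.values, entropy_params, prsa_params))
    return out


def subject_features(
    subject: SubjectRecord,
    correction: CorrectionParams = CorrectionParams(),
    spectral_cfg: SpectralConfig = SpectralConfig(),
    entropy_params: EntropyParams = EntropyParams(),
    prsa_params: PRSAParams = PRSAParams(),
    n_hours: int = 6,
) -> dict[str, float]:
    """One feature row: per-index mean over the six hourly segments plus
    oximetry and anthropometrics.  Raises if any segment is ineligible."""
    segments = select_segments(subject.rri_hours, n_hours=n_hours,
                               params=correction)
    per_segment = []
    for seg in segments:
        corrected = correct_rri(seg, correction)
        per_segment.append(segment_features(
            corrected.values, spectral_cfg, entropy_params, prsa_params))
    hrv = pd.DataFrame(per_segment)[HRV_COLUMNS].mean(axis=0)
    row = hrv.to_dict()
    row["SatMin"] = sat_min(subject.spo2)
    row["T90"] = t90(subject.spo2)
    row["Gender"] = 1.0 if subject.gender == "male" else 0.0
    row["Age"] = subject.age
    row["Height"] = subject.height
    row["Weight"] = subject.weight
    row["BMI"] = subject.bmi
    return row


def build_feature_table(
    cohort: list[SubjectRecord],
    correction: CorrectionParams = CorrectionParams(),
    spectral_cfg: SpectralConfig = SpectralConfig(),
    entropy_params: EntropyParams = EntropyParams(),
    prsa_params: PRSAParams = PRSAParams(),
    n_hours: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the per-subject feature table.

    Returns ``(table, exclusions)``.  Subjects whose recording fails the
    segment or correction eligibility rules are dropped from the table and
    logged with the reason, mirroring a clinical exclusion flow.
    """
    rows, excluded = [], []
    for subj in cohort:
        try:
            row = subject_features(subj, correction, spectral_cfg,
                                   entropy_params, prsa_params, n_hours)
        except IneligibleSeriesError as exc:
            excluded.append({"id": subj.id, "reason": "poor quality",
                             "detail": str(exc)})
            continue
        except InsufficientDataError as exc:
            excluded.append({"id": subj.id, "reason": "insufficient time",
                             "detail": str(exc)})
            continue
        row["id"] = subj.id
        row["severity"] = subj.severity
        row["binary"] = binary_label(subj.ahi)
        rows.append(row)
    cols = FEATURE_SETS["all"] + ["id", "severity", "binary"]
    table = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
    exclusions = pd.DataFrame(excluded, columns=["id", "reason", "detail"])
    return table, exclusions


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Balance all classes to the majority count by SMOTE interpolation.

    Each synthetic row is ``x + u * (nn - x)`` with ``u ~ U[0, 1]``, where
    ``nn`` is one of the ``k`` nearest same-class neighbors of ``x``
    (Euclidean distance on standardized features; interpolation happens in
    the original feature space).  A class with fewer than ``k + 1`` members
    gets a reduced ``k`` with a warning.

    Returns ``(X_out, y_out, synthetic_mask)``; the original rows come
    first, in their input order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / scale
    new_X, new_y = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit == 0:
            continue
        members = np.flatnonzero(y == cls)
        k_eff = min(k, count - 1)
        if k_eff < 1:
            raise ValueError(f"class {cls!r} has a single member; SMOTE impossible")
        if k_eff < k:
            warnings.warn(
                f"class {cls!r} has {count} members < k+1={k + 1}; using k={k_eff}",
                stacklevel=2,
            )
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(Xs[members])
        _, neigh = nn.kneighbors(Xs[members])
        neigh = neigh[:, 1:]  # drop self
        base = rng.integers(0, count, deficit)
        pick = neigh[base, rng.integers(0, k_eff, deficit)]
        u = rng.uniform(0, 1, deficit)[:, None]
        synth = X[members[base]] + u * (X[members[pick]] - X[members[base]])
        new_X.append(synth)
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    X_out = np.vstack(new_X)
    y_out = np.concatenate(new_y)
    synthetic = np.zeros(len(y_out), dtype=bool)
    synthetic[len(y):] = True
    return X_out, y_out, synthetic


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

def _bootstrap_ci(
    y: np.ndarray, scores: np.ndarray, reps: int, seed: int
) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUROC, resampling subjects."""
    rng = np.random.default_rng(seed)
    n = len(y)
    vals = np.empty(reps)
    for b in range(reps):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():       # degenerate resample, redraw
            vals[b] = np.nan
            continue
        vals[b] = roc_auc_score(yb, scores[idx])
    vals = vals[~np.isnan(vals)]
    return float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))


def run_experiment(table: pd.DataFrame, spec: ExperimentSpec) -> ModelReport:
    """Cross-validated random-forest experiment on a feature table.

    SMOTE balancing is fit inside each training fold; validation folds see
    only real subjects.  AUROC is computed on the pooled out-of-fold class
    probabilities — one-vs-rest per class for the multiclass task, a single
    value for the binary task — with subject-level bootstrap CIs.
    Importances come from a forest on the full SMOTE-balanced table.
    """
    features = FEATURE_SETS[spec.feature_set]
    X = table[features].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    label_col = "binary" if spec.task == "binary" else "severity"
    y_raw = table[label_col].to_numpy()
    classes = sorted(np.unique(y_raw).tolist())
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.array([class_index[c] for c in y_raw])

    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.seed)
    oof = np.zeros((len(y), len(classes)))
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr, _ = smote_oversample(X[tr], y[tr], k=spec.smote_k,
                                         seed=spec.seed * 1000 + fold)
        rf = RandomForestClassifier(n_estimators=spec.n_trees,
                                    max_depth=spec.max_depth,
                                    random_state=spec.seed)
        rf.fit(X_tr, y_tr)
        proba = rf.predict_proba(X[te])
        for ci_, cls in enumerate(rf.classes_):
            oof[te, cls] = proba[:, ci_]

    auroc: dict[str, float] = {}
    ci: dict[str, tuple[float, float]] = {}
    if spec.task == "binary":
        pos = class_index["moderate-to-severe"]
        scores = oof[:, pos]
        auroc["binary"] = float(roc_auc_score(y == pos, scores))
        ci["binary"] = _bootstrap_ci((y == pos).astype(int), scores,
                                     spec.bootstrap_reps, spec.seed)
    else:
        for cls in classes:
            k = class_index[cls]
            auroc[cls] = float(roc_auc_score(y == k, oof[:, k]))
            ci[cls] = _bootstrap_ci((y == k).astype(int), oof[:, k],
                                    spec.bootstrap_reps, spec.seed + k)

    # impurity-decrease importances from a full-data balanced forest
    X_full, y_full, _ = smote_oversample(X, y, k=spec.smote_k, seed=spec.seed)
    rf_full = RandomForestClassifier(n_estimators=spec.n_trees,
                                     max_depth=spec.max_depth,
                                     random_state=spec.seed)
    rf_full.fit(X_full, y_full)
    pct = 100.0 * rf_full.feature_importances_
    order = np.argsort(pct)[::-1]
    importances = pd.DataFrame({
        "feature": [features[i] for i in order],
        "pct": pct[order],
        "rank": np.arange(1, len(features) + 1),
    })

    return ModelReport(
        spec=spec, classes=classes,
        subject_ids=table["id"].tolist() if "id" in table else
        [str(i) for i in range(len(y))],
        y_true=y, oof_scores=oof, auroc=auroc, ci=ci,
        importances=importances,
    )


# ---------------------------------------------------------------------------
# ROC inference
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def delong_test(
    y_true: np.ndarray, scores_a: np.ndarray, scores_b: np.ndarray
) -> tuple[float, float, float]:
    """DeLong test for two correlated AUROCs on the same subjects.

    Uses the structural-components (midrank) formulation of the covariance
    of the two AUROC estimates.  Returns ``(delta, z, p_two_sided)``; for
    identical score vectors the difference is 0 and p is 1.
    """
    y_true = np.asarray(y_true).astype(int)
    if set(np.unique(y_true)) - {0, 1}:
        raise ValueError("y_true must be binary 0/1")
    pos = np.flatnonzero(y_true == 1)
    neg = np.flatnonzero(y_true == 0)
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("need both classes for AUROC")

    aucs = np.empty(2)
    v_pos = np.empty((2, m))
    v_neg = np.empty((2, n))
    for idx, scores in enumerate((scores_a, scores_b)):
        scores = np.asarray(scores, dtype=float)
        tx = _midrank(scores[pos])
        ty = _midrank(scores[neg])
        tz = _midrank(scores)
        auc = (tz[pos].sum() - m * (m + 1) / 2.0) / (m * n)
        aucs[idx] = auc
        v_pos[idx] = (tz[pos] - tx) / n                 # V10 components
        v_neg[idx] = 1.0 - (tz[neg] - ty) / m           # V01 components

    s10 = np.cov(v_pos)
    s01 = np.cov(v_neg)
    var = s10 / m + s01 / n
    delta = aucs[0] - aucs[1]
    sd = np.sqrt(max(var[0, 0] + var[1, 1] - 2 * var[0, 1], 0.0))
    if sd == 0:
        return float(delta), 0.0, 1.0
    z = delta / sd
    p = float(2 * stats.norm.sf(abs(z)))
    return float(delta), float(z), p


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (false-discovery-rate control)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def compare_models(
    report_a: ModelReport, report_b: ModelReport, cls: str | None = None
) -> tuple[float, float]:
    """DeLong comparison of two reports built on the same subjects.

    ``cls`` selects the class whose one-vs-rest scores are compared
    (defaults to the positive class of a binary task).  Returns
    ``(delta_auroc, p_raw)``; apply :func:`benjamini_hochberg` across the
    family of comparisons for corrected p-values.
    """
    if report_a.subject_ids != report_b.subject_ids:
        raise ValueError("reports built from different subject sets")
    if cls is None:
        if report_a.spec.task != "binary":
            raise ValueError("cls is required for multiclass reports")
        cls = "moderate-to-severe"
    k = report_a.classes.index(cls)
    y = (report_a.y_true == k).astype(int)
    delta, _, p = delong_test(y, report_a.oof_scores[:, k],
                              report_b.oof_scores[:, k])
    return delta, p
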