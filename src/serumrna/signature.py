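"""Marker-panel selection and bagged-tree classifier evaluation.

A feature enters a category panel only if it passes all three filters:
(1) significant differential expression in the discovery cohort,
(2) mean expression above an RPM threshold (default 10), and
(3) univariate logistic-regression significance below alpha (default 0.05)
on log2(RPM+1).  The logistic filter uses the likelihood-ratio p: the Wald
p is non-monotone near separation (Hauck-Donner effect) and would silently
discard exactly the strongest markers; both statistics are reported.
Panels are evaluated with a bootstrap-aggregated tree
ensemble (sqrt-feature splits): out-of-bag votes give the discovery-side
scores and OOB error, and the fitted ensemble scores a disjoint validation
cohort; ranking quality is summarized as the Mann-Whitney AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata
from sklearn.ensemble import RandomForestClassifier

log = logging.getLogger(__name__)

SEPARATION_COEF = 20.0


@dataclass
class FeatureFilterCriteria:
    require_de: bool = True
    min_mean_expression: float = 10.0   # RPM
    logreg_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_mean_expression <= 0:
            raise ValueError("min_mean_expression must be positive")
        if not 0.0 < self.logreg_alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class LogisticResult:
    coefficient: float
    p_wald: float
    p_lrt: float
    separated: bool


def logistic_fit(values: np.ndarray, labels: np.ndarray) -> LogisticResult:
    """Univariate logistic fit (intercept + slope) by IRLS.

    Returns the slope with its two-sided Wald p (coefficient / standard
    error) and the likelihood-ratio p against the intercept-only model
    (chi-square, 1 df).  Complete separation (|coefficient| > 20 or
    non-convergence) is flagged and assigned the smallest representable
    positive p: such a feature separates the classes perfectly.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    tiny = np.nextafter(0.0, 1.0)
    if np.ptp(x) == 0:
        return LogisticResult(0.0, 1.0, 1.0, False)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.zeros(2)
    converged = False
    for _ in range(50):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        try:
            delta = np.linalg.solve((X.T * w) @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            return LogisticResult(float(beta[1]), tiny, tiny, True)
        beta = beta + delta
        if np.abs(delta).max() < 1e-8:
            converged = True
            break
        if np.abs(beta[1]) > SEPARATION_COEF * 5:
            break
    eta = np.clip(X @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    eps = 1e-300
    dev = -2.0 * float(np.sum(y * np.log(mu + eps)
                              + (1 - y) * np.log(1 - mu + eps)))
    k, n = y.sum(), len(y)
    p0 = k / n
    dev0 = -2.0 * float(k * np.log(p0) + (n - k) * np.log(1 - p0))
    p_lrt = float(chi2.sf(max(dev0 - dev, 0.0), df=1))
    if not converged or abs(beta[1]) > SEPARATION_COEF:
        return LogisticResult(float(beta[1]), tiny, tiny, True)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se
    p_wald = float(2.0 * norm.sf(abs(z)))
    return LogisticResult(float(beta[1]), max(p_wald, tiny),
                          max(p_lrt, tiny), False)


def logistic_wald(values: np.ndarray, labels: np.ndarray
                  ) -> Tuple[float, float, bool]:
    """Slope, two-sided Wald p and separation flag of the univariate fit."""
    res = logistic_fit(values, labels)
    return res.coefficient, res.p_wald, res.separated


def log2_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Classifier input transform: log2(RPM + 1), samples x features."""
    rpm = counts * 1e6 / counts.sum(axis=0)
    return np.log2(rpm + 1.0).T


def select_signature(counts: pd.DataFrame, de_results: pd.DataFrame,
                     labels: pd.Series, category: str,
                     feature_meta: pd.DataFrame,
                     criteria: FeatureFilterCriteria | None = None
                     ) -> List[str]:
    """Three-criterion marker selection within one sncRNA category.

    Deterministic given its inputs; returns an empty list (with a warning)
    when nothing qualifies.
    """
    if criteria is None:
        criteria = FeatureFilterCriteria()
    labels = labels[counts.columns]
    y = (labels == "AML").to_numpy(dtype=float)
    rpm = counts * 1e6 / counts.sum(axis=0)
    X = log2_rpm(counts)
    selected = []
    candidates = feature_meta.index[feature_meta["category"] == category]
    for fid in candidates:
        if fid not in de_results.index or fid not in rpm.index:
            continue
        if criteria.require_de and not bool(de_results.loc[fid, "significant"]):
            continue
        if rpm.loc[fid].mean() <= criteria.min_mean_expression:
            continue
        res = logistic_fit(X[fid].to_numpy(), y)
        if res.p_lrt < criteria.logreg_alpha:
            selected.append(fid)
    if not selected:
        log.warning("no %s features pass the selection criteria", category)
    return selected


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Mann-Whitney AUC: P(score_case > score_control) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


def train_and_oob(panel_values: pd.DataFrame, labels: np.ndarray,
                  n_trees: int = 500, seed: int = 0
                  ) -> Tuple[RandomForestClassifier, float, np.ndarray]:
    """Fit a bagged tree ensemble and score samples out-of-bag.

    ``panel_values`` is samples x features.  Per split, floor(sqrt(panel))
    candidate features are considered; each sample's OOB score is the
    fraction of trees not trained on it that vote for the case class, and
    the OOB error is the misclassification rate at score 0.5.
    """
    if panel_values.shape[1] == 0:
        raise ValueError("panel is empty")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    model = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        oob_score=True, random_state=seed, n_jobs=1,
    )
    model.fit(panel_values.to_numpy(), y)
    pos = int(np.flatnonzero(model.classes_ == 1)[0])
    oob_scores = model.oob_decision_function_[:, pos]
    oob_scores = np.where(np.isnan(oob_scores), 0.5, oob_scores)
    oob_error = float(np.mean((oob_scores > 0.5).astype(int) != y))
    return model, oob_error, oob_scores


@dataclass
class ClassifierReport:
    category: str
    panel: List[str]
    n_trees: int
    oob_error: float
    auc_discovery: float
    auc_validation: float
    importances: Dict[str, float]
    separation_flags: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "category": self.category, "panel": list(self.panel),
            "n_trees": self.n_trees, "oob_error": self.oob_error,
            "auc_discovery": self.auc_discovery,
            "auc_validation": self.auc_validation,
            "importances": dict(self.importances),
            "separation_flags": list(self.separation_flags),
        }


def evaluate_panels(
    discovery_counts: pd.DataFrame, discovery_labels: pd.Series,
    de_results: pd.DataFrame, feature_meta: pd.DataFrame,
    validation_counts: pd.DataFrame, validation_labels: pd.Series,
    categories: Sequence[str] = ("miRNA", "tsRNA"),
    criteria: FeatureFilterCriteria | None = None,
    n_trees: int = 500, seed: int = 0,
) -> Dict[str, ClassifierReport]:
    """Select and evaluate one marker panel per category.

    Selection and training touch the discovery cohort only; the validation
    cohort (disjoint sample ids) is scored with the fitted ensemble.  An
    empty panel yields a chance-level report rather than an error.
    """
    overlap = set(discovery_counts.columns) & set(validation_counts.columns)
    if overlap:
        raise ValueError(f"cohorts share sample ids: {sorted(overlap)}")
    if criteria is None:
        criteria = FeatureFilterCriteria()
    y_disc = (discovery_labels[discovery_counts.columns] == "AML"
              ).to_numpy(dtype=int)
    y_val = (validation_labels[validation_counts.columns] == "AML"
             ).to_numpy(dtype=int)
    X_disc = log2_rpm(discovery_counts)
    X_val = log2_rpm(validation_counts)

    reports: Dict[str, ClassifierReport] = {}
    for category in categories:
        panel = select_signature(discovery_counts, de_results,
                                 discovery_labels, category, feature_meta,
                                 criteria)
        flags = []
        for fid in panel:
            _, _, sep = logistic_wald(X_disc[fid].to_numpy(), y_disc)
            if sep:
                flags.append(fid)
        if not panel:
            reports[category] = ClassifierReport(
                category=category, panel=[], n_trees=n_trees,
                oob_error=0.5, auc_discovery=0.5, auc_validation=0.5,
                importances={},
            )
            continue
        model, oob_error, oob_scores = train_and_oob(
            X_disc[panel], y_disc, n_trees=n_trees, seed=seed)
        X_val_panel = X_val.reindex(columns=panel, fill_value=0.0)
        val_scores = model.predict_proba(X_val_panel.to_numpy())
        pos = int(np.flatnonzero(model.classes_ == 1)[0])
        reports[category] = ClassifierReport(
            category=category, panel=panel, n_trees=n_trees,
            oob_error=oob_error,
            auc_discovery=roc_auc(oob_scores, y_disc),
            auc_validation=roc_auc(val_scores[:, pos], y_val),
            importances=dict(zip(panel, map(float, model.feature_importances_))),
            separation_flags=flags,
        )
    return reports
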