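"""Binary-classification metrics and cross-validated evaluation.

Implements the standard suite for protein-pair classification —
accuracy, sensitivity, precision, Matthews correlation coefficient and
ROC/AUC — plus stratified k-fold cross-validation of the full pipeline
(Legendre-moment descriptors -> per-fold PCA -> PCVM), a cross-species
train/test protocol, and an RBF-SVM baseline run on identical features.

Metric conventions: Acc = (TP+TN)/n, Sn = TP/(TP+FN), Pe = TP/(TP+FP),
and MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)).  An
undefined metric (zero denominator) is reported as NaN with a warning,
never silently as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .legendre import LegendreConfig, LMFeatureVector, legendre_moments_exact
from .pairs import apply_projection, build_pair_matrix, fit_projection
from .pcvm import PCVM, FitConfig
from .pssm import PSSM

__all__ = [
    "ConfusionSummary",
    "confusion",
    "metrics",
    "roc_auc",
    "PipelineConfig",
    "CVReport",
    "kfold_cv",
    "cross_species_eval",
    "svm_baseline",
]

METRIC_COLUMNS = ["acc", "sn", "pe", "mcc", "auc"]


@dataclass(frozen=True)
class ConfusionSummary:
    """2 x 2 confusion counts for +/-1 labels (+1 = interacting)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred) -> ConfusionSummary:
    """Count TP/FP/TN/FN for +/-1 label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D of equal length")
    if y_true.size < 1:
        raise ValueError("need at least one sample")
    for v in (y_true, y_pred):
        if not np.all(np.isin(v, (-1, 1))):
            raise ValueError("labels must be +/-1")
    return ConfusionSummary(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        tn=int(np.sum((y_true == -1) & (y_pred == -1))),
        fn=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def metrics(c: ConfusionSummary) -> dict[str, float]:
    """Accuracy, sensitivity, precision and MCC from confusion counts."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    acc = _safe_div(tp + tn, c.n, "accuracy")
    sn = _safe_div(tp, tp + fn, "sensitivity")
    pe = _safe_div(tp, tp + fp, "precision")
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = _safe_div(tp * tn - fp * fn, float(np.sqrt(denom)), "MCC")
    return {"acc": acc, "sn": sn, "pe": pe, "mcc": mcc}


def roc_auc(y_true, scores) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC curve points (fpr, tpr).

    AUC is the rank statistic P(score+ > score-) + P(score+ = score-)/2
    (trapezoidal area with midrank tie handling).  Requires both classes.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC/AUC needs both classes present")
    auc = float(roc_auc_score(y_true, scores))
    fpr, tpr, _ = roc_curve(y_true, scores)
    return auc, fpr, tpr


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    legendre: descriptor settings (max_order 20 -> 441 per protein).
    n_components: PCA width of the reduced pair vector (default 100).
    fit: PCVM EM settings.
    pca_global: fit the PCA once on all pairs instead of per training
        fold (leakage escape hatch; off by default).
    swap_augment: add the swapped concatenation of each training pair.
    svm_baseline: also run the RBF-SVM comparison on the same features.
    """

    legendre: LegendreConfig = field(default_factory=LegendreConfig)
    n_components: int = 100
    fit: FitConfig = field(default_factory=FitConfig)
    pca_global: bool = False
    swap_augment: bool = False
    svm_baseline: bool = False
    svm_c: float = 0.02
    svm_gamma: float = 0.03


@dataclass
class CVReport:
    """Per-fold metrics plus mean and standard deviation.

    folds is a DataFrame with one row per test fold and columns
    acc/sn/pe/mcc/auc; mean and std are recomputed from it.
    """

    folds: pd.DataFrame
    baseline: "CVReport | None" = None
    params: dict = field(default_factory=dict)
    #: out-of-fold scores: one (y_true, proba) pair per test fold
    fold_scores: list = field(default_factory=list, repr=False)

    @property
    def mean(self) -> pd.Series:
        return self.folds[METRIC_COLUMNS].mean()

    @property
    def std(self) -> pd.Series:
        return self.folds[METRIC_COLUMNS].std(ddof=1)

    def to_table(self) -> str:
        """Render the fold/Average table (percentages, +/- SD)."""
        lines = ["Testing Set\tAcc (%)\tSn (%)\tPe (%)\tMcc (%)\tAUC (%)"]
        for idx, row in self.folds.iterrows():
            cells = "\t".join(f"{100 * row[c]:.2f}" for c in METRIC_COLUMNS)
            lines.append(f"{idx}\t{cells}")
        mean, std = self.mean, self.std
        cells = "\t".join(
            f"{100 * mean[c]:.2f} ± {100 * std[c]:.2f}" for c in METRIC_COLUMNS
        )
        lines.append(f"Average\t{cells}")
        return "\n".join(lines) + "\n"

    def save_table(self, path: str | Path) -> None:
        Path(path).write_text(self.to_table())

    def save_roc_points(self, directory: str | Path, prefix: str = "roc") -> None:
        """Write per-fold ROC curve points as TSV (fpr, tpr) files."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, (y_true, proba) in enumerate(self.fold_scores, start=1):
            _, fpr, tpr = roc_auc(y_true, proba)
            pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(
                directory / f"{prefix}_fold{i}.tsv", sep="\t", index=False
            )

    def plot_roc(self, path: str | Path | None = None):
        """Per-fold ROC curves on one axes; saves to path if given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        for i, (y_true, proba) in enumerate(self.fold_scores, start=1):
            auc, fpr, tpr = roc_auc(y_true, proba)
            ax.plot(fpr, tpr, lw=1, label=f"fold {i} (AUC {auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(loc="lower right", fontsize=8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def _descriptor_store(
    store: Mapping[str, PSSM] | Iterable[PSSM] | Mapping[str, LMFeatureVector],
    cfg: LegendreConfig,
) -> dict[str, LMFeatureVector]:
    """Accept PSSMs (mapping or iterable) or precomputed descriptors."""
    if isinstance(store, Mapping):
        values = list(store.values())
    else:
        values = list(store)
    if values and isinstance(values[0], LMFeatureVector):
        return {f.protein_id: f for f in values}
    return {p.protein_id: legendre_moments_exact(p, cfg) for p in values}


def _fit_and_score(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    config: PipelineConfig,
) -> tuple[dict[str, float], np.ndarray]:
    res = PCVM(y_tr, X_tr).fit(config.fit)
    proba = res.predict_proba(X_te)
    row = metrics(confusion(y_te, np.where(proba >= 0.5, 1, -1)))
    row["auc"] = roc_auc(y_te, proba)[0]
    return row, proba


def _svm_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    c: float,
    g: float,
) -> dict[str, float]:
    clf = SVC(C=c, gamma=g, kernel="rbf")
    clf.fit(X_tr, y_tr)
    scores = clf.decision_function(X_te)
    row = metrics(confusion(y_te, np.where(scores >= 0, 1, -1)))
    row["auc"] = roc_auc(y_te, scores)[0]
    return row


def kfold_cv(
    pairs: Sequence[tuple[str, str, int]],
    store,
    config: PipelineConfig = PipelineConfig(),
    k: int = 5,
    seed: int = 0,
) -> CVReport:
    """Stratified k-fold cross-validation of the full pipeline.

    Descriptors are computed once per protein; within each fold the PCA
    projection is fitted on the training pairs only (unless pca_global)
    and the PCVM is trained on the reduced training vectors and scored
    on the held-out fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not pairs:
        raise ValueError("cannot cross-validate an empty pair list")
    features = _descriptor_store(store, config.legendre)
    X_all, y_all = build_pair_matrix(pairs, features)
    counts = np.bincount((y_all > 0).astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"class counts {counts} cannot fill {k} stratified folds")
    global_proj = (
        fit_projection(X_all, config.n_components, fitted_on="all-pairs")
        if config.pca_global
        else None
    )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, svm_rows, fold_scores = [], [], []
    for tr, te in skf.split(X_all, y_all):
        X_tr, y_tr = X_all[tr], y_all[tr]
        if config.swap_augment:
            train_pairs = [pairs[i] for i in tr]
            X_tr, y_tr = build_pair_matrix(train_pairs, features, swap_augment=True)
        proj = global_proj or fit_projection(
            X_tr, config.n_components, fitted_on="train-fold"
        )
        Z_tr = apply_projection(proj, X_tr)
        Z_te = apply_projection(proj, X_all[te])
        row, proba = _fit_and_score(Z_tr, y_tr, Z_te, y_all[te], config)
        rows.append(row)
        fold_scores.append((y_all[te].copy(), proba))
        if config.svm_baseline:
            svm_rows.append(
                _svm_fold(Z_tr, y_tr, Z_te, y_all[te], config.svm_c, config.svm_gamma)
            )
    folds = pd.DataFrame(rows, index=range(1, len(rows) + 1))
    report = CVReport(folds=folds, params={"k": k, "seed": seed},
                      fold_scores=fold_scores)
    if svm_rows:
        report.baseline = CVReport(
            folds=pd.DataFrame(svm_rows, index=range(1, len(svm_rows) + 1)),
            params={"c": config.svm_c, "g": config.svm_gamma, "k": k, "seed": seed},
        )
    return report


def cross_species_eval(
    train_pairs: Sequence[tuple[str, str, int]],
    train_store,
    test_pairs: Sequence[tuple[str, str, int]],
    test_store,
    config: PipelineConfig = PipelineConfig(),
) -> dict[str, float]:
    """Train one model on the full training species, score another species.

    Both sides must use the same descriptor configuration; the PCA and
    the PCVM are fitted on the training species only.  Returns the full
    metric row (acc/sn/pe/mcc/auc) on the test pairs.
    """
    if not test_pairs:
        raise ValueError("empty test pair list")
    feats_tr = _descriptor_store(train_store, config.legendre)
    feats_te = _descriptor_store(test_store, config.legendre)
    X_tr, y_tr = build_pair_matrix(train_pairs, feats_tr, config.swap_augment)
    X_te, y_te = build_pair_matrix(test_pairs, feats_te)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValueError(
            f"feature width mismatch: train {X_tr.shape[1]} vs test {X_te.shape[1]}"
        )
    proj = fit_projection(X_tr, config.n_components, fitted_on="train-species")
    row, _ = _fit_and_score(
        apply_projection(proj, X_tr), y_tr, apply_projection(proj, X_te), y_te, config
    )
    return row


def svm_baseline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    c: float = 0.02,
    g: float = 0.03,
) -> dict[str, float]:
    """RBF-SVM comparison on identical features (library classifier).

    Exists to reproduce the comparison protocol: same reduced pair
    vectors, fixed C and gamma.  The returned row records the parameter
    values used.
    """
    row = _svm_fold(
        np.asarray(X_train, float),
        np.asarray(y_train),
        np.asarray(X_test, float),
        np.asarray(y_test),
        c,
        g,
    )
    row["c"] = c
    row["g"] = g
    return row
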