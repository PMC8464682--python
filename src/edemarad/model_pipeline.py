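"""Dichotomous labeling, best-first wrapper feature selection with a
random-forest evaluator, nested cross-validated evaluation, and the paired
semantic-only versus semantic+radiomics comparison.

The evaluation protocol is deliberately bias-free: feature selection runs
*inside* each training fold, so the held-out fold never influences which
features the classifier sees.  Held-out probabilities are pooled across
folds into a single ROC curve and a single confusion matrix per experiment.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "LABEL_NAMES",
    "LesionRecord",
    "LabelSet",
    "DichotomizeThresholds",
    "dichotomize",
    "SelectionConfig",
    "best_first_select",
    "EvalConfig",
    "EvaluationReport",
    "crossval_evaluate",
    "compare_configurations",
]

#: the five dichotomous prediction targets, canonical order
LABEL_NAMES = ("histology", "grading", "er", "pgr", "ki67")


# ---------------------------------------------------------------------------
# records and labels
# ---------------------------------------------------------------------------


@dataclass
class LesionRecord:
    """Semantic features and raw histological fields for one lesion.

    Semantic fields are the 11 human-recorded descriptors; the raw histology
    fields (type, grade, receptor percentages, Ki-67 index) are thresholded
    into the five binary labels by :func:`dichotomize`.
    """

    lesion_id: str
    age: float                      # years
    menopause: int                  # 0 pre / 1 post
    family_history: int             # 0 / 1 / 2 (= more than one relative)
    hormone_therapy: int            # 0 no / 1 yes
    location: int                   # breast quadrant code 1-5
    stadiation: int                 # stage code 1-4
    margins: int                    # 0 regular / 1 irregular / 2 lobulated / 3 spiculated / 4 non-mass
    dimensions: float               # largest diameter, mm
    morphology: int                 # 0 round / 1 oval / 2 irregular
    kinetic_curve: int              # DCE curve type 1-3
    edema_type: int                 # 1 peritumoral / 2 pre-pectoral / 3 subcutaneous / 4 diffuse
    histological_type: str = "IDC"  # "IDC" or "ILC"
    grade: int = 2                  # Nottingham grade 1-3
    er_percent: float = 0.0         # [0, 100]
    pgr_percent: float = 0.0        # [0, 100]
    her2_status: int = 0            # 0 / 1 (recorded, not a prediction target)
    ki67_percent: float = 0.0       # [0, 100]

    def __post_init__(self) -> None:
        if self.histological_type not in ("IDC", "ILC"):
            raise ValueError(f"histological_type must be IDC or ILC, got {self.histological_type!r}")
        if self.grade not in (1, 2, 3):
            raise ValueError(f"grade must be 1, 2 or 3, got {self.grade}")
        for name in ("er_percent", "pgr_percent", "ki67_percent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.kinetic_curve not in (1, 2, 3):
            raise ValueError(f"kinetic_curve must be 1-3, got {self.kinetic_curve}")
        if self.edema_type not in (1, 2, 3, 4):
            raise ValueError(f"edema_type must be 1-4, got {self.edema_type}")

    def semantic_values(self) -> Dict[str, float]:
        """The 11 semantic features, numerically encoded, canonical order."""
        return {
            "age": float(self.age),
            "menopause": float(self.menopause),
            "family_history": float(self.family_history),
            "hormone_therapy": float(self.hormone_therapy),
            "location": float(self.location),
            "stadiation": float(self.stadiation),
            "margins": float(self.margins),
            "dimensions": float(self.dimensions),
            "morphology": float(self.morphology),
            "kinetic_curve": float(self.kinetic_curve),
            "edema_type": float(self.edema_type),
        }


@dataclass(frozen=True)
class DichotomizeThresholds:
    """Cut points turning raw histology fields into binary labels.

    Receptor thresholds are expressed in percent of immunoreactive cells.
    Defaults: ER/PgR positive at >= 1%, Ki-67 high at >= 14%; both admit
    the alternative cut points in circulation (10% receptors, 20% Ki-67)
    via configuration.
    """

    er: float = 1.0
    pgr: float = 1.0
    ki67: float = 14.0


@dataclass(frozen=True)
class LabelSet:
    """The five binary labels for one lesion.

    Positive classes: ILC (histology), G3 (grading: G1+G2 grouped as the
    negative class), receptor-positive (ER, PgR), Ki-67 high.
    """

    histology: int
    grading: int
    er: int
    pgr: int
    ki67: int

    def __post_init__(self) -> None:
        for name in LABEL_NAMES:
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"label {name} must be 0 or 1")

    def as_dict(self) -> Dict[str, int]:
        return {name: getattr(self, name) for name in LABEL_NAMES}


def dichotomize(record: LesionRecord, thresholds: DichotomizeThresholds | None = None) -> LabelSet:
    """Threshold a record's raw histology fields into the five binary labels."""
    thr = thresholds or DichotomizeThresholds()
    return LabelSet(
        histology=int(record.histological_type == "ILC"),
        grading=int(record.grade == 3),
        er=int(record.er_percent >= thr.er),
        pgr=int(record.pgr_percent >= thr.pgr),
        ki67=int(record.ki67_percent >= thr.ki67),
    )


# ---------------------------------------------------------------------------
# best-first wrapper selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the wrapper search and its random-forest evaluator."""

    n_internal_folds: int = 5     # stratified CV folds scoring each subset
    n_trees: int = 100            # evaluator forest size
    patience: int = 5             # consecutive non-improving expansions before stopping
    epsilon: float = 1e-4         # minimum merit improvement that counts
    max_subset_size: Optional[int] = None  # optional cap on the selected set


def _subset_merit(
    X: np.ndarray,
    y: np.ndarray,
    subset: Tuple[int, ...],
    folds: List[Tuple[np.ndarray, np.ndarray]],
    n_trees: int,
    seed: int,
) -> float:
    """Mean held-out AUC of the evaluator forest over the internal folds."""
    Xs = X[:, subset]
    aucs = []
    for tr, te in folds:
        if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            continue
        rf = RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed, n_jobs=1
        )
        rf.fit(Xs[tr], y[tr])
        prob = rf.predict_proba(Xs[te])[:, list(rf.classes_).index(1)]
        aucs.append(roc_auc_score(y[te], prob))
    return float(np.mean(aucs)) if aucs else 0.0


def best_first_select(
    features: pd.DataFrame | np.ndarray,
    labels: Sequence[int],
    cfg: SelectionConfig | None = None,
    seed: int = 0,
) -> List:
    """Forward best-first search over feature subsets.

    The open list is ordered by merit — the mean AUC of a random forest
    under internal stratified cross-validation on the *given* (training)
    data.  Each expansion adds one unused feature to the best open node; the
    search stops after ``cfg.patience`` consecutive expansions that fail to
    improve the best merit by more than ``cfg.epsilon``.  Ties resolve to
    the earlier feature in canonical column order, and the whole search is
    deterministic under ``seed``.

    Returns the selected feature identifiers (column names for a DataFrame,
    column indices for an array).
    """
    cfg = cfg or SelectionConfig()
    if isinstance(features, pd.DataFrame):
        columns = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        columns = list(range(X.shape[1]))
    y = np.asarray(labels, dtype=int)
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class for wrapper selection")

    n_folds = min(cfg.n_internal_folds, int(counts.min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = [(tr, te) for tr, te in skf.split(X, y)]

    p = X.shape[1]
    evaluated: Dict[Tuple[int, ...], float] = {(): 0.0}
    best_subset: Tuple[int, ...] = ()
    best_merit = 0.0
    # heap entries: (-merit, insertion order) -> earlier-inserted wins ties,
    # and children are inserted in canonical feature order
    heap: List[Tuple[float, int, Tuple[int, ...]]] = [(0.0, 0, ())]
    counter = 1
    stale = 0

    while heap and stale < cfg.patience:
        _, _, node = heapq.heappop(heap)
        if cfg.max_subset_size is not None and len(node) >= cfg.max_subset_size:
            stale += 1
            continue
        improved = False
        for f in range(p):
            if f in node:
                continue
            child = tuple(sorted(node + (f,)))
            if child in evaluated:
                continue
            merit = _subset_merit(X, y, child, folds, cfg.n_trees, seed)
            evaluated[child] = merit
            heapq.heappush(heap, (-merit, counter, child))
            counter += 1
            if merit > best_merit + cfg.epsilon:
                best_merit = merit
                best_subset = child
                improved = True
        stale = 0 if improved else stale + 1

    if not best_subset:
        # nothing beat the empty set by epsilon: fall back to the single
        # best-scoring feature so downstream fits always have a column
        singles = {s: m for s, m in evaluated.items() if len(s) == 1}
        best_subset = max(singles, key=lambda s: (singles[s], -s[0]))
    return [columns[i] for i in best_subset]


# ---------------------------------------------------------------------------
# cross-validated evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvalConfig:
    """Settings for one cross-validated experiment."""

    n_folds: int = 10
    seed: int = 0
    select_inside_folds: bool = True
    n_trees: int = 100            # classifier forest size
    threshold: float = 0.5        # probability cut for the confusion matrix
    selection: SelectionConfig = field(default_factory=SelectionConfig)


@dataclass
class EvaluationReport:
    """Pooled cross-validated performance of one feature configuration."""

    label_name: str
    configuration: str            # "semantic" | "semantic+radiomics" | free-form
    tp: int
    fp: int
    tn: int
    fn: int
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    undefined_rates: List[str]    # rates with zero denominator, reported as 0
    selected_per_fold: List[List]
    fold_assignments: List[List[int]]  # test-row indices per fold
    seed: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def metrics(self) -> Dict[str, float]:
        return {
            "auc": self.auc,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n"] = self.n
        return d


def _safe_rate(num: int, den: int, name: str, flags: List[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def crossval_evaluate(
    features: pd.DataFrame,
    labels: Sequence[int],
    cfg: EvalConfig | None = None,
    label_name: str = "label",
    configuration: str = "custom",
    folds: Optional[List[Tuple[np.ndarray, np.ndarray]]] = None,
) -> EvaluationReport:
    """Stratified k-fold evaluation with in-fold wrapper selection.

    Within each training fold the best-first wrapper picks a feature subset,
    a random forest is fit on it, and held-out probabilities are recorded.
    Pooled held-out probabilities give a single AUC; thresholding them at
    ``cfg.threshold`` gives the pooled confusion matrix and the derived
    rates.  Rates with a zero denominator are reported as 0 and flagged.

    ``folds`` may supply precomputed (train, test) index pairs so that
    paired configurations are evaluated on identical splits.
    """
    cfg = cfg or EvalConfig()
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    columns = list(features.columns)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"label {label_name!r} has a single class; cannot evaluate")

    n_folds = cfg.n_folds
    if counts.min() < n_folds:
        n_folds = max(2, int(counts.min()))
        logger.warning(
            "label %s: minority class (%d) smaller than %d folds; using %d folds",
            label_name, counts.min(), cfg.n_folds, n_folds,
        )
    if folds is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
        folds = [(tr, te) for tr, te in skf.split(X, y)]

    pooled_prob = np.empty(len(y), dtype=float)
    selected_per_fold: List[List] = []
    fold_assignments: List[List[int]] = []
    for k, (tr, te) in enumerate(folds):
        assert len(np.intersect1d(tr, te)) == 0, "train/test folds overlap"
        fold_seed = (cfg.seed * 10007 + k) % (2**31)
        if len(np.unique(y[tr])) < 2:
            # degenerate training fold (extreme imbalance): constant score
            logger.warning("label %s: single-class training fold %d", label_name, k)
            pooled_prob[te] = float(y[tr][0])
            selected_per_fold.append(list(columns))
            fold_assignments.append([int(i) for i in te])
            continue
        if cfg.select_inside_folds:
            sel = best_first_select(
                features.iloc[tr], y[tr], cfg.selection, seed=fold_seed
            )
        else:
            sel = columns
        sel_idx = [columns.index(c) for c in sel]
        rf = RandomForestClassifier(
            n_estimators=cfg.n_trees, max_features="sqrt",
            random_state=fold_seed, n_jobs=1,
        )
        rf.fit(X[np.ix_(tr, sel_idx)], y[tr])
        prob = rf.predict_proba(X[np.ix_(te, sel_idx)])
        pooled_prob[te] = prob[:, list(rf.classes_).index(1)]
        selected_per_fold.append(list(sel))
        fold_assignments.append([int(i) for i in te])

    auc = float(roc_auc_score(y, pooled_prob))
    pred = (pooled_prob >= cfg.threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    flags: List[str] = []
    return EvaluationReport(
        label_name=label_name,
        configuration=configuration,
        tp=tp, fp=fp, tn=tn, fn=fn,
        auc=auc,
        accuracy=(tp + tn) / len(y),
        sensitivity=_safe_rate(tp, tp + fn, "sensitivity", flags),
        specificity=_safe_rate(tn, tn + fp, "specificity", flags),
        ppv=_safe_rate(tp, tp + fp, "ppv", flags),
        npv=_safe_rate(tn, tn + fn, "npv", flags),
        undefined_rates=flags,
        selected_per_fold=selected_per_fold,
        fold_assignments=fold_assignments,
        seed=cfg.seed,
    )


# ---------------------------------------------------------------------------
# paired comparison: semantic-only vs semantic + radiomics
# ---------------------------------------------------------------------------


def compare_configurations(
    features: pd.DataFrame,
    labels: pd.DataFrame,
    cfg: EvalConfig | None = None,
    semantic_columns: Optional[List[str]] = None,
) -> Tuple[Dict[str, Dict[str, EvaluationReport]], pd.DataFrame]:
    """Evaluate every label twice — semantic features only, then the full
    semantic+radiomics vector — on identical folds, and tabulate deltas.

    ``semantic_columns`` defaults to the columns prefixed ``sem_``.  Labels
    with a single class are skipped with a warning.  Returns the per-label
    report pairs and a delta table with one row per label and, per metric,
    the semantic-only value, the combined value and their difference.
    """
    cfg = cfg or EvalConfig()
    if semantic_columns is None:
        semantic_columns = [c for c in features.columns if c.startswith("sem_")]
    if not semantic_columns:
        raise ValueError("no semantic columns found (and none given)")

    reports: Dict[str, Dict[str, EvaluationReport]] = {}
    rows = []
    for li, label_name in enumerate(labels.columns):
        y = labels[label_name].to_numpy(dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            logger.warning("label %s has a single class; skipped", label_name)
            continue
        pair_seed = (cfg.seed * 131 + li) % (2**31)
        pair_cfg = EvalConfig(
            n_folds=cfg.n_folds, seed=pair_seed,
            select_inside_folds=cfg.select_inside_folds,
            n_trees=cfg.n_trees, threshold=cfg.threshold,
            selection=cfg.selection,
        )
        n_folds = min(cfg.n_folds, max(2, int(counts.min())))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=pair_seed)
        folds = [(tr, te) for tr, te in skf.split(features, y)]

        rep_sem = crossval_evaluate(
            features[semantic_columns], y, pair_cfg,
            label_name=label_name, configuration="semantic", folds=folds,
        )
        rep_full = crossval_evaluate(
            features, y, pair_cfg,
            label_name=label_name, configuration="semantic+radiomics", folds=folds,
        )
        reports[label_name] = {"semantic": rep_sem, "semantic+radiomics": rep_full}
        row: Dict[str, float | str] = {"label": label_name}
        for metric, a in rep_sem.metrics().items():
            b = rep_full.metrics()[metric]
            row[f"{metric}_semantic"] = a
            row[f"{metric}_combined"] = b
            row[f"{metric}_delta"] = b - a
        rows.append(row)
    delta = pd.DataFrame(rows)
    return reports, delta
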