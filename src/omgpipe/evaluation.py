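"""Random-Forest expression recognition with leave-one-subject-out evaluation.

Per LOSO fold, the training partition (all participants but one) has its
neutral class undersampled to the rounded mean count of the four expression
classes, a Random Forest is fit, and the held-out participant's windows are
predicted.  The single model trained per fold is reused for every
condition-sliced report (intensity, head movement, glasses position); slices
restrict only the *test* windows.

Reports carry the raw 5x5 confusion matrix, a row-normalized view, per-class
precision/recall/f1, unweighted macro averages, overall accuracy and
per-participant accuracies.  Metrics are kept in full precision; rounding to
two decimals happens only in the formatted presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from . import vocab


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Random-Forest ensemble configuration.

    Each tree is fit on a 15% bootstrap subsample with sqrt(d) features per
    split and unlimited depth; at this cohort's class separability the
    accuracy plateaus well below 40 trees, so the modest ensemble keeps a
    full LOSO run cheap on a single core.
    """

    n_estimators: int = 40
    max_features: str | float = "sqrt"
    max_depth: int | None = None
    max_samples: float | None = 0.15
    undersample_seed: int = 1
    model_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise EvaluationError("n_estimators must be >= 1")


@dataclass
class EvaluationReport:
    """Confusion matrix + classification report for one (sliced) evaluation."""

    counts: pd.DataFrame  # rows = true, columns = predicted
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_participant_accuracy: dict[str, float] = field(default_factory=dict)
    n_instances: int = 0

    @property
    def normalized(self) -> pd.DataFrame:
        """Row-normalized confusion matrix (rows with support sum to 1)."""
        c = self.counts.to_numpy(float)
        rowsum = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            norm = np.where(rowsum > 0, c / rowsum, 0.0)
        return pd.DataFrame(norm, index=self.counts.index, columns=self.counts.columns)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.counts.index),
            "confusion_counts": self.counts.to_numpy().tolist(),
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_participant_accuracy": self.per_participant_accuracy,
            "n_instances": self.n_instances,
        }

    def formatted(self) -> str:
        """Two-decimal classification report in the conventional layout."""
        lines = [f"{'class':<15}{'precision':>10}{'recall':>10}{'f1-score':>10}"]
        for c in self.counts.index:
            lines.append(
                f"{c:<15}{self.precision[c]:>10.2f}{self.recall[c]:>10.2f}{self.f1[c]:>10.2f}"
            )
        lines.append(f"{'accuracy':<15}{'':>10}{'':>10}{self.accuracy:>10.2f}")
        lines.append(
            f"{'macro avg':<15}{self.macro_precision:>10.2f}"
            f"{self.macro_recall:>10.2f}{self.macro_f1:>10.2f}"
        )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# fold bookkeeping


def loso_folds(table: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds: (held-out id, train index, test index)."""
    pids = table["participant_id"].to_numpy()
    unique = list(dict.fromkeys(pids))  # stable order of appearance
    if len(unique) < 2:
        raise EvaluationError("LOSO requires at least 2 participants")
    folds = []
    for pid in unique:
        test = np.flatnonzero(pids == pid)
        train = np.flatnonzero(pids != pid)
        folds.append((pid, train, test))
    return folds


def undersample_neutral(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Downsample neutral rows to the rounded mean of the expression counts.

    Sampling is without replacement and deterministic in ``seed``; the four
    expression classes are untouched.  Intended for training folds only.
    """
    counts = table["label"].value_counts()
    missing = [c for c in vocab.CLASSES if c not in counts.index]
    if missing:
        raise EvaluationError(f"class(es) absent from training data: {missing}")
    target = int(round(np.mean([counts[e] for e in vocab.EXPRESSIONS])))
    n_neutral = int(counts[vocab.NEUTRAL])
    if n_neutral <= target:
        return table
    rng = np.random.default_rng(seed)
    neutral_pos = np.flatnonzero((table["label"] == vocab.NEUTRAL).to_numpy())
    keep_neutral = rng.choice(neutral_pos, size=target, replace=False)
    keep = np.sort(
        np.concatenate([np.flatnonzero((table["label"] != vocab.NEUTRAL).to_numpy()), keep_neutral])
    )
    return table.iloc[keep]


# ---------------------------------------------------------------------------
# training / prediction


def _matrix(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    return table[cols].to_numpy(np.float32)


def train_and_predict(
    train: pd.DataFrame,
    test: pd.DataFrame,
    config: TrainConfig | None = None,
    feature_cols: list[str] | None = None,
) -> np.ndarray:
    """Undersample-neutral -> fit Random Forest -> predict the test windows."""
    from .features import feature_columns

    config = config or TrainConfig()
    cols = feature_cols or feature_columns()
    train = undersample_neutral(train, config.undersample_seed)
    clf = RandomForestClassifier(
        n_estimators=config.n_estimators,
        max_features=config.max_features,
        max_depth=config.max_depth,
        max_samples=config.max_samples,
        random_state=config.model_seed,
        n_jobs=1,
    )
    clf.fit(_matrix(train, cols), train["label"].to_numpy())
    return clf.predict(_matrix(test, cols))


def _undersample_indices(labels: np.ndarray, idx: np.ndarray, seed: int) -> np.ndarray:
    """Index-level variant of :func:`undersample_neutral` (same policy)."""
    lab = labels[idx]
    counts = {c: int((lab == c).sum()) for c in vocab.CLASSES}
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise EvaluationError(f"class(es) absent from training data: {missing}")
    target = int(round(np.mean([counts[e] for e in vocab.EXPRESSIONS])))
    if counts[vocab.NEUTRAL] <= target:
        return idx
    rng = np.random.default_rng(seed)
    neutral = idx[lab == vocab.NEUTRAL]
    keep = rng.choice(neutral, size=target, replace=False)
    return np.sort(np.concatenate([idx[lab != vocab.NEUTRAL], keep]))


def run_loso(table: pd.DataFrame, config: TrainConfig | None = None) -> pd.DataFrame:
    """LOSO predictions for every window; returns metadata + true/predicted.

    The feature matrix is materialised once (float32) and folds slice it,
    which keeps the 27-fold run linear in the table size.
    """
    from .features import METADATA_COLUMNS, feature_columns

    config = config or TrainConfig()
    cols = feature_columns()
    x = table[cols].to_numpy(np.float32)
    y = table["label"].to_numpy()
    predicted = np.empty(len(table), dtype=object)
    for _, train_idx, test_idx in loso_folds(table):
        train_idx = _undersample_indices(y, train_idx, config.undersample_seed)
        clf = RandomForestClassifier(
            n_estimators=config.n_estimators,
            max_features=config.max_features,
            max_depth=config.max_depth,
            max_samples=config.max_samples,
            random_state=config.model_seed,
            n_jobs=1,
        )
        clf.fit(x[train_idx], y[train_idx])
        predicted[test_idx] = clf.predict(x[test_idx])
    out = table[list(METADATA_COLUMNS)].copy()
    out = out.rename(columns={"label": "true"})
    out["predicted"] = predicted
    return out


# ---------------------------------------------------------------------------
# reporting


def build_report(
    y_true,
    y_pred,
    participant_ids=None,
) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise EvaluationError("label sequences must have equal length")
    bad = set(y_true) | set(y_pred)
    if not bad <= set(vocab.CLASSES):
        raise EvaluationError(f"labels outside vocabulary: {sorted(bad - set(vocab.CLASSES))}")
    classes = list(vocab.CLASSES)
    counts = confusion_matrix(y_true, y_pred, labels=classes)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, zero_division=0
    )
    per_part: dict[str, float] = {}
    if participant_ids is not None:
        pids = np.asarray(participant_ids)
        for pid in dict.fromkeys(pids):
            mask = pids == pid
            per_part[str(pid)] = float(np.mean(y_true[mask] == y_pred[mask]))
    return EvaluationReport(
        counts=pd.DataFrame(counts, index=classes, columns=classes),
        precision=dict(zip(classes, map(float, prec))),
        recall=dict(zip(classes, map(float, rec))),
        f1=dict(zip(classes, map(float, f1))),
        accuracy=float(np.mean(y_true == y_pred)),
        macro_precision=float(np.mean(prec)),
        macro_recall=float(np.mean(rec)),
        macro_f1=float(np.mean(f1)),
        per_participant_accuracy=per_part,
        n_instances=int(len(y_true)),
    )


def slice_report(results: pd.DataFrame, mask: np.ndarray, name: str = "slice") -> EvaluationReport:
    """Report restricted to the test windows selected by ``mask``.

    Training is untouched: slices re-score the predictions of the single
    model trained per fold.
    """
    mask = np.asarray(mask, bool)
    if mask.shape[0] != len(results):
        raise EvaluationError("mask length must match the results table")
    if not mask.any():
        raise EvaluationError(f"empty slice: {name!r} selects no test windows")
    sub = results.loc[mask]
    return build_report(
        sub["true"].to_numpy(), sub["predicted"].to_numpy(), sub["participant_id"].to_numpy()
    )


def standard_slices(results: pd.DataFrame) -> dict[str, EvaluationReport]:
    """The condition-sliced reports: intensity, head movement, glasses position.

    Intensity slices partition the controlled (Task A) windows; the movement
    comparison contrasts Task A high-intensity long events against Task B;
    position slices partition Task C.  Neutral windows inside a sliced block
    are included with the block's condition metadata.
    """
    task = results["task"].to_numpy()
    intensity = results["intensity"].to_numpy()
    duration = results["duration"].to_numpy()
    out = {}
    for lv in vocab.INTENSITIES:
        out[f"intensity_{lv}"] = slice_report(
            results, (task == "A") & (intensity == lv), f"intensity_{lv}"
        )
    out["still"] = slice_report(
        results, (task == "A") & (intensity == "high") & (duration == "long"), "still"
    )
    out["moving"] = slice_report(results, task == "B", "moving")
    for pos in vocab.GLASSES_POSITIONS:
        out[f"position_{pos}"] = slice_report(
            results, (task == "C") & (results["glasses_position"].to_numpy() == pos), f"position_{pos}"
        )
    return out
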