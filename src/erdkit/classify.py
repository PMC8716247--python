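"""Recognition-rate estimation with CSP features and an RBF-kernel SVM.

Protocol: band-pass the epochs to the decoding band (default 8-30 Hz, where
the ERD contrast lives), crop to the signal window (default 1-4 s after MI
onset), then run stratified 10-fold cross-validation. Inside each outer
training fold the CSP filters are fitted and the SVM cost C is chosen by an
inner stratified grid search — nothing from the test fold touches the fitted
model, so the reported mean accuracy is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .csp import csp_features, fit_csp
from .preprocess import FilterSpec, bandpass, crop_window
from .trials import TrialSet

__all__ = [
    "EvalProtocol",
    "RecognitionResult",
    "recognition_rate",
    "mi_vs_rest_trialset",
    "condition_rest_rates",
]


@dataclass(frozen=True)
class EvalProtocol:
    """Cross-validated SVM evaluation protocol.

    ``c_grid`` is scanned in ascending order and ties in inner-CV score go
    to the smallest (most regularized) C. ``gamma`` follows the "auto"
    convention: 1 / number of features.
    """

    c_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0)
    n_folds: int = 10
    inner_folds: int = 5
    signal_window: Optional[tuple[float, float]] = (1.0, 4.0)
    band: tuple[float, float] = (8.0, 30.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_folds < 2 or self.inner_folds < 2:
            raise ValueError("n_folds and inner_folds must be >= 2")
        if not self.c_grid:
            raise ValueError("c_grid must be non-empty")


@dataclass
class RecognitionResult:
    """Outer-CV recognition rates for one subject/contrast."""

    fold_accuracies: np.ndarray
    mean_accuracy: float
    chosen_c_per_fold: list[float]
    subject_id: str
    contrast: tuple[str, str]
    #: per-condition recall (fraction of that condition's trials recognized)
    class_rates: dict = field(default_factory=dict)


def _prepare(trials: TrialSet, protocol: EvalProtocol) -> TrialSet:
    out = bandpass(
        trials, FilterSpec(low_cut=protocol.band[0], high_cut=protocol.band[1])
    )
    if protocol.signal_window is not None:
        out = crop_window(out, *protocol.signal_window)
    return out


def recognition_rate(
    trials: TrialSet, protocol: EvalProtocol = EvalProtocol(), n_pairs: int = 3
) -> RecognitionResult:
    """Nested-CV recognition rate of a two-class trial set.

    Outer stratified ``n_folds``-fold CV estimates accuracy; per outer fold,
    CSP is fitted on the training portion only and C is selected by an inner
    stratified grid search on the training portion only.
    """
    protocol.validate()
    classes = trials.conditions
    if len(classes) != 2:
        raise ValueError(f"recognition needs exactly two classes, got {classes}")
    counts = {c: int((trials.condition_labels == c).sum()) for c in classes}
    for c, n in counts.items():
        if n < protocol.n_folds:
            raise ValueError(
                f"class {c!r} has {n} trials < n_folds={protocol.n_folds}"
            )

    prepared = _prepare(trials, protocol)
    y = prepared.condition_labels.astype(str)
    outer = StratifiedKFold(
        n_splits=protocol.n_folds, shuffle=True, random_state=protocol.seed
    )
    fold_acc: list[float] = []
    chosen_c: list[float] = []
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    for k, (train_idx, test_idx) in enumerate(
        outer.split(np.zeros(len(y)), y)
    ):
        train = prepared.select_trials(train_idx)
        test = prepared.select_trials(test_idx)
        model = fit_csp(train, n_pairs=n_pairs)
        f_train = csp_features(model, train)
        f_test = csp_features(model, test)
        inner = StratifiedKFold(
            n_splits=protocol.inner_folds,
            shuffle=True,
            random_state=protocol.seed + 1 + k,
        )
        search = GridSearchCV(
            SVC(kernel="rbf", gamma="auto"),
            param_grid={"C": list(protocol.c_grid)},
            cv=inner,
        )
        search.fit(f_train.features, f_train.labels.astype(str))
        pred = search.predict(f_test.features)
        truth = f_test.labels.astype(str)
        fold_acc.append(float((pred == truth).mean()))
        chosen_c.append(float(search.best_params_["C"]))
        for c in classes:
            m = truth == c
            total[c] += int(m.sum())
            correct[c] += int((pred[m] == c).sum())

    accs = np.asarray(fold_acc)
    return RecognitionResult(
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        chosen_c_per_fold=chosen_c,
        subject_id=trials.subject_id,
        contrast=(classes[0], classes[1]),
        class_rates={
            c: (correct[c] / total[c] if total[c] else float("nan"))
            for c in classes
        },
    )


def mi_vs_rest_trialset(
    trials: TrialSet,
    condition: str,
    mi_window: tuple[float, float] = (1.0, 4.0),
    rest_window: tuple[float, float] = (5.0, 8.0),
    rest_label: str = "rest",
) -> TrialSet:
    """Build a two-class set: one condition's MI-window epochs vs same-length
    rest epochs cut from the post-MI relax period of the same trials.

    Both segments are re-anchored onto the MI window's time axis so the
    classifier sees epochs of identical geometry.
    """
    if (mi_window[1] - mi_window[0]) != (rest_window[1] - rest_window[0]):
        raise ValueError("mi_window and rest_window must have equal length")
    cond = trials.select_condition(condition)
    mi = crop_window(cond, *mi_window)
    rest = crop_window(cond, *rest_window)
    rest = replace(
        rest,
        time_origin=mi.time_origin,
        condition_labels=np.array([rest_label] * rest.n_trials, dtype=object),
    )
    return TrialSet.concatenate([mi, rest])


def condition_rest_rates(
    trials: TrialSet,
    protocol: EvalProtocol = EvalProtocol(),
    n_pairs: int = 3,
    rest_window: tuple[float, float] = (5.0, 8.0),
) -> dict[str, RecognitionResult]:
    """Per-condition recognition rate of MI vs rest (one binary decoding per
    condition), mirroring a per-condition recognition-rate table."""
    window = protocol.signal_window or (1.0, 4.0)
    results = {}
    for condition in trials.conditions:
        pair = mi_vs_rest_trialset(
            trials, condition, mi_window=window, rest_window=rest_window
        )
        # epochs are already windowed; skip the protocol's crop
        results[condition] = recognition_rate(
            pair, replace(protocol, signal_window=None), n_pairs=n_pairs
        )
    return results
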