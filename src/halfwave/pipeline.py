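"""End-to-end sleep-stage classification protocol.

Epochs -> level-2 Halfwave reduction -> six time-domain features ->
stratified 60-40 train/test split -> feature standardization (train
statistics) -> ADASYN oversampling of the training partition only ->
KNN (K=2, Gram-trick squared distances) -> pooled
sensitivity/specificity/accuracy report.

Balancing happens strictly after the split and only on the training side, so
no synthetic copy of a test neighbourhood leaks into training (a literal
pre-split mode exists for replication attempts).  Every run is deterministic
under its seed and carries a provenance block (config echo, class histograms
before/after balancing).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .balance import BalanceConfig, balance
from .features import Epoch, HalfwaveFeatureExtractor
from .metrics import EvalReport, class_sort_key, confusion, report
from .neighbors import GramKNNClassifier

__all__ = ["RunConfig", "PipelineResult", "SleepStager", "run", "run_record_suite"]


@dataclass(frozen=True)
class RunConfig:
    """Protocol knobs; defaults reproduce the published experimental setup."""

    level: int = 2
    epoch_seconds: float = 30.0
    fs: float = 250.0
    split_fraction: float = 0.6
    stratified: bool = True
    k: int = 2
    distance: str = "gram"
    balance: str = "adasyn"
    balance_k: int = 5
    seed: int = 17
    standardize: bool = True
    balance_before_split: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")
        if self.balance not in ("adasyn", "smote", "none"):
            raise ValueError(f"unknown balance method {self.balance!r}")


@dataclass(frozen=True)
class PipelineResult:
    report: EvalReport
    provenance: dict
    y_test: np.ndarray
    y_pred: np.ndarray
    test_features: np.ndarray

    def to_dict(self) -> dict:
        return {"report": self.report.to_dict(), "provenance": self.provenance}


class SleepStager(ClassifierMixin, BaseEstimator):
    """Sleep-stage classifier over raw epochs.

    ``fit`` takes X of shape ``(n_epochs, n_samples)`` and stage labels;
    internally it extracts the six Halfwave features, standardizes them,
    oversamples the training classes to the largest class count, and fits the
    Gram-trick KNN.  ``predict`` maps raw epochs through the same feature
    transform and scaler.
    """

    def __init__(
        self,
        level: int = 2,
        fs: float = 250.0,
        k: int = 2,
        distance: str = "gram",
        balance_method: str = "adasyn",
        balance_k: int = 5,
        standardize: bool = True,
        random_state: int | None = None,
    ):
        self.level = level
        self.fs = fs
        self.k = k
        self.distance = distance
        self.balance_method = balance_method
        self.balance_k = balance_k
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_features=2)
        self.classes_ = unique_labels(y)
        self.extractor_ = HalfwaveFeatureExtractor(level=self.level, fs=self.fs)
        F = self.extractor_.fit_transform(X)
        if self.standardize:
            self.scaler_ = StandardScaler().fit(F)
            F = self.scaler_.transform(F)
        else:
            self.scaler_ = None
        self.class_counts_before_ = _histogram(y)
        if self.balance_method != "none":
            cfg = BalanceConfig(
                method=self.balance_method,
                k_neighbors=self.balance_k,
                seed=self.random_state,
            )
            F, y, _ = balance(F, y, cfg)
        self.class_counts_after_ = _histogram(y)
        self.knn_ = GramKNNClassifier(
            n_neighbors=self.k, algorithm=self.distance
        ).fit(F, y)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        F = self.extractor_.transform(X)
        if self.scaler_ is not None:
            F = self.scaler_.transform(F)
        return self.knn_.predict(F)


def _histogram(y) -> dict:
    labels, counts = np.unique(np.asarray(y, dtype=str), return_counts=True)
    return {str(l): int(c) for l, c in zip(labels, counts)}


def _epochs_to_arrays(
    data: Sequence[Epoch] | tuple[np.ndarray, np.ndarray],
    labels=None,
) -> tuple[np.ndarray, np.ndarray]:
    if labels is not None:
        return np.asarray(data, dtype=float), np.asarray(labels, dtype=object)
    first = data[0]
    if isinstance(first, Epoch):
        X = np.vstack([ep.signal.samples for ep in data])
        y = np.asarray([ep.label for ep in data], dtype=object)
        return X, y
    raise TypeError("pass labelled Epoch objects, or (epochs_array, labels)")


def run(
    config: RunConfig,
    data: Sequence[Epoch] | np.ndarray,
    labels: Sequence[str] | None = None,
) -> PipelineResult:
    """Execute the full protocol on labelled epochs and report pooled metrics.

    ``data`` is either a sequence of labelled :class:`~halfwave.features.Epoch`
    objects or an ``(n_epochs, n_samples)`` array with ``labels`` alongside.
    """
    X, y = _epochs_to_arrays(data, labels)
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to run the protocol")
    singletons = [str(c) for c, n in zip(classes, counts) if n < 2]
    if singletons:
        raise ValueError(
            f"class(es) {singletons} have a single epoch; stratified splitting "
            "needs >= 2 per class — merge classes or provide more data"
        )

    stager = SleepStager(
        level=config.level,
        fs=config.fs,
        k=config.k,
        distance=config.distance,
        balance_method=config.balance,
        balance_k=config.balance_k,
        standardize=config.standardize,
        random_state=config.seed,
    )

    if config.balance_before_split:
        # literal replication mode: oversample everything, then split
        ext = HalfwaveFeatureExtractor(level=config.level, fs=config.fs)
        F = ext.fit_transform(X)
        cfg = BalanceConfig(
            method=config.balance if config.balance != "none" else "adasyn",
            k_neighbors=config.balance_k,
            seed=config.seed,
        )
        F_b, y_b, _ = balance(F, y, cfg)
        F_tr, F_te, y_tr, y_te = train_test_split(
            F_b,
            y_b,
            train_size=config.split_fraction,
            random_state=config.seed,
            stratify=y_b if config.stratified else None,
        )
        if config.standardize:
            sc = StandardScaler().fit(F_tr)
            F_tr, F_te = sc.transform(F_tr), sc.transform(F_te)
        knn = GramKNNClassifier(
            n_neighbors=config.k, algorithm=config.distance
        ).fit(F_tr, y_tr)
        y_pred = knn.predict(F_te)
        hist_before = _histogram(y)
        hist_after = _histogram(y_b)
        test_features = F_te
    else:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X,
            y,
            train_size=config.split_fraction,
            random_state=config.seed,
            stratify=y if config.stratified else None,
        )
        stager.fit(X_tr, y_tr)
        y_pred = stager.predict(X_te)
        hist_before = stager.class_counts_before_
        hist_after = stager.class_counts_after_
        test_features = stager.extractor_.transform(X_te)

    ordered = sorted(map(str, classes), key=class_sort_key)
    cm = confusion(y_te, y_pred, classes=ordered)
    rep = report(cm)
    provenance = {
        "config": asdict(config),
        "n_epochs": int(len(y)),
        "n_train": int(len(y) - len(y_te)),
        "n_test": int(len(y_te)),
        "class_counts_before_balancing": hist_before,
        "train_class_counts_after_balancing": hist_after,
    }
    return PipelineResult(
        report=rep,
        provenance=provenance,
        y_test=np.asarray(y_te),
        y_pred=np.asarray(y_pred),
        test_features=test_features,
    )


def run_record_suite(
    config: RunConfig,
    records: Mapping[str, tuple[np.ndarray, Sequence[str]] | Sequence[Epoch]],
) -> dict:
    """Per-record evaluation table plus the arithmetic average row.

    ``records`` maps record ids to labelled epochs (Epoch sequences or
    (epochs, labels) tuples), e.g. prepared from slpdb files by the io layer.
    Records that fail to run are listed under ``failed`` and a partial table
    is returned.
    """
    rows = []
    failed = {}
    for rec_id, payload in records.items():
        try:
            if isinstance(payload, tuple):
                result = run(config, payload[0], payload[1])
            else:
                result = run(config, payload)
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            failed[str(rec_id)] = str(exc)
            continue
        rep = result.report
        rows.append(
            {
                "record": str(rec_id),
                "classes": sorted(
                    result.provenance["class_counts_before_balancing"],
                    key=class_sort_key,
                ),
                "sensitivity_pct": rep.sensitivity_pct,
                "specificity_pct": rep.specificity_pct,
                "accuracy_pct": rep.accuracy_pct,
            }
        )
    table: dict = {"rows": rows, "failed": failed}
    if rows:
        table["average"] = {
            key: float(np.mean([r[key] for r in rows]))
            for key in ("sensitivity_pct", "specificity_pct", "accuracy_pct")
        }
    return table
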