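"""Repeated stratified-split evaluation of feature/classifier pipelines.

Protocol, per subject: 10 repeated stratified 70/15/15 train/validation/test
splits of the windowed data; z-score statistics fitted on each split's
training partition; clipping applied in z-units (all partitions by default);
hyperparameters grid-searched on the validation set; window-wise accuracy
reported on the held-out test set.  Aggregation is two-stage: repeats are
averaged within a subject first, then subject means are averaged (with
subject-wise min-max dispersion) — repeats are never pooled across subjects.

Intra-session evaluation repeats the splits within each session; the
inter-session protocol is leave-one-session-out (train+val from the held-in
sessions, test on the held-out one), averaged over folds.

Seeding is hierarchical: split plans depend only on (experiment seed,
subject, session/fold) and classifier seeds only on (experiment seed,
subject, repeat), so two conditions differing only in the degradation consume
identical split plans and paired comparisons are valid.
"""

from __future__ import annotations

import itertools
import logging
import time
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .degrade import DegradationSpec, apply_dropout, clip_signal
from .features import FeatureSpec, assemble_features
from .preprocess import (
    PreprocessConfig,
    WindowSet,
    apply_norm,
    concat_window_sets,
    filter_recording,
    fit_norm_stats,
    replace_windows,
    window_stream,
)
from .synth import Recording

__all__ = [
    "SplitPlan",
    "ClassifierSpec",
    "DEFAULT_GRIDS",
    "make_stratified_splits",
    "tune_and_fit",
    "test_accuracy",
    "evaluate_split",
    "prepare_windows",
    "run_condition",
    "run_sweep",
    "summarize",
    "chance_level",
]

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "subject",
    "session",
    "protocol",
    "classifier",
    "features",
    "degradation",
    "repeat",
    "accuracy",
    "params",
]

DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm-rbf": {"C": [1, 10, 100], "gamma": [0.01, 0.1, 1]},
    "lda": {"shrinkage": [None, "auto"]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 20]},
}


@dataclass(frozen=True)
class SplitPlan:
    """Repeated (train, val, test) index partitions of one window population."""

    repeats: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]
    fractions: tuple[float, float, float]
    seed: int


@dataclass(frozen=True)
class ClassifierSpec:
    """Classifier kind plus hyperparameter grid (None -> the default grid)."""

    kind: str
    grid: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFAULT_GRIDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.grid is not None and not self.grid:
            raise ValueError("grid must be non-empty (or None for defaults)")

    @property
    def effective_grid(self) -> dict[str, list]:
        return self.grid if self.grid is not None else DEFAULT_GRIDS[self.kind]


def _derive_seed(seed: int, *key) -> int:
    """Stable sub-seed from an experiment seed and a mixed int/str key path."""
    ints = tuple(
        zlib.crc32(k.encode()) if isinstance(k, str) else int(k) for k in key
    )
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=ints)
    return int(ss.generate_state(1)[0] % (2**31))


def chance_level(n_classes: int) -> float:
    """Balanced-class chance accuracy, 1/n_classes."""
    return 1.0 / n_classes


# ------------------------------------------------------------------ splits


def make_stratified_splits(
    labels: np.ndarray,
    n_repeats: int = 10,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> SplitPlan:
    """Repeated stratified train/val/test partitions preserving class
    proportions (within integer rounding) in every set."""
    labels = np.asarray(labels)
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("fractions must sum to 1")
    classes, counts = np.unique(labels, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < 3:
            raise ValueError(
                f"class {cls!r} has only {cnt} windows; need >= 3 to stratify"
            )
    idx = np.arange(len(labels))
    n = len(labels)
    n_test = int(round(f_test * n))
    n_val = int(round(f_val * n))
    repeats = []
    for r in range(n_repeats):
        s1 = _derive_seed(seed, 11, r)
        s2 = _derive_seed(seed, 12, r)
        outer = StratifiedShuffleSplit(n_splits=1, test_size=n_test, random_state=s1)
        trainval, test = next(outer.split(idx.reshape(-1, 1), labels))
        inner = StratifiedShuffleSplit(n_splits=1, test_size=n_val, random_state=s2)
        tr_rel, va_rel = next(
            inner.split(trainval.reshape(-1, 1), labels[trainval])
        )
        repeats.append((trainval[tr_rel], trainval[va_rel], test))
    return SplitPlan(repeats=tuple(repeats), fractions=fractions, seed=seed)


# ------------------------------------------------------------- classifiers


def _build_estimator(kind: str, params: dict, seed: int):
    if kind == "svm-rbf":
        return SVC(kernel="rbf", **params)
    if kind == "lda":
        shrinkage = params.get("shrinkage")
        solver = "lsqr" if shrinkage is not None else "svd"
        return LinearDiscriminantAnalysis(solver=solver, shrinkage=shrinkage)
    if kind == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    raise ValueError(f"unknown classifier kind {kind!r}")


def tune_and_fit(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
):
    """Grid search scored by validation accuracy; ties broken by grid order;
    the returned model is fitted on the training partition only."""
    if X_train.shape[1] != X_val.shape[1]:
        raise ValueError("train and val must share columns")
    if len(np.unique(y_train)) < 2:
        raise ValueError("training partition must contain >= 2 classes")
    grid = spec.effective_grid
    keys = list(grid.keys())
    best = None
    for combo in itertools.product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        model = _build_estimator(spec.kind, params, spec.seed)
        model.fit(X_train, y_train)
        acc = accuracy_score(y_val, model.predict(X_val))
        if best is None or acc > best[0]:  # strict: first grid point wins ties
            best = (acc, model, params)
    return best[1], best[2]


def test_accuracy(model, X_test: np.ndarray, y_test: np.ndarray) -> float:
    """Fraction of correctly labeled test windows."""
    n_fit = getattr(model, "n_features_in_", X_test.shape[1])
    if X_test.shape[1] != n_fit:
        raise ValueError("test columns do not match the fitted model")
    return float(accuracy_score(y_test, model.predict(X_test)))


# -------------------------------------------------------------- per split


@dataclass(frozen=True)
class SplitResult:
    """Everything one split produces (norm stats exposed for leakage audits)."""

    accuracy: float
    params: dict
    norm_stats: object


def evaluate_split(
    windows: WindowSet,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
    degradation: DegradationSpec = DegradationSpec(),
    delta: float = 1e-8,
) -> SplitResult:
    """Run one split end to end: fit z-score stats on train, normalize, clip
    in z-units per the degradation scope, extract features, tune on val,
    report test accuracy.  Zero-signal dropout is split-independent and should
    be applied to ``windows`` before calling."""
    tr, va, te = split
    stats = fit_norm_stats(windows.select(tr), delta=delta)
    normed = apply_norm(windows, stats)

    if degradation.kind == "clip":
        if degradation.scope == "all-partitions":
            # in-place saturation of the fresh normalized copy (== clip_signal)
            np.clip(normed.windows, -degradation.tau, degradation.tau,
                    out=normed.windows)
            fm = assemble_features(normed, feature_spec)
            X = fm.values
            X_te = X[te]
        else:  # test-only
            fm = assemble_features(normed, feature_spec)
            X = fm.values
            clipped_te = replace_windows(
                normed.select(te), clip_signal(normed.select(te).windows, degradation.tau)
            )
            X_te = assemble_features(clipped_te, feature_spec).values
    else:
        fm = assemble_features(normed, feature_spec)
        if degradation.kind == "dropout" and degradation.dropout_mode == "drop-columns":
            fm = apply_dropout(fm, degradation)
        X = fm.values
        X_te = X[te]

    y = fm.labels
    model, params = tune_and_fit(classifier_spec, X[tr], y[tr], X[va], y[va])
    acc = test_accuracy(model, X_te, y[te])
    return SplitResult(accuracy=acc, params=params, norm_stats=stats)


# ---------------------------------------------------------------- cohorts


def prepare_windows(
    recordings: list[Recording],
    preproc: PreprocessConfig = PreprocessConfig(),
    dtype: np.dtype | None = None,
) -> dict[str, dict[str, WindowSet]]:
    """Filter and window every recording, grouped subject -> session.

    ``dtype=np.float32`` halves the window-storage footprint for large
    sweeps; feature values then carry ~1e-7 relative rounding, far below any
    effect the sweeps measure.
    """
    out: dict[str, dict[str, WindowSet]] = {}
    for rec in recordings:
        ws = window_stream(
            filter_recording(rec, preproc), preproc.win_ms, preproc.hop_ms,
            preproc.label_rule, dtype=dtype,
        )
        out.setdefault(rec.subject_id, {})[rec.session_id] = ws
    return out


def _maybe_zero_dropout(ws: WindowSet, degradation: DegradationSpec) -> WindowSet:
    if degradation.kind == "dropout" and degradation.dropout_mode == "zero-signal":
        return apply_dropout(ws, degradation)
    return ws


def _feature_label(spec: FeatureSpec) -> str:
    return "+".join(spec.names)


def run_condition(
    cohort: list[Recording] | dict[str, dict[str, WindowSet]],
    feature_spec: FeatureSpec,
    classifier_spec: ClassifierSpec,
    degradation: DegradationSpec = DegradationSpec(),
    protocol: str = "pooled",
    n_repeats: int = 10,
    seed: int = 0,
    preproc: PreprocessConfig = PreprocessConfig(),
) -> pd.DataFrame:
    """Evaluate one (features, classifier, degradation) condition.

    Returns a tidy result table with one row per subject x session/fold x
    repeat (columns ``RESULT_COLUMNS``).
    """
    if protocol not in ("pooled", "intra-session", "inter-session"):
        raise ValueError(f"unknown protocol {protocol!r}")
    prepared = cohort if isinstance(cohort, dict) else prepare_windows(cohort, preproc)
    if not prepared:
        raise ValueError("empty cohort")
    rows = []
    cond = dict(
        protocol=protocol,
        classifier=classifier_spec.kind,
        features=_feature_label(feature_spec),
        degradation=degradation.label,
    )

    for subject in sorted(prepared):
        sessions = prepared[subject]
        if protocol == "pooled":
            ws = concat_window_sets([sessions[k] for k in sorted(sessions)])
            ws = _maybe_zero_dropout(ws, degradation)
            plan = make_stratified_splits(
                ws.labels, n_repeats, seed=_derive_seed(seed, 21, subject)
            )
            for r, split in enumerate(plan.repeats):
                cs = ClassifierSpec(
                    classifier_spec.kind,
                    classifier_spec.grid,
                    seed=_derive_seed(seed, 22, subject, r),
                )
                res = evaluate_split(
                    ws, split, feature_spec, cs, degradation, preproc.delta
                )
                rows.append(
                    dict(subject=subject, session="pooled", repeat=r,
                         accuracy=res.accuracy, params=repr(res.params), **cond)
                )
        elif protocol == "intra-session":
            for sess in sorted(sessions):
                ws = _maybe_zero_dropout(sessions[sess], degradation)
                plan = make_stratified_splits(
                    ws.labels, n_repeats, seed=_derive_seed(seed, 23, subject, sess)
                )
                for r, split in enumerate(plan.repeats):
                    cs = ClassifierSpec(
                        classifier_spec.kind,
                        classifier_spec.grid,
                        seed=_derive_seed(seed, 22, subject, r),
                    )
                    res = evaluate_split(
                        ws, split, feature_spec, cs, degradation, preproc.delta
                    )
                    rows.append(
                        dict(subject=subject, session=sess, repeat=r,
                             accuracy=res.accuracy, params=repr(res.params), **cond)
                    )
        else:  # inter-session: leave-one-session-out
            names = sorted(sessions)
            if len(names) < 2:
                raise ValueError(
                    "inter-session protocol needs >= 2 sessions per subject"
                )
            for held_out in names:
                held_in = [sessions[k] for k in names if k != held_out]
                ws = concat_window_sets(held_in + [sessions[held_out]])
                ws = _maybe_zero_dropout(ws, degradation)
                n_in = sum(w.n_windows for w in held_in)
                te = np.arange(n_in, ws.n_windows)
                in_idx = np.arange(n_in)
                f_tr, f_va, _ = (0.70, 0.15, 0.15)
                for r in range(n_repeats):
                    sss = StratifiedShuffleSplit(
                        n_splits=1,
                        test_size=f_va / (f_tr + f_va),
                        random_state=_derive_seed(seed, 24, subject, held_out, r),
                    )
                    tr_rel, va_rel = next(
                        sss.split(in_idx.reshape(-1, 1), ws.labels[in_idx])
                    )
                    cs = ClassifierSpec(
                        classifier_spec.kind,
                        classifier_spec.grid,
                        seed=_derive_seed(seed, 22, subject, r),
                    )
                    res = evaluate_split(
                        ws, (in_idx[tr_rel], in_idx[va_rel], te),
                        feature_spec, cs, degradation, preproc.delta,
                    )
                    rows.append(
                        dict(subject=subject, session=held_out, repeat=r,
                             accuracy=res.accuracy, params=repr(res.params), **cond)
                    )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


CONDITION_KEYS = ["protocol", "classifier", "features", "degradation"]


def run_sweep(
    cohort: list[Recording] | dict[str, dict[str, WindowSet]],
    feature_specs: list[FeatureSpec],
    classifier_specs: list[ClassifierSpec],
    taus: list[float] = (),
    dropout_channels: list[int] = (),
    protocol: str = "pooled",
    n_repeats: int = 10,
    seed: int = 0,
    preproc: PreprocessConfig = PreprocessConfig(),
    existing: pd.DataFrame | None = None,
    include_clean: bool = False,
) -> pd.DataFrame:
    """Cartesian grid of conditions x repeats with condition-independent
    seeding (paired comparisons stay valid) and resume support: conditions
    already present in ``existing`` are skipped.  Per-condition failures are
    logged and recorded in ``result.attrs['failures']`` while the grid
    continues."""
    degradations: list[DegradationSpec] = []
    if include_clean:
        degradations.append(DegradationSpec())
    degradations += [DegradationSpec(kind="clip", tau=float(t)) for t in taus]
    degradations += [
        DegradationSpec(kind="dropout", channel=int(c)) for c in dropout_channels
    ]
    if not feature_specs or not classifier_specs or not degradations:
        raise ValueError("feature, classifier and degradation grids must be non-empty")

    prepared = cohort if isinstance(cohort, dict) else prepare_windows(cohort, preproc)
    done: set[tuple] = set()
    if existing is not None and len(existing):
        done = set(map(tuple, existing[CONDITION_KEYS].drop_duplicates().to_numpy()))

    tables = [] if existing is None else [existing]
    failures = []
    for fspec, cspec, deg in itertools.product(
        feature_specs, classifier_specs, degradations
    ):
        key = (protocol, cspec.kind, _feature_label(fspec), deg.label)
        if key in done:
            logger.info("skipping already-computed condition %s", key)
            continue
        t0 = time.perf_counter()
        try:
            tables.append(
                run_condition(
                    prepared, fspec, cspec, deg, protocol, n_repeats, seed, preproc
                )
            )
            logger.info("condition %s done in %.1f s", key, time.perf_counter() - t0)
        except Exception as exc:  # record and continue the grid
            logger.warning("condition %s failed after %.1f s: %s",
                           key, time.perf_counter() - t0, exc)
            failures.append((key, str(exc)))
    out = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(columns=RESULT_COLUMNS)
    )
    out.attrs["failures"] = failures
    return out


def summarize(
    results: pd.DataFrame, group_by: list[str] | tuple[str, ...] = tuple(CONDITION_KEYS)
) -> pd.DataFrame:
    """Two-stage aggregation: mean over repeats (and sessions/folds) within
    each subject, then mean/min/max over subject means.  Never pools repeats
    across subjects directly."""
    if results.empty:
        raise ValueError("empty result table")
    group_by = list(group_by)
    per_subject = (
        results.groupby(group_by + ["subject"], sort=True)["accuracy"]
        .mean()
        .reset_index()
    )
    rows = []
    for key, grp in per_subject.groupby(group_by, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = grp["accuracy"].to_numpy()
        rows.append(
            {
                **dict(zip(group_by, key)),
                "mean_accuracy": float(vals.mean()),
                "min_accuracy": float(vals.min()),
                "max_accuracy": float(vals.max()),
                "n_subjects": int(len(vals)),
                "per_subject": ";".join(f"{v:.6f}" for v in vals),
            }
        )
    return pd.DataFrame(rows)
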