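"""Interval-based time-series classifiers for spontaneous-activity detection.

Two forest ensembles, implemented from scratch over scikit-learn decision
trees:

* **TSF** (time series forest) — each tree draws √m random intervals of the
  m-frame series and summarizes each with its mean, standard deviation and
  least-squares slope; one decision tree is fitted on the 3·√m features.
* **RISE** (random interval spectral ensemble) — each tree owns a single
  random interval (the first tree sees the whole series) and describes it
  with spectral features: autocorrelation coefficients, Yule-Walker
  autoregressive coefficients and periodogram power, concatenated into a
  fixed-length, zero-padded vector.

The training protocol mirrors the lidocaine-anchored design: "active"
segments are pre-lidocaine traces of neurons whose activity the block
silenced; "inactive" segments are post-lidocaine traces of those same
neurons plus traces of never-active neurons; ambiguous neurons are excluded.
Segments are 1100 frames (~5 min at 3.65 Hz) by default, and a trained
model refuses test inputs longer than its training segments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.fft import next_fast_len
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.tree import DecisionTreeClassifier

from . import metrics as _metrics
from .trace import ACTIVE, AMBIGUOUS, INACTIVE, LabelSet, TraceMatrix

__all__ = [
    "TrainingSet",
    "ForestModel",
    "build_training_set",
    "train_tsf",
    "train_rise",
    "predict",
    "crossvalidate",
    "FRAME_BUDGET_RULE",
]

# the protocol's hard constraint on test inputs, quoted in error messages
FRAME_BUDGET_RULE = ("the number of frames used for testing must not exceed "
                     "the number of frames used for training")

DEFAULT_SEGMENT_FRAMES = 1100
DEFAULT_N_TREES = 500


# ---------------------------------------------------------------------------
# training-set construction
# ---------------------------------------------------------------------------

@dataclass
class TrainingSet:
    """Fixed-length labeled trace segments with per-segment provenance."""

    X: np.ndarray                      # (n_segments, segment_frames)
    y: np.ndarray                      # str array: active / inactive
    sampling_rate: float
    segment_frames: int
    provenance: list[dict] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y length mismatch")
        n_active = int(np.sum(self.y == ACTIVE))
        n_inactive = int(np.sum(self.y == INACTIVE))
        self.metadata.setdefault("n_active", n_active)
        self.metadata.setdefault("n_inactive", n_inactive)
        self.metadata.setdefault(
            "imbalance_ratio",
            n_active / n_inactive if n_inactive else math.nan)

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def y01(self) -> np.ndarray:
        return (self.y == ACTIVE).astype(int)


def build_training_set(
    recordings: Iterable[tuple[TraceMatrix, float | None,
                               Mapping[str, str] | LabelSet]],
    segment_frames: int = DEFAULT_SEGMENT_FRAMES,
) -> TrainingSet:
    """Assemble active/inactive training segments from lidocaine recordings.

    Each recording is ``(traces, lidocaine_time, verdicts)`` where
    ``verdicts`` maps neuron_id to the lidocaine ground-truth call
    (active / inactive / ambiguous).  Per the protocol:

    * **active** segments — head (pre-lidocaine) ``segment_frames`` frames of
      neurons whose spontaneous activity the block confirmed;
    * **inactive** segments — tail (post-lidocaine) frames of those same
      neurons, plus tails of neurons that were never spontaneously active;
    * ambiguous neurons are excluded entirely.

    Recordings shorter than 2 × ``segment_frames`` are skipped with a
    warning.
    """
    X_rows: list[np.ndarray] = []
    y_rows: list[str] = []
    prov: list[dict] = []
    rate: float | None = None

    for ridx, (traces, lido_time, verdicts) in enumerate(recordings):
        if isinstance(verdicts, LabelSet):
            verdicts = dict(verdicts.labels)
        if traces.n_frames < 2 * segment_frames:
            warnings.warn(
                f"recording {ridx} has {traces.n_frames} frames, fewer than "
                f"2 × {segment_frames}; skipped", RuntimeWarning, stacklevel=2)
            continue
        if rate is None:
            rate = traces.sampling_rate
        elif not math.isclose(rate, traces.sampling_rate, rel_tol=0.02):
            warnings.warn(
                f"recording {ridx} sampling rate {traces.sampling_rate} Hz "
                f"differs from {rate} Hz", RuntimeWarning, stacklevel=2)
        tail_start = traces.n_frames - segment_frames
        if lido_time is not None and tail_start / traces.sampling_rate < lido_time:
            warnings.warn(
                f"recording {ridx}: tail segment overlaps the pre-lidocaine "
                "period", RuntimeWarning, stacklevel=2)
        head = traces.values[:, :segment_frames]
        tail = traces.values[:, tail_start:]
        for i, nid in enumerate(traces.neuron_ids):
            verdict = verdicts.get(nid, AMBIGUOUS)
            if verdict == AMBIGUOUS:
                continue
            if verdict == ACTIVE:
                X_rows.append(head[i])
                y_rows.append(ACTIVE)
                prov.append({"recording": ridx, "neuron_id": nid,
                             "origin": "pre_lidocaine_sa"})
                X_rows.append(tail[i])
                y_rows.append(INACTIVE)
                prov.append({"recording": ridx, "neuron_id": nid,
                             "origin": "post_lidocaine_sa"})
            else:
                X_rows.append(tail[i])
                y_rows.append(INACTIVE)
                prov.append({"recording": ridx, "neuron_id": nid,
                             "origin": "post_lidocaine_non_sa"})

    X = (np.vstack(X_rows) if X_rows
         else np.empty((0, segment_frames)))
    return TrainingSet(
        X=X, y=np.array(y_rows, dtype=object),
        sampling_rate=rate if rate is not None else math.nan,
        segment_frames=segment_frames, provenance=prov)


# ---------------------------------------------------------------------------
# interval features
# ---------------------------------------------------------------------------

def interval_summary_features(X: np.ndarray) -> np.ndarray:
    """Mean, SD and least-squares slope of each row of ``X`` → (n, 3)."""
    n, L = X.shape
    mean = X.mean(axis=1)
    sd = X.std(axis=1)
    t = np.arange(L, dtype=float)
    tc = t - t.mean()
    denom = float(np.dot(tc, tc))
    slope = (X @ tc) / denom if denom > 0 else np.zeros(n)
    return np.column_stack([mean, sd, slope])


def autocorrelation(X: np.ndarray, n_lags: int) -> np.ndarray:
    """Biased-normalization ACF at lags 1..n_lags per row; zero-variance
    rows yield all-zero coefficients."""
    n, L = X.shape
    xc = X - X.mean(axis=1, keepdims=True)
    nfft = next_fast_len(2 * L)
    f = np.fft.rfft(xc, n=nfft, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, : n_lags + 1] / L
    var = acov[:, 0].copy()
    ok = var > 0
    out = np.zeros((n, n_lags))
    out[ok] = acov[ok, 1:] / var[ok, None]
    return out


def _levinson_ar(acf: np.ndarray, order: int) -> np.ndarray:
    """Yule-Walker AR coefficients via a row-vectorized Levinson-Durbin
    recursion.  ``acf`` holds normalized lags 1..order per row."""
    n = acf.shape[0]
    phi = np.zeros((n, order))
    prev = np.zeros((n, order))
    err = np.ones(n)
    for k in range(1, order + 1):
        acc = acf[:, k - 1].copy()
        if k > 1:
            acc -= np.sum(prev[:, : k - 1] * acf[:, k - 2::-1], axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            kappa = np.where(err > 1e-12, acc / err, 0.0)
        if k > 1:
            phi[:, : k - 1] = prev[:, : k - 1] \
                - kappa[:, None] * prev[:, k - 2::-1]
        phi[:, k - 1] = kappa
        err = err * (1.0 - kappa ** 2)
        prev[:, :k] = phi[:, :k]
    return phi


def ar_coefficients(X: np.ndarray, order: int) -> np.ndarray:
    """Autoregressive coefficients of each row (Yule-Walker, biased ACF)."""
    if order < 1:
        return np.zeros((X.shape[0], 0))
    acf = autocorrelation(X, order)
    return _levinson_ar(acf, order)


def periodogram_power(X: np.ndarray) -> np.ndarray:
    """Periodogram power at the first L//2 nonzero frequencies per row."""
    n, L = X.shape
    xc = X - X.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(xc, axis=1)) ** 2 / L
    return spec[:, 1 : L // 2 + 1]


def _rise_block_sizes(L: int, max_acf_lag: int, ar_order: int) -> tuple[int, int, int]:
    return (min(max_acf_lag, L - 1), min(ar_order, L // 4), L // 2)


def rise_features(X: np.ndarray, full_sizes: tuple[int, int, int],
                  max_acf_lag: int, ar_order: int) -> np.ndarray:
    """Spectral feature vector of an interval, padded to the fixed layout.

    Blocks — ACF, AR coefficients, periodogram power — are each computed at
    the interval's own natural size, then zero-padded (or truncated) to the
    sizes of the full-series interval so every tree sees the same vector
    length.
    """
    L = X.shape[1]
    n_acf, n_ar, n_per = _rise_block_sizes(L, max_acf_lag, ar_order)
    blocks = [autocorrelation(X, n_acf),
              ar_coefficients(X, n_ar),
              periodogram_power(X)]
    out = []
    for block, size in zip(blocks, full_sizes):
        if block.shape[1] >= size:
            out.append(block[:, :size])
        else:
            pad = np.zeros((X.shape[0], size - block.shape[1]))
            out.append(np.hstack([block, pad]))
    return np.hstack(out)


# ---------------------------------------------------------------------------
# forests
# ---------------------------------------------------------------------------

class _TSFForest:
    """Time series forest: √m random intervals per tree, 3 summary features
    per interval, one decision tree per interval set."""

    def __init__(self, n_trees: int, min_interval_length: int, seed: int,
                 class_weight: str | None = None):
        self.n_trees = n_trees
        self.min_interval_length = min_interval_length
        self.seed = seed
        self.class_weight = class_weight
        self.trees_: list[tuple[np.ndarray, DecisionTreeClassifier]] = []

    def _features(self, X: np.ndarray, intervals: np.ndarray) -> np.ndarray:
        return np.hstack([interval_summary_features(X[:, a:b])
                          for a, b in intervals])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_TSFForest":
        rng = np.random.default_rng(self.seed)
        m = X.shape[1]
        lmin = min(self.min_interval_length, m)
        n_int = max(1, int(round(math.sqrt(m))))
        self.trees_ = []
        for _ in range(self.n_trees):
            starts = rng.integers(0, m - lmin + 1, size=n_int)
            lengths = np.array([rng.integers(lmin, m - s + 1) for s in starts])
            intervals = np.column_stack([starts, starts + lengths])
            feats = self._features(X, intervals)
            # per-node random feature candidates, as in the original
            # time-series-forest design
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(2 ** 31)),
                max_features="sqrt", class_weight=self.class_weight)
            tree.fit(feats, y)
            self.trees_.append((intervals, tree))
        return self

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(X.shape[0])
        for intervals, tree in self.trees_:
            votes += tree.predict(self._features(X, intervals))
        return votes / len(self.trees_)


class _RISEForest:
    """Random interval spectral ensemble: one random interval per tree
    (whole series for the first tree), spectral features, one tree each."""

    def __init__(self, n_trees: int, min_interval_length: int,
                 max_acf_lag: int, ar_order: int, seed: int,
                 class_weight: str | None = None):
        self.n_trees = n_trees
        self.min_interval_length = min_interval_length
        self.max_acf_lag = max_acf_lag
        self.ar_order = ar_order
        self.seed = seed
        self.class_weight = class_weight
        self.trees_: list[tuple[tuple[int, int], DecisionTreeClassifier]] = []
        self.full_sizes_: tuple[int, int, int] | None = None

    def _features(self, X: np.ndarray, interval: tuple[int, int]) -> np.ndarray:
        a, b = interval
        return rise_features(X[:, a:b], self.full_sizes_,
                             self.max_acf_lag, self.ar_order)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_RISEForest":
        rng = np.random.default_rng(self.seed)
        m = X.shape[1]
        self.full_sizes_ = _rise_block_sizes(m, self.max_acf_lag, self.ar_order)
        lmin = min(max(self.min_interval_length, 4), m)
        self.trees_ = []
        for i in range(self.n_trees):
            if i == 0:
                interval = (0, m)  # first tree sees the whole series
            else:
                for _ in range(100):
                    a = int(rng.integers(0, m - lmin + 1))
                    b = int(rng.integers(a + lmin, m + 1))
                    # resample intervals too short for the AR order in use
                    if (b - a) >= 2 * min(self.ar_order, (b - a) // 4):
                        break
                interval = (a, b)
            feats = self._features(X, interval)
            # canonical RISE trees: plain best-split CART, no feature
            # subsampling (diversity comes from the random intervals)
            tree = DecisionTreeClassifier(
                random_state=int(rng.integers(2 ** 31)),
                class_weight=self.class_weight)
            tree.fit(feats, y)
            self.trees_.append((interval, tree))
        return self

    def vote_fractions(self, X: np.ndarray) -> np.ndarray:
        votes = np.zeros(X.shape[0])
        for interval, tree in self.trees_:
            votes += tree.predict(self._features(X, interval))
        return votes / len(self.trees_)


# ---------------------------------------------------------------------------
# public model object + train / predict
# ---------------------------------------------------------------------------

@dataclass
class ForestModel:
    """A trained interval forest plus its training-protocol contract."""

    algorithm: str                     # "tsf" | "rise"
    forest: object
    training_length: int               # frames; hard cap on test inputs
    sampling_rate: float
    seed: int
    n_trees: int
    normalization_mode: str = "dff0"   # or "raw"
    class_labels: tuple[str, str] = (INACTIVE, ACTIVE)
    hyperparams: dict = field(default_factory=dict)
    training_metadata: dict = field(default_factory=dict)


def _check_training_set(train: TrainingSet) -> None:
    if len(train) == 0:
        raise ValueError("training set is empty")
    classes = set(train.y.tolist())
    if classes != {ACTIVE, INACTIVE}:
        raise ValueError(
            f"training set must contain both classes, got {sorted(classes)}")


def train_tsf(train: TrainingSet, n_trees: int = DEFAULT_N_TREES,
              seed: int = 0, min_interval_length: int = 3,
              class_weight: str | None = None,
              normalization_mode: str = "dff0") -> ForestModel:
    """Fit a time series forest on a training set."""
    _check_training_set(train)
    forest = _TSFForest(n_trees, min_interval_length, seed, class_weight)
    forest.fit(train.X, train.y01)
    return ForestModel(
        algorithm="tsf", forest=forest,
        training_length=train.segment_frames,
        sampling_rate=train.sampling_rate, seed=seed, n_trees=n_trees,
        normalization_mode=normalization_mode,
        hyperparams={"min_interval_length": min_interval_length,
                     "class_weight": class_weight},
        training_metadata=dict(train.metadata))


def train_rise(train: TrainingSet, n_trees: int = DEFAULT_N_TREES,
               seed: int = 0, min_interval_length: int = 16,
               max_acf_lag: int = 100, ar_order: int = 12,
               class_weight: str | None = None,
               normalization_mode: str = "dff0") -> ForestModel:
    """Fit a random interval spectral ensemble on a training set."""
    _check_training_set(train)
    forest = _RISEForest(n_trees, min_interval_length, max_acf_lag,
                         ar_order, seed, class_weight)
    forest.fit(train.X, train.y01)
    return ForestModel(
        algorithm="rise", forest=forest,
        training_length=train.segment_frames,
        sampling_rate=train.sampling_rate, seed=seed, n_trees=n_trees,
        normalization_mode=normalization_mode,
        hyperparams={"min_interval_length": min_interval_length,
                     "max_acf_lag": max_acf_lag, "ar_order": ar_order,
                     "class_weight": class_weight},
        training_metadata=dict(train.metadata))


def _prepare_probe(model: ForestModel, traces: TraceMatrix) -> np.ndarray:
    if traces.n_frames > model.training_length:
        raise ValueError(
            f"test input has {traces.n_frames} frames but the model was "
            f"trained on {model.training_length}-frame segments: "
            + FRAME_BUDGET_RULE)
    if not math.isclose(traces.sampling_rate, model.sampling_rate,
                        rel_tol=0.02):
        warnings.warn(
            f"input sampling rate {traces.sampling_rate:g} Hz differs from "
            f"the model's {model.sampling_rate:g} Hz; consider resampling",
            RuntimeWarning, stacklevel=3)
    X = traces.values
    if traces.n_frames < model.training_length:
        warnings.warn(
            f"input shorter than training length "
            f"({traces.n_frames} < {model.training_length}); right-padding "
            "with the edge value", RuntimeWarning, stacklevel=3)
        pad = model.training_length - traces.n_frames
        X = np.hstack([X, np.repeat(X[:, -1:], pad, axis=1)])
    return X


def predict(model: ForestModel,
            traces: TraceMatrix) -> tuple[LabelSet, np.ndarray]:
    """Label each neuron by majority vote; return vote fractions too.

    Ties (vote fraction exactly 0.5) go to the inactive class.  Inputs
    longer than the training segments are rejected; shorter inputs are
    right-padded with their edge value, with a warning.
    """
    if model.normalization_mode == "dff0" and not traces.normalized:
        raise ValueError("model expects ΔF/F0-normalized traces")
    if model.normalization_mode == "raw" and traces.normalized:
        raise ValueError("model expects raw (non-normalized) traces")
    X = _prepare_probe(model, traces)
    votes = model.forest.vote_fractions(X)
    flags = votes > 0.5  # tie → inactive, the conservative call
    labels = LabelSet.from_array(traces.neuron_ids, flags.astype(int),
                                 source=f"predicted_{model.algorithm}")
    return labels, votes


# ---------------------------------------------------------------------------
# cross-validation protocol
# ---------------------------------------------------------------------------

_TRAINERS = {"tsf": train_tsf, "rise": train_rise}


def _fit_and_score(train: TrainingSet, algorithm: str, tr_idx, te_idx,
                   n_trees: int, seed: int, **kw) -> dict:
    sub = TrainingSet(X=train.X[tr_idx], y=train.y[tr_idx],
                      sampling_rate=train.sampling_rate,
                      segment_frames=train.segment_frames)
    model = _TRAINERS[algorithm](sub, n_trees=n_trees, seed=seed, **kw)
    votes = model.forest.vote_fractions(train.X[te_idx])
    y_pred = votes > 0.5
    counts = _metrics.binary_confusion(train.y01[te_idx], y_pred)
    rep = _metrics.metrics(counts)
    return rep.as_dict()


def crossvalidate(train: TrainingSet, algorithm: str = "rise", k: int = 5,
                  seed: int = 0, n_trees: int = DEFAULT_N_TREES,
                  holdout_fraction: float = 0.0, **kw) -> pd.DataFrame:
    """Stratified k-fold cross-validation of a forest on a training set.

    Returns a per-fold table of sensitivity/specificity/accuracy with the
    fold means in ``attrs["mean"]``.  With ``holdout_fraction`` > 0 the set
    is first split (stratified); CV runs on the large part and a model
    fitted on all of it is scored on the holdout
    (``attrs["holdout"]``).
    """
    if algorithm not in _TRAINERS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    _check_training_set(train)
    y01 = train.y01
    n_min = min(int(np.sum(y01 == 1)), int(np.sum(y01 == 0)))
    if n_min < k:
        raise ValueError(
            f"smallest class has {n_min} members, fewer than k={k} folds")

    idx_all = np.arange(len(train))
    holdout_metrics = None
    if holdout_fraction > 0:
        cv_idx, ho_idx = train_test_split(
            idx_all, test_size=holdout_fraction, stratify=y01,
            random_state=seed)
        holdout_metrics = _fit_and_score(
            train, algorithm, cv_idx, ho_idx, n_trees, seed, **kw)
    else:
        cv_idx = idx_all

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows = []
    for fold, (tr, te) in enumerate(skf.split(cv_idx, y01[cv_idx])):
        scores = _fit_and_score(train, algorithm, cv_idx[tr], cv_idx[te],
                                n_trees, seed + fold, **kw)
        rows.append({"fold": fold, **scores})
    table = pd.DataFrame(rows)
    table.attrs["mean"] = {
        m: float(np.nanmean(table[m]))
        for m in ("sensitivity", "specificity", "accuracy")}
    table.attrs["algorithm"] = algorithm
    if holdout_metrics is not None:
        table.attrs["holdout"] = holdout_metrics
    return table
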