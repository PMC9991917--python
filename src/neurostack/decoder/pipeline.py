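"""Verbal-memory decoding pipeline: windowing, balancing, training,
transfer learning, metrics and filter visualization.

LFP is windowed around each labelled word onset: 10-s chunks at 250 Hz
(-5 s to +5 s), weighted by a Gaussian (SD 2.5 s, peak 1 at the onset) so
onset-proximal samples dominate.  Classes are balanced by subsampling the
majority class.  The base decoder is trained offline with stratified
cross-validation; online transfer retrains only the dense head on an
accumulating shuffled pool of chunks, block by block, with the branch
(conv/LSTM) parameters frozen.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ..core import CoreError, EventStream, FilterSpec, Recording, filter_array, resample
from .model import BranchDecoder, DecoderSpec


@dataclass
class WindowedDataset:
    chunks: np.ndarray  # (n_events, n_times, n_channels), weighted
    labels: np.ndarray  # remembered booleans
    weights: np.ndarray  # per-time Gaussian weights (peak 1 at onset)
    region_ids: list  # per-channel branch assignment
    fs: float
    event_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    blocks: np.ndarray | None = None  # per-event block index, if known

    @property
    def n_events(self) -> int:
        return self.chunks.shape[0]

    def channels_per_region(self) -> list[int]:
        regs = sorted(set(self.region_ids))
        return [sum(r == reg for r in self.region_ids) for reg in regs]

    def subset(self, idx) -> "WindowedDataset":
        idx = np.asarray(idx)
        return WindowedDataset(
            chunks=self.chunks[idx],
            labels=self.labels[idx],
            weights=self.weights,
            region_ids=self.region_ids,
            fs=self.fs,
            event_times=self.event_times[idx],
            blocks=None if self.blocks is None else self.blocks[idx],
        )


@dataclass
class DecodeReport:
    f1: float
    accuracy: float
    roc_points: np.ndarray  # (n_thresholds, 2): (fpr, tpr)
    auc: float
    predictions: np.ndarray
    labels: np.ndarray
    per_fold: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("f1", "accuracy", "auc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise CoreError(f"{name}={v} outside [0, 1]")


def extract_windows(
    rec: Recording,
    events: EventStream,
    fs_target: float = 250.0,
    span_s: tuple = (-5.0, 5.0),
    sigma_s: float = 2.5,
    region_ids: list | None = None,
    highpass_hz: float = 0.1,
    normalize: bool = True,
) -> WindowedDataset:
    """Cut Gaussian-weighted chunks around labelled word onsets.

    The recording is 0.1-Hz high-passed and resampled to 250 Hz (with
    anti-alias filtering); each chunk spans ``span_s`` around its onset
    (2,500 samples at the defaults) and is multiplied by the Gaussian
    weight profile.  Onsets too close to the recording edges are dropped
    with a warning.

    With ``normalize`` the chunks are divided by the session-wide SD
    (one scale for the whole recording), bringing raw microvolt data to
    unit order for the network while preserving between-event amplitude
    differences — the discriminative signal.
    """
    if region_ids is None:
        region_ids = getattr(rec, "region_ids", [0] * rec.n_channels)
    proc = rec
    if highpass_hz > 0:
        spec = FilterSpec(kind="highpass", cutoffs=(highpass_hz,), order=2)
        proc = proc.copy_with(filter_array(proc.data, spec, proc.fs))
    if abs(proc.fs - fs_target) > 1e-9:
        proc = resample(proc, fs_target)
    if normalize:
        scale = proc.data.std()
        if scale > 0:
            proc = proc.copy_with(proc.data / scale)

    n_win = int(round((span_s[1] - span_s[0]) * fs_target))
    offsets = span_s[0] + np.arange(n_win) / fs_target
    weights = np.exp(-0.5 * (offsets / sigma_s) ** 2)

    chunks, labels, times, blocks = [], [], [], []
    n_dropped = 0
    for e in events.of_kind("word_onset"):
        if "remembered" not in e.payload:
            raise CoreError(f"word_onset at {e.time_s} s has no remembered label")
        i0 = int(round((e.time_s - proc.t0 + span_s[0]) * fs_target))
        i1 = i0 + n_win
        if i0 < 0 or i1 > proc.n_samples:
            n_dropped += 1
            continue
        chunk = proc.data[:, i0:i1].T  # (time, channels)
        chunks.append(chunk * weights[:, None])
        labels.append(bool(e.payload["remembered"]))
        times.append(e.time_s)
        blocks.append(e.payload.get("block", -1))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} onset(s) too close to recording edges")
    if not chunks:
        raise CoreError("no usable word onsets")
    return WindowedDataset(
        chunks=np.stack(chunks),
        labels=np.array(labels, dtype=bool),
        weights=weights,
        region_ids=list(region_ids),
        fs=fs_target,
        event_times=np.array(times),
        blocks=np.array(blocks),
    )


def balance_classes(ds: WindowedDataset, seed: int = 0) -> WindowedDataset:
    """Equalize class counts by randomly subsampling the majority class
    (typically remembered) down to the minority count."""
    rng = np.random.default_rng(seed)
    pos = np.where(ds.labels)[0]
    neg = np.where(~ds.labels)[0]
    m = min(pos.size, neg.size)
    if m == 0:
        raise CoreError("a class is empty; cannot balance")
    keep_pos = pos if pos.size == m else rng.choice(pos, m, replace=False)
    keep_neg = neg if neg.size == m else rng.choice(neg, m, replace=False)
    idx = np.sort(np.concatenate([keep_pos, keep_neg]))
    return ds.subset(idx)


def decode_metrics(
    predictions: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> DecodeReport:
    """Precision/recall/F1 at the threshold, accuracy, ROC and trapezoid AUC.

    F1 = 2PR/(P+R); an empty denominator yields 0.
    """
    scores = np.asarray(predictions, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=bool).reshape(-1)
    pred = scores > threshold
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    fn = int(np.sum(~pred & y))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    accuracy = float(np.mean(pred == y))

    # ROC via threshold sweep over the observed scores
    thresholds = np.concatenate([[np.inf], np.sort(np.unique(scores))[::-1]])
    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((~y).sum()), 1)
    points = []
    for th in thresholds:
        p = scores >= th
        points.append((np.sum(p & ~y) / n_neg, np.sum(p & y) / n_pos))
    points.append((1.0, 1.0))
    roc = np.array(points)
    auc = float(np.trapezoid(roc[:, 1], roc[:, 0]))
    return DecodeReport(
        f1=float(f1), accuracy=accuracy, roc_points=roc, auc=auc,
        predictions=scores, labels=y,
    )


def _stratified_folds(y: np.ndarray, folds: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    test_sets: list[list[int]] = [[] for _ in range(folds)]
    for cls in (True, False):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            test_sets[j % folds].append(i)
    return [np.sort(np.array(s)) for s in test_sets]


def train_base(
    ds: WindowedDataset,
    spec: DecoderSpec | None = None,
    folds: int = 5,
    epochs: int | None = None,
    seed: int = 0,
) -> tuple[BranchDecoder, DecodeReport]:
    """Offline base-model training with stratified cross-validation.

    Per fold, a fresh decoder is trained on the complement and scored on
    the held-out fold; out-of-fold predictions are pooled into the report
    (per-fold F1/accuracy in ``report.per_fold``).  The returned model is
    retrained on the full dataset.  Deterministic given the seed.
    """
    spec = spec or DecoderSpec()
    ds = balance_classes(ds, seed=seed)
    y = ds.labels.astype(float)
    cpr = ds.channels_per_region()

    oof_scores = np.zeros(ds.n_events)
    per_fold = []
    for k, test_idx in enumerate(_stratified_folds(ds.labels, folds, seed)):
        train_idx = np.setdiff1d(np.arange(ds.n_events), test_idx)
        model = BranchDecoder(cpr, spec, seed=seed + k)
        model.fit(ds.chunks[train_idx], y[train_idx], epochs=epochs,
                  seed=seed + k)
        scores = model.predict_proba(ds.chunks[test_idx])
        oof_scores[test_idx] = scores
        rep = decode_metrics(scores, ds.labels[test_idx], spec.threshold)
        per_fold.append({"fold": k, "f1": rep.f1, "accuracy": rep.accuracy})

    report = decode_metrics(oof_scores, ds.labels, spec.threshold)
    report.per_fold = per_fold
    final = BranchDecoder(cpr, spec, seed=seed)
    final.fit(ds.chunks, y, epochs=epochs, seed=seed)
    return final, report


def transfer_and_predict(
    model: BranchDecoder,
    stream: list[WindowedDataset],
    n_train_blocks: int,
    epochs_per_block: int = 20,
    seed: int = 0,
) -> DecodeReport:
    """Online transfer learning and prediction replay.

    The first ``n_train_blocks`` blocks personalize the model: after each,
    the accumulated chunk pool is shuffled and the dense head retrained
    starting from the current coefficients (branch conv/LSTM parameters
    stay frozen — bit-identical before and after).  The remaining blocks
    are scored as the prediction phase.
    """
    from .nn import RMSProp

    frozen_before = [p.value.copy() for p in model.branch_params()]
    opt = RMSProp(lr=model.spec.learning_rate)
    pool_X: list[np.ndarray] = []
    pool_y: list[np.ndarray] = []
    for b in range(n_train_blocks):
        ds = stream[b]
        pool_X.append(ds.chunks)
        pool_y.append(ds.labels.astype(float))
        X = np.concatenate(pool_X)
        y = np.concatenate(pool_y)
        model.fit(X, y, epochs=epochs_per_block, seed=seed + b,
                  trainable="head", optimizer=opt)

    for p, w in zip(model.branch_params(), frozen_before):
        if not np.array_equal(p.value, w):
            raise CoreError("frozen branch parameters changed during transfer")

    scores, labels = [], []
    for ds in stream[n_train_blocks:]:
        scores.append(model.predict_proba(ds.chunks))
        labels.append(ds.labels)
    if not scores:
        raise CoreError("no prediction blocks")
    return decode_metrics(
        np.concatenate(scores), np.concatenate(labels), model.spec.threshold
    )


def split_by_block(ds: WindowedDataset) -> list[WindowedDataset]:
    """Split a windowed dataset into per-block datasets (task blocks)."""
    if ds.blocks is None:
        raise CoreError("dataset has no block annotations")
    return [ds.subset(np.where(ds.blocks == b)[0]) for b in np.unique(ds.blocks)]


def visualize_filters(
    model: BranchDecoder,
    branch: int = 0,
    conv_layer: int = 1,
    filter_idx: int = 0,
    input_span_s: float = 10.0,
    steps: int = 40,
    step_size: float = 1.0,
    norm: float = 10.0,
) -> dict:
    """Gradient-ascent filter visualization.

    Starting from an all-zero 10-s input chunk, the input is adjusted to
    maximize the mean activation of the chosen filter (ascent with
    normalized gradient steps and per-step L2 normalization of the input).
    The optimized chunk is returned together with its Morse-CWT power map
    (averaged over channels).  A dead filter (zero gradient from the zero
    chunk) yields an all-zero map and ``dead=True``.
    """
    from ..spectral import cwt_scalogram

    br = model.branches[branch]
    n_ch = model.channels_per_region[branch]
    T = int(round(input_span_s * 250.0))
    x = np.zeros((1, T, n_ch))
    losses = []
    dead = False
    for _ in range(steps):
        loss, g = br.conv_input_gradient(x, conv_layer, filter_idx)
        gnorm = np.sqrt(np.sum(g**2))
        if gnorm < 1e-12:
            dead = not losses
            break
        x = x + step_size * g / gnorm
        xnorm = np.sqrt(np.sum(x**2))
        if xnorm > 0:
            x = x * (norm / xnorm)
        losses.append(loss)
    chunk = x[0]
    if dead or not losses:
        tf_map = None
        freqs = None
    else:
        sc = None
        acc = None
        for c in range(n_ch):
            sc = cwt_scalogram(chunk[:, c], fs=250.0, f_range_hz=(1.0, 100.0))
            acc = sc.power if acc is None else acc + sc.power
        tf_map = acc / n_ch
        freqs = sc.freqs_hz
    return {
        "chunk": chunk,
        "tf_map": tf_map,
        "freqs_hz": freqs,
        "activations": losses,
        "dead": dead,
    }


def baseline_classifiers(
    ds: WindowedDataset,
    method: str = "svm_raw",
    seed: int = 0,
    folds: int = 5,
    time_decimate: int = 10,
) -> DecodeReport:
    """Shallow comparison classifiers on identical stratified splits.

    ``svm_raw`` flattens (time-decimated) chunks into an SVM; ``pca_svm``
    projects onto principal components first; ``alt_nn`` is a small MLP.
    """
    from sklearn.decomposition import PCA
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    ds = balance_classes(ds, seed=seed)
    X = ds.chunks[:, ::time_decimate, :].reshape(ds.n_events, -1)
    y = ds.labels

    def make_model():
        if method == "svm_raw":
            return make_pipeline(StandardScaler(), SVC(probability=True,
                                                       random_state=seed))
        if method == "pca_svm":
            return make_pipeline(
                StandardScaler(),
                PCA(n_components=min(50, X.shape[0] - 2, X.shape[1])),
                SVC(probability=True, random_state=seed),
            )
        if method == "alt_nn":
            return make_pipeline(
                StandardScaler(),
                MLPClassifier(hidden_layer_sizes=(32,), max_iter=500,
                              random_state=seed),
            )
        raise CoreError(f"unknown baseline method {method!r}")

    oof = np.zeros(y.size)
    for k, test_idx in enumerate(_stratified_folds(y, folds, seed)):
        train_idx = np.setdiff1d(np.arange(y.size), test_idx)
        clf = make_model()
        clf.fit(X[train_idx], y[train_idx])
        oof[test_idx] = clf.predict_proba(X[test_idx])[:, 1]
    return decode_metrics(oof, y)
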