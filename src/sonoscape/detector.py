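"""Multi-label acoustic detection: spectrogram frontend, max-blend
augmentation, class rebalancing, a trainable detector, sliding-window
scoring, presence calling and evaluation metrics.

The frontend converts three-second clips into log-mel spectrograms:
audio is resampled to 16 kHz, an STFT with a 0.1 s window and 0.025 s hop
is computed, the frequency axis is mel-scaled into 224 bins spanning
50 Hz - 8 kHz, and amplitudes are log-scaled (floor 1e-10). A 3 s clip
therefore yields 117 frames.

Training data follows the single-positive labelling regime: for each clip
only one class's presence/absence is known, and every other class is
assumed absent. Max-blend augmentation combines random sample pairs within
a batch: sample B's spectrogram is cropped in frequency to the band of its
labelled class and blended into A's band with an element-wise maximum; the
label vectors are combined the same way. Class imbalance is handled by
resampling each class to fixed positive/negative targets (200/50 by
default), dropping classes with fewer than 10 positives.

The default backbone is a compact multilayer perceptron over
time-averaged log-mel features — average pooling of the extracted
features, a dropout layer, and a dense sigmoid output layer — trained with
binary cross-entropy and Adam (initial learning rate 0.001, batch size 16),
selecting the epoch with the best class-wise mean average precision on a
validation set. Any object with the same ``score(features) -> [0,1]^C``
contract can stand in as the backbone.

Files are scored on every three-second window with a one-second hop; a
class is declared present in a file if any window score reaches the
presence threshold (0.8 by default), and "frequency per plot" is the count
of positive files per plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import resample_poly

from .audio import Waveform

__all__ = [
    "SongClassSpec",
    "TrainingSample",
    "ModelInput",
    "DetectionScore",
    "PresenceTable",
    "make_model_input",
    "augment_pair",
    "rebalance",
    "MLPDetector",
    "TrainedDetector",
    "train_detector",
    "score_file",
    "call_presence",
    "average_precision",
    "evaluate",
]

TARGET_RATE = 16_000
CLIP_SECONDS = 3.0
STFT_WINDOW_S = 0.1
STFT_HOP_S = 0.025
N_MELS = 224
FMIN = 50.0
FMAX = 8000.0
LOG_EPS = 1e-10


@dataclass(frozen=True)
class SongClassSpec:
    """One song class: a species' call type and its frequency band."""

    class_id: str
    species_id: str
    band: tuple[float, float]  # (f_lo, f_hi) Hz

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (FMIN <= lo < hi <= FMAX):
            raise ValueError(
                f"band {self.band} must satisfy {FMIN} <= f_lo < f_hi <= {FMAX}")


@dataclass
class ModelInput:
    """Log-mel features of one window: (time, 224) matrix."""

    features: np.ndarray
    window_start: float = 0.0

    def __post_init__(self) -> None:
        if self.features.ndim != 2 or self.features.shape[1] != N_MELS:
            raise ValueError(
                f"features must be (time, {N_MELS}), got {self.features.shape}")


@dataclass
class TrainingSample:
    """A single-positive training clip: presence/absence is known for
    exactly one class; all other classes are assumed absent."""

    input: ModelInput
    known_class: str
    known_label: bool

    def full_labels(self, class_ids: list[str]) -> np.ndarray:
        y = np.zeros(len(class_ids))
        if self.known_label:
            y[class_ids.index(self.known_class)] = 1.0
        return y


@dataclass
class DetectionScore:
    """Per-class scores for one scored window of one file."""

    file_id: str
    window_start: float
    scores: np.ndarray  # per-class, in [0, 1]


@dataclass
class PresenceTable:
    """File-level presences and per-plot 'frequency per plot' counts."""

    presence: pd.DataFrame   # files x classes booleans
    frequency: pd.DataFrame  # plots x species counts


# ---------------------------------------------------------------------------
# Spectrogram frontend

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def mel_filterbank(n_fft: int, rate: int = TARGET_RATE, n_mels: int = N_MELS,
                   fmin: float = FMIN, fmax: float = FMAX) -> np.ndarray:
    """Triangular mel filterbank, (n_mels, n_fft // 2 + 1)."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    freqs = np.fft.rfftfreq(n_fft, 1.0 / rate)
    fb = np.zeros((n_mels, len(freqs)))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-9)
        down = (hi - freqs) / max(hi - ctr, 1e-9)
        fb[m] = np.clip(np.minimum(up, down), 0.0, None)
    return fb


def mel_center_freqs(n_mels: int = N_MELS, fmin: float = FMIN,
                     fmax: float = FMAX) -> np.ndarray:
    """Centre frequency (Hz) of each mel bin."""
    mel_pts = np.linspace(_hz_to_mel(fmin), _hz_to_mel(fmax), n_mels + 2)
    return _mel_to_hz(mel_pts)[1:-1]


def band_to_mel_bins(band: tuple[float, float]) -> np.ndarray:
    """Indices of mel bins whose centre lies inside a frequency band."""
    centers = mel_center_freqs()
    idx = np.where((centers >= band[0]) & (centers <= band[1]))[0]
    if len(idx) == 0:
        raise ValueError(f"band {band} covers no mel bins")
    return idx


_FB_CACHE: dict[int, np.ndarray] = {}


def make_model_input(clip: Waveform, window_start: float = 0.0) -> ModelInput:
    """Log-mel features of a three-second clip.

    The clip is resampled to 16 kHz if needed, zero-padded or truncated to
    exactly 3 s, analysed with a 0.1 s Hann STFT window hopping by 0.025 s,
    projected onto 224 mel bins spanning 50 Hz - 8 kHz and log-scaled.
    """
    if len(clip.samples) == 0:
        raise ValueError("empty clip")
    x = clip.samples
    if clip.rate != TARGET_RATE:
        g = np.gcd(int(clip.rate), TARGET_RATE)
        x = resample_poly(x, TARGET_RATE // g, int(clip.rate) // g)
    n_target = int(CLIP_SECONDS * TARGET_RATE)
    if len(x) < n_target:
        x = np.pad(x, (0, n_target - len(x)))
    else:
        x = x[:n_target]

    n_fft = int(STFT_WINDOW_S * TARGET_RATE)   # 1600
    hop = int(STFT_HOP_S * TARGET_RATE)        # 400
    n_frames = 1 + (n_target - n_fft) // hop   # 117
    window = np.hanning(n_fft)
    idx = np.arange(n_fft)[None, :] + hop * np.arange(n_frames)[:, None]
    mag = np.abs(np.fft.rfft(x[idx] * window, axis=1))
    if n_fft not in _FB_CACHE:
        _FB_CACHE[n_fft] = mel_filterbank(n_fft)
    mel = mag @ _FB_CACHE[n_fft].T
    return ModelInput(features=np.log(mel + LOG_EPS), window_start=window_start)


# ---------------------------------------------------------------------------
# Augmentation and rebalancing

def augment_pair(a: tuple[ModelInput, np.ndarray],
                 b: tuple[ModelInput, np.ndarray],
                 band_b: tuple[float, float]) -> tuple[ModelInput, np.ndarray]:
    """Max-blend sample B into sample A within B's labelled band.

    The output spectrogram equals A outside ``band_b`` and the element-wise
    maximum of A and B inside it; labels are combined element-wise with
    maximum. Cells never decrease and labels are never cleared.
    """
    (mi_a, lab_a), (mi_b, lab_b) = a, b
    if mi_a.features.shape != mi_b.features.shape:
        raise ValueError("inputs must share shape")
    bins = band_to_mel_bins(band_b)
    out = mi_a.features.copy()
    out[:, bins] = np.maximum(out[:, bins], mi_b.features[:, bins])
    labels = np.maximum(np.asarray(lab_a, float), np.asarray(lab_b, float))
    return ModelInput(out, mi_a.window_start), labels


def rebalance(samples: list[TrainingSample], target_pos: int = 200,
              target_neg: int = 50, min_pos: int = 10,
              seed: int = 0) -> tuple[list[str], list[TrainingSample]]:
    """Resample per-class counts to fixed targets.

    Classes with fewer than ``min_pos`` positives are dropped. The
    remaining classes' positives are resampled to exactly ``target_pos``
    and negatives to ``target_neg`` (with replacement when short, without
    when in excess). Returns the surviving class ids and the resampled
    sample list.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, dict[bool, list[TrainingSample]]] = {}
    for s in samples:
        by_class.setdefault(s.known_class, {True: [], False: []})[s.known_label].append(s)

    kept = sorted(c for c, d in by_class.items() if len(d[True]) >= min_pos)
    if not kept:
        raise ValueError(
            f"no class has >= {min_pos} positive training examples")

    out: list[TrainingSample] = []
    for c in kept:
        for label, target in ((True, target_pos), (False, target_neg)):
            group = by_class[c][label]
            if not group:
                continue
            picks = rng.choice(len(group), size=target,
                               replace=len(group) < target)
            out.extend(group[i] for i in picks)
    return kept, out


# ---------------------------------------------------------------------------
# The detector network

class MLPDetector:
    """Compact multilayer perceptron over time-averaged log-mel features.

    Average pooling over time, feature standardisation, one dense ReLU
    hidden layer, dropout, and a dense sigmoid output layer — one
    independent score per song class.
    """

    def __init__(self, n_classes: int, hidden: int = 64,
                 dropout: float = 0.2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.n_classes = n_classes
        self.dropout = dropout
        self.W1 = rng.normal(0, np.sqrt(2.0 / N_MELS), (N_MELS, hidden))
        self.b1 = np.zeros(hidden)
        self.W2 = rng.normal(0, np.sqrt(2.0 / hidden), (hidden, n_classes))
        self.b2 = np.zeros(n_classes)
        self.feat_mean = np.zeros(N_MELS)
        self.feat_std = np.ones(N_MELS)

    # -- parameter plumbing ------------------------------------------------
    def get_params(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k).copy()
                for k in ("W1", "b1", "W2", "b2", "feat_mean", "feat_std")}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for k, v in params.items():
            setattr(self, k, v.copy())

    # -- forward -----------------------------------------------------------
    @staticmethod
    def pool(mi: ModelInput) -> np.ndarray:
        return mi.features.mean(axis=0)

    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        z = (x - self.feat_mean) / self.feat_std
        h = np.maximum(z @ self.W1 + self.b1, 0.0)
        mask = None
        if rng is not None and self.dropout > 0:
            mask = (rng.uniform(size=h.shape) >= self.dropout) / (1 - self.dropout)
            h = h * mask
        logits = h @ self.W2 + self.b2
        s = 1.0 / (1.0 + np.exp(-logits))
        return s, (z, h, mask)

    def score(self, inputs: list[ModelInput]) -> np.ndarray:
        """(n_inputs, n_classes) scores in [0, 1]; no dropout at inference."""
        x = np.stack([self.pool(mi) for mi in inputs])
        s, _ = self._forward(x)
        return s

    # -- one Adam/BCE step -------------------------------------------------
    def train_step(self, x: np.ndarray, y: np.ndarray, opt: "_Adam",
                   rng: np.random.Generator) -> float:
        s, (z, h, mask) = self._forward(x, rng)
        n = x.shape[0]
        eps = 1e-7
        loss = -np.mean(y * np.log(s + eps) + (1 - y) * np.log(1 - s + eps))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"divergent training loss ({loss}); check learning rate and "
                f"input scaling")
        dlogits = (s - y) / (n * self.n_classes)
        gW2 = h.T @ dlogits
        gb2 = dlogits.sum(axis=0)
        dh = dlogits @ self.W2.T
        if mask is not None:
            dh = dh * mask
        dh = dh * (h > 0)
        gW1 = z.T @ dh
        gb1 = dh.sum(axis=0)
        opt.update([self.W1, self.b1, self.W2, self.b2],
                   [gW1, gb1, gW2, gb2])
        return float(loss)


class _Adam:
    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def update(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass
class TrainedDetector:
    """A trained scorer plus its class list and selection trace."""

    net: MLPDetector
    class_ids: list[str]
    class_specs: dict[str, SongClassSpec]
    best_epoch: int
    val_map_history: list[float]

    def score(self, inputs: list[ModelInput]) -> np.ndarray:
        return self.net.score(inputs)


@dataclass
class DetectorConfig:
    epochs: int = 100
    batch_size: int = 16
    learning_rate: float = 1e-3
    hidden: int = 64
    dropout: float = 0.2
    target_pos: int = 200
    target_neg: int = 50
    min_pos: int = 10
    augment_prob: float = 1.0


def train_detector(
    train: list[TrainingSample],
    val: list[tuple[ModelInput, np.ndarray]],
    class_specs: list[SongClassSpec],
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> TrainedDetector:
    """Train the detector under the single-positive regime.

    Per-batch max-blend augmentation pairs every sample A with a random
    sample B from the batch (B cropped to its labelled class's band). The
    loss is binary cross-entropy over the full assumed label vector,
    optimised with Adam; the returned weights are those of the epoch with
    the best class-wise mean average precision on ``val``.
    """
    cfg = config or DetectorConfig()
    if not val:
        raise ValueError("validation set must be non-empty")
    spec_by_id = {c.class_id: c for c in class_specs}
    class_ids, balanced = rebalance(train, cfg.target_pos, cfg.target_neg,
                                    cfg.min_pos, seed=seed)
    for c in class_ids:
        if c not in spec_by_id:
            raise ValueError(f"no SongClassSpec for class {c!r}")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    net = MLPDetector(len(class_ids), cfg.hidden, cfg.dropout, seed=seed)
    pooled = np.stack([net.pool(s.input) for s in balanced])
    net.feat_mean = pooled.mean(axis=0)
    net.feat_std = np.maximum(pooled.std(axis=0), 1e-6)
    opt = _Adam([p.shape for p in (net.W1, net.b1, net.W2, net.b2)],
                lr=cfg.learning_rate)

    val_inputs = [mi for mi, _ in val]
    val_truth = np.stack([y for _, y in val])

    labels = np.stack([s.full_labels(class_ids) for s in balanced])
    best = (-np.inf, None, -1)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(balanced))
        for lo in range(0, len(order), cfg.batch_size):
            batch_idx = order[lo: lo + cfg.batch_size]
            xs, ys = [], []
            for i in batch_idx:
                mi, y = balanced[i].input, labels[i]
                if len(batch_idx) > 1 and rng.uniform() < cfg.augment_prob:
                    j = int(rng.choice(batch_idx[batch_idx != i]))
                    band = spec_by_id[balanced[j].known_class].band
                    mi, y = augment_pair((mi, y), (balanced[j].input, labels[j]),
                                         band)
                xs.append(net.pool(mi))
                ys.append(y)
            net.train_step(np.stack(xs), np.stack(ys), opt, rng)
        val_scores = net.score(val_inputs)
        m = mean_average_precision(val_truth, val_scores)
        history.append(m)
        if m > best[0]:
            best = (m, net.get_params(), epoch)

    net.set_params(best[1])
    return TrainedDetector(net=net, class_ids=class_ids,
                           class_specs=spec_by_id, best_epoch=best[2],
                           val_map_history=history)


# ---------------------------------------------------------------------------
# Scoring and presence calling

def score_file(model, w: Waveform, file_id: str | None = None,
               window: float = CLIP_SECONDS, hop: float = 1.0
               ) -> list[DetectionScore]:
    """Score every ``window``-second window with a ``hop``-second shift.

    Windows start at 0, hop, 2*hop, ... s; a file shorter than one window
    yields a single zero-padded window. Each window is scored
    independently.
    """
    fid = file_id or (f"{w.plot_id}_{w.start_time}" if w.plot_id else "file")
    dur = w.duration
    if dur < window:
        starts = [0.0]
    else:
        n = int(np.floor((dur - window) / hop)) + 1
        starts = [i * hop for i in range(n)]
    inputs = [make_model_input(w.slice(s, s + window), window_start=s)
              for s in starts]
    scores = model.score(inputs)
    return [DetectionScore(fid, s, scores[i]) for i, s in enumerate(starts)]


def call_presence(scores_by_file: dict[str, list[DetectionScore]],
                  class_ids: list[str], threshold: float = 0.8,
                  plot_of_file: dict[str, str] | None = None,
                  species_of_class: dict[str, str] | None = None
                  ) -> PresenceTable:
    """Declare a class present in a file iff any window score reaches the
    threshold, and count positive files per plot ("frequency per plot")."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    rows = {}
    for fid, items in scores_by_file.items():
        mat = np.stack([d.scores for d in items])
        rows[fid] = mat.max(axis=0) >= threshold
    presence = pd.DataFrame.from_dict(rows, orient="index",
                                      columns=class_ids).sort_index()

    frequency = pd.DataFrame()
    if plot_of_file:
        sp_of = species_of_class or {c: c for c in class_ids}
        df = presence.copy()
        df["__plot"] = [plot_of_file[f] for f in df.index]
        counts = df.groupby("__plot").sum()
        counts.columns = [sp_of[c] for c in class_ids]
        # merge classes of the same species: a file counts once per species
        frequency = counts.T.groupby(level=0).max().T
        frequency.index.name = None
    return PresenceTable(presence=presence, frequency=frequency)


# ---------------------------------------------------------------------------
# Evaluation

def average_precision(y_true: np.ndarray, y_score: np.ndarray) -> float:
    """Average precision: sum over descending score thresholds of
    (recall change) x (precision at that threshold)."""
    y_true = np.asarray(y_true, dtype=float)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = y_true.sum()
    if n_pos == 0:
        raise ValueError("average precision undefined without positives")
    ap = 0.0
    prev_recall = 0.0
    for t in np.unique(y_score)[::-1]:
        sel = y_score >= t
        tp = y_true[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return float(ap)


def mean_average_precision(truth: np.ndarray, scores: np.ndarray) -> float:
    """Unweighted mean of per-class AP; classes without positives are
    excluded with a warning."""
    aps = []
    skipped = []
    for c in range(truth.shape[1]):
        if truth[:, c].sum() == 0:
            skipped.append(c)
            continue
        aps.append(average_precision(truth[:, c], scores[:, c]))
    if skipped:
        warnings.warn(
            f"{len(skipped)} class(es) without positives excluded from mAP",
            UserWarning, stacklevel=2)
    if not aps:
        raise ValueError("no class with positives; mAP undefined")
    return float(np.mean(aps))


def evaluate(truth: np.ndarray, scores: np.ndarray,
             threshold: float = 0.5) -> dict:
    """Per-class AP, mAP, and precision/recall/F1 at a score cutoff.

    Precision is 0 by convention when nothing is predicted positive.
    Classes with zero positives in truth are excluded from AP/mAP.
    """
    truth = np.asarray(truth, dtype=float)
    scores = np.asarray(scores, dtype=float)
    per_class_ap: dict[int, float] = {}
    for c in range(truth.shape[1]):
        if truth[:, c].sum() > 0:
            per_class_ap[c] = average_precision(truth[:, c], scores[:, c])
    if not per_class_ap:
        raise ValueError("no class with positives")

    pred = scores >= threshold
    precisions, recalls, f1s = [], [], []
    for c in per_class_ap:
        tp = float(np.sum(pred[:, c] & (truth[:, c] > 0)))
        fp = float(np.sum(pred[:, c] & (truth[:, c] == 0)))
        fn = float(np.sum(~pred[:, c] & (truth[:, c] > 0)))
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precisions.append(p)
        recalls.append(r)
        f1s.append(f)
    return {
        "per_class_ap": per_class_ap,
        "mAP": float(np.mean(list(per_class_ap.values()))),
        "precision": float(np.mean(precisions)),
        "recall": float(np.mean(recalls)),
        "f1": float(np.mean(f1s)),
        "threshold": threshold,
    }
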