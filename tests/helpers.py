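"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here evaluates a definition directly — explicit loops,
exhaustive threshold enumeration, hand-rolled pool-adjacent-violators —
and stays independent of the package's implementation paths.
"""

from __future__ import annotations

import math

import numpy as np


def entropy_oracle(weights) -> float:
    """Normalised Shannon entropy of a non-negative weight vector."""
    w = [float(x) for x in weights]
    total = sum(w)
    p = [x / total for x in w]
    h = -sum(x * math.log(x) for x in p if x > 0)
    return h / math.log(len(p))


def aci_oracle(matrix: np.ndarray, frames_per_win: int) -> float:
    """Acoustic complexity by direct loops over windows and bins."""
    n_frames, n_bins = matrix.shape
    wins = max(n_frames // frames_per_win, 1)
    totals = []
    for wi in range(wins):
        seg = matrix[wi * frames_per_win:(wi + 1) * frames_per_win]
        if seg.shape[0] < 2:
            continue
        total = 0.0
        for k in range(n_bins):
            num = sum(abs(seg[t + 1, k] - seg[t, k])
                      for t in range(seg.shape[0] - 1))
            den = sum(seg[t, k] for t in range(seg.shape[0]))
            total += num / den if den > 0 else 0.0
        totals.append(total)
    return sum(totals) / len(totals) if totals else 0.0


def gini_oracle(x) -> float:
    x = [float(v) for v in x]
    s = sum(x)
    if s <= 0:
        return 0.0
    n = len(x)
    return sum(abs(a - b) for a in x for b in x) / (2 * n * s)


def adi_oracle(props) -> float:
    """Shannon entropy (nats) of normalised band proportions."""
    total = sum(props)
    p = [x / total for x in props]
    return -sum(x * math.log(x) for x in p if x > 0)


def saturation_oracle(values: np.ndarray, profile: np.ndarray,
                      threshold_db: float) -> float:
    gain = 10.0 ** (threshold_db / 20.0) - 1.0
    active = 0
    for t in range(values.shape[0]):
        for k in range(values.shape[1]):
            if values[t, k] > gain * max(profile[k], 1e-12):
                active += 1
    return 100.0 * active / values.size


def bi_oracle(values: np.ndarray, freqs: np.ndarray,
              band: tuple[float, float]) -> float:
    cols = [k for k, f in enumerate(freqs) if band[0] <= f <= band[1]]
    mean_db = [20 * math.log10(values[:, k].mean() + 1e-12) for k in cols]
    m = min(mean_db)
    return sum(v - m for v in mean_db)


def ap_bruteforce(y_true, y_score) -> float:
    """Average precision by exhaustive enumeration of all cutpoints."""
    y_true = [float(v) for v in y_true]
    y_score = [float(v) for v in y_score]
    n_pos = sum(y_true)
    thresholds = sorted(set(y_score), reverse=True)
    ap = 0.0
    prev_r = 0.0
    for t in thresholds:
        tp = sum(yt for yt, ys in zip(y_true, y_score) if ys >= t)
        npred = sum(1 for ys in y_score if ys >= t)
        p = tp / npred
        r = tp / n_pos
        ap += (r - prev_r) * p
        prev_r = r
    return ap


def pava(y: np.ndarray) -> np.ndarray:
    """Pool adjacent violators: least-squares isotonic (increasing) fit."""
    y = [float(v) for v in y]
    blocks = [[v, 1.0] for v in y]  # (mean, weight)
    out = []
    for b in blocks:
        out.append(b)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            m2, w2 = out.pop()
            m1, w1 = out.pop()
            out.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    fit = []
    for m, w in out:
        fit.extend([m] * int(round(w)))
    return np.array(fit)


def stress1_oracle(d: np.ndarray, scores: np.ndarray) -> float:
    """Kruskal stress-1 with primary tie handling, via hand-rolled PAVA."""
    n = d.shape[0]
    delta, dist = [], []
    for i in range(n):
        for j in range(i + 1, n):
            delta.append(d[i, j])
            dist.append(float(np.sqrt(((scores[i] - scores[j]) ** 2).sum())))
    delta, dist = np.array(delta), np.array(dist)
    order = np.lexsort((dist, delta))
    fitted = pava(dist[order])
    resid = dist[order] - fitted
    return float(np.sqrt((resid ** 2).sum() / (dist ** 2).sum()))


def p_distance_oracle(a: str, b: str) -> tuple[float, int]:
    """p-distance for equal-length, gap-free fixture sequences."""
    assert len(a) == len(b)
    compared = mism = 0
    for ca, cb in zip(a.upper(), b.upper()):
        if ca in "ACGT" and cb in "ACGT":
            compared += 1
            mism += ca != cb
    return mism / compared, compared
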