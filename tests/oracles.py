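"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-implementations — sample-by-sample loops
and pairwise enumerations — kept separate from the package so the tests
compare two independently coded routes.
"""

import itertools

import numpy as np


def velocity_oracle(t, x, y, valid):
    """Finite-difference speed, sample by sample."""
    n = len(t)
    v = [float("nan")] * n
    defined = [False] * n
    for i in range(1, n):
        if valid[i] and valid[i - 1]:
            dx = x[i] - x[i - 1]
            dy = y[i] - y[i - 1]
            v[i] = (dx * dx + dy * dy) ** 0.5 / (t[i] - t[i - 1])
            defined[i] = True
    return v, defined


def segment_oracle(t, v, defined, threshold, min_fixation, min_saccade):
    """Sample-by-sample I-VT labeling with the package's documented merge
    rules: label, split into defined blocks, relabel short saccades to
    fixation (merge), then short fixations to saccade (merge)."""
    events = []
    i = 0
    n = len(v)
    while i < n:
        if not defined[i]:
            i += 1
            continue
        j = i
        while j < n and defined[j]:
            j += 1
        events.extend(_oracle_block(t, v, i, j, threshold, min_fixation, min_saccade))
        i = j
    return events


def _oracle_block(t, v, i, j, threshold, min_fixation, min_saccade):
    labels = ["saccade" if v[k] >= threshold else "fixation" for k in range(i, j)]
    runs = []
    for k, lab in enumerate(labels):
        if runs and runs[-1][2] == lab:
            runs[-1][1] = k + 1
        else:
            runs.append([k, k + 1, lab])

    def dur(run):
        return t[i + run[1] - 1] - t[i + run[0] - 1]

    def relabel(runs, kind, min_dur, other):
        out = []
        for s, e, lab in runs:
            new = other if (lab == kind and dur([s, e, lab]) < min_dur) else lab
            if out and out[-1][2] == new:
                out[-1][1] = e
            else:
                out.append([s, e, new])
        return out

    runs = relabel(runs, "saccade", min_saccade, "fixation")
    runs = relabel(runs, "fixation", min_fixation, "saccade")
    return [
        (lab, t[i + s - 1], t[i + e - 1], max(v[i + s : i + e]))
        for s, e, lab in runs
    ]


def auc_pairwise_oracle(y_true, score):
    """AUC as the fraction of correctly ordered (pos, neg) pairs, ties 1/2."""
    pos = [s for s, yy in zip(score, y_true) if yy == 1]
    neg = [s for s, yy in zip(score, y_true) if yy == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def features_oracle(window):
    """One-pass recomputation of the 13 features from an event subset."""

    def stats(vals):
        if not vals:
            return 0.0, 0.0, 0.0
        m = sum(vals) / len(vals)
        if len(vals) == 1:
            sd = 0.0
        else:
            sd = (sum((u - m) ** 2 for u in vals) / (len(vals) - 1)) ** 0.5
        return max(vals), sd, m

    sv = [e.mean_velocity for e in window if e.kind == "saccade"]
    sd_ = [e.duration for e in window if e.kind == "saccade"]
    fv = [e.mean_velocity for e in window if e.kind == "fixation"]
    fd = [e.duration for e in window if e.kind == "fixation"]
    out = []
    out.extend(stats(sv))
    out.extend(stats(sd_))
    out.append(float(len(sv)))
    out.extend(stats(fv))
    out.extend(stats(fd))
    # reorder: stats() yields (max, sd, mean) already in feature order
    return np.array(out)


def wilcoxon_exact_oracle(d):
    """Two-sided exact signed-rank p by enumerating all sign assignments.

    Assumes no zeros and no tied absolute values.
    """
    d = np.asarray(d, dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    count = 0
    total = 2**n
    for signs in itertools.product([0, 1], repeat=n):
        w = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total
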