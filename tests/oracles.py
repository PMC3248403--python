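"""Independent hand-coded reference statistics used only by the tests."""

import numpy as np


def logrank_chi2_binary(time, event, group):
    """Textbook two-group log-rank chi-square (hypergeometric variance).

    Plain loop over event times; handles censoring and tied event times.
    Returns None when the variance is zero (degenerate comparison).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group, int)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        dying = (time == t) & (event == 1)
        d = dying.sum()
        d1 = (dying & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        return None
    return o_minus_e**2 / var


def average_linkage_merges(dist):
    """Brute-force agglomerative average linkage on a dense distance matrix.

    Returns the merge heights in order, smallest cluster-pair distance first.
    """
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([[dist[i, j] for j in clusters[b]] for i in clusters[a]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return heights


def auc_by_pair_counting(score, label):
    """AUC as the fraction of concordant (pos > neg) pairs, ties 1/2."""
    score = np.asarray(score, float)
    label = np.asarray(label, int)
    pos = score[label == 1]
    neg = score[label == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
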