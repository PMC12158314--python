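"""Naive from-definition implementations used as independent oracles in tests.

Everything here is written directly from the defining formulas (plain loops
and sums), independent of the package's implementation paths.
"""

import math


def o_mean(xs):
    return sum(xs) / len(xs)


def o_std(xs):
    m = o_mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


def o_mad(xs):
    m = o_mean(xs)
    return sum(abs(x - m) for x in xs) / len(xs)


def o_skewness(xs):
    m, s = o_mean(xs), o_std(xs)
    return sum((x - m) ** 3 for x in xs) / len(xs) / s**3


def o_kurtosis(xs):
    """Excess kurtosis (standardized fourth moment minus 3)."""
    m, s = o_mean(xs), o_std(xs)
    return sum((x - m) ** 4 for x in xs) / len(xs) / s**4 - 3.0


def o_quantile(xs, q):
    """Linear-interpolation quantile."""
    ys = sorted(xs)
    h = (len(ys) - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return ys[lo] + (h - lo) * (ys[hi] - ys[lo])


def o_iqr(xs):
    return o_quantile(xs, 0.75) - o_quantile(xs, 0.25)


def o_energy_per_second(xs, rate):
    return sum(x * x for x in xs) / (len(xs) / rate)


def o_ranks(xs):
    """Average ranks (1-based) with ties sharing the mean rank."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def o_pearson(xs, ys):
    mx, my = o_mean(xs), o_mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def o_spearman(xs, ys):
    return o_pearson(o_ranks(xs), o_ranks(ys))


def o_spectral_moments(freqs, power):
    """(mean, skewness, excess kurtosis, normalized entropy) of the
    power-normalized spectrum treated as a distribution over frequency."""
    total = sum(power)
    p = [v / total for v in power]
    mean = sum(pi * f for pi, f in zip(p, freqs))
    var = sum(pi * (f - mean) ** 2 for pi, f in zip(p, freqs))
    sd = math.sqrt(var)
    skew = sum(pi * (f - mean) ** 3 for pi, f in zip(p, freqs)) / sd**3
    kurt = sum(pi * (f - mean) ** 4 for pi, f in zip(p, freqs)) / var**2 - 3.0
    ent = -sum(pi * math.log(pi) for pi in p if pi > 0) / math.log(len(p))
    return mean, skew, kurt, ent


def o_auc_trapezoid(truth, scores):
    """AUC by trapezoidal integration of the ROC curve over score thresholds."""
    pairs = sorted(zip(scores, truth), reverse=True)
    n_pos = sum(truth)
    n_neg = len(truth) - n_pos
    tps, fps = [0], [0]
    i = 0
    while i < len(pairs):
        j = i
        while j + 1 < len(pairs) and pairs[j + 1][0] == pairs[i][0]:
            j += 1
        tps.append(tps[-1] + sum(t for _, t in pairs[i:j + 1]))
        fps.append(fps[-1] + sum(1 - t for _, t in pairs[i:j + 1]))
        i = j + 1
    auc = 0.0
    for k in range(1, len(tps)):
        auc += (fps[k] - fps[k - 1]) * (tps[k] + tps[k - 1]) / 2
    return auc / (n_pos * n_neg)
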