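"""Independent brute-force oracles: every defining sum written as an
explicit Python loop, deliberately sharing no code with the package."""

import math


def snr_db_oracle(raw_rms, noise_rms):
    return 20.0 * math.log10(math.sqrt(raw_rms**2 - noise_rms**2) / noise_rms)


def lmav_oracle(x, eps=1e-12):
    total = 0.0
    for v in x:
        total += abs(v)
    return math.log(max(eps, total / len(x)))


def nsv_oracle(x, eps=1e-12):
    xbar = 0.0
    for v in x:
        xbar += abs(v)
    xbar /= len(x)
    total = 0.0
    for v in x:
        d = xbar - v
        cbrt = math.copysign(abs(d) ** (1.0 / 3.0), d)
        total += cbrt * cbrt
    return math.log(max(eps, total / len(x)))


def mav_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def iemg_oracle(x):
    return sum(abs(v) for v in x)


def rms_oracle(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def var_oracle(x):
    mu = sum(x) / len(x)
    return sum((v - mu) ** 2 for v in x) / (len(x) - 1)


def ssi_oracle(x):
    return sum(v * v for v in x)


def wl_oracle(x):
    return sum(abs(x[i + 1] - x[i]) for i in range(len(x) - 1))


def zc_oracle(x, thr=0.0):
    count = 0
    for i in range(len(x) - 1):
        if x[i] * x[i + 1] < 0 and abs(x[i + 1] - x[i]) >= thr:
            count += 1
    return count


def ssc_oracle(x, thr=0.0):
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > thr:
            count += 1
    return count


def wamp_oracle(x, thr=0.01):
    return sum(1 for i in range(len(x) - 1) if abs(x[i + 1] - x[i]) >= thr)


def myop_oracle(x, thr=0.016):
    return sum(1 for v in x if abs(v) >= thr) / len(x)


def log_detector_oracle(x, eps=1e-12):
    return math.exp(sum(math.log(max(eps, abs(v))) for v in x) / len(x))


def damv_oracle(x):
    return wl_oracle(x) / (len(x) - 1)


def dasdv_oracle(x):
    return math.sqrt(
        sum((x[i + 1] - x[i]) ** 2 for i in range(len(x) - 1)) / (len(x) - 1)
    )


def _central_moment(x, k):
    mu = sum(x) / len(x)
    return sum((v - mu) ** k for v in x) / len(x)


def skw_oracle(x):
    m2 = _central_moment(x, 2)
    if m2 <= 1e-24:
        return 0.0
    return _central_moment(x, 3) / m2**1.5


def kurt_oracle(x):
    m2 = _central_moment(x, 2)
    if m2 <= 1e-24:
        return 0.0
    return _central_moment(x, 4) / m2**2


def _pvar(x):
    mu = sum(x) / len(x)
    return sum((v - mu) ** 2 for v in x) / len(x)


def _diff(x):
    return [x[i + 1] - x[i] for i in range(len(x) - 1)]


def mob_oracle(x):
    v = _pvar(x)
    if v <= 1e-24:
        return 0.0
    return math.sqrt(_pvar(_diff(x)) / v)


def com_oracle(x):
    m = mob_oracle(x)
    if m == 0.0:
        return 0.0
    return mob_oracle(_diff(x)) / m


def mfl_oracle(x, eps=1e-12):
    return math.log10(max(eps, math.sqrt(sum(d * d for d in _diff(x)))))


def res_index_oracle(points, labels):
    classes = sorted(set(labels))
    K = len(classes)
    means, sds = {}, {}
    for c in classes:
        pts = [p for p, l in zip(points, labels) if l == c]
        n = len(pts)
        m1 = sum(p[0] for p in pts) / n
        m2 = sum(p[1] for p in pts) / n
        s1 = math.sqrt(sum((p[0] - m1) ** 2 for p in pts) / (n - 1))
        s2 = math.sqrt(sum((p[1] - m2) ** 2 for p in pts) / (n - 1))
        means[c] = (m1, m2)
        sds[c] = (s1, s2)
    ed = 0.0
    for p in range(K - 1):
        for q in range(p + 1, K):
            a, b = means[classes[p]], means[classes[q]]
            ed += math.sqrt((a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2)
    ed_bar = 2.0 / (K * (K - 1)) * ed
    sigma_bar = sum(s for pair in sds.values() for s in pair) / (2 * K)
    return ed_bar / sigma_bar


def metrics_oracle(confusion, m):
    """Five one-vs-rest metrics (percent) for class index m of a square
    confusion matrix given as nested lists."""
    K = len(confusion)
    total = sum(sum(row) for row in confusion)
    tp = confusion[m][m]
    fn = sum(confusion[m]) - tp
    fp = sum(confusion[r][m] for r in range(K)) - tp
    tn = total - tp - fn - fp

    def ratio(num, den):
        return num / den if den else 0.0

    sens = ratio(tp, tp + fn)
    prec = ratio(tp, tp + fp)
    return {
        "accuracy": 100.0 * ratio(tp + tn, total),
        "sensitivity": 100.0 * sens,
        "specificity": 100.0 * ratio(tn, tn + fp),
        "precision": 100.0 * prec,
        "f1": 100.0 * ratio(2 * prec * sens, prec + sens),
    }
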