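"""Independent brute-force oracles, written with plain loops.

These deliberately avoid the package's vectorized code paths so they can
serve as cross-checks: a literal transcription of the ratio /
normalization / channel-mean / volatility construction, and a bisection
solver for the two-state equilibrium.
"""

import math


def brute_force_vr(q, I, J, q_min, q_max, d_max, c=0.0):
    """Literal evaluation of the volatility ratio, loop by loop."""
    delta_q = math.pi / d_max
    n_channels = math.ceil((q_max - q_min) / delta_q - 1e-12)
    assert n_channels >= 2

    # ratio over retained points
    pts = []
    for qi, Ii, Ji in zip(q, I, J):
        if qi < q_min or qi > q_max:
            continue
        if Ii > 0 and Ji > 0 and Ii + c > 0 and Ji - c > 0:
            pts.append((qi, (Ii + c) / (Ji - c)))
    assert len(pts) >= 2

    # geometric normalization
    log_sum = 0.0
    for _, r in pts:
        log_sum += math.log(r)
    gmean = math.exp(log_sum / len(pts))
    pts = [(qi, r / gmean) for qi, r in pts]

    # channel assignment and geometric channel means
    channels = [[] for _ in range(n_channels)]
    for qi, r in pts:
        idx = int((qi - q_min) // delta_q)
        idx = min(max(idx, 0), n_channels - 1)
        channels[idx].append(r)
    counts = [len(ch) for ch in channels]
    assert all(cnt > 0 for cnt in counts)
    means = []
    for ch in channels:
        s = 0.0
        for r in ch:
            s += math.log(r)
        means.append(math.exp(s / len(ch)))

    full = counts[:-1]
    m_q = sum(full) / len(full)
    w_last = min(1.0, counts[-1] / m_q)

    vr = 0.0
    for i in range(n_channels - 1):
        w = w_last if i + 1 == n_channels - 1 else 1.0
        vr += w * abs(means[i + 1] - means[i]) / ((means[i] + means[i + 1]) / 2.0)
    return vr


def bisect_bound_complex(r_total, l_total, k_d, iterations=200):
    """[RL] by bisection of (R-x)(L-x) = K x on [0, min(R, L)]."""
    if r_total == 0 or l_total == 0:
        return 0.0

    def f(x):
        return (r_total - x) * (l_total - x) - k_d * x

    lo, hi = 0.0, min(r_total, l_total)
    for _ in range(iterations):
        mid = (lo + hi) / 2.0
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0
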