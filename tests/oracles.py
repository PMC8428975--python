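"""Independent brute-force oracles shared by the unit and acceptance tests."""

import math


def cma_bursts_oracle(times, bin_width=0.005, min_spikes=3):
    """Plain-loop reimplementation of the CMA burst detector."""
    times = list(times)
    if len(times) < min_spikes + 1:
        return []
    isis = [b - a for a, b in zip(times, times[1:])]
    max_isi = max(isis)
    if max_isi <= 0:
        return [(times[0], times[-1], len(times))]
    n_bins = max(1, math.ceil(2.0 * max_isi / bin_width))
    counts = [0] * n_bins
    for isi in isis:
        idx = int(isi / bin_width)
        if idx >= n_bins:
            idx = n_bins - 1
        counts[idx] += 1
    cma = []
    total = 0
    for k, c in enumerate(counts, start=1):
        total += c
        cma.append(total / k)
    peak = max(range(len(cma)), key=lambda k: (cma[k], -k))
    mean = sum(cma) / len(cma)
    m2 = sum((v - mean) ** 2 for v in cma) / len(cma)
    m3 = sum((v - mean) ** 3 for v in cma) / len(cma)
    skew = 0.0 if m2 == 0 else m3 / m2 ** 1.5
    if skew < 1:
        alpha = 1.0
    elif skew < 4:
        alpha = 0.7
    elif skew < 9:
        alpha = 0.5
    else:
        alpha = 0.3
    last = peak
    for k in range(peak, len(cma)):
        if cma[k] >= alpha * cma[peak]:
            last = k
    thr = (last + 1) * bin_width
    bursts = []
    start = 0
    for j in range(len(isis) + 1):
        if j == len(isis) or isis[j] > thr:
            if j - start + 1 >= min_spikes:
                bursts.append((times[start], times[j], j - start + 1))
            start = j + 1
    return bursts


def balanced_oneway_reml(y2d):
    """Closed-form REML for the balanced one-way random-intercept model."""
    n_groups = len(y2d)
    n_per = len(y2d[0])
    gm = [sum(row) / n_per for row in y2d]
    grand = sum(gm) / n_groups
    msb = n_per * sum((g - grand) ** 2 for g in gm) / (n_groups - 1)
    msw = sum(
        (v - gm[i]) ** 2 for i, row in enumerate(y2d) for v in row
    ) / (n_groups * (n_per - 1))
    sig_b2 = max(0.0, (msb - msw) / n_per)
    return grand, math.sqrt(sig_b2), math.sqrt(msw)
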