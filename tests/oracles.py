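"""Naive reference implementations used to cross-check the package.

These deliberately use plain Python loops and textbook formulas, sharing no
code with the implementation under test.
"""

import math


def textbook_pearson(xs, ys):
    """Pearson r from the raw-sums formula; conventions as documented:
    identical sequences -> 1, zero variance on either side -> 0."""
    n = len(xs)
    if list(xs) == list(ys):
        return 1.0
    sx = sum(xs)
    sy = sum(ys)
    sxx = sum(x * x for x in xs)
    syy = sum(y * y for y in ys)
    sxy = sum(x * y for x, y in zip(xs, ys))
    vx = n * sxx - sx * sx
    vy = n * syy - sy * sy
    if vx <= 0 or vy <= 0:
        return 0.0
    return (n * sxy - sx * sy) / math.sqrt(vx * vy)


def naive_directional_usf(raw_self, peaks_self, raw_other, threshold,
                          ppm_window=700.0, halfwidth_factor=2.0):
    """Count peaks of one spectrum uncorrelated with the other raw trace."""
    count = 0
    mz = list(raw_self.mz)
    for center in peaks_self.mz:
        half = halfwidth_factor * ppm_window * center * 1e-6
        window = [k for k in range(len(mz)) if center - half <= mz[k] <= center + half]
        assert len(window) >= 3, "fixture grid too coarse for the window"
        a = [float(raw_self.intensity[k]) for k in window]
        b = [float(raw_other.intensity[k]) for k in window]
        if textbook_pearson(a, b) < threshold:
            count += 1
    return count


def naive_usf_pair(a, b, threshold=0.5, ppm_window=700.0, halfwidth_factor=2.0):
    raw_a, peaks_a = a
    raw_b, peaks_b = b
    return (
        naive_directional_usf(raw_a, peaks_a, raw_b, threshold, ppm_window, halfwidth_factor),
        naive_directional_usf(raw_b, peaks_b, raw_a, threshold, ppm_window, halfwidth_factor),
    )
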