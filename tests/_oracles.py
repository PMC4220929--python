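"""Independent brute-force oracles used by the test suite.

These deliberately restate the definitions from scratch (per-class entropy
and variance computed directly from the class histograms, exhaustive search
over all ordered boundary pairs) so they share no code path with the
implementation they check.
"""

import numpy as np


def otsu3_oracle(values, criterion="entropy", bins=256):
    hist, edges = np.histogram(np.ravel(values), bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    best_val, best_pair = np.inf, None
    for a in range(1, bins - 1):
        classes_a = (p[:a], centers[:a])
        for b in range(a + 1, bins):
            total = 0.0
            for cls, cen in (
                classes_a,
                (p[a:b], centers[a:b]),
                (p[b:], centers[b:]),
            ):
                w = cls.sum()
                if w <= 0:
                    continue
                if criterion == "entropy":
                    q = cls[cls > 0] / w
                    total += w * float(-(q * np.log(q)).sum())
                else:
                    m = float((cls * cen).sum() / w)
                    total += float((cls * (cen - m) ** 2).sum())
            if total < best_val:
                best_val, best_pair = total, (edges[a], edges[b])
    return best_pair


def otsu3_oracle_fast(values, criterion="entropy", bins=256):
    """Same exhaustive search, vectorized over the high boundary.

    Still built directly from the per-class definitions (suffix/prefix class
    statistics), used where the triple loop would be too slow.
    """
    hist, edges = np.histogram(np.ravel(values), bins=bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    def class_stats(cls, cen):
        w = cls.sum()
        if w <= 0:
            return 0.0
        if criterion == "entropy":
            q = cls[cls > 0] / w
            return w * float(-(q * np.log(q)).sum())
        m = float((cls * cen).sum() / w)
        return float((cls * (cen - m) ** 2).sum())

    best_val, best_pair = np.inf, None
    for a in range(1, bins - 1):
        left = class_stats(p[:a], centers[:a])
        for b in range(a + 1, bins):
            total = (
                left
                + class_stats(p[a:b], centers[a:b])
                + class_stats(p[b:], centers[b:])
            )
            if total < best_val:
                best_val, best_pair = total, (edges[a], edges[b])
    return best_pair


def random_histogram_values(rng):
    """Random multi-modal value sample clipped to [0, 1]."""
    parts = []
    for _ in range(rng.integers(2, 5)):
        mu, sd, n = rng.uniform(0, 1), rng.uniform(0.01, 0.15), rng.integers(200, 1500)
        parts.append(rng.normal(mu, sd, n))
    return np.clip(np.concatenate(parts), 0, 1)


def icc31_oracle(data):
    """ICC(3,1) via an explicitly fitted two-way cell-means decomposition."""
    data = np.asarray(data, dtype=np.float64)
    n, k = data.shape
    mu = data.mean()
    alpha = data.mean(axis=1) - mu  # subject effects
    beta = data.mean(axis=0) - mu  # rater effects
    resid = data - (mu + alpha[:, None] + beta[None, :])
    ms_rows = k * (alpha**2).sum() / (n - 1)
    ms_err = (resid**2).sum() / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)
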