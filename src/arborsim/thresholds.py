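"""Histogram-based global thresholds used by the segmentation streams.

Two thresholds are needed: a mode-plus-fraction-of-SD rule for the
neuron-fill channel (computed on the max-Z projection of the LoG
transform) and a Renyi-entropy threshold for the soma-localization
stream.
"""

from __future__ import annotations

import numpy as np


def mode_sd_threshold(values, sd_fraction=0.1, bins=1024):
    """Mode plus a fraction of the standard deviation.

    The mode of a continuous-valued transform is taken as the center of
    the fullest bin of a ``bins``-bin histogram over the value range; the
    SD is the plain standard deviation of all values.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=bins)
    i = int(np.argmax(counts))
    mode = 0.5 * (edges[i] + edges[i + 1])
    return mode + sd_fraction * values.std()


def renyi_entropy(p, alpha):
    """Renyi entropy of order ``alpha`` of a probability vector (natural log).

    Zero-probability entries are ignored.  ``alpha`` = 1 falls back to the
    Shannon limit.
    """
    p = np.asarray(p, dtype=np.float64)
    p = p[p > 0]
    if p.size == 0:
        return -np.inf
    if abs(alpha - 1.0) < 1e-12:
        return float(-np.sum(p * np.log(p)))
    return float(np.log(np.sum(p**alpha)) / (1.0 - alpha))


def renyi_threshold(hist, alpha=0.5):
    """Exhaustive-search Renyi-entropy threshold on an intensity histogram.

    For each candidate threshold t the histogram is split into background
    (bins <= t) and foreground (bins > t); each side is renormalized and
    its Renyi entropy of order ``alpha`` computed.  The returned t
    maximizes the summed entropies.  Values strictly greater than t are
    foreground.

    Parameters
    ----------
    hist : sequence of int
        Bin counts, typically 256 bins of an 8-bit image.
    alpha : float
        Entropy order; 0.5 weights the two classes away from the Shannon
        maximum-entropy criterion.

    Returns
    -------
    int bin index t in [0, len(hist) - 2].
    """
    hist = np.asarray(hist, dtype=np.float64)
    total = hist.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = hist / total
    best_t, best_score = None, -np.inf
    cumsum = np.cumsum(p)
    for t in range(len(hist) - 1):
        w0 = cumsum[t]
        w1 = 1.0 - w0
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = renyi_entropy(p[: t + 1] / w0, alpha)
        h1 = renyi_entropy(p[t + 1 :] / w1, alpha)
        score = h0 + h1
        if score > best_score:
            best_score, best_t = score, t
    if best_t is None:
        raise ValueError("histogram has a single occupied bin; no threshold exists")
    return int(best_t)
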