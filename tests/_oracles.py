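"""Naive reference implementations used as independent test oracles.

Everything here is written as plain double loops / pairwise enumeration,
deliberately avoiding the vectorized code paths of the package.
"""

import math

import numpy as np


def glcm_reference(u8, d=1, levels=256):
    """Co-occurrence probabilities at offset (0, +d), double-loop count."""
    u8 = np.asarray(u8)
    if levels < 256:
        u8 = (u8.astype(np.int64) * levels // 256)
    counts = np.zeros((levels, levels), dtype=np.float64)
    h, w = u8.shape
    for r in range(h):
        for c in range(w - d):
            counts[u8[r, c], u8[r, c + d]] += 1
    return counts / counts.sum()


def lbp_reference(u8, radius=1, points=8):
    """Classic LBP codes by per-pixel scalar loops with bilinear sampling.

    Bit k is set when the neighbor at angle 2πk/points (counter-clockwise
    from east, image rows growing downward) is ≥ the center.
    """
    x = np.asarray(u8, dtype=np.float64)
    h, w = x.shape
    out = np.zeros((h - 2 * radius, w - 2 * radius), dtype=np.int64)
    for r in range(radius, h - radius):
        for c in range(radius, w - radius):
            center = x[r, c]
            code = 0
            for k in range(points):
                theta = 2.0 * math.pi * k / points
                rr = r + round(-radius * math.sin(theta), 8)
                cc = c + round(radius * math.cos(theta), 8)
                r0, c0 = math.floor(rr), math.floor(cc)
                fr, fc = rr - r0, cc - c0
                r1, c1 = min(r0 + 1, h - 1), min(c0 + 1, w - 1)
                val = (x[r0, c0] * (1 - fr) * (1 - fc)
                       + x[r0, c1] * (1 - fr) * fc
                       + x[r1, c0] * fr * (1 - fc)
                       + x[r1, c1] * fr * fc)
                if val - center >= -1e-6:
                    code |= 1 << k
            out[r - radius, c - radius] = code
    return out


def pearson_reference(p, a):
    p, a = np.asarray(p, float), np.asarray(a, float)
    dp, da = p - p.mean(), a - a.mean()
    return float((dp * da).sum() / math.sqrt((dp**2).sum() * (da**2).sum()))


def ranks_reference(x):
    """Mean (fractional) ranks by sorting, ties averaged."""
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_tiefree_reference(p, a):
    """Closed form 1 − 6ΣRᵢ²/(S(S²−1)); valid only without ties."""
    rp, ra = ranks_reference(p), ranks_reference(a)
    s = len(rp)
    return float(1.0 - 6.0 * np.sum((rp - ra) ** 2) / (s * (s**2 - 1)))


def kendall_taub_reference(p, a):
    """Tau-b by O(n²) pair classification: (Sc−Sd)/√((Sc+Sd+Tp)(Sc+Sd+Ta))."""
    p, a = np.asarray(p, float), np.asarray(a, float)
    n = len(p)
    sc = sd = tp = ta = 0
    for i in range(n):
        for j in range(i + 1, n):
            dp, da = p[i] - p[j], a[i] - a[j]
            if dp == 0 and da == 0:
                continue  # tied in both: counts to neither term
            if dp == 0:
                tp += 1
            elif da == 0:
                ta += 1
            elif dp * da > 0:
                sc += 1
            else:
                sd += 1
    denom = math.sqrt((sc + sd + tp) * (sc + sd + ta))
    if denom == 0:
        return math.nan
    return (sc - sd) / denom
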