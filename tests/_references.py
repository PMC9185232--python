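"""Independent straight-line reference implementations (oracles).

Explicit Python loops and plain NumPy only; intentionally shares no code
with the package so it can serve as a second, independent route in
equivalence tests.
"""

import math

import numpy as np


def ref_spatial_softmax(feats, w, b):
    """Per-channel softmax over positions after a 1x1 conv; loops only."""
    c, h, wd = feats.shape
    z = np.zeros_like(feats)
    for f in range(c):
        for i in range(h):
            for j in range(wd):
                z[f, i, j] = sum(w[f, cc] * feats[cc, i, j] for cc in range(c)) + b[f]
    att = np.zeros_like(z)
    for f in range(c):
        e = np.exp(z[f] - z[f].max())
        att[f] = e / e.sum()
    return att


def ref_nga(main, guide, w, b):
    att = ref_spatial_softmax(guide, w, b)
    return main + main * att


def ref_sdpa(q, k, v):
    nq, d = q.shape
    nk = k.shape[0]
    out = np.zeros((nq, v.shape[1]))
    for i in range(nq):
        logits = np.array([q[i] @ k[j] / math.sqrt(d) for j in range(nk)])
        e = np.exp(logits - logits.max())
        a = e / e.sum()
        out[i] = sum(a[j] * v[j] for j in range(nk))
    return out


def ref_ngf(main_tokens, guide_tokens, wqs, wks):
    v = main_tokens.copy()
    for wq, wk in zip(wqs, wks):
        v = v + ref_sdpa(guide_tokens @ wq, v @ wk, v)
    return v
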