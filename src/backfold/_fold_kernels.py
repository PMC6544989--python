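"""Numba kernels for the built-in partition-function folding engine.

The energy model is purely additive over base pairs: each admissible pair
(GC, AU, GU in either orientation) contributes a fixed Boltzmann weight
``exp(E/kT)``; no stacking or loop terms.  Structures are pseudoknot-free
matchings with at least ``min_hp`` unpaired bases inside every hairpin.

The grammar used for both the inside and outside passes is the unambiguous
leftmost-decision form

    S(i, j) -> S(i+1, j)                          (i unpaired)
    S(i, j) -> pair(i, k) S(i+1, k-1) S(k+1, j)   (k - i > min_hp)

Numerical scaling: every unpaired base carries a factor 1/s and every pair a
factor w/s^2, so the computed quantities equal the true ones times
s^-(span length); the scale cancels exactly in every probability ratio.
The driver retries with a larger scale if the unscaled pass overflows.
"""

from __future__ import annotations

import numpy as np
from numba import njit

#: base encoding used throughout: A=0, C=1, G=2, T/U=3
BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def encode(sequence: str) -> np.ndarray:
    try:
        return np.array([BASE_INDEX[b] for b in sequence], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTU base {exc.args[0]!r} in sequence") from None


def weight_matrix(pair_weights: dict[str, float], kt: float) -> np.ndarray:
    """4x4 Boltzmann weight matrix from per-pair energies (in units of kT)."""
    w = np.zeros((4, 4))
    for pair, energy in pair_weights.items():
        a, b = BASE_INDEX[pair[0]], BASE_INDEX[pair[1]]
        w[a, b] = w[b, a] = np.exp(energy / kt)
    return w


@njit(cache=True)
def inside_outside(enc, pair_w, min_hp, scale):
    """Exact pair probabilities on one sequence.

    Returns ``(P, ok)`` with P upper-triangular; ok=False signals numeric
    overflow/underflow at this scale (caller retries with another scale).
    """
    n = enc.shape[0]
    inv_s = 1.0 / scale
    wm = np.zeros((n, n))
    for i in range(n):
        for k in range(i + min_hp + 1, n):
            w = pair_w[enc[i], enc[k]]
            if w > 0.0:
                wm[i, k] = w * inv_s * inv_s

    # zm[i, j] = scaled partition function of span [i..j]; empty spans = 1
    zm = np.ones((n + 2, n + 2))
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            acc = inv_s * (zm[i + 1, j] if span > 1 else 1.0)
            for k in range(i + min_hp + 1, j + 1):
                w = wm[i, k]
                if w > 0.0:
                    acc += w * zm[i + 1, k - 1] * (zm[k + 1, j] if k < j else 1.0)
            zm[i, j] = acc
    ztot = zm[0, n - 1]
    if not np.isfinite(ztot) or ztot <= 0.0:
        return np.zeros((n, n)), False

    # outside pass, pushing from long spans to short, accumulating pair use
    outs = np.zeros((n + 2, n + 2))
    outs[0, n - 1] = 1.0
    pacc = np.zeros((n, n))
    for span in range(n, 0, -1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            o = outs[i, j]
            if o == 0.0:
                continue
            if span > 1:
                outs[i + 1, j] += o * inv_s
            for k in range(i + min_hp + 1, j + 1):
                w = wm[i, k]
                if w > 0.0:
                    zin = zm[i + 1, k - 1]
                    zout = zm[k + 1, j] if k < j else 1.0
                    ow = o * w
                    pacc[i, k] += ow * zin * zout
                    outs[i + 1, k - 1] += ow * zout
                    if k < j:
                        outs[k + 1, j] += ow * zin
    pacc /= ztot
    if not np.isfinite(pacc).all():
        return pacc, False
    return pacc, True


@njit(cache=True)
def windowed_band(enc, pair_w, min_hp, window, scale):
    """Sliding-window pair probabilities, RNAplfold-style averaging.

    A window of length `window` slides with step 1; within each window exact
    pair probabilities are computed; the averaged probability of pair (i, j)
    divides by the number of windows fully containing both i and j.  Output
    is a band: ``band[i, d-1] = p(i, i+d)`` for d in 1..window-1.

    Returns ``(band, ok)``.
    """
    n = enc.shape[0]
    band = np.zeros((n, window - 1))
    counts = np.zeros((n, window - 1))
    nwin = n - window + 1
    ok_all = True
    for s in range(nwin):
        p, ok = inside_outside(enc[s : s + window], pair_w, min_hp, scale)
        if not ok:
            ok_all = False
            break
        for a in range(window):
            for b in range(a + 1, window):
                if p[a, b] != 0.0:
                    band[s + a, b - a - 1] += p[a, b]
                counts[s + a, b - a - 1] += 1.0
    if ok_all:
        for i in range(n):
            for d in range(window - 1):
                if counts[i, d] > 0.0:
                    band[i, d] /= counts[i, d]
    return band, ok_all


@njit(cache=True)
def dbf_many_global(encs, pair_w, min_hp, scale):
    """Mean pairedness (DBF) for a batch of equal-length sequences.

    ``encs`` is an (m, n) int8 matrix of encoded sequences.  Returns a
    vector of m DBF values; entries are NaN where the scale failed.
    """
    m = encs.shape[0]
    n = encs.shape[1]
    out = np.empty(m)
    for r in range(m):
        p, ok = inside_outside(encs[r], pair_w, min_hp, scale)
        if not ok:
            out[r] = np.nan
        else:
            out[r] = 2.0 * p.sum() / n
    return out
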