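"""Per-position base-pairing probabilities and the degree of backfolding.

The degree of backfolding (DBF) of a coding sequence is the mean, over
positions, of the probability that each base is paired in the predicted
secondary-structure ensemble.  Short sequences are folded globally with an
exact partition function; sequences at or above ``local_threshold`` are
folded locally with a sliding window (step 1), mirroring the RNAfold /
RNAplfold division of labour of thermodynamic folding suites.

The built-in engine uses an additive per-pair Boltzmann energy model
(defaults GC=3, AU=2, GU=1 in units of kT) with a minimum hairpin of 3
unpaired bases and no stacking or loop terms.  This keeps the exhaustive
enumeration oracle exact and the dynamic program transparent; every
statistic downstream compares the original ORF against alternatives under
the *same* model, so only relative structuredness matters.  For
replication-grade thermodynamic probabilities, plug in the ViennaRNA
adapter from :mod:`backfold.vienna`, which honours the same contracts.

Windowed probabilities follow the RNAplfold convention: the probability of
a pair is its mean over all windows fully containing it.  Because different
pairs average over different numbers of windows, per-position sums of
windowed probabilities are a weighted mixture and may exceed 1; such
matrices are flagged ``windowed`` and exempt from the [0, 1] profile bound
that global matrices must satisfy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _fold_kernels as _k

__all__ = [
    "FoldParams",
    "PairProbMatrix",
    "BuiltinEngine",
    "pair_probabilities",
    "pair_probabilities_global",
    "pair_probabilities_local",
    "enumerate_structures",
    "pairedness_profile",
    "dbf",
]

_DEFAULT_WEIGHTS = {"GC": 3.0, "AU": 2.0, "GU": 1.0}

#: scales tried in turn when the partition function over/underflows
_SCALE_LADDER = (1.0, math.e, math.e**2, math.e**0.5, math.e**1.5)


@dataclass(frozen=True)
class FoldParams:
    """Parameters of the folding model.

    pair_weights:
        Energies per pair type in units of kT (Boltzmann weight = exp(E/kT)).
    min_hairpin:
        Minimum number of unpaired bases enclosed by a pair.
    window:
        Window length (and maximal pair span) of the local mode.
    local_threshold:
        Sequences of at least this length are folded in local mode.
    temperature_scale:
        kT; energies are divided by this before exponentiation.
    """

    pair_weights: dict = field(default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    min_hairpin: int = 3
    window: int = 100
    local_threshold: int = 100
    temperature_scale: float = 1.0

    def weight_matrix(self) -> np.ndarray:
        return _k.weight_matrix(self.pair_weights, self.temperature_scale)


class PairProbMatrix:
    """Upper-triangular base-pair probabilities in banded storage.

    ``band[i, d-1]`` holds p(i, i+d) for spans d = 1 .. span_limit.
    Global-mode matrices have ``span_limit = n - 1`` (full triangle);
    windowed matrices are limited to spans below the window length and are
    flagged ``windowed`` (their per-position sums may exceed 1, see module
    docstring).
    """

    def __init__(self, band: np.ndarray, *, windowed: bool = False):
        self.band = band
        self.n = band.shape[0]
        self.span_limit = band.shape[1]
        self.windowed = windowed

    def get(self, i: int, j: int) -> float:
        if i > j:
            i, j = j, i
        d = j - i
        if d == 0 or d > self.span_limit:
            return 0.0
        return float(self.band[i, d - 1])

    def toarray(self) -> np.ndarray:
        """Dense upper-triangular matrix (intended for small n)."""
        p = np.zeros((self.n, self.n))
        for d in range(1, self.span_limit + 1):
            idx = np.arange(self.n - d)
            p[idx, idx + d] = self.band[: self.n - d, d - 1]
        return p

    def row_sums(self) -> np.ndarray:
        q = np.zeros(self.n)
        for d in range(1, self.span_limit + 1):
            col = self.band[: self.n - d, d - 1]
            q[: self.n - d] += col
            q[d:] += col
        return q


def _fold_encoded(enc: np.ndarray, params: FoldParams) -> np.ndarray:
    wm = params.weight_matrix()
    for scale in _SCALE_LADDER:
        p, ok = _k.inside_outside(enc, wm, params.min_hairpin, scale)
        if ok:
            return p
    raise ArithmeticError("partition function over/underflowed at every scale")


def pair_probabilities_global(sequence: str, params: FoldParams | None = None) -> PairProbMatrix:
    """Exact equilibrium pair probabilities of the whole sequence.

    O(n^3) inside-outside over the additive per-pair model; no pseudoknots;
    the minimum hairpin separation is enforced.
    """
    params = params or FoldParams()
    enc = _k.encode(sequence)
    n = len(enc)
    if n == 0:
        raise ValueError("empty sequence")
    p = _fold_encoded(enc, params)
    band = np.zeros((n, max(n - 1, 1)))
    for d in range(1, n):
        idx = np.arange(n - d)
        band[: n - d, d - 1] = p[idx, idx + d]
    return PairProbMatrix(band, windowed=False)


def pair_probabilities_local(sequence: str, params: FoldParams | None = None) -> PairProbMatrix:
    """Sliding-window pair probabilities (RNAplfold-style averaging).

    A window of length ``params.window`` slides with step 1; each pair's
    probability is the mean over windows fully containing it.  Pairs with a
    span of at least the window length have probability 0.  Sequences
    shorter than the window fall back to global mode with a warning.
    """
    params = params or FoldParams()
    enc = _k.encode(sequence)
    if len(enc) < params.window:
        warnings.warn(
            f"sequence length {len(enc)} < window {params.window}; falling back to global folding"
        )
        return pair_probabilities_global(sequence, params)
    wm = params.weight_matrix()
    for scale in _SCALE_LADDER:
        band, ok = _k.windowed_band(enc, wm, params.min_hairpin, params.window, scale)
        if ok:
            return PairProbMatrix(band, windowed=True)
    raise ArithmeticError("windowed partition function over/underflowed at every scale")


def pair_probabilities(sequence: str, params: FoldParams | None = None) -> PairProbMatrix:
    """Dispatch to local mode at/above ``local_threshold``, else global."""
    params = params or FoldParams()
    if len(sequence) >= params.local_threshold:
        return pair_probabilities_local(sequence, params)
    return pair_probabilities_global(sequence, params)


_ENUM_LIMIT = 25


def enumerate_structures(sequence: str, params: FoldParams | None = None) -> PairProbMatrix:
    """Exhaustive-enumeration oracle for pair probabilities (length <= 25).

    Enumerates every pseudoknot-free matching over the admissible pairs,
    weights each structure by exp(sum of pair energies / kT), and sums to
    exact probabilities.  Independent of the dynamic program; used to
    validate it.
    """
    params = params or FoldParams()
    enc = _k.encode(sequence)
    n = len(enc)
    if n > _ENUM_LIMIT:
        raise ValueError(f"enumeration oracle refuses length {n} > {_ENUM_LIMIT}")
    wm = params.weight_matrix()
    min_hp = params.min_hairpin

    def structures(i: int, j: int):
        if i > j:
            yield ()
            return
        yield from structures(i + 1, j)
        for k in range(i + min_hp + 1, j + 1):
            if wm[enc[i], enc[k]] > 0.0:
                for left in structures(i + 1, k - 1):
                    for right in structures(k + 1, j):
                        yield ((i, k),) + left + right

    z = 0.0
    acc = np.zeros((n, n))
    for struct in structures(0, n - 1):
        w = 1.0
        for i, j in struct:
            w *= wm[enc[i], enc[j]]
        z += w
        for i, j in struct:
            acc[i, j] += w
    acc /= z
    band = np.zeros((n, max(n - 1, 1)))
    for d in range(1, n):
        idx = np.arange(n - d)
        band[: n - d, d - 1] = acc[idx, idx + d]
    return PairProbMatrix(band, windowed=False)


def pairedness_profile(matrix: PairProbMatrix) -> np.ndarray:
    """Per-position probability of being paired: q[i] = sum_j p(i, j).

    For global matrices entries must lie in [0, 1]; values exceeding 1 by at
    most 1e-9 are clipped, larger excesses raise.  Windowed matrices are
    exempt from the upper bound (window averaging is a weighted mixture).
    """
    q = matrix.row_sums()
    if not matrix.windowed:
        over = q.max(initial=0.0) - 1.0
        if over > 1e-9:
            raise ArithmeticError(f"pairedness {1.0 + over:.12f} exceeds 1 beyond tolerance")
        np.clip(q, 0.0, 1.0, out=q)
    return q


def dbf(profile: np.ndarray) -> float:
    """Degree of backfolding: mean per-position pairedness."""
    profile = np.asarray(profile)
    if profile.size == 0:
        raise ValueError("empty pairedness profile")
    return float(profile.mean())


class BuiltinEngine:
    """Folding engine facade over the built-in partition function.

    Exposes the two operations downstream code needs: a full probability
    matrix for one sequence, and a batched DBF computation for many
    equal-length sequences (the hot path of null-model scoring).
    """

    name = "builtin"

    def __init__(self, params: FoldParams | None = None):
        self.params = params or FoldParams()

    def pair_probabilities(self, sequence: str) -> PairProbMatrix:
        return pair_probabilities(sequence, self.params)

    def dbf(self, sequence: str) -> float:
        return dbf(pairedness_profile(self.pair_probabilities(sequence)))

    def dbf_many(self, sequences: list[str]) -> np.ndarray:
        """DBF of each sequence; all must share one length.

        Short sequences (below ``local_threshold``) go through one batched
        global-folding kernel call; long ones fall back to per-sequence
        windowed folding.
        """
        if not sequences:
            return np.zeros(0)
        n = len(sequences[0])
        if any(len(s) != n for s in sequences):
            raise ValueError("dbf_many requires equal-length sequences")
        if n >= self.params.local_threshold:
            return np.array([self.dbf(s) for s in sequences])
        encs = np.stack([_k.encode(s) for s in sequences])
        wm = self.params.weight_matrix()
        for scale in _SCALE_LADDER:
            out = _k.dbf_many_global(encs, wm, self.params.min_hairpin, scale)
            if not np.isnan(out).any():
                return out
        raise ArithmeticError("partition function over/underflowed at every scale")
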