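"""The per-ORF DBF score: empirical rank of an ORF's structuredness.

For each original ORF (oORF) a set of n alternative ORFs (aORFs, default
n = 100) is sampled under one of the null models, every sequence is folded,
and the oORF's degree of backfolding (DBF) is ranked within the aORF
sample:

    score = (j + k/2) / (i + j + k)

where i / j / k count aORFs with higher / lower / identical DBF.  The score
lives in [0, 1]: 0 means every aORF is more structured than the oORF, 1
means none is, and 0.5 means all aORFs behave exactly like the oORF (all
ties).  The published form of this formula is typographically corrupted;
the expression above is the unique simple form satisfying those three
boundary conditions and is used throughout.

Ties are declared when two DBF values differ by at most ``tie_epsilon``
(default 1e-12); aORFs whose sequence is identical to the oORF are ties by
a fast path that skips folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aorf_models import CodonUsageTable, rng_for, sample_aorf
from .folding import BuiltinEngine, FoldParams
from .sequence_io import OrfRecord

__all__ = ["DbfResult", "dbf_score", "score_records", "score_record"]

DEFAULT_N_AORFS = 100
DEFAULT_TIE_EPSILON = 1e-12


@dataclass(frozen=True)
class DbfResult:
    """Scored record: the oORF DBF, its aORF DBF sample and the rank score."""

    id: str
    model: int
    dbf_o: float
    dbf_a: np.ndarray
    i: int  # aORFs with higher DBF
    j: int  # aORFs with lower DBF
    k: int  # aORFs with identical DBF
    score: float

    @property
    def n(self) -> int:
        return self.i + self.j + self.k


def dbf_score(
    dbf_o: float, dbf_a, tie_epsilon: float = DEFAULT_TIE_EPSILON
) -> tuple[int, int, int, float]:
    """Rank ``dbf_o`` within the aORF DBF sample.

    Returns ``(i, j, k, score)`` with i/j/k the counts of higher/lower/tied
    aORFs and score = (j + k/2) / (i + j + k).
    """
    dbf_a = np.asarray(dbf_a, dtype=float)
    if dbf_a.size == 0:
        raise ValueError("empty aORF DBF sample")
    k = int(np.sum(np.abs(dbf_a - dbf_o) <= tie_epsilon))
    i = int(np.sum(dbf_a > dbf_o + tie_epsilon))
    j = dbf_a.size - i - k
    score = (j + k / 2.0) / dbf_a.size
    return i, j, k, score


def score_record(
    record: OrfRecord,
    model: int,
    *,
    n_aorfs: int = DEFAULT_N_AORFS,
    engine=None,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
    tie_epsilon: float = DEFAULT_TIE_EPSILON,
) -> DbfResult:
    """Score one ORF against ``n_aorfs`` null-model recodings.

    All sequences (oORF and aORFs) are folded with the same engine and the
    same mode — global or windowed is decided once by the oORF length — so
    the comparison is like-for-like.  Duplicate aORF sequences are folded
    once; aORFs identical to the oORF share its fold and register as exact
    ties.
    """
    engine = engine or BuiltinEngine()
    if model == 1 and usage is None:
        raise ValueError("model 1 requires a codon usage table")
    oseq = record.sequence
    aorf_seqs = []
    for rep in range(n_aorfs):
        rng = rng_for(seed, record.id, model, rep)
        aorf_seqs.append("".join(sample_aorf(record, model, rng, usage)))

    unique = {oseq: None}
    for s in aorf_seqs:
        unique.setdefault(s, None)
    unique_list = list(unique)
    dbfs = engine.dbf_many(unique_list)
    table = dict(zip(unique_list, dbfs))
    dbf_o = float(table[oseq])
    dbf_a = np.array([table[s] for s in aorf_seqs])
    i, j, k, score = dbf_score(dbf_o, dbf_a, tie_epsilon)
    return DbfResult(record.id, model, dbf_o, dbf_a, i, j, k, score)


def score_records(
    records: list[OrfRecord],
    model: int,
    *,
    n_aorfs: int = DEFAULT_N_AORFS,
    params: FoldParams | None = None,
    engine=None,
    usage: CodonUsageTable | None = None,
    seed: int = 0,
    tie_epsilon: float = DEFAULT_TIE_EPSILON,
) -> list[DbfResult]:
    """Score every record; deterministic given ``seed`` and order-independent.

    ``params`` configures the built-in engine when no ``engine`` is given.
    """
    if engine is None:
        engine = BuiltinEngine(params or FoldParams())
    return [
        score_record(
            rec,
            model,
            n_aorfs=n_aorfs,
            engine=engine,
            usage=usage,
            seed=seed,
            tie_epsilon=tie_epsilon,
        )
        for rec in records
    ]
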