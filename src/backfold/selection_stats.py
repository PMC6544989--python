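"""Score-distribution statistics and the structural-selection fraction S.

DBF scores are sectioned into 101 quantile bins (0.00 to 1.00 in steps of
0.01).  Under neutrality each bin is expected to hold ~1/101 of all scored
ORFs; enrichment of the extreme bins signals selection for unusually low
(bins 0-4) or high (bins 96-100) structuredness.  A bin counts as enriched
when its Z-score — deviation of its fraction from the mean bin fraction,
standardized by the population SD over the 101 bin fractions — reaches
1.96.  The selection fraction sums the enrichment excess over the neutral
expectation:

    s_low  = sum over enriched bins 0..4    of (a_bin - 1/101)
    s_high = sum over enriched bins 96..100 of (a_bin - 1/101)
    S      = s_low + s_high

A built-in calibration harness generates a null corpus (each "oORF" is
itself a fresh model-2 shuffle of a random ORF) where the score rank is
uniform by construction, and a recovery harness implants a chosen fraction
of deliberately extreme ORFs (each the most-structured of a shuffle
search) to verify that S recovers the implanted fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .aorf_models import model2_sample, rng_for
from .dbf_scoring import DEFAULT_N_AORFS, dbf_score
from .folding import BuiltinEngine
from .sequence_io import OrfRecord

__all__ = [
    "N_BINS",
    "ScoreDistribution",
    "SelectionSummary",
    "bin_scores",
    "selection_fraction",
    "null_scores",
    "null_uniformity_experiment",
    "implant_scores",
    "recovery_experiment",
]

N_BINS = 101
Z_DEFAULT = 1.96


def score_bin(score: float) -> int:
    """Quantile bin of a score: round(score*100) half away from zero.

    Scores from n=100 aORFs live on a half-percent grid; grid midpoints
    (x.5) round up.  A 1e-9 nudge absorbs binary representation error so
    binning is bit-reproducible.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return int(math.floor(score * 100.0 + 0.5 + 1e-9))


@dataclass(frozen=True)
class ScoreDistribution:
    """Counts, fractions and Z-scores over the 101 score quantile bins."""

    counts: np.ndarray
    fractions: np.ndarray
    z: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SelectionSummary:
    s_low: float
    s_high: float
    enriched_low_bins: tuple[int, ...]
    enriched_high_bins: tuple[int, ...]
    null_rejected: bool

    @property
    def S(self) -> float:
        return self.s_low + self.s_high


def bin_scores(scores) -> ScoreDistribution:
    """Section scores into the 101 bins and attach per-bin Z-scores.

    Z-scores standardize each bin fraction by the mean (1/101) and the
    population standard deviation over the 101 bin fractions; a perfectly
    uniform histogram has all-zero Z.
    """
    scores = np.asarray(scores, dtype=float)
    counts = np.zeros(N_BINS, dtype=np.int64)
    for s in scores:
        counts[score_bin(float(s))] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no scores to bin")
    fractions = counts / total
    dev = fractions - fractions.mean()
    sd = float(fractions.std())  # population SD across the 101 bins
    if np.abs(dev).max() < 1e-12:  # uniform histogram: all-zero Z
        z = np.zeros(N_BINS)
    else:
        z = dev / sd
    return ScoreDistribution(counts, fractions, z)


def selection_fraction(
    dist: ScoreDistribution, z_threshold: float = Z_DEFAULT
) -> SelectionSummary:
    """Fraction of ORFs under structural selection, S = s_low + s_high.

    Only the five lowest (0-4) and five highest (96-100) bins can
    contribute, and each only when its Z-score reaches ``z_threshold``; the
    neutral expectation 1/101 is deducted per contributing bin.
    """
    expected = 1.0 / N_BINS
    low = tuple(b for b in range(0, 5) if dist.z[b] >= z_threshold)
    high = tuple(b for b in range(96, 101) if dist.z[b] >= z_threshold)
    s_low = float(sum(dist.fractions[b] - expected for b in low))
    s_high = float(sum(dist.fractions[b] - expected for b in high))
    return SelectionSummary(s_low, s_high, low, high, bool(low or high))


# ---------------------------------------------------------------------------
# calibration harnesses


def _random_orf_codons(rng: np.random.Generator, n_codons: int) -> tuple[str, ...]:
    from .sequence_io import SENSE_CODONS, STOP_CODONS

    body = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 2)]
    codons = ("ATG", *body, STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return codons


def _as_record(rid: str, codons: tuple[str, ...]) -> OrfRecord:
    from .sequence_io import translate

    return OrfRecord(rid, codons, translate(codons))


def null_scores(
    n_records: int,
    *,
    n_aorfs: int = DEFAULT_N_AORFS,
    seed: int = 0,
    orf_codons: int = 25,
    engine=None,
) -> np.ndarray:
    """Scores of a null corpus where every oORF is itself a random shuffle.

    Each record is a random ORF (ATG + uniform sense codons + stop) whose
    "oORF" is redrawn as a model-2 shuffle, scored against ``n_aorfs``
    fresh shuffles.  Under this construction the score's rank statistic is
    exactly exchangeable, so with n_aorfs = 100 the scores are uniform over
    the 101 grid values.
    """
    engine = engine or BuiltinEngine()
    out = np.empty(n_records)
    for r in range(n_records):
        rid = f"null{r}"
        base = _as_record(rid, _random_orf_codons(rng_for(seed, rid, 9, 0), orf_codons))
        oorf = model2_sample(base, rng_for(seed, rid, 2, n_aorfs))
        seqs = ["".join(oorf)]
        for rep in range(n_aorfs):
            seqs.append("".join(model2_sample(base, rng_for(seed, rid, 2, rep))))
        dbfs = engine.dbf_many(seqs)
        _, _, _, score = dbf_score(dbfs[0], dbfs[1:])
        out[r] = score
    return out


def null_uniformity_experiment(
    n_records: int,
    n_aorfs: int = DEFAULT_N_AORFS,
    seed: int = 0,
    *,
    orf_codons: int = 25,
    engine=None,
) -> ScoreDistribution:
    """Built-in null calibration: bin the scores of a null corpus."""
    if n_records < 100:
        raise ValueError("need at least 100 records for a meaningful calibration")
    return bin_scores(null_scores(n_records, n_aorfs=n_aorfs, seed=seed, orf_codons=orf_codons, engine=engine))


def implant_scores(
    n_implants: int,
    *,
    n_aorfs: int = DEFAULT_N_AORFS,
    n_search: int = 200,
    seed: int = 0,
    orf_codons: int = 25,
    engine=None,
) -> np.ndarray:
    """Scores of deliberately extreme ORFs (max-DBF of an n_search shuffle set).

    Each implant takes a random ORF, picks the most structured arrangement
    among ``n_search`` model-2 shuffles as its oORF, and scores it against
    ``n_aorfs`` fresh shuffles — emulating strong selection for high
    structuredness.
    """
    engine = engine or BuiltinEngine()
    out = np.empty(n_implants)
    for r in range(n_implants):
        rid = f"implant{r}"
        base = _as_record(rid, _random_orf_codons(rng_for(seed, rid, 9, 0), orf_codons))
        search = ["".join(model2_sample(base, rng_for(seed, rid, 3, rep))) for rep in range(n_search)]
        search_dbfs = engine.dbf_many(search)
        oseq = search[int(np.argmax(search_dbfs))]
        seqs = [oseq] + ["".join(model2_sample(base, rng_for(seed, rid, 2, rep))) for rep in range(n_aorfs)]
        dbfs = engine.dbf_many(seqs)
        _, _, _, score = dbf_score(dbfs[0], dbfs[1:])
        out[r] = score
    return out


def recovery_experiment(
    base_null: np.ndarray,
    implants: np.ndarray,
    implant_fraction: float,
    z_threshold: float = Z_DEFAULT,
) -> SelectionSummary:
    """Replace a fraction of null scores by implant scores and measure S.

    ``base_null`` and ``implants`` are score vectors (from
    :func:`null_scores` / :func:`implant_scores`); the first
    ``implant_fraction * len(base_null)`` null scores are replaced.
    """
    n = len(base_null)
    m = int(round(implant_fraction * n))
    if m > len(implants):
        raise ValueError(f"need {m} implant scores, have {len(implants)}")
    mixed = np.concatenate([implants[:m], base_null[m:]])
    return selection_fraction(bin_scores(mixed), z_threshold)
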