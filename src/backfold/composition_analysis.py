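"""Codon / amino-acid composition versus DBF-score quantiles.

Highly and lowly structured ORFs differ systematically in composition:
within every synonymous family the G+C-richer codons are over-represented
among highly structured ORFs, and amino acids whose codons are G+C-richer
on average are likewise enriched there.  This module

* tabulates codon, amino-acid and GC composition of ORFs pooled into three
  score-quantile groups (low = bins 0-4, mid = 5-95, high = 96-100);
* derives the "set 1" (low-structure) / "set 2" (high-structure) codon and
  amino-acid partitions, either empirically from composition trends across
  several datasets (majority vote), or directly from the genetic code by
  G+C rank — the rule the empirical trends converge to.

Methionine and tryptophan have single-codon families and so cannot carry a
codon-level signal; they are excluded from the codon partition but do
participate in the 10 + 10 amino-acid partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aorf_models import gc_content
from .dbf_scoring import DbfResult
from .selection_stats import score_bin
from .sequence_io import AMINO_ACIDS, SENSE_CODONS, SYNONYMOUS_FAMILIES
from .sequence_io import OrfRecord

__all__ = [
    "QuantileCompositionTable",
    "CodonSetPartition",
    "composition_by_quantile",
    "derive_sets_by_trend",
    "gc_rank_partition",
    "aa_gc_comparison",
]

GROUPS = ("low", "mid", "high")

#: third-position tie-break order for codons of equal G+C count
_THIRD_RANK = {"C": 3, "G": 2, "T": 1, "A": 0}

_SINGLE_CODON_AAS = frozenset(aa for aa in AMINO_ACIDS if len(SYNONYMOUS_FAMILIES[aa]) == 1)


def _gc_count(codon: str) -> int:
    return sum(1 for b in codon if b in "GC")


@dataclass(frozen=True)
class QuantileCompositionTable:
    """Composition of ORFs pooled by score-quantile group.

    ``codon_freq`` / ``aa_freq`` are DataFrames (index codon or amino acid,
    one column per group) of relative frequencies within the group's pooled
    codon content; groups without any ORF hold NaN.  ``gc`` maps group to
    the pooled GC content, ``n_orfs`` to the group size.
    """

    codon_freq: pd.DataFrame
    aa_freq: pd.DataFrame
    gc: dict
    n_orfs: dict


def _group_of(score: float) -> str:
    b = score_bin(score)
    if b <= 4:
        return "low"
    if b >= 96:
        return "high"
    return "mid"


def composition_by_quantile(
    records: list[OrfRecord], results: list[DbfResult]
) -> QuantileCompositionTable:
    """Pool codons of scored ORFs into low/mid/high quantile groups."""
    by_id = {r.id: r for r in records}
    codon_counts = {g: {c: 0 for c in SENSE_CODONS} for g in GROUPS}
    aa_counts = {g: {a: 0 for a in AMINO_ACIDS} for g in GROUPS}
    gc_bases = {g: [0, 0] for g in GROUPS}  # (gc, total)
    n_orfs = {g: 0 for g in GROUPS}
    for res in results:
        rec = by_id[res.id]
        g = _group_of(res.score)
        n_orfs[g] += 1
        for codon, aa in zip(rec.codons, rec.peptide):
            if aa == "*":
                continue
            codon_counts[g][codon] += 1
            aa_counts[g][aa] += 1
        seq = rec.sequence
        gc_bases[g][0] += sum(1 for b in seq if b in "GC")
        gc_bases[g][1] += len(seq)

    def _freq_frame(counts: dict, index) -> pd.DataFrame:
        cols = {}
        for g in GROUPS:
            total = sum(counts[g].values())
            if total == 0:
                cols[g] = pd.Series(np.nan, index=index)
            else:
                cols[g] = pd.Series({k: v / total for k, v in counts[g].items()})
        return pd.DataFrame(cols).loc[index]

    gc = {
        g: (gc_bases[g][0] / gc_bases[g][1]) if gc_bases[g][1] else float("nan") for g in GROUPS
    }
    return QuantileCompositionTable(
        _freq_frame(codon_counts, list(SENSE_CODONS)),
        _freq_frame(aa_counts, list(AMINO_ACIDS)),
        gc,
        n_orfs,
    )


@dataclass(frozen=True)
class CodonSetPartition:
    """Disjoint low-structure (set 1) / high-structure (set 2) partitions.

    Codon sets cover every multi-codon sense family with at least one codon
    per side (single-codon families M and W excluded); amino-acid sets are
    a 10 + 10 split of all twenty amino acids.
    """

    set1_codons: frozenset
    set2_codons: frozenset
    set1_aas: frozenset
    set2_aas: frozenset

    def __post_init__(self):
        if self.set1_codons & self.set2_codons:
            raise ValueError("codon sets overlap")
        if self.set1_aas & self.set2_aas:
            raise ValueError("amino-acid sets overlap")
        if len(self.set1_aas) != 10 or len(self.set2_aas) != 10:
            raise ValueError("amino-acid sets must contain exactly 10 members each")
        for aa in AMINO_ACIDS:
            if aa in _SINGLE_CODON_AAS:
                continue
            fam = set(SYNONYMOUS_FAMILIES[aa])
            if not (fam & self.set1_codons) or not (fam & self.set2_codons):
                raise ValueError(f"family {aa!r} lacks a codon on one side of the partition")

    def codons_for(self, aa: str, side: int) -> list[str]:
        """Codons of ``aa`` on the given side (1 or 2); single-codon
        families return their codon regardless of side."""
        fam = SYNONYMOUS_FAMILIES[aa]
        if len(fam) == 1:
            return list(fam)
        chosen = self.set1_codons if side == 1 else self.set2_codons
        return sorted(set(fam) & chosen)


def gc_rank_partition() -> CodonSetPartition:
    """The G+C-rank partition, a pure function of the genetic code.

    Within each multi-codon family, codons sorted by (G+C count, then
    third-position base C > G > T > A) descending; the top half goes to
    set 2 (high structure), the rest to set 1.  Amino-acid sets are the 10
    with the highest / lowest mean codon G+C count, ties broken
    alphabetically.
    """
    set1, set2 = set(), set()
    for aa in AMINO_ACIDS:
        fam = SYNONYMOUS_FAMILIES[aa]
        if len(fam) == 1:
            continue
        order = sorted(
            fam, key=lambda c: (_gc_count(c), _THIRD_RANK[c[2]], c), reverse=True
        )
        half = (len(order) + 1) // 2
        set2.update(order[:half])
        set1.update(order[half:])
    mean_gc = {aa: float(np.mean([_gc_count(c) for c in SYNONYMOUS_FAMILIES[aa]])) for aa in AMINO_ACIDS}
    ranked = sorted(AMINO_ACIDS, key=lambda a: (-mean_gc[a], a))
    return CodonSetPartition(
        frozenset(set1), frozenset(set2), frozenset(ranked[10:]), frozenset(ranked[:10])
    )


def _trend(low: float, mid: float, high: float) -> int:
    """+1 for a strict increase low < mid < high, -1 for a strict decrease."""
    if np.isnan([low, mid, high]).any():
        return 0
    if low < mid < high:
        return 1
    if low > mid > high:
        return -1
    return 0


def derive_sets_by_trend(tables: list[QuantileCompositionTable]) -> CodonSetPartition:
    """Empirical partition from composition trends across datasets.

    Per codon and dataset: a steady increase of its frequency from the low
    via the mid to the high quantile group votes +1 (set 2), a steady
    decrease votes -1 (set 1).  The majority across datasets decides;
    codons left unresolved (tied or trendless) fall back to the G+C-rank
    rule.  Amino acids are ranked by their mean vote (G+C rank, then
    alphabet, as tie-breaks) and split 10 + 10.
    """
    if not tables:
        raise ValueError("need at least one composition table")
    fallback = gc_rank_partition()

    codon_votes = {c: 0 for c in SENSE_CODONS}
    aa_votes = {a: 0.0 for a in AMINO_ACIDS}
    for t in tables:
        for c in SENSE_CODONS:
            codon_votes[c] += _trend(
                t.codon_freq.at[c, "low"], t.codon_freq.at[c, "mid"], t.codon_freq.at[c, "high"]
            )
        for a in AMINO_ACIDS:
            aa_votes[a] += _trend(
                t.aa_freq.at[a, "low"], t.aa_freq.at[a, "mid"], t.aa_freq.at[a, "high"]
            )

    set1, set2 = set(), set()
    for aa in AMINO_ACIDS:
        fam = SYNONYMOUS_FAMILIES[aa]
        if len(fam) == 1:
            continue
        for c in fam:
            if codon_votes[c] > 0:
                set2.add(c)
            elif codon_votes[c] < 0:
                set1.add(c)
            elif c in fallback.set2_codons:
                set2.add(c)
            else:
                set1.add(c)
        # a family swept entirely to one side cannot inform the codon-set
        # experiments; restore the fallback split for it
        if not (set(fam) & set1) or not (set(fam) & set2):
            for c in fam:
                set1.discard(c)
                set2.discard(c)
            set1.update(set(fam) & fallback.set1_codons)
            set2.update(set(fam) & fallback.set2_codons)

    mean_gc = {aa: float(np.mean([_gc_count(c) for c in SYNONYMOUS_FAMILIES[aa]])) for aa in AMINO_ACIDS}
    ranked = sorted(AMINO_ACIDS, key=lambda a: (-aa_votes[a], -mean_gc[a], a))
    return CodonSetPartition(
        frozenset(set1), frozenset(set2), frozenset(ranked[10:]), frozenset(ranked[:10])
    )


def write_partition(partition: CodonSetPartition, path) -> None:
    """Write a partition as two-column ``item set`` text (codons then aas)."""
    with open(path, "w") as fh:
        for c in sorted(partition.set1_codons):
            fh.write(f"{c}\t1\n")
        for c in sorted(partition.set2_codons):
            fh.write(f"{c}\t2\n")
        for a in sorted(partition.set1_aas):
            fh.write(f"{a}\t1\n")
        for a in sorted(partition.set2_aas):
            fh.write(f"{a}\t2\n")


def read_partition(path) -> CodonSetPartition:
    """Read a partition written by :func:`write_partition`."""
    sets: dict[tuple[int, int], set] = {(3, 1): set(), (3, 2): set(), (1, 1): set(), (1, 2): set()}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            item, side = line.split()
            sets[(len(item), int(side))].add(item)
    return CodonSetPartition(
        frozenset(sets[(3, 1)]), frozenset(sets[(3, 2)]),
        frozenset(sets[(1, 1)]), frozenset(sets[(1, 2)]),
    )


def aa_gc_comparison(partition: CodonSetPartition):
    """Mann-Whitney U comparison of mean codon GC share between aa sets.

    Returns ``(U, p)`` for the two-sided rank-sum test on the per-amino-acid
    mean GC share (mean over the family's codons of G+C count / 3).
    """
    share = {
        aa: float(np.mean([_gc_count(c) / 3.0 for c in SYNONYMOUS_FAMILIES[aa]]))
        for aa in AMINO_ACIDS
    }
    x1 = [share[a] for a in sorted(partition.set1_aas)]
    x2 = [share[a] for a in sorted(partition.set2_aas)]
    if sorted(x1) == sorted(x2):
        return len(x1) * len(x2) / 2.0, 1.0
    res = stats.mannwhitneyu(x1, x2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)
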