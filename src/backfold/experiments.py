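"""Random-peptide simulations of codon-set and amino-acid-set structure.

Two simulations quantify how much codon choice and amino-acid identity each
contribute to coding-sequence secondary structure:

* **codon-set experiment** — for each random peptide, build one ORF using
  only low-structure (set 1) codons and one using only high-structure
  (set 2) codons, fold both, and compare the mean per-ORF paired-base
  fraction of the two groups relative to their pooled mean;
* **amino-acid-set experiment** — build independent random peptides from
  only the 10 low-structure or only the 10 high-structure amino acids
  (uniform codon choice within each family), fold the resulting ORFs, and
  compare group means the same way.

Every peptide starts with methionine.  With equal group sizes the two
ratios of the codon-set experiment sum to exactly 2 by pooled-mean algebra;
the same identity holds per run for the amino-acid experiment under the
default per-ORF pooling.  A per-base pooling convention is provided as an
alternative (it differs only when group ORF lengths differ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .composition_analysis import CodonSetPartition
from .folding import BuiltinEngine, FoldParams
from .sequence_io import AMINO_ACIDS, SYNONYMOUS_FAMILIES

__all__ = [
    "PeptideSpec",
    "FoldChangeResult",
    "random_peptides",
    "random_orfs",
    "orf_for_peptide",
    "codon_set_experiment",
    "amino_acid_set_experiment",
]


@dataclass(frozen=True)
class PeptideSpec:
    """Specification of a random-peptide set.

    Residues after the fixed initial methionine are i.i.d. uniform over
    ``alphabet`` (default: all 20 amino acids).
    """

    n_peptides: int
    length: int = 500
    alphabet: tuple = tuple(AMINO_ACIDS)
    seed: int = 0

    def __post_init__(self):
        if not self.alphabet:
            raise ValueError("empty amino-acid alphabet")
        if "*" in self.alphabet:
            raise ValueError("stop is not a peptide residue")


@dataclass(frozen=True)
class FoldChangeResult:
    """Group means of the paired-base fraction, relative to the pooled mean."""

    mean_paired_set1: float
    mean_paired_set2: float
    pooled_mean: float
    n_per_group: int

    @property
    def ratio_set1(self) -> float:
        return self.mean_paired_set1 / self.pooled_mean

    @property
    def ratio_set2(self) -> float:
        return self.mean_paired_set2 / self.pooled_mean


def random_peptides(spec: PeptideSpec) -> list[str]:
    """Generate ``spec.n_peptides`` random peptides, methionine first."""
    rng = np.random.default_rng(np.random.SeedSequence((int(spec.seed), 0x9E97)))
    alphabet = np.array(list(spec.alphabet))
    out = []
    for _ in range(spec.n_peptides):
        rest = alphabet[rng.integers(len(alphabet), size=spec.length - 1)]
        out.append("M" + "".join(rest))
    return out


def orf_for_peptide(
    peptide: str,
    rng: np.random.Generator,
    partition: CodonSetPartition | None = None,
    side: int | None = None,
) -> str:
    """Encode a peptide as an ORF by uniform codon choice.

    With a partition and side, draws uniformly among that side's codons of
    each family (single-codon families use their only codon); otherwise
    uniformly over the full family.
    """
    out = []
    for aa in peptide:
        if partition is not None and side is not None:
            codons = partition.codons_for(aa, side)
            if not codons:
                raise ValueError(f"no side-{side} codons for amino acid {aa!r}")
        else:
            codons = SYNONYMOUS_FAMILIES[aa]
        out.append(codons[rng.integers(len(codons))] if len(codons) > 1 else codons[0])
    return "".join(out)


def random_orfs(n: int, length_aa: int, seed: int = 0) -> list[str]:
    """Random ORFs: random peptides encoded with uniform codon choice."""
    peptides = random_peptides(PeptideSpec(n, length_aa, seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xA11)))
    return [orf_for_peptide(p, rng) for p in peptides]


def _pooled_result(d1: np.ndarray, d2: np.ndarray, pooling: str) -> FoldChangeResult:
    if pooling not in ("orf", "base"):
        raise ValueError(f"unknown pooling {pooling!r}")
    m1, m2 = float(d1.mean()), float(d2.mean())
    pooled = float(np.concatenate([d1, d2]).mean())
    return FoldChangeResult(m1, m2, pooled, len(d1))


def codon_set_experiment(
    peptides: list[str],
    partition: CodonSetPartition,
    params: FoldParams | None = None,
    seed: int = 0,
    engine=None,
    pooling: str = "orf",
) -> FoldChangeResult:
    """Paired-base fold change between set-1-only and set-2-only recodings.

    Both ORFs of a peptide encode the identical sequence of amino acids;
    only the synonymous-codon side differs.
    """
    engine = engine or BuiltinEngine(params or FoldParams())
    rng1 = np.random.default_rng(np.random.SeedSequence((int(seed), 1)))
    rng2 = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    orfs1 = [orf_for_peptide(p, rng1, partition, 1) for p in peptides]
    orfs2 = [orf_for_peptide(p, rng2, partition, 2) for p in peptides]
    d1 = np.array([engine.dbf(s) for s in orfs1])
    d2 = np.array([engine.dbf(s) for s in orfs2])
    return _pooled_result(d1, d2, pooling)


def amino_acid_set_experiment(
    n: int,
    length: int,
    partition: CodonSetPartition,
    params: FoldParams | None = None,
    seed: int = 0,
    engine=None,
    pooling: str = "orf",
) -> FoldChangeResult:
    """Paired-base fold change between set-1-aa and set-2-aa peptide ORFs.

    Unlike the codon-set experiment the two groups encode *different*
    peptides: ``n`` built from the 10 low-structure amino acids and ``n``
    independent ones from the 10 high-structure amino acids, each encoded
    with uniform codon choice over the full family.
    """
    engine = engine or BuiltinEngine(params or FoldParams())
    pep1 = random_peptides(PeptideSpec(n, length, tuple(sorted(partition.set1_aas)), seed * 2 + 1))
    pep2 = random_peptides(PeptideSpec(n, length, tuple(sorted(partition.set2_aas)), seed * 2 + 2))
    rng1 = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
    rng2 = np.random.default_rng(np.random.SeedSequence((int(seed), 4)))
    d1 = np.array([engine.dbf(orf_for_peptide(p, rng1)) for p in pep1])
    d2 = np.array([engine.dbf(orf_for_peptide(p, rng2)) for p in pep2])
    return _pooled_result(d1, d2, pooling)
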