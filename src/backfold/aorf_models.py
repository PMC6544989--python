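"""Null models generating alternative ORFs (aORFs) for a given peptide.

An aORF is a synonymous recoding of an original ORF (oORF): it translates
to exactly the same peptide but may use different codons.  Three models are
provided:

* **model 0 (free)** — every position draws uniformly from the synonymous
  family of its amino acid, independently;
* **model 1 (strict)** — draws follow a supplied codon-usage table
  (within-family relative frequencies), independently per position;
* **model 2 (shuffle)** — within each amino-acid family, the multiset of
  codons actually present in the oORF is permuted uniformly over that
  family's positions.  The global codon multiset — and therefore GC content
  and codon usage — is preserved exactly; only the *arrangement* of
  synonymous codons changes.

Stop codons form a three-codon family of their own and are treated like any
other family (model 2 shuffles within the usually singleton stop family, a
no-op).

Reproducibility: random streams are derived per (seed, record id, model,
replicate) so that results do not depend on processing order or worker
count.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .sequence_io import CODON_TO_AA, OrfRecord, SYNONYMOUS_FAMILIES

__all__ = [
    "CodonUsageTable",
    "rng_for",
    "model0_sample",
    "model1_sample",
    "model2_sample",
    "sample_aorf",
    "compute_codon_usage",
    "gc_content",
]


def rng_for(seed: int, record_id: str, model: int, replicate: int) -> np.random.Generator:
    """Derive a dedicated random stream for one (record, model, replicate).

    The record id enters via CRC32 so that streams are stable across runs
    and independent of the order in which records are processed.
    """
    key = zlib.crc32(record_id.encode())
    ss = np.random.SeedSequence((int(seed), key, int(model), int(replicate)))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class CodonUsageTable:
    """Per-amino-acid relative synonymous codon frequencies.

    ``freq[aa][codon]`` sums to 1 within every family; every standard-code
    codon (including the stop family ``*``) belongs to exactly one family.
    """

    freq: dict = field(default_factory=dict)

    def __post_init__(self):
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            if aa not in self.freq:
                raise ValueError(f"family {aa!r} missing from usage table")
            total = sum(self.freq[aa].get(c, 0.0) for c in fam)
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"family {aa!r} frequencies sum to {total}, not 1")
            if any(self.freq[aa].get(c, 0.0) < 0 for c in fam):
                raise ValueError(f"family {aa!r} has negative frequencies")

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        return cls({aa: {c: 1.0 / len(fam) for c in fam} for aa, fam in SYNONYMOUS_FAMILIES.items()})

    @classmethod
    def from_counts(cls, counts: dict) -> "CodonUsageTable":
        """Build a table from raw codon counts; empty families get uniform
        frequencies with a warning."""
        freq: dict = {}
        for aa, fam in SYNONYMOUS_FAMILIES.items():
            fam_counts = {c: float(counts.get(c, 0)) for c in fam}
            total = sum(fam_counts.values())
            if total == 0:
                warnings.warn(f"no codons observed for family {aa!r}; using uniform frequencies")
                freq[aa] = {c: 1.0 / len(fam) for c in fam}
            else:
                freq[aa] = {c: v / total for c, v in fam_counts.items()}
        return cls(freq)

    @classmethod
    def read(cls, path) -> "CodonUsageTable":
        """Read a whitespace-separated ``codon frequency`` file.

        Frequencies are interpreted as within-family relative weights and
        renormalized, matching common codon-usage-table exports.
        """
        weights: dict[str, float] = {}
        with open(path) as handle:
            for line in handle:
                line = line.split("#")[0].strip()
                if not line:
                    continue
                codon, value = line.split()[:2]
                codon = codon.upper().replace("U", "T")
                if codon not in CODON_TO_AA:
                    raise ValueError(f"unknown codon {codon!r} in usage table")
                weights[codon] = float(value)
        return cls.from_counts(weights)

    def write(self, path) -> None:
        with open(path, "w") as handle:
            for aa in sorted(self.freq):
                for codon in SYNONYMOUS_FAMILIES[aa]:
                    handle.write(f"{codon}\t{self.freq[aa][codon]:.6f}\n")


def model0_sample(orf: OrfRecord, rng: np.random.Generator) -> tuple[str, ...]:
    """Uniform synonymous recoding (model 0, 'free')."""
    out = []
    for aa in orf.peptide:
        fam = SYNONYMOUS_FAMILIES[aa]
        out.append(fam[rng.integers(len(fam))] if len(fam) > 1 else fam[0])
    return tuple(out)


def model1_sample(
    orf: OrfRecord, usage: CodonUsageTable, rng: np.random.Generator
) -> tuple[str, ...]:
    """Codon-usage-weighted synonymous recoding (model 1, 'strict')."""
    out = []
    for aa in orf.peptide:
        fam = SYNONYMOUS_FAMILIES[aa]
        if len(fam) == 1:
            out.append(fam[0])
            continue
        probs = np.array([usage.freq[aa][c] for c in fam])
        total = probs.sum()
        if total <= 0:
            raise ValueError(f"codon usage table has zero mass for required family {aa!r}")
        out.append(fam[rng.choice(len(fam), p=probs / total)])
    return tuple(out)


def model2_sample(orf: OrfRecord, rng: np.random.Generator) -> tuple[str, ...]:
    """Within-family permutation of the codons present (model 2, 'shuffle').

    Exactly preserves the codon multiset, hence GC content and codon usage.
    """
    out = list(orf.codons)
    by_aa: dict[str, list[int]] = {}
    for pos, aa in enumerate(orf.peptide):
        by_aa.setdefault(aa, []).append(pos)
    for positions in by_aa.values():
        if len(positions) < 2:
            continue
        codons_here = [orf.codons[p] for p in positions]
        for p, c in zip(positions, rng.permutation(codons_here)):
            out[p] = str(c)
    return tuple(out)


def sample_aorf(
    orf: OrfRecord,
    model: int,
    rng: np.random.Generator,
    usage: CodonUsageTable | None = None,
) -> tuple[str, ...]:
    if model == 0:
        return model0_sample(orf, rng)
    if model == 1:
        if usage is None:
            raise ValueError("model 1 requires a codon usage table")
        return model1_sample(orf, usage, rng)
    if model == 2:
        return model2_sample(orf, rng)
    raise ValueError(f"unknown model {model}; expected 0, 1 or 2")


def compute_codon_usage(records: list[OrfRecord]) -> CodonUsageTable:
    """Pool codon counts over records into a relative-usage table."""
    if not records:
        raise ValueError("cannot compute codon usage from an empty record list")
    counts: dict[str, int] = {}
    for rec in records:
        for codon in rec.codons:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable.from_counts(counts)


def gc_content(sequence) -> float:
    """Fraction of G+C bases in a nucleotide string or codon iterable."""
    if not isinstance(sequence, str):
        sequence = "".join(sequence)
    if not sequence:
        raise ValueError("empty sequence")
    gc = sum(1 for b in sequence if b in "GCgc")
    return gc / len(sequence)
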