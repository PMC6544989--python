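"""Reading, validation and preparation of protein-coding sequences.

Coding sequences arrive as FASTA records (one ORF per record), as GenBank
flat files with CDS features, or as cDNA + peptide pairs from which ORFs are
inferred by translating all forward frames.  Everything downstream operates
on :class:`OrfRecord` objects: an in-frame codon list together with its
translation under the standard genetic code.

Sequences are normalized to the DNA alphabet (U -> T) on input; the folding
engine re-interprets T as U.  Records containing ambiguous bases are
rejected rather than masked, because base-pairing probabilities are
undefined for ambiguity codes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> amino acid for the standard genetic code, stops mapped to '*'
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD_TABLE.stop_codons})

#: amino acid (or '*') -> sorted list of synonymous codons
SYNONYMOUS_FAMILIES: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, []).append(_codon)

AMINO_ACIDS: list[str] = sorted(aa for aa in SYNONYMOUS_FAMILIES if aa != "*")
SENSE_CODONS: list[str] = sorted(_STANDARD_TABLE.forward_table)
STOP_CODONS: list[str] = sorted(_STANDARD_TABLE.stop_codons)

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SequenceError(ValueError):
    """Raised for sequences that violate the coding-sequence contracts."""


@dataclass(frozen=True)
class OrfRecord:
    """A validated in-frame coding sequence.

    Attributes
    ----------
    id:
        Record identifier (FASTA header word or GenBank feature id).
    codons:
        The sequence as an ordered tuple of 3-mers over {A,C,G,T}.
    peptide:
        Translation under the standard genetic code, ``*`` for stop.
    """

    id: str
    codons: tuple[str, ...]
    peptide: str

    @property
    def sequence(self) -> str:
        return "".join(self.codons)

    def __len__(self) -> int:
        return 3 * len(self.codons)


@dataclass(frozen=True)
class OrfRejection:
    """A record that failed ORF validation, with a machine-readable reason."""

    id: str
    reason: str  # one of: alphabet, length, frame, internal_stop
    detail: str = ""


def normalize(sequence: str) -> str:
    """Uppercase a nucleotide string and map U to T.

    Raises :class:`SequenceError` if any character outside {A,C,G,T,U}
    remains after case folding.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _VALID_BASES
    if bad:
        raise SequenceError(f"non-ACGTU characters: {sorted(bad)}")
    return seq


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def translate(codons: Iterable[str]) -> str:
    """Translate a codon list under the standard genetic code ('*' = stop)."""
    out = []
    for codon in codons:
        if len(codon) != 3 or set(codon) - _VALID_BASES:
            raise SequenceError(f"not an unambiguous codon: {codon!r}")
        out.append(CODON_TO_AA[codon])
    return "".join(out)


def read_fasta(path, on_invalid: str = "warn") -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, normalized sequence)`` tuples.

    Records containing characters outside {A,C,G,T,U} are dropped with a
    warning (``on_invalid="warn"``, the default) or raise
    (``on_invalid="raise"``).  An empty file yields an empty list with a
    warning.  A file whose first non-blank line is not a header raises a
    parse error naming the offending line.
    """
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise SequenceError(
                        f"{path}: line {lineno}: expected FASTA header, got {line.strip()[:30]!r}"
                    )
                break
        else:
            warnings.warn(f"{path}: empty FASTA file")
            return []

    out: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append((rec.id, normalize(str(rec.seq))))
        except SequenceError as exc:
            if on_invalid == "raise":
                raise SequenceError(f"record {rec.id}: {exc}") from exc
            warnings.warn(f"record {rec.id} rejected: {exc}")
    return out


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 60) -> None:
    """Write ``(id, sequence)`` records as FASTA, wrapped at `width` columns."""
    with open(path, "w") as handle:
        for rid, seq in records:
            handle.write(f">{rid}\n")
            for start in range(0, len(seq), width):
                handle.write(seq[start : start + width] + "\n")


def validate_orf(
    rid: str, sequence: str, *, allow_internal_stop: bool = False
) -> OrfRecord | OrfRejection:
    """Validate a nucleotide sequence as an in-frame ORF.

    Accepted iff the normalized sequence has length >= 6, a multiple of 3,
    and no internal stop codon.  A terminal stop codon is allowed and
    retained (it is part of the folded sequence and translates to '*').
    With ``allow_internal_stop=True`` internal stops demote to a warning.
    """
    try:
        seq = normalize(sequence)
    except SequenceError as exc:
        return OrfRejection(rid, "alphabet", str(exc))
    if len(seq) < 6:
        return OrfRejection(rid, "length", f"{len(seq)} nt < 6")
    if len(seq) % 3:
        return OrfRejection(rid, "frame", f"{len(seq)} nt not a multiple of 3")
    codons = tuple(seq[i : i + 3] for i in range(0, len(seq), 3))
    peptide = translate(codons)
    if "*" in peptide[:-1]:
        if allow_internal_stop:
            warnings.warn(f"record {rid}: internal stop codon retained")
        else:
            pos = peptide.index("*")
            return OrfRejection(rid, "internal_stop", f"stop at codon {pos}")
    return OrfRecord(rid, codons, peptide)


def select_longest_transcripts(
    records: Sequence[tuple[str, str]], gene_key: Callable[[str], str]
) -> list[tuple[str, str]]:
    """Keep the longest record per gene; ties break to the smaller record id.

    ``gene_key`` maps a record id to its gene id.  Input order of genes is
    preserved by first appearance.
    """
    best: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    for rid, seq in records:
        gene = gene_key(rid)
        if gene not in best:
            best[gene] = (rid, seq)
            order.append(gene)
        else:
            cur_id, cur_seq = best[gene]
            if (len(seq), ) > (len(cur_seq), ) or (len(seq) == len(cur_seq) and rid < cur_id):
                best[gene] = (rid, seq)
    return [best[g] for g in order]


def orfs_from_cdna(
    cdna_records: Sequence[tuple[str, str]],
    peptides: Iterable[str],
    *,
    substring: bool = False,
) -> list[OrfRecord]:
    """Infer nucleotide ORFs from cDNA by frame translation and peptide match.

    Each cDNA is translated in forward frames 0/1/2; the translation of each
    frame is split at stop codons into maximal stop-free segments.  A segment
    that equals a peptide in ``peptides`` exactly (default), or contains one
    as a substring (``substring=True``), yields the corresponding nucleotide
    ORF; a stop codon terminating the segment is retained.  Identical
    nucleotide ORFs are collapsed, order of first appearance preserved.
    """
    pepset = {p for p in peptides if p}
    if not pepset:
        return []
    seen: set[str] = set()
    out: list[OrfRecord] = []

    def emit(rid: str, nt: str) -> None:
        if nt in seen:
            return
        seen.add(nt)
        rec = validate_orf(rid, nt)
        if isinstance(rec, OrfRecord):
            out.append(rec)

    for rid, seq in cdna_records:
        for frame in range(3):
            sub = seq[frame : frame + 3 * ((len(seq) - frame) // 3)]
            if len(sub) < 3:
                continue
            codons = [sub[i : i + 3] for i in range(0, len(sub), 3)]
            aa = translate(codons)
            # walk maximal stop-free segments
            start = 0
            for pos in range(len(aa) + 1):
                if pos == len(aa) or aa[pos] == "*":
                    seg = aa[start:pos]
                    if seg:
                        has_stop = pos < len(aa)
                        if not substring:
                            if seg in pepset:
                                nt = sub[3 * start : 3 * (pos + (1 if has_stop else 0))]
                                emit(f"{rid}|frame{frame}", nt)
                        else:
                            for pep in pepset:
                                off = seg.find(pep)
                                while off != -1:
                                    lo = start + off
                                    hi = lo + len(pep)
                                    keep_stop = has_stop and hi == pos
                                    nt = sub[3 * lo : 3 * (hi + (1 if keep_stop else 0))]
                                    emit(f"{rid}|frame{frame}", nt)
                                    off = seg.find(pep, off + 1)
                    start = pos + 1
    return out


def extract_cds_from_genbank(path) -> list[OrfRecord]:
    """Extract CDS features from a GenBank flat file as validated ORFs.

    Multi-interval (joined) CDS are concatenated; minus-strand features are
    reverse-complemented by the coordinate machinery.  Features that fail
    extraction or ORF validation are skipped with a warning.
    """
    out: list[OrfRecord] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for idx, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            quals = feat.qualifiers
            fid = (
                quals.get("protein_id", quals.get("locus_tag", quals.get("gene", [None])))[0]
                or f"{rec.id}.CDS{idx}"
            )
            try:
                nt = str(feat.extract(rec.seq))
            except Exception as exc:  # malformed coordinates
                warnings.warn(f"{rec.id} CDS {fid}: unparseable feature ({exc}); skipped")
                continue
            orf = validate_orf(fid, nt)
            if isinstance(orf, OrfRecord):
                out.append(orf)
            else:
                warnings.warn(f"{rec.id} CDS {fid}: rejected ({orf.reason}); skipped")
    return out
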