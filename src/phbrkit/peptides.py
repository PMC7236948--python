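"""Mutant protein construction and 8–11-mer peptide window enumeration.

Missense variants are applied at the protein level (replace one residue);
in-frame insertions/deletions are applied at the CDS level and the edited CDS
is re-translated.  Candidate MHC-I ligands are then all peptides of length
8–11 that cover a mutated residue; an interior substitution with at least ten
flanking residues on each side yields exactly 38 such windows
(8 + 9 + 10 + 11).  For indels, candidates are additionally filtered to
peptides absent from the wild-type protein ("novel" peptides).

All coordinates are 1-based and inclusive, both on the CDS and the protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

from Bio.Seq import Seq

from .errors import (
    InvalidInputError,
    InvalidSequenceError,
    ReferenceMismatchError,
    UnsupportedVariantError,
)

DEFAULT_WINDOW_LENGTHS = (8, 9, 10, 11)

_NUCLEOTIDES = frozenset("ACGT")
_STOP = "*"


def translate_cds(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    Translation proceeds codon by codon and stops at (and excludes) the first
    stop codon; with no stop codon every complete codon is translated and any
    trailing partial codon is ignored.

    Raises
    ------
    InvalidSequenceError
        If `cds` is shorter than one codon or contains characters outside
        A/C/G/T (ambiguity codes are rejected rather than guessed).
    """
    if len(cds) < 3:
        raise InvalidSequenceError(f"CDS shorter than one codon: {len(cds)} nt")
    bad = set(cds) - _NUCLEOTIDES
    if bad:
        raise InvalidSequenceError(f"non-ACGT characters in CDS: {sorted(bad)}")
    trimmed = cds[: len(cds) - len(cds) % 3]
    return str(Seq(trimmed).translate(table="Standard", to_stop=True))


@dataclass(frozen=True)
class TranscriptRecord:
    """A transcript coding sequence and its derived protein."""

    transcript_id: str
    cds: str

    def __post_init__(self):
        protein = translate_cds(self.cds)  # validates the CDS as a side effect
        if not protein:
            raise InvalidSequenceError(
                f"{self.transcript_id}: CDS translates to an empty protein"
            )

    @cached_property
    def protein(self) -> str:
        return translate_cds(self.cds)


@dataclass(frozen=True)
class MissenseVariant:
    """Single amino-acid substitution, e.g. A2V on some transcript."""

    transcript_id: str
    protein_position: int  # 1-based
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise InvalidInputError(
                f"{self}: reference and alternate residues are identical"
            )
        if self.protein_position < 1:
            raise InvalidInputError(f"{self}: protein position must be >= 1")

    def __str__(self) -> str:
        return f"{self.transcript_id}:{self.ref_aa}{self.protein_position}{self.alt_aa}"


@dataclass(frozen=True)
class InFrameIndel:
    """In-frame CDS insertion and/or deletion.

    `cds_position` is the first affected base (1-based): deleted bases start
    there, inserted bases are placed immediately before it.  A pure insertion
    "after base k" therefore has cds_position k+1.
    """

    transcript_id: str
    cds_position: int
    deleted_bases: str = ""
    inserted_bases: str = ""

    def __post_init__(self):
        if not self.deleted_bases and not self.inserted_bases:
            raise InvalidInputError(f"{self}: indel with nothing inserted or deleted")
        if (len(self.inserted_bases) - len(self.deleted_bases)) % 3 != 0:
            raise UnsupportedVariantError(
                f"{self}: net length change not a multiple of 3 (frameshift)"
            )
        if self.cds_position < 1:
            raise InvalidInputError(f"{self}: CDS position must be >= 1")

    def __str__(self) -> str:
        return (
            f"{self.transcript_id}:c.{self.cds_position}"
            f"del{self.deleted_bases or '-'}ins{self.inserted_bases or '-'}"
        )


@dataclass(frozen=True)
class MutantPeptideSet:
    """The candidate peptide windows for one variant.

    Each element of `peptides` is ``(sequence, start)`` with `start` the
    1-based position of the window in the *mutant* protein.  The same sequence
    may legitimately recur at different starts; scoring deduplicates by
    sequence.
    """

    variant: object
    peptides: tuple[tuple[str, int], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def sequences(self) -> tuple[str, ...]:
        """Unique peptide sequences, in order of first occurrence."""
        return tuple(dict.fromkeys(seq for seq, _ in self.peptides))


def apply_missense(transcript: TranscriptRecord, variant: MissenseVariant) -> str:
    """Return the mutant protein for a single-residue substitution."""
    protein = transcript.protein
    pos = variant.protein_position
    if pos > len(protein):
        raise InvalidInputError(
            f"{variant}: position {pos} beyond protein length {len(protein)}"
        )
    if protein[pos - 1] != variant.ref_aa:
        raise ReferenceMismatchError(
            f"{variant}: transcript has {protein[pos - 1]} at position {pos}, "
            f"variant states {variant.ref_aa}"
        )
    return protein[: pos - 1] + variant.alt_aa + protein[pos:]


def apply_cds_indel(transcript: TranscriptRecord, variant: InFrameIndel) -> str:
    """Edit the CDS by an in-frame indel and return the re-translated protein."""
    cds = transcript.cds
    pos, deleted = variant.cds_position, variant.deleted_bases
    if pos + len(deleted) - 1 > len(cds):
        raise InvalidInputError(f"{variant}: edit extends beyond CDS end {len(cds)}")
    if cds[pos - 1 : pos - 1 + len(deleted)] != deleted:
        raise ReferenceMismatchError(
            f"{variant}: CDS has {cds[pos - 1:pos - 1 + len(deleted)]!r} at "
            f"{pos}, variant states deletion of {deleted!r}"
        )
    edited = cds[: pos - 1] + variant.inserted_bases + cds[pos - 1 + len(deleted) :]
    return translate_cds(edited)


def mutated_protein_positions(transcript: TranscriptRecord, variant) -> set[int]:
    """Protein positions touched by a variant, for window enumeration.

    For a missense variant this is the substituted residue.  For an in-frame
    indel it is every residue of the mutant protein whose codon overlaps the
    edited CDS interval (insertions of k codons mark k+1 positions when they
    split a codon).
    """
    if isinstance(variant, MissenseVariant):
        return {variant.protein_position}
    if isinstance(variant, InFrameIndel):
        first_codon = (variant.cds_position - 1) // 3 + 1
        n_ins = len(variant.inserted_bases)
        n_del = len(variant.deleted_bases)
        # Last affected base in mutant coordinates.
        last_base = variant.cds_position - 1 + n_ins + (1 if n_del and not n_ins else 0)
        last_codon = max(first_codon, (max(last_base, 1) - 1) // 3 + 1)
        mutant_len = (len(transcript.cds) + n_ins - n_del) // 3
        return {p for p in range(first_codon, last_codon + 1) if p <= mutant_len}
    raise UnsupportedVariantError(f"unsupported variant type {type(variant).__name__}")


def enumerate_mutant_windows(
    mutant_protein: str,
    mutated_positions: set[int],
    lengths: tuple[int, ...] = DEFAULT_WINDOW_LENGTHS,
    variant: object = None,
) -> MutantPeptideSet:
    """All windows of the requested lengths that cover a mutated position.

    Windows must lie fully inside the protein; no padding is fabricated near
    the termini, so terminal mutations yield fewer than the interior count of
    38 (for lengths 8–11).
    """
    if not mutant_protein:
        raise InvalidInputError("empty mutant protein")
    if not mutated_positions:
        raise InvalidInputError("no mutated positions given")
    n = len(mutant_protein)
    for p in mutated_positions:
        if not 1 <= p <= n:
            raise InvalidInputError(f"mutated position {p} outside protein of length {n}")
    windows: list[tuple[str, int]] = []
    for length in lengths:
        for start in range(1, n - length + 2):
            end = start + length - 1
            if any(start <= p <= end for p in mutated_positions):
                windows.append((mutant_protein[start - 1 : end], start))
    # dedupe by (sequence, start); different lengths never collide
    unique = tuple(dict.fromkeys(windows))
    return MutantPeptideSet(variant=variant, peptides=unique)


def novel_peptides(
    candidate: MutantPeptideSet, wildtype_protein: str
) -> MutantPeptideSet:
    """Subset of candidate windows absent from the wild-type protein.

    Used for indel-derived peptides: a window identical to some wild-type
    substring (even elsewhere in the protein) is self and is dropped.
    Missense windows are retained upstream without this filter, since they
    always contain the substituted residue.
    """
    kept = tuple(
        (seq, start) for seq, start in candidate.peptides if seq not in wildtype_protein
    )
    return MutantPeptideSet(variant=candidate.variant, peptides=kept)


def peptides_for_variant(
    transcript: TranscriptRecord,
    variant,
    lengths: tuple[int, ...] = DEFAULT_WINDOW_LENGTHS,
) -> MutantPeptideSet:
    """End-to-end candidate peptides for one variant on one transcript.

    Missense: apply the substitution and take all covering windows.
    In-frame indel: edit the CDS, re-translate, take windows over the edited
    region, then keep only peptides novel with respect to the wild type.
    """
    if isinstance(variant, MissenseVariant):
        mutant = apply_missense(transcript, variant)
        return enumerate_mutant_windows(
            mutant, {variant.protein_position}, lengths, variant=variant
        )
    if isinstance(variant, InFrameIndel):
        mutant = apply_cds_indel(transcript, variant)
        positions = {
            p for p in mutated_protein_positions(transcript, variant) if p <= len(mutant)
        }
        if not positions:
            return MutantPeptideSet(variant=variant, peptides=())
        windows = enumerate_mutant_windows(mutant, positions, lengths, variant=variant)
        return novel_peptides(windows, transcript.protein)
    raise UnsupportedVariantError(
        f"variant class {type(variant).__name__} is not scored (missense and "
        "in-frame indels only)"
    )
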