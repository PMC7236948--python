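"""PHBR scoring: per-allele best rank and harmonic-mean aggregation.

A rank oracle maps (HLA allele, peptide) to a binding-rank percentile in
(0, 100]; NetMHCpan-style predictors stand behind this contract, here it is
pluggable (a precomputed rank table or a deterministic synthetic oracle).
For each mutation, every allele of the six-slot class-I genotype is assigned
its best (minimum) rank over the candidate peptides, and the six best ranks
are aggregated by a harmonic mean into the PHBR score.  Low PHBR means at
least most alleles present some mutant peptide well; a patient's min-PHBR
across mutations is the score of their best-presented mutation.

Conventional rank thresholds: < 2 weak binder, < 0.5 strong binder.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass
from typing import Protocol, Sequence

import pandas as pd

from .errors import (
    ArityError,
    DomainError,
    EmptyInputError,
    InvalidInputError,
    MissingPredictionError,
    PatientNotEvaluableError,
    TableParseError,
)
from .peptides import MutantPeptideSet

WEAK_BINDER_RANK = 2.0
STRONG_BINDER_RANK = 0.5
#: floor applied to oracle ranks before reciprocals, guarding against
#: pathological tables with ranks of exactly 0
RANK_FLOOR = 1e-6

_ALLELE_RE = re.compile(r"^([ABC])\*(\d{1,3}):(\d{2,3})$")


@dataclass(frozen=True, order=True)
class HlaAllele:
    """Four-digit class-I allele, e.g. ``A*02:01``."""

    name: str

    def __post_init__(self):
        if not _ALLELE_RE.match(self.name):
            raise InvalidInputError(
                f"{self.name!r} does not parse as a 4-digit class-I allele "
                "(expected e.g. A*02:01 with locus A, B or C)"
            )

    @property
    def locus(self) -> str:
        return self.name[0]


@dataclass(frozen=True)
class HlaGenotype:
    """Six ordered allele slots: A×2, B×2, C×2; homozygous loci repeat."""

    slots: tuple[HlaAllele, ...]

    def __post_init__(self):
        if len(self.slots) != 6:
            raise ArityError(f"genotype needs exactly 6 allele slots, got {len(self.slots)}")
        counts = {"A": 0, "B": 0, "C": 0}
        for allele in self.slots:
            counts[allele.locus] += 1
        if counts != {"A": 2, "B": 2, "C": 2}:
            raise ArityError(f"genotype needs two alleles per locus, got {counts}")

    @classmethod
    def from_names(cls, names: Sequence[str]) -> "HlaGenotype":
        return cls(tuple(HlaAllele(n) for n in names))

    def is_homozygous(self, locus: str) -> bool:
        pair = [a for a in self.slots if a.locus == locus]
        return pair[0] == pair[1]


class RankOracle(Protocol):
    """Contract for binding-rank predictors: percentile rank in (0, 100]."""

    def rank(self, allele: HlaAllele, peptide: str) -> float: ...


@dataclass(frozen=True)
class PhbrScore:
    """Harmonic mean of the six per-allele best ranks for one mutation."""

    value: float
    per_allele_best_ranks: tuple[float, ...]
    variant: object = None

    def __post_init__(self):
        lo, hi = min(self.per_allele_best_ranks), max(self.per_allele_best_ranks)
        if not (lo - 1e-12 <= self.value <= hi + 1e-12):
            raise DomainError("PHBR outside [min, max] of its best ranks")


def best_rank(oracle: RankOracle, allele: HlaAllele, peptides: MutantPeptideSet) -> float:
    """Minimum oracle rank over the unique peptide sequences of one mutation.

    Identical sequences arising at different starts are scored once.  Ranks
    are floored at RANK_FLOOR.
    """
    sequences = peptides.sequences
    if not sequences:
        raise EmptyInputError("cannot take a best rank over an empty peptide set")
    return max(min(oracle.rank(allele, seq) for seq in sequences), RANK_FLOOR)


def phbr(best_ranks: Sequence[float]) -> float:
    """Harmonic mean of exactly six positive best ranks: 6 / Σ(1/BRᵢ)."""
    if len(best_ranks) != 6:
        raise ArityError(f"PHBR aggregates exactly 6 best ranks, got {len(best_ranks)}")
    if any(r <= 0 for r in best_ranks):
        raise DomainError("best ranks must be strictly positive")
    return 6.0 / sum(1.0 / r for r in best_ranks)


def mutation_phbr(
    oracle: RankOracle, genotype: HlaGenotype, peptides: MutantPeptideSet
) -> PhbrScore:
    """PHBR of one mutation for one patient.

    Homozygous loci occupy two slots, so their allele's best rank enters the
    harmonic mean twice — a fully homozygous patient's PHBR equals the
    three-distinct-allele harmonic mean.
    """
    ranks = tuple(best_rank(oracle, allele, peptides) for allele in genotype.slots)
    return PhbrScore(value=phbr(ranks), per_allele_best_ranks=ranks,
                     variant=peptides.variant)


def patient_min_phbr(scores: Sequence[PhbrScore]) -> PhbrScore:
    """The minimum-PHBR mutation of a patient; ties keep the first in input order.

    Patients with no scored mutation are not evaluable (they are excluded
    from the cohort upstream, mirroring the exclusion of patients without an
    identified missense alteration).
    """
    if not scores:
        raise PatientNotEvaluableError("patient has no scored mutation")
    return min(scores, key=lambda s: s.value)


class SyntheticRankOracle:
    """Deterministic stand-in for a binding-rank predictor.

    The rank of (allele, peptide) is a pure hash function of
    (seed, allele, peptide): a configured fraction of peptides fall in the
    strong-binder band (RANK_FLOOR, 0.5) and the rest in [0.5, 100].
    Optional per-allele multiplicative effects shift ranks before clamping
    to (0, 100].
    """

    def __init__(
        self,
        seed: int,
        strong_binder_fraction: float = 0.02,
        allele_effects: dict[str, float] | None = None,
    ):
        if not 0.0 <= strong_binder_fraction <= 1.0:
            raise DomainError("strong_binder_fraction must be in [0, 1]")
        self.seed = int(seed)
        self.strong_binder_fraction = float(strong_binder_fraction)
        self.allele_effects = dict(allele_effects or {})

    def _uniforms(self, allele: HlaAllele, peptide: str) -> tuple[float, float]:
        key = f"{self.seed}|{allele.name}|{peptide}".encode()
        digest = hashlib.blake2b(key, digest_size=16).digest()
        u1 = int.from_bytes(digest[:8], "big") / 2**64
        u2 = int.from_bytes(digest[8:], "big") / 2**64
        return u1, u2

    def rank(self, allele: HlaAllele, peptide: str) -> float:
        u1, u2 = self._uniforms(allele, peptide)
        if u1 < self.strong_binder_fraction:
            value = RANK_FLOOR + u2 * (STRONG_BINDER_RANK - RANK_FLOOR)
        else:
            value = STRONG_BINDER_RANK + u2 * (100.0 - STRONG_BINDER_RANK)
        effect = self.allele_effects.get(allele.name, 1.0)
        return min(max(value * effect, RANK_FLOOR), 100.0)


class TableRankOracle:
    """Oracle backed by a precomputed (allele, peptide) → rank table."""

    def __init__(self, table: dict[tuple[str, str], float]):
        self._table = table

    def rank(self, allele: HlaAllele, peptide: str) -> float:
        try:
            return self._table[(allele.name, peptide)]
        except KeyError:
            raise MissingPredictionError(
                f"no rank prediction for ({allele.name}, {peptide})"
            ) from None

    def __len__(self) -> int:
        return len(self._table)


def load_rank_table(path) -> TableRankOracle:
    """Read a tab-separated allele / peptide / rank_percentile table.

    '#'-prefixed comment lines are ignored.  Duplicate (allele, peptide)
    pairs with differing ranks are ambiguous and rejected; exact duplicate
    rows are tolerated.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TableParseError(f"cannot read rank table {path}: {exc}") from exc
    required = {"allele", "peptide", "rank_percentile"}
    if not required.issubset(df.columns):
        raise TableParseError(
            f"rank table missing columns {sorted(required - set(df.columns))}"
        )
    table: dict[tuple[str, str], float] = {}
    for row in df.itertuples():
        line_no = row.Index + 2  # header occupies line 1
        try:
            rank = float(row.rank_percentile)
        except (TypeError, ValueError):
            raise TableParseError(
                f"rank_percentile {row.rank_percentile!r} is not numeric",
                line=line_no,
            ) from None
        if not rank > 0:
            raise TableParseError("rank percentile must be > 0", line=line_no)
        key = (row.allele, row.peptide)
        if key in table and table[key] != rank:
            raise TableParseError(
                f"conflicting duplicate entry for {key}", line=line_no
            )
        table[key] = rank
    return TableRankOracle(table)
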