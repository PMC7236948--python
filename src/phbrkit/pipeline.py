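"""End-to-end cohort scoring: variants → peptides → PHBR → patient records."""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .errors import PatientNotEvaluableError
from .peptides import TranscriptRecord, peptides_for_variant
from .scoring import HlaGenotype, RankOracle, mutation_phbr, patient_min_phbr


def score_mutations(
    transcripts: Mapping[str, TranscriptRecord],
    patient_variants: Mapping[str, Iterable],
    genotypes: Mapping[str, HlaGenotype],
    oracle: RankOracle,
) -> pd.DataFrame:
    """PHBR of every scored mutation of every patient.

    Returns one row per (patient, variant) with the PHBR value, the six
    per-allele best ranks, and a flag on each patient's minimum-PHBR mutation
    (ties keep the first in input order).
    """
    rows = []
    for patient_id, variants in patient_variants.items():
        genotype = genotypes[patient_id]
        scores = []
        for variant in variants:
            pset = peptides_for_variant(transcripts[variant.transcript_id], variant)
            if not pset.peptides:
                continue  # indel whose windows are all self peptides
            scores.append(mutation_phbr(oracle, genotype, pset))
        if not scores:
            continue
        selected = patient_min_phbr(scores)
        for score in scores:
            br = score.per_allele_best_ranks
            rows.append(
                {
                    "patient_id": patient_id,
                    "variant": str(score.variant),
                    "phbr": score.value,
                    "best_rank_A1": br[0],
                    "best_rank_A2": br[1],
                    "best_rank_B1": br[2],
                    "best_rank_B2": br[3],
                    "best_rank_C1": br[4],
                    "best_rank_C2": br[5],
                    "selected": score is selected,
                }
            )
    return pd.DataFrame(rows)


def min_phbr_per_patient(scored: pd.DataFrame) -> pd.Series:
    """patient_id → min-PHBR from a score_mutations() table."""
    if scored.empty:
        raise PatientNotEvaluableError("no scored mutations in the cohort")
    return scored[scored["selected"]].set_index("patient_id")["phbr"]


def attach_min_phbr(clinical: pd.DataFrame, scored: pd.DataFrame) -> pd.DataFrame:
    """Clinical table with a `min_phbr` column; unscored patients are dropped.

    Mirrors the cohort rule that patients without an identified missense
    alteration are excluded.
    """
    min_phbr = min_phbr_per_patient(scored)
    out = clinical.merge(
        min_phbr.rename("min_phbr"), left_on="patient_id", right_index=True, how="inner"
    )
    return out.reset_index(drop=True)
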