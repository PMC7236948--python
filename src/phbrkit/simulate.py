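"""Synthetic checkpoint-blockade cohort generator with ground truth.

Generates every input the pipeline consumes — transcript CDS pool, variant
table, HLA genotypes, a rank table, and a clinical outcome table — with the
statistical structure the analysis assumes: long-tailed (log-normal) TMB with
occasional missingness, Poisson mutation counts proportional to TMB times the
panel footprint, a configurable fraction of patients whose best-presented
mutation scores PHBR < 0.5, stratum-dependent benefit probabilities, and
stratum-dependent exponential survival with uniform administrative censoring.

Presentation is controlled by a latent per-patient class: with probability
`phbr_low_prevalence` a patient is a "presenter" and one of their mutations
receives strong best ranks (uniform on 0.1–0.45) on all six allele slots,
giving PHBR < 0.5; all other allele/mutation best ranks are ≥ 0.6, so
non-presenters have min-PHBR ≥ 0.6.  The latent class is recorded as ground
truth for recovery tests.

Default parameters mirror the headline cohort shape: n = 83 patients,
PHBR-low prevalence 32/83, TMB missing for 6/83, log-normal TMB calibrated so
roughly half of evaluable patients have ≥ 10 mutations/Mb and ~15% have
≥ 50, stratum benefit probabilities (0.18, 0.33, 0.43, 0.78) and stratum
median PFS/OS of the four TMB × PHBR groups.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import DEFAULT_PANEL_MB, assign_stratum, dichotomize_tmb
from .errors import ConfigError
from .peptides import TranscriptRecord, MissenseVariant, peptides_for_variant
from .scoring import HlaAllele, HlaGenotype

_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOP_CODONS = {"TAA", "TAG", "TGA"}

#: stratum labels in a fixed reporting order
STRATA = (
    "TMB-low/PHBR-low",
    "TMB-low/PHBR-high",
    "TMB-high/PHBR-high",
    "TMB-high/PHBR-low",
)

_DEFAULT_POOL = {
    "A": [("A*01:01", 0.30), ("A*02:01", 0.40), ("A*03:01", 0.15), ("A*24:02", 0.15)],
    "B": [("B*07:02", 0.30), ("B*08:01", 0.25), ("B*35:01", 0.20), ("B*44:02", 0.25)],
    "C": [("C*04:01", 0.25), ("C*05:01", 0.20), ("C*07:01", 0.30), ("C*07:02", 0.25)],
}


@dataclass
class CohortConfig:
    """All knobs of the generator; defaults are the study-shaped conditions."""

    n_patients: int = 83
    seed: int = 0
    hla_allele_pool: dict = field(default_factory=lambda: {k: list(v) for k, v in _DEFAULT_POOL.items()})
    homozygosity_rate: float = 0.1  # per locus
    tmb_log_median: float = math.log(10.2)
    tmb_log_sigma: float = 1.6
    tmb_missing_rate: float = 6 / 83
    panel_mb: float = DEFAULT_PANEL_MB
    max_scored_mutations: int = 8
    phbr_low_prevalence: float = 32 / 83
    strong_rank_range: tuple[float, float] = (0.10, 0.45)
    weak_rank_range: tuple[float, float] = (0.60, 80.0)
    benefit_probs: dict = field(
        default_factory=lambda: {
            "TMB-low/PHBR-low": 0.18,
            "TMB-low/PHBR-high": 0.33,
            "TMB-high/PHBR-high": 0.43,
            "TMB-high/PHBR-low": 0.78,
        }
    )
    pfs_median_months: dict = field(
        default_factory=lambda: {
            "TMB-low/PHBR-low": 4.2,
            "TMB-low/PHBR-high": 3.5,
            "TMB-high/PHBR-high": 5.8,
            "TMB-high/PHBR-low": 26.8,
        }
    )
    os_median_months: dict = field(
        default_factory=lambda: {
            "TMB-low/PHBR-low": 12.0,
            "TMB-low/PHBR-high": 10.1,
            "TMB-high/PHBR-high": 17.2,
            "TMB-high/PHBR-low": 40.0,
        }
    )
    censor_window_months: tuple[float, float] = (12.0, 36.0)
    tmb_threshold: float = 10.0
    phbr_threshold: float = 0.5
    n_transcripts: int = 60
    transcript_codons: int = 120  # protein length per synthetic transcript
    tumor_types: tuple[str, ...] = ("NSCLC", "cutaneous SCC", "head and neck SCC", "other")
    tumor_type_probs: tuple[float, ...] = (26 / 83, 10 / 83, 9 / 83, 38 / 83)

    def validate(self) -> None:
        for locus, pool in self.hla_allele_pool.items():
            total = sum(f for _, f in pool)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigError(f"allele frequencies for locus {locus} sum to {total}")
        for name, probs in (("benefit_probs", self.benefit_probs),):
            for stratum, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{stratum}] = {p} outside [0, 1]")
        for medians in (self.pfs_median_months, self.os_median_months):
            for stratum, m in medians.items():
                if m <= 0:
                    raise ConfigError(f"median for {stratum} must be positive")
        if not 0.0 <= self.phbr_low_prevalence <= 1.0:
            raise ConfigError("phbr_low_prevalence must be in [0, 1]")
        missing = set(STRATA) - set(self.benefit_probs)
        if missing:
            raise ConfigError(f"benefit_probs lacks strata {sorted(missing)}")


@dataclass
class GroundTruth:
    """Latent state of an emitted cohort, for recovery tests."""

    latent_phbr_class: dict  # patient_id -> "low"/"high"
    tmb_class: dict  # patient_id -> "low"/"high" at config.tmb_threshold
    stratum: dict  # patient_id -> joint label
    benefit_probs: dict
    pfs_median_months: dict
    os_median_months: dict
    n_candidates_drawn: int = 0
    n_excluded_no_missense: int = 0


@dataclass
class SyntheticCohort:
    """In-memory result of one generator run."""

    config: CohortConfig
    transcripts: dict  # transcript_id -> TranscriptRecord
    genotypes: dict  # patient_id -> HlaGenotype
    variants: pd.DataFrame
    clinical: pd.DataFrame
    rank_table: pd.DataFrame
    ground_truth: GroundTruth


def _patient_rng(config: CohortConfig, index: int) -> np.random.Generator:
    # deterministic per-patient sub-stream: reproducible under parallel scoring
    return np.random.default_rng([config.seed, index])


def make_transcript_pool(config: CohortConfig, rng: np.random.Generator) -> dict:
    """Random CDS pool standing in for a targeted gene panel."""
    codon_pool = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
    ]
    transcripts = {}
    for i in range(config.n_transcripts):
        body = rng.choice(codon_pool, size=config.transcript_codons - 1)
        cds = "ATG" + "".join(body) + "TAA"
        tid = f"TX{i:04d}"
        transcripts[tid] = TranscriptRecord(transcript_id=tid, cds=cds)
    return transcripts


def sample_genotype(config: CohortConfig, rng: np.random.Generator) -> HlaGenotype:
    """Two draws per locus from the pool; homozygosity copies the first draw."""
    slots = []
    for locus in "ABC":
        names = [n for n, _ in config.hla_allele_pool[locus]]
        freqs = [f for _, f in config.hla_allele_pool[locus]]
        first = rng.choice(names, p=freqs)
        if rng.random() < config.homozygosity_rate:
            second = first
        else:
            second = rng.choice(names, p=freqs)
        slots.extend([HlaAllele(str(first)), HlaAllele(str(second))])
    return HlaGenotype(tuple(slots))


def sample_tmb(config: CohortConfig, rng: np.random.Generator) -> Optional[float]:
    """Long-tailed TMB (log-normal); missing with the configured rate."""
    if rng.random() < config.tmb_missing_rate:
        return None
    return float(rng.lognormal(mean=config.tmb_log_median, sigma=config.tmb_log_sigma))


def sample_patient_variants(
    config: CohortConfig,
    rng: np.random.Generator,
    transcripts: dict,
    patient_id: str,
    tmb: Optional[float],
) -> tuple[int, list[MissenseVariant]]:
    """Panel mutation count and the scored missense subset for one patient.

    The count drives TMB (count / panel footprint); only the first
    `max_scored_mutations` become variant-table rows, since PHBR selection
    needs each patient's best-presented mutation, not the full catalogue.
    An empty list marks a patient to be excluded (no missense alteration).
    """
    latent_rate = (tmb if tmb is not None else 0.0) * config.panel_mb
    count = int(rng.poisson(latent_rate))
    n_scored = min(count, config.max_scored_mutations)
    tids = list(transcripts)
    variants: list[MissenseVariant] = []
    seen: set[tuple[str, int]] = set()
    while len(variants) < n_scored:
        tid = tids[int(rng.integers(len(tids)))]
        protein = transcripts[tid].protein
        # interior positions only: every mutation then has the full 38 windows
        pos = int(rng.integers(11, len(protein) - 9))
        if (tid, pos) in seen:
            continue
        seen.add((tid, pos))
        ref = protein[pos - 1]
        alt = rng.choice([a for a in _AMINO_ACIDS if a != ref])
        variants.append(
            MissenseVariant(
                transcript_id=tid, protein_position=pos, ref_aa=ref, alt_aa=str(alt)
            )
        )
    return count, variants


def _build_rank_rows(
    config: CohortConfig,
    rng: np.random.Generator,
    transcripts: dict,
    genotype: HlaGenotype,
    variants: list[MissenseVariant],
    strong_variant_index: Optional[int],
    rank_assignments: dict,
) -> None:
    """Assign ranks for every (allele, peptide) a patient's scoring will query.

    The designated strong variant (presenters only) gets an all-slot best
    rank in the strong range; everything else stays in the weak range, so the
    patient-level PHBR dichotomy follows the latent class.  Assignments are
    global so the emitted table stays conflict-free across patients.
    """
    lo_s, hi_s = config.strong_rank_range
    lo_w, hi_w = config.weak_rank_range
    for v_idx, variant in enumerate(variants):
        pset = peptides_for_variant(transcripts[variant.transcript_id], variant)
        sequences = list(pset.sequences)
        strong = v_idx == strong_variant_index
        for allele in dict.fromkeys(genotype.slots):  # unique alleles
            target = rng.uniform(lo_s, hi_s) if strong else rng.uniform(lo_w, hi_w)
            best_idx = int(rng.integers(len(sequences)))
            for p_idx, seq in enumerate(sequences):
                key = (allele.name, seq)
                rank = target if p_idx == best_idx else min(
                    target + rng.uniform(0.5, 60.0), 100.0
                )
                if strong and p_idx == best_idx:
                    rank_assignments[key] = rank  # guarantee the strong best rank
                else:
                    rank_assignments.setdefault(key, rank)


def sample_outcomes(
    stratum: str, config: CohortConfig, rng: np.random.Generator
) -> dict:
    """Response category and censored PFS/OS for one patient of a stratum.

    Benefit is Bernoulli with the stratum's probability; PFS and OS are
    exponential with the stratum's median; administrative censoring is
    uniform over the configured window.  Benefit and survival are coupled
    through the stratum only.
    """
    if stratum not in config.benefit_probs:
        raise ConfigError(f"unknown stratum {stratum!r}")
    benefit = rng.random() < config.benefit_probs[stratum]
    if benefit:
        response = str(rng.choice(["CR", "PR", "SD>=6mo"], p=[0.1, 0.5, 0.4]))
    else:
        response = str(rng.choice(["PD", "SD<6mo"], p=[0.8, 0.2]))
    lo, hi = config.censor_window_months
    censor = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    pfs_latent = float(rng.exponential(config.pfs_median_months[stratum] / math.log(2)))
    os_latent = float(rng.exponential(config.os_median_months[stratum] / math.log(2)))
    return {
        "response": response,
        "pfs_months": min(pfs_latent, censor),
        "pfs_event": pfs_latent <= censor,
        "os_months": min(os_latent, censor),
        "os_event": os_latent <= censor,
        "followup_months": censor,
    }


def generate_cohort(config: CohortConfig, outdir=None) -> SyntheticCohort:
    """Draw a full cohort; deterministic per seed.

    Candidate patients without any missense mutation are excluded and
    redrawn (mirroring the cohort's exclusion rule) until `n_patients`
    retained patients exist; the exclusion count is kept in the ground truth.
    When `outdir` is given, all interchange files are written there.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    transcripts = make_transcript_pool(config, rng)

    genotypes: dict[str, HlaGenotype] = {}
    variant_rows: list[dict] = []
    clinical_rows: list[dict] = []
    rank_assignments: dict[tuple[str, str], float] = {}
    latent_phbr: dict[str, str] = {}
    tmb_class: dict[str, str] = {}
    stratum_of: dict[str, str] = {}

    retained = 0
    drawn = 0
    excluded = 0
    while retained < config.n_patients:
        prng = _patient_rng(config, drawn)
        drawn += 1
        tmb = sample_tmb(config, prng)
        pid = f"P{retained + 1:03d}"
        count, variants = sample_patient_variants(config, prng, transcripts, pid, tmb)
        if not variants:
            excluded += 1
            continue
        genotype = sample_genotype(config, prng)
        is_presenter = prng.random() < config.phbr_low_prevalence
        strong_idx = int(prng.integers(len(variants))) if is_presenter else None
        _build_rank_rows(
            config, prng, transcripts, genotype, variants, strong_idx, rank_assignments
        )
        tmb_value = count / config.panel_mb if tmb is not None else None
        t_class = dichotomize_tmb(tmb_value, config.tmb_threshold)
        p_class = "low" if is_presenter else "high"
        stratum = assign_stratum(t_class, p_class).joint
        outcome = sample_outcomes(stratum, config, prng)

        genotypes[pid] = genotype
        latent_phbr[pid] = p_class
        tmb_class[pid] = t_class
        stratum_of[pid] = stratum
        for variant in variants:
            variant_rows.append(
                {
                    "patient_id": pid,
                    "gene": f"GENE_{variant.transcript_id}",
                    "transcript_id": variant.transcript_id,
                    "variant_class": "missense",
                    "protein_change": f"{variant.ref_aa}{variant.protein_position}{variant.alt_aa}",
                    "cds_effect": "",
                }
            )
        clinical_rows.append(
            {
                "patient_id": pid,
                "tumor_type": str(
                    prng.choice(config.tumor_types, p=config.tumor_type_probs)
                ),
                "sex": str(prng.choice(["male", "female"], p=[46 / 83, 37 / 83])),
                "ethnicity": str(prng.choice(["caucasian", "other"], p=[71 / 83, 12 / 83])),
                "age_at_treatment": float(np.clip(prng.normal(64, 11), 25, 92)),
                "therapy": str(prng.choice(["monotherapy", "combination"], p=[66 / 83, 17 / 83])),
                "tmb": None if tmb_value is None else round(tmb_value, 4),
                **outcome,
            }
        )
        retained += 1

    rank_table = pd.DataFrame(
        [
            {"allele": allele, "peptide": peptide, "rank_percentile": round(rank, 6)}
            for (allele, peptide), rank in sorted(rank_assignments.items())
        ]
    )
    cohort = SyntheticCohort(
        config=config,
        transcripts=transcripts,
        genotypes=genotypes,
        variants=pd.DataFrame(variant_rows),
        clinical=pd.DataFrame(clinical_rows),
        rank_table=rank_table,
        ground_truth=GroundTruth(
            latent_phbr_class=latent_phbr,
            tmb_class=tmb_class,
            stratum=stratum_of,
            benefit_probs=dict(config.benefit_probs),
            pfs_median_months=dict(config.pfs_median_months),
            os_median_months=dict(config.os_median_months),
            n_candidates_drawn=drawn,
            n_excluded_no_missense=excluded,
        ),
    )
    if outdir is not None:
        from . import io as _io

        _io.write_cohort(cohort, outdir)
    return cohort


def simulate_stratified_survival(
    n: int,
    hazard_ratio: float,
    rng: np.random.Generator,
    baseline_medians: tuple[float, float] = (4.0, 12.0),
    covariate_prevalence: float = 0.45,
    censor_window: tuple[float, float] = (12.0, 36.0),
) -> pd.DataFrame:
    """Two-stratum survival data with a known within-stratum covariate effect.

    Each subject gets a stratum (two baseline hazards, e.g. TMB low/high) and
    a binary covariate (e.g. PHBR-low) whose hazard is multiplied by
    `hazard_ratio` within either stratum.  Used by the recovery tests: a
    stratified Cox fit should cover log(hazard_ratio).
    """
    stratum = rng.integers(0, 2, size=n)
    covariate = (rng.random(n) < covariate_prevalence).astype(int)
    base = np.where(stratum == 0, baseline_medians[0], baseline_medians[1]) / math.log(2)
    scale = base / np.where(covariate == 1, hazard_ratio, 1.0)
    latent = rng.exponential(scale)
    censor = rng.uniform(*censor_window, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(latent, censor),
            "event": (latent <= censor).astype(int),
            "covariate": covariate,
            "stratum": stratum,
        }
    )
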