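"""Per-patient record assembly: TMB, dichotomizations, strata, benefit labels.

TMB from a targeted panel is the somatic mutation count over the interrogated
footprint (1.2 Mb by default) expressed as mutations per megabase.  TMB and
min-PHBR are each dichotomized (TMB high means ≥ threshold, with 10/20/50 the
conventional cutoffs and missing TMB assigned low; PHBR low means < 0.5,
i.e. strong presentation) and crossed into four strata.  Clinical benefit is
complete/partial response or stable disease lasting ≥ 6 months; a patient
with ongoing stable disease but under 6 months of follow-up is not evaluable
and leaves the benefit-rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .errors import DomainError, InvalidInputError

DEFAULT_PANEL_MB = 1.2
DEFAULT_TMB_PSEUDOCOUNT = 0.001
DEFAULT_TMB_THRESHOLD = 10.0
DEFAULT_PHBR_THRESHOLD = 0.5
TMB_THRESHOLDS = (10.0, 20.0, 50.0)

#: response categories, best to worst
RESPONSE_CATEGORIES = ("CR", "PR", "SD>=6mo", "SD<6mo-ongoing", "SD<6mo", "PD")

BENEFIT = "benefit"
NO_BENEFIT = "no_benefit"
NOT_EVALUABLE = "not_evaluable"


def tmb_from_panel(
    mutation_count: int, interrogated_mb: float = DEFAULT_PANEL_MB
) -> float:
    """Mutations per megabase from a panel count.

    The count must already exclude known/likely oncogenic drivers and
    germline polymorphisms; this function only forms the density that is
    extrapolated to the whole exome.
    """
    if interrogated_mb <= 0:
        raise DomainError(f"interrogated footprint must be positive, got {interrogated_mb}")
    if mutation_count < 0:
        raise DomainError("mutation count cannot be negative")
    return mutation_count / interrogated_mb


def add_pseudocount(
    tmb: Optional[float], pseudocount: float = DEFAULT_TMB_PSEUDOCOUNT
) -> Optional[float]:
    """TMB + pseudocount for log-scale/correlation analyses.

    Missing TMB stays missing — the pseudocount never imputes.  Threshold
    dichotomization uses the raw TMB, never the pseudocounted one.
    """
    return None if tmb is None else tmb + pseudocount


def dichotomize_tmb(tmb: Optional[float], threshold: float = DEFAULT_TMB_THRESHOLD) -> str:
    """'high' iff TMB is present and ≥ threshold; missing TMB is 'low'."""
    if threshold <= 0:
        raise DomainError("TMB threshold must be positive")
    return "high" if tmb is not None and tmb >= threshold else "low"


def dichotomize_phbr(min_phbr: float, threshold: float = DEFAULT_PHBR_THRESHOLD) -> str:
    """'low' (strong presentation) iff min-PHBR < threshold; ≥ is 'high'."""
    if min_phbr <= 0:
        raise DomainError("min-PHBR must be positive")
    return "low" if min_phbr < threshold else "high"


@dataclass(frozen=True)
class StratumAssignment:
    """Joint TMB × PHBR stratum of one patient."""

    tmb_class: str
    phbr_class: str

    def __post_init__(self):
        for cls in (self.tmb_class, self.phbr_class):
            if cls not in ("low", "high"):
                raise InvalidInputError(f"stratum class must be low/high, got {cls!r}")

    @property
    def joint(self) -> str:
        return f"TMB-{self.tmb_class}/PHBR-{self.phbr_class}"


def assign_stratum(tmb_class: str, phbr_class: str) -> StratumAssignment:
    """Cross the two dichotomizations; TMB-high/PHBR-low is the best-prognosis stratum."""
    return StratumAssignment(tmb_class=tmb_class, phbr_class=phbr_class)


def overall_benefit(response: str, followup_months: Optional[float] = None) -> str:
    """Clinical-benefit label from the response category.

    CR/PR/SD≥6mo → benefit; PD and progressed SD<6mo → no benefit; ongoing SD
    with follow-up under 6 months → not evaluable.  A bare "SD" is resolved
    by follow-up when provided.
    """
    if response in ("CR", "PR", "SD>=6mo"):
        return BENEFIT
    if response in ("PD", "SD<6mo"):
        return NO_BENEFIT
    if response == "SD<6mo-ongoing":
        return NOT_EVALUABLE
    if response == "SD" and followup_months is not None:
        return BENEFIT if followup_months >= 6 else NOT_EVALUABLE
    raise InvalidInputError(f"unknown response category {response!r}")


@dataclass
class PatientRecord:
    """One row of every downstream analysis."""

    patient_id: str
    tumor_type: str = "other"
    sex: Optional[str] = None
    ethnicity: Optional[str] = None
    age_at_treatment: Optional[float] = None
    therapy: Optional[str] = None  # monotherapy | combination
    tmb: Optional[float] = None
    min_phbr: Optional[float] = None
    response: Optional[str] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None
    msi_status: Optional[str] = None
    followup_months: Optional[float] = None
    covariates: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("pfs_months", "os_months", "followup_months"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise InvalidInputError(f"{self.patient_id}: {name} negative ({value})")
        if self.tmb is not None and self.tmb < 0:
            raise InvalidInputError(f"{self.patient_id}: negative TMB")
        if self.min_phbr is not None and self.min_phbr <= 0:
            raise InvalidInputError(f"{self.patient_id}: nonpositive min-PHBR")
        if self.therapy is not None and self.therapy not in ("monotherapy", "combination"):
            raise InvalidInputError(
                f"{self.patient_id}: therapy must be monotherapy/combination"
            )

    def tmb_class(self, threshold: float = DEFAULT_TMB_THRESHOLD) -> str:
        return dichotomize_tmb(self.tmb, threshold)

    def phbr_class(self, threshold: float = DEFAULT_PHBR_THRESHOLD) -> str:
        if self.min_phbr is None:
            raise InvalidInputError(f"{self.patient_id}: min-PHBR not scored")
        return dichotomize_phbr(self.min_phbr, threshold)

    def stratum(
        self,
        tmb_threshold: float = DEFAULT_TMB_THRESHOLD,
        phbr_threshold: float = DEFAULT_PHBR_THRESHOLD,
    ) -> StratumAssignment:
        return assign_stratum(self.tmb_class(tmb_threshold), self.phbr_class(phbr_threshold))

    def benefit(self) -> str:
        if self.response is None:
            return NOT_EVALUABLE
        return overall_benefit(self.response, self.followup_months)
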