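"""Readers and writers for the interchange formats.

All tables are tab-separated UTF-8 with a header row; '#'-prefixed comment
lines are permitted; missing values are empty cells.  All CDS and protein
coordinates are 1-based and inclusive.  Transcript FASTA headers carry the
transcript id; bodies are CDS nucleotides.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cohort import PatientRecord
from .errors import SchemaError, TableParseError, UnsupportedVariantError
from .peptides import InFrameIndel, MissenseVariant, TranscriptRecord
from .scoring import HlaGenotype

SUPPORTED_VARIANT_CLASSES = ("missense", "inframe_ins", "inframe_del")

_PROTEIN_CHANGE_RE = re.compile(r"^([A-Y])(\d+)([A-Y])$")
_CDS_INS_RE = re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$")
_CDS_DEL_RE = re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]*)$")

GENOTYPE_COLUMNS = ("A1", "A2", "B1", "B2", "C1", "C2")

CLINICAL_COLUMNS = (
    "patient_id",
    "tumor_type",
    "sex",
    "ethnicity",
    "age_at_treatment",
    "therapy",
    "tmb",
    "response",
    "pfs_months",
    "pfs_event",
    "os_months",
    "os_event",
    "followup_months",
)


# ---------------------------------------------------------------------------
# transcripts
# ---------------------------------------------------------------------------

def read_transcript_fasta(path) -> dict[str, TranscriptRecord]:
    """Transcript id → record from a CDS FASTA."""
    transcripts = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        transcripts[rec.id] = TranscriptRecord(transcript_id=rec.id, cds=str(rec.seq))
    if not transcripts:
        raise SchemaError(f"no FASTA records in {path}")
    return transcripts


def write_transcript_fasta(transcripts: Mapping[str, TranscriptRecord], path) -> None:
    records = [
        SeqRecord(Seq(t.cds), id=tid, description="")
        for tid, t in transcripts.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

def parse_protein_change(text: str) -> tuple[str, int, str]:
    """'A2V' → (ref, position, alt)."""
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if not m:
        raise TableParseError(f"bad protein_change syntax {text!r} (expected e.g. A2V)")
    return m.group(1), int(m.group(2)), m.group(3)


def parse_cds_effect(text: str, transcript: TranscriptRecord) -> InFrameIndel:
    """'6_7insGGG' or '4_6del' / '4_6delGCC' → an in-frame indel.

    Insertion coordinates name the flanking bases; the first affected base is
    the right flank.  Deletions without explicit bases take them from the
    transcript CDS.
    """
    text = text.strip()
    m = _CDS_INS_RE.match(text)
    if m:
        left, right, bases = int(m.group(1)), int(m.group(2)), m.group(3)
        if right != left + 1:
            raise TableParseError(f"insertion coordinates {text!r} are not adjacent")
        return InFrameIndel(
            transcript_id=transcript.transcript_id,
            cds_position=right,
            inserted_bases=bases,
        )
    m = _CDS_DEL_RE.match(text)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        stated = m.group(3)
        if end < start or end > len(transcript.cds):
            raise TableParseError(f"deletion interval {text!r} outside the CDS")
        deleted = stated or transcript.cds[start - 1 : end]
        return InFrameIndel(
            transcript_id=transcript.transcript_id,
            cds_position=start,
            deleted_bases=deleted,
        )
    raise TableParseError(f"bad cds_effect syntax {text!r}")


def read_variant_table(
    path, transcripts: Mapping[str, TranscriptRecord]
) -> tuple[dict[str, list], dict[str, int]]:
    """patient_id → variant objects, plus a count of skipped variant classes.

    Unsupported classes (frameshift, splice, ...) are counted and reported,
    not silently dropped; truly malformed rows raise with a line number.
    """
    df = _read_tsv(path, required={"patient_id", "transcript_id", "variant_class"})
    variants: dict[str, list] = {}
    skipped: dict[str, int] = {}
    for row in df.itertuples():
        line_no = row.Index + 2
        v_class = str(row.variant_class)
        if v_class not in SUPPORTED_VARIANT_CLASSES:
            skipped[v_class] = skipped.get(v_class, 0) + 1
            continue
        tid = str(row.transcript_id)
        if tid not in transcripts:
            raise TableParseError(f"unknown transcript {tid!r}", line=line_no)
        try:
            if v_class == "missense":
                ref, pos, alt = parse_protein_change(str(row.protein_change))
                variant = MissenseVariant(
                    transcript_id=tid, protein_position=pos, ref_aa=ref, alt_aa=alt
                )
            else:
                effect = getattr(row, "cds_effect", "")
                if not isinstance(effect, str) or not effect.strip():
                    raise TableParseError("indel row lacks a cds_effect")
                variant = parse_cds_effect(effect, transcripts[tid])
        except UnsupportedVariantError:
            skipped[v_class] = skipped.get(v_class, 0) + 1
            continue
        except TableParseError as exc:
            raise TableParseError(str(exc), line=line_no) from None
        variants.setdefault(str(row.patient_id), []).append(variant)
    return variants, skipped


# ---------------------------------------------------------------------------
# genotype table
# ---------------------------------------------------------------------------

def read_genotype_table(path) -> dict[str, HlaGenotype]:
    """patient_id → six-slot genotype; homozygosity (repeated alleles) preserved."""
    df = _read_tsv(path, required={"patient_id", *GENOTYPE_COLUMNS})
    genotypes: dict[str, HlaGenotype] = {}
    for row in df.itertuples():
        line_no = row.Index + 2
        pid = str(row.patient_id)
        if pid in genotypes:
            raise TableParseError(f"duplicate patient id {pid!r}", line=line_no)
        names = [getattr(row, col) for col in GENOTYPE_COLUMNS]
        if any(not isinstance(n, str) or not n.strip() for n in names):
            raise TableParseError(
                f"patient {pid!r} does not have six allele slots", line=line_no
            )
        try:
            genotypes[pid] = HlaGenotype.from_names([n.strip() for n in names])
        except Exception as exc:
            raise TableParseError(f"patient {pid!r}: {exc}", line=line_no) from None
    return genotypes


def write_genotype_table(genotypes: Mapping[str, HlaGenotype], path) -> None:
    rows = [
        {"patient_id": pid, **{c: a.name for c, a in zip(GENOTYPE_COLUMNS, g.slots)}}
        for pid, g in genotypes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# clinical table
# ---------------------------------------------------------------------------

def read_clinical_table(path) -> pd.DataFrame:
    """Clinical outcome table; event flags to booleans, blanks to missing."""
    df = _read_tsv(path, required={"patient_id"})
    for col in ("pfs_event", "os_event"):
        if col in df.columns:
            df[col] = df[col].map(_parse_bool)
    for col in ("tmb", "min_phbr", "age_at_treatment", "pfs_months", "os_months",
                "followup_months"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def clinical_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """Validated PatientRecord objects from a clinical table."""
    records = []
    for row in df.to_dict("records"):
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                tumor_type=row.get("tumor_type", "other"),
                sex=_opt(row.get("sex")),
                ethnicity=_opt(row.get("ethnicity")),
                age_at_treatment=_opt(row.get("age_at_treatment")),
                therapy=_opt(row.get("therapy")),
                tmb=_opt(row.get("tmb")),
                min_phbr=_opt(row.get("min_phbr")),
                response=_opt(row.get("response")),
                pfs_months=_opt(row.get("pfs_months")),
                pfs_event=_opt(row.get("pfs_event")),
                os_months=_opt(row.get("os_months")),
                os_event=_opt(row.get("os_event")),
                followup_months=_opt(row.get("followup_months")),
            )
        )
    return records


# ---------------------------------------------------------------------------
# peptide / score outputs
# ---------------------------------------------------------------------------

def write_peptide_table(rows: pd.DataFrame, path) -> None:
    """patient_id, transcript_id, variant, peptide, start, length."""
    rows.to_csv(path, sep="\t", index=False)


def write_score_table(scored: pd.DataFrame, path) -> None:
    scored.to_csv(path, sep="\t", index=False)


def write_rank_table(rank_table: pd.DataFrame, path) -> None:
    rank_table.to_csv(path, sep="\t", index=False)


def write_cohort(cohort, outdir) -> dict[str, Path]:
    """Write every file of a synthetic cohort; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "transcripts": outdir / "transcripts.fasta",
        "variants": outdir / "variants.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "ranks": outdir / "ranks.tsv",
        "clinical": outdir / "clinical.tsv",
    }
    write_transcript_fasta(cohort.transcripts, paths["transcripts"])
    cohort.variants.to_csv(paths["variants"], sep="\t", index=False)
    write_genotype_table(cohort.genotypes, paths["genotypes"])
    write_rank_table(cohort.rank_table, paths["ranks"])
    cohort.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _read_tsv(path, required: set[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise TableParseError(f"cannot read {path}: {exc}") from exc
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    return df


def _parse_bool(value):
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    if text == "":
        return None
    raise TableParseError(f"cannot interpret {value!r} as an event flag")


def _opt(value):
    if value is None:
        return None
    if isinstance(value, float) and pd.isna(value):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return value
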