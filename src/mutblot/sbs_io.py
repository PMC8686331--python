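"""Reading somatic SBS calls (MAF), clinical tables, and reference flanks.

Coordinates follow the MAF convention externally (1-based, inclusive);
all internal arithmetic is 0-based half-open.  Flank extraction is
strand-naive: bases are reported exactly as on the reference (plus)
strand; pyrimidine collapse happens only at reporting time (see
:mod:`mutblot.encoding`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: default MAF column names (TCGA dialect) -> internal field names
MAF_COLUMNS = {
    "sample_barcode": "Tumor_Sample_Barcode",
    "chromosome": "Chromosome",
    "position": "Start_Position",
    "ref_allele": "Reference_Allele",
    "alt_allele": "Tumor_Seq_Allele2",
    "gene_symbol": "Hugo_Symbol",
}

#: optional MAF columns; absent columns yield empty strings
MAF_OPTIONAL_COLUMNS = {"cancer_type": "Project_Code"}


class MAFFormatError(ValueError):
    """The MAF file is malformed (missing column, bad position, ...)."""


class RefMismatchError(ValueError):
    """The reference genome base disagrees with the MAF reference allele."""


@dataclass(frozen=True)
class SBSRecord:
    """One somatic single-base substitution.

    ``position`` is the 1-based reference coordinate of the mutated base.
    """

    sample_barcode: str
    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    gene_symbol: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(
                f"alleles must be single A/C/G/T bases, got "
                f"{self.ref_allele!r}>{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles are identical ({self.ref_allele})")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    @property
    def patient_id(self) -> str:
        """Patient-level barcode: the first three dash-separated fields of a
        TCGA aliquot barcode, or the whole barcode if it has fewer fields."""
        return "-".join(self.sample_barcode.split("-")[:3])


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and survival follow-up.

    ``event`` is 1 for death and 0 for censoring at last follow-up; any
    covariate may be None (missing) and is dropped per-analysis downstream.
    """

    sample_barcode: str
    age: Optional[float] = None
    sex: Optional[str] = None
    weight: Optional[float] = None
    t_stage: Optional[str] = None
    n_stage: Optional[str] = None
    m_stage: Optional[str] = None
    ajcc_stage: Optional[str] = None
    survival_time: Optional[float] = None
    event: Optional[int] = None

    def __post_init__(self) -> None:
        if self.survival_time is not None and self.survival_time < 0:
            raise ValueError(
                f"survival_time must be >= 0, got {self.survival_time} "
                f"for {self.sample_barcode}"
            )
        if self.event is not None and self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")


@dataclass(frozen=True)
class MutationSequence:
    """A substitution with its 5' and 3' reference flanks (plus strand).

    Both flanks have exactly F bases; out-of-chromosome positions are
    padded with N so the represented length is always 2F+1.
    """

    five_prime_flank: str
    ref_allele: str
    alt_allele: str
    three_prime_flank: str
    record: Optional[SBSRecord] = None

    def __post_init__(self) -> None:
        if len(self.five_prime_flank) != len(self.three_prime_flank):
            raise ValueError("flanks must have equal length")

    @property
    def flank_length(self) -> int:
        return len(self.five_prime_flank)


class GenomeSource:
    """Indexed FASTA wrapper with chromosome-name normalization.

    Queries return uppercase bases; chromosome names are matched with or
    without the ``chr`` prefix.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._fasta = Fasta(str(path), sequence_always_upper=True)
        self._name_map: dict[str, str] = {}
        for name in self._fasta.keys():
            self._name_map[name] = name
            alt = name[3:] if name.startswith("chr") else "chr" + name
            self._name_map.setdefault(alt, name)

    def chromosomes(self) -> list[str]:
        return list(self._fasta.keys())

    def _resolve(self, chromosome: str) -> str:
        try:
            return self._name_map[chromosome]
        except KeyError:
            raise KeyError(
                f"chromosome {chromosome!r} not found in {self.path.name} "
                f"(known: {sorted(self._fasta.keys())[:5]}...)"
            ) from None

    def chromosome_length(self, chromosome: str) -> int:
        return len(self._fasta[self._resolve(chromosome)])

    def fetch(self, chromosome: str, start0: int, end0: int) -> str:
        """Bases in the 0-based half-open window [start0, end0).

        Positions outside the chromosome are padded with N, preserving
        the requested length.
        """
        name = self._resolve(chromosome)
        length = len(self._fasta[name])
        lo, hi = max(start0, 0), min(end0, length)
        core = str(self._fasta[name][lo:hi]) if hi > lo else ""
        return "N" * (lo - start0) + core + "N" * (end0 - hi)


def read_maf(
    path: str | Path,
    columns: Optional[Mapping[str, str]] = None,
) -> list[SBSRecord]:
    """Read a MAF file and return valid SBS records.

    Rows that are not single-base substitutions (indels, multi-base
    alleles, ref==alt) are dropped; the dropped count is logged.
    ``columns`` overrides the default TCGA column names per field.
    """
    colmap = dict(MAF_COLUMNS)
    if columns:
        colmap.update(columns)

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for field_name, col in colmap.items():
        if col not in df.columns:
            raise MAFFormatError(
                f"required MAF column {col!r} (for {field_name}) not found in {path}"
            )

    records: list[SBSRecord] = []
    n_dropped = 0
    cancer_col = MAF_OPTIONAL_COLUMNS["cancer_type"]
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        ref = row_d[colmap["ref_allele"]].upper()
        alt = row_d[colmap["alt_allele"]].upper()
        if len(ref) != 1 or len(alt) != 1 or ref not in VALID_BASES \
                or alt not in VALID_BASES or ref == alt:
            n_dropped += 1
            continue
        pos_str = row_d[colmap["position"]]
        try:
            position = int(pos_str)
        except ValueError:
            raise MAFFormatError(
                f"unparseable position {pos_str!r} at data line {i + 1} of {path}"
            ) from None
        records.append(
            SBSRecord(
                sample_barcode=row_d[colmap["sample_barcode"]],
                chromosome=row_d[colmap["chromosome"]],
                position=position,
                ref_allele=ref,
                alt_allele=alt,
                gene_symbol=row_d[colmap["gene_symbol"]],
                cancer_type=row_d.get(cancer_col, ""),
            )
        )
    if n_dropped:
        logger.info("read_maf: dropped %d non-SBS rows from %s", n_dropped, path)
    return records


_CLINICAL_NUMERIC = ("age", "weight", "survival_time")
_CLINICAL_STRING = ("sex", "t_stage", "n_stage", "m_stage", "ajcc_stage")


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read a clinical CSV/TSV keyed by sample barcode.

    Absent columns or empty cells become missing values; rows are only
    dropped later, per-analysis, when a required item is missing.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "sample_barcode" not in df.columns:
        raise MAFFormatError(f"clinical table {path} lacks a sample_barcode column")
    dup = df["sample_barcode"][df["sample_barcode"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate barcodes in clinical table: {sorted(set(dup))}")

    records = []
    for row in df.to_dict("records"):
        kwargs: dict = {"sample_barcode": row["sample_barcode"]}
        for name in _CLINICAL_NUMERIC:
            val = row.get(name, "")
            kwargs[name] = float(val) if val not in ("", "NA", "nan") else None
        for name in _CLINICAL_STRING:
            val = row.get(name, "")
            kwargs[name] = val if val not in ("", "NA", "nan") else None
        val = row.get("event", "")
        kwargs["event"] = int(val) if val not in ("", "NA", "nan") else None
        records.append(ClinicalRecord(**kwargs))
    return records


def clinical_frame(records: Sequence[ClinicalRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by barcode (None -> NaN)."""
    rows = [vars(r) for r in records]
    df = pd.DataFrame(rows).set_index("sample_barcode")
    return df


def extract_flanks(
    record: SBSRecord,
    genome: GenomeSource,
    F: int = 50,
    on_mismatch: str = "raise",
) -> Optional[MutationSequence]:
    """Extract F bases of 5' and 3' flank around an SBS from the genome.

    The genome base at the mutation position is checked against the MAF
    reference allele; ``on_mismatch`` is "raise" (default), "drop"
    (return None) or "keep".
    """
    if on_mismatch not in ("raise", "drop", "keep"):
        raise ValueError(f"unknown on_mismatch mode {on_mismatch!r}")
    pos0 = record.position - 1  # 0-based site index
    window = genome.fetch(record.chromosome, pos0 - F, pos0 + F + 1)
    genome_base = window[F]
    if genome_base != record.ref_allele:
        if on_mismatch == "raise":
            raise RefMismatchError(
                f"{record.chromosome}:{record.position} genome base "
                f"{genome_base!r} != MAF ref allele {record.ref_allele!r}"
            )
        if on_mismatch == "drop":
            return None
    return MutationSequence(
        five_prime_flank=window[:F],
        ref_allele=record.ref_allele,
        alt_allele=record.alt_allele,
        three_prime_flank=window[F + 1:],
        record=record,
    )


def extract_all_flanks(
    records: Iterable[SBSRecord],
    genome: GenomeSource,
    F: int = 50,
    on_mismatch: str = "raise",
) -> list[MutationSequence]:
    """Vector form of :func:`extract_flanks`; drops rejected records."""
    out = []
    n_dropped = 0
    for rec in records:
        seq = extract_flanks(rec, genome, F=F, on_mismatch=on_mismatch)
        if seq is None:
            n_dropped += 1
        else:
            out.append(seq)
    if n_dropped:
        logger.info("extract_all_flanks: dropped %d ref-mismatch records", n_dropped)
    return out


def write_maf(records: Sequence[SBSRecord], path: str | Path) -> None:
    """Write SBS records as a minimal TCGA-dialect MAF."""
    df = pd.DataFrame(
        {
            "Hugo_Symbol": [r.gene_symbol for r in records],
            "Chromosome": [r.chromosome for r in records],
            "Start_Position": [r.position for r in records],
            "Reference_Allele": [r.ref_allele for r in records],
            "Tumor_Seq_Allele2": [r.alt_allele for r in records],
            "Tumor_Sample_Barcode": [r.sample_barcode for r in records],
            "Project_Code": [r.cancer_type for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)
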