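"""Reading and writing somatic substitution inputs.

Two input dialects are supported:

* **MAF** — TCGA-style tab-delimited mutation annotation format.  Alleles
  are assumed reported on the genomic + strand; the gene's ``Strand``
  column drives complementation onto the coding non-transcribed strand.
* **pair list** — a minimal two-column text file (reference allele,
  mutated allele), one substitution per row, already oriented to the
  coding non-transcribed strand.  This is the exchange format used for
  blinded external cohorts.

Per-sample spectrum summaries can be written to / read from a TSV profile
table with a fixed column layout (counts and percent frequencies in the
canonical class order, total, target size and sub/Mb prevalence).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ContractError, FormatError, SchemaError
from .spectrum import BASES, CLASSES, COMPLEMENT, SHORT_LABELS, SpectrumProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubstitutionCall:
    """One somatic single-base substitution.

    ``gene_strand`` ('+' or '-') is the strand of the gene the variant
    falls in; it is ``None`` for inputs already oriented to the coding
    non-transcribed strand.
    """

    ref_base: str
    alt_base: str
    gene_strand: str | None = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ContractError(
                f"alleles must be uppercase A/C/G/T, got "
                f"({self.ref_base!r}, {self.alt_base!r})"
            )
        if self.ref_base == self.alt_base:
            raise ContractError(f"ref == alt ({self.ref_base!r}) is not a substitution")
        if self.gene_strand is not None and self.gene_strand not in ("+", "-"):
            raise ContractError(f"gene_strand must be '+' or '-', got {self.gene_strand!r}")


@dataclass
class SampleVariants:
    """All somatic substitutions of one tumor plus its exome target size."""

    sample_id: str
    calls: list[SubstitutionCall] = field(default_factory=list)
    target_region_mb: float = 50.0

    def __post_init__(self) -> None:
        if self.target_region_mb <= 0:
            raise ContractError(
                f"target_region_mb must be positive, got {self.target_region_mb}"
            )


def orient_to_coding_strand(call: SubstitutionCall) -> SubstitutionCall:
    """Flip a call onto the coding non-transcribed (+) strand.

    Calls on '-' strand genes have both alleles complemented; '+' strand
    calls are returned unchanged.  Requires ``gene_strand`` to be set.
    """
    if call.gene_strand is None:
        raise ContractError(
            "gene_strand unset; use pre-oriented input (pair-list dialect) "
            "or supply a strand before orientation"
        )
    if call.gene_strand == "+":
        return call
    return replace(
        call,
        ref_base=COMPLEMENT[call.ref_base],
        alt_base=COMPLEMENT[call.alt_base],
        gene_strand="+",
    )


# ---------------------------------------------------------------------------
# pair-list dialect


def read_pair_list(path: str | Path, sample_id: str, target_region_mb: float) -> SampleVariants:
    """Read a two-column (ref, alt) substitution list for one sample.

    Rows are tab- or whitespace-delimited; alleles must already be on the
    coding non-transcribed strand.  An empty file yields a valid
    zero-substitution sample.
    """
    calls: list[SubstitutionCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(fields)}"
                )
            ref, alt = fields
            if ref not in BASES or alt not in BASES:
                raise FormatError(
                    f"{path}: line {lineno}: non-ACGT allele ({ref!r}, {alt!r})"
                )
            if ref == alt:
                raise FormatError(
                    f"{path}: line {lineno}: reference equals mutated allele ({ref!r})"
                )
            calls.append(SubstitutionCall(ref, alt, None, sample_id))
    return SampleVariants(sample_id=sample_id, calls=calls, target_region_mb=target_region_mb)


def write_pair_list(sv: SampleVariants, path: str | Path) -> None:
    """Write a sample's calls as a two-column ref/alt list (row order kept)."""
    with open(path, "w") as fh:
        for call in sv.calls:
            fh.write(f"{call.ref_base}\t{call.alt_base}\n")


# ---------------------------------------------------------------------------
# MAF dialect

#: Default TCGA column names; user-overridable via ``column_map``.
DEFAULT_MAF_COLUMNS: dict[str, str] = {
    "sample": "Tumor_Sample_Barcode",
    "ref": "Reference_Allele",
    "alt1": "Tumor_Seq_Allele1",
    "alt2": "Tumor_Seq_Allele2",
    "variant_type": "Variant_Type",
    "strand": "Strand",
}

#: Variant_Type values treated as single-nucleotide substitutions.
SNV_TYPES = {"SNP", "SNV"}


def read_maf(
    path: str | Path,
    default_target_mb: float,
    column_map: Mapping[str, str] | None = None,
    target_mb_by_sample: Mapping[str, float] | None = None,
) -> dict[str, SampleVariants]:
    """Read a MAF file into per-sample substitution collections.

    Only single-nucleotide substitution rows are retained (insertions,
    deletions and multi-base substitutions are not considered).  The
    mutated allele is the first tumor-allele column that differs from the
    reference.  Rows with ambiguous/non-ACGT alleles or where no tumor
    allele differs from the reference are skipped with a logged warning
    (counts reported), keeping batch runs alive.
    """
    cols = dict(DEFAULT_MAF_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [name for name in cols.values() if name not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory MAF columns: {missing}")

    samples: dict[str, SampleVariants] = {}
    n_no_alt = 0
    n_bad_base = 0
    for row in df.itertuples(index=False):
        rec = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        vtype = str(rec[cols["variant_type"]]).upper()
        if vtype not in SNV_TYPES:
            continue
        barcode = rec[cols["sample"]]
        ref = str(rec[cols["ref"]]).upper()
        alts = [str(rec[cols["alt1"]]).upper(), str(rec[cols["alt2"]]).upper()]
        alt = next((a for a in alts if a != ref), None)
        if alt is None:
            n_no_alt += 1
            continue
        strand = str(rec[cols["strand"]]).strip()
        strand = {"+": "+", "-": "-", "−": "-", "1": "+", "-1": "-"}.get(strand)
        if ref not in BASES or alt not in BASES or strand is None:
            n_bad_base += 1
            continue
        sv = samples.get(barcode)
        if sv is None:
            mb = (target_mb_by_sample or {}).get(barcode, default_target_mb)
            sv = samples[barcode] = SampleVariants(barcode, [], mb)
        sv.calls.append(SubstitutionCall(ref, alt, strand, barcode))
    if n_no_alt:
        logger.warning("%s: skipped %d rows where no tumor allele differs from reference", path, n_no_alt)
    if n_bad_base:
        logger.warning("%s: skipped %d rows with ambiguous alleles or strand", path, n_bad_base)
    return samples


def orient_sample(sv: SampleVariants) -> SampleVariants:
    """Orient every call of a sample to the coding non-transcribed strand."""
    return SampleVariants(
        sample_id=sv.sample_id,
        calls=[orient_to_coding_strand(c) for c in sv.calls],
        target_region_mb=sv.target_region_mb,
    )


# ---------------------------------------------------------------------------
# profile table

_COUNT_COLS = [f"n_{SHORT_LABELS[c]}" for c in CLASSES]
_FREQ_COLS = [f"pct_{SHORT_LABELS[c]}" for c in CLASSES]
PROFILE_COLUMNS = ["sample_id", *_COUNT_COLS, *_FREQ_COLS, "total", "target_mb", "prevalence"]


def profiles_to_frame(profiles: Iterable[SpectrumProfile]) -> pd.DataFrame:
    """Tabulate profiles with the fixed column order (class order C>A..T>A)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id}
        for c in CLASSES:
            row[f"n_{SHORT_LABELS[c]}"] = p.counts[c]
        for c in CLASSES:
            row[f"pct_{SHORT_LABELS[c]}"] = p.freqs[c] if p.freqs is not None else float("nan")
        row["total"] = p.total
        row["target_mb"] = p.target_mb
        row["prevalence"] = p.prevalence
        rows.append(row)
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profile_table(profiles: Iterable[SpectrumProfile], path: str | Path) -> None:
    profiles_to_frame(profiles).to_csv(path, sep="\t", index=False)


def read_profile_table(path: str | Path) -> list[SpectrumProfile]:
    """Re-load profiles written by :func:`write_profile_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing profile columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        rec = row._asdict()
        counts = {c: int(rec[f"n_{SHORT_LABELS[c]}"]) for c in CLASSES}
        out.append(
            SpectrumProfile.from_counts(str(rec["sample_id"]), counts, float(rec["target_mb"]))
        )
    return out


__all__ = [
    "SubstitutionCall",
    "SampleVariants",
    "orient_to_coding_strand",
    "orient_sample",
    "read_pair_list",
    "write_pair_list",
    "read_maf",
    "profiles_to_frame",
    "write_profile_table",
    "read_profile_table",
    "PROFILE_COLUMNS",
    "DEFAULT_MAF_COLUMNS",
]
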