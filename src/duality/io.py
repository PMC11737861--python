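"""Readers and writers for hotspot tables, germline tables, and cohort VCFs.

Tables are plain TSV. Column names are resolved through a *dialect* — a
mapping from the canonical field names used here to the column headers in
the file — so externally produced tables can be read without renaming.
Parsing is total: every input row either becomes a record or is returned
as a :class:`RejectedRow` with a reason, and the two always sum to the
row count of the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam

from .variants import (
    AlleleOrigin,
    ClassLabel,
    GenomicVariant,
    GermlineRecord,
    HotspotMutation,
    normalize_chrom,
    parse_protein_change,
)

HOTSPOT_COLUMNS = (
    "gene",
    "protein_change",
    "chrom",
    "pos",
    "ref",
    "alt",
    "tumor_count_change",
    "tumor_count_residue",
)

GERMLINE_COLUMNS = (
    "chrom",
    "pos",
    "ref",
    "alt",
    "gene",
    "protein_change",
    "classification",
    "allele_origin",
    "revel",
    "phylop_mam20",
    "phylop_vert7",
    "phastcons_mam20",
    "phastcons_vert7",
)

#: default mapping of ClinVar-style clinical significance strings to labels;
#: matching is case-insensitive on the stripped string.
DEFAULT_CLASSIFICATION_MAP: dict[str, ClassLabel] = {
    "pathogenic": ClassLabel.LP_P,
    "likely pathogenic": ClassLabel.LP_P,
    "pathogenic/likely pathogenic": ClassLabel.LP_P,
    "uncertain significance": ClassLabel.VUS,
    "benign": ClassLabel.LB_B,
    "likely benign": ClassLabel.LB_B,
    "benign/likely benign": ClassLabel.LB_B,
    "conflicting interpretations of pathogenicity": ClassLabel.CIP,
    "conflicting classifications of pathogenicity": ClassLabel.CIP,
    "risk factor": ClassLabel.RISK_FACTOR,
    "lp_p": ClassLabel.LP_P,
    "vus": ClassLabel.VUS,
    "lb_b": ClassLabel.LB_B,
    "cip": ClassLabel.CIP,
    "risk_factor": ClassLabel.RISK_FACTOR,
    "other": ClassLabel.OTHER,
}

_ORIGIN_MAP = {
    "germline": AlleleOrigin.GERMLINE,
    "somatic": AlleleOrigin.SOMATIC,
    "unknown": AlleleOrigin.UNKNOWN,
    "": AlleleOrigin.UNKNOWN,
}


class FormatError(ValueError):
    """A table is missing a mandatory column or is otherwise unreadable."""


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str


@dataclass
class ParseResult:
    """Records plus enumerated rejections; together they cover every input row."""

    records: list
    rejections: list[RejectedRow] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.rejections)

    def rejection_report(self) -> list[dict]:
        return [{"row": r.row_index, "reason": r.reason} for r in self.rejections]


def _resolve_columns(
    df: pd.DataFrame, canonical: Sequence[str], dialect: Optional[Mapping[str, str]]
) -> dict[str, str]:
    dialect = dict(dialect or {})
    resolved = {}
    for name in canonical:
        col = dialect.get(name, name)
        if col in df.columns:
            resolved[name] = col
    return resolved


def _require(resolved: Mapping[str, str], names: Iterable[str]) -> None:
    missing = [n for n in names if n not in resolved]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"na", "nan", "none", "."}:
        return None
    return float(s)


def read_hotspot_table(
    path, dialect: Optional[Mapping[str, str]] = None
) -> ParseResult:
    """Read a Cancer Hotspots-style TSV into :class:`HotspotMutation` records.

    Rows that are not missense substitutions, have malformed alleles, or
    violate the count invariant are returned as rejections rather than
    raised, preserving input order among accepted records.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df, HOTSPOT_COLUMNS, dialect)
    _require(cols, HOTSPOT_COLUMNS)
    records: list[HotspotMutation] = []
    rejections: list[RejectedRow] = []
    for i in range(len(df)):
        raw = {name: df.iloc[i][cols[name]] for name in HOTSPOT_COLUMNS}
        try:
            change = parse_protein_change(str(raw["gene"]).strip(), str(raw["protein_change"]))
            variant = GenomicVariant(
                chrom=str(raw["chrom"]),
                pos=int(raw["pos"]),
                ref=str(raw["ref"]).strip().upper(),
                alt=str(raw["alt"]).strip().upper(),
            )
            records.append(
                HotspotMutation(
                    variant=variant,
                    change=change,
                    tumor_count_change=int(raw["tumor_count_change"]),
                    tumor_count_residue=int(raw["tumor_count_residue"]),
                )
            )
        except (ValueError, TypeError) as exc:
            rejections.append(RejectedRow(row_index=i, reason=str(exc)))
    return ParseResult(records=records, rejections=rejections)


def read_germline_table(
    path,
    dialect: Optional[Mapping[str, str]] = None,
    classification_map: Optional[Mapping[str, ClassLabel]] = None,
    strict: bool = False,
    extra_score_columns: Sequence[str] = (),
) -> ParseResult:
    """Read a ClinVar-style germline TSV into :class:`GermlineRecord` records.

    The classification-string mapping is total: strings absent from the map
    become :data:`ClassLabel.OTHER` unless ``strict`` is set, in which case
    an unmappable string raises a :class:`FormatError` naming it.
    """
    cmap = {k.lower(): v for k, v in (classification_map or DEFAULT_CLASSIFICATION_MAP).items()}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty and len(df.columns) == 0:
        return ParseResult(records=[])
    cols = _resolve_columns(df, GERMLINE_COLUMNS, dialect)
    _require(cols, ("chrom", "pos", "ref", "alt", "gene", "protein_change", "classification"))
    records: list[GermlineRecord] = []
    rejections: list[RejectedRow] = []
    for i in range(len(df)):
        raw = {name: df.iloc[i][col] for name, col in cols.items()}
        cls_string = str(raw["classification"]).strip().lower()
        if cls_string not in cmap and strict:
            raise FormatError(f"unmappable classification string: {raw['classification']!r}")
        label = cmap.get(cls_string, ClassLabel.OTHER)
        origin = _ORIGIN_MAP.get(str(raw.get("allele_origin", "germline")).strip().lower())
        if origin is None:
            origin = AlleleOrigin.UNKNOWN
        try:
            change = parse_protein_change(str(raw["gene"]).strip(), str(raw["protein_change"]))
            variant = GenomicVariant(
                chrom=str(raw["chrom"]),
                pos=int(raw["pos"]),
                ref=str(raw["ref"]).strip().upper(),
                alt=str(raw["alt"]).strip().upper(),
            )
            extra = {}
            for name in extra_score_columns:
                if name in df.columns:
                    v = _opt_float(df.iloc[i][name])
                    if v is not None:
                        extra[name] = v
            records.append(
                GermlineRecord(
                    variant=variant,
                    change=change,
                    label=label,
                    allele_origin=origin,
                    revel=_opt_float(raw.get("revel")),
                    phylop_mam20=_opt_float(raw.get("phylop_mam20")),
                    phylop_vert7=_opt_float(raw.get("phylop_vert7")),
                    phastcons_mam20=_opt_float(raw.get("phastcons_mam20")),
                    phastcons_vert7=_opt_float(raw.get("phastcons_vert7")),
                    extra_scores=extra,
                )
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, FormatError):
                raise
            rejections.append(RejectedRow(row_index=i, reason=str(exc)))
    return ParseResult(records=records, rejections=rejections)


def write_hotspot_table(records: Iterable[HotspotMutation], path) -> None:
    rows = [
        {
            "gene": h.change.gene,
            "protein_change": f"{h.change.ref_aa}{h.change.residue}{h.change.alt_aa}",
            "chrom": h.variant.chrom,
            "pos": h.variant.pos,
            "ref": h.variant.ref,
            "alt": h.variant.alt,
            "tumor_count_change": h.tumor_count_change,
            "tumor_count_residue": h.tumor_count_residue,
        }
        for h in records
    ]
    pd.DataFrame(rows, columns=list(HOTSPOT_COLUMNS)).to_csv(path, sep="\t", index=False)


def write_germline_table(records: Iterable[GermlineRecord], path) -> None:
    def fmt(v):
        return "" if v is None else repr(v)

    rows = []
    extra_names: list[str] = []
    for g in records:
        row = {
            "chrom": g.variant.chrom,
            "pos": g.variant.pos,
            "ref": g.variant.ref,
            "alt": g.variant.alt,
            "gene": g.change.gene,
            "protein_change": f"{g.change.ref_aa}{g.change.residue}{g.change.alt_aa}",
            "classification": g.label.value,
            "allele_origin": g.allele_origin.value,
            "revel": fmt(g.revel),
            "phylop_mam20": fmt(g.phylop_mam20),
            "phylop_vert7": fmt(g.phylop_vert7),
            "phastcons_mam20": fmt(g.phastcons_mam20),
            "phastcons_vert7": fmt(g.phastcons_vert7),
        }
        for name, v in g.extra_scores.items():
            row[name] = repr(v)
            if name not in extra_names:
                extra_names.append(name)
        rows.append(row)
    cols = list(GERMLINE_COLUMNS) + extra_names
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def query_cohort_vcf(
    hotspots: Sequence[HotspotMutation],
    vcf_path,
    contig_aliases: Optional[Mapping[str, str]] = None,
) -> list[tuple[HotspotMutation, list[str]]]:
    """Find hotspot alleles in a cohort VCF and return carrier sample IDs.

    Matching is allele-level: chrom, pos, ref and alt must all agree after
    multi-allelic records are decomposed. A ``chr`` prefix difference between
    the query and the VCF contig names is resolved automatically; other
    mismatches can be supplied via ``contig_aliases``.
    """
    aliases = {normalize_chrom(k): v for k, v in (contig_aliases or {}).items()}
    wanted: dict[tuple[str, int, str, str], HotspotMutation] = {
        h.variant.key: h for h in hotspots
    }
    hits: dict[tuple[str, int, str, str], list[str]] = {}
    with pysam.VariantFile(str(vcf_path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            chrom = normalize_chrom(rec.chrom)
            chrom = aliases.get(chrom, chrom)
            for alt_index, alt in enumerate(rec.alts or ()):
                key = (chrom, rec.pos, rec.ref, alt)
                if key not in wanted:
                    continue
                carriers = []
                for name in samples:
                    gt = rec.samples[name].get("GT") or ()
                    if (alt_index + 1) in [a for a in gt if a is not None]:
                        carriers.append(name)
                hits.setdefault(key, []).extend(carriers)
    return [(wanted[k], sorted(set(v))) for k, v in sorted(hits.items())]


def read_training_spreadsheet(
    path, column_map: Mapping[str, str], sheet: int | str = 0
) -> pd.DataFrame:
    """Read a training/test variant spreadsheet (XLSX) under an explicit
    column mapping — headers are never guessed."""
    if not column_map:
        raise FormatError("a column mapping is required for spreadsheet input")
    df = pd.read_excel(path, sheet_name=sheet)
    missing = [col for col in column_map.values() if col not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    out = df[[col for col in column_map.values()]].copy()
    out.columns = list(column_map.keys())
    return out
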