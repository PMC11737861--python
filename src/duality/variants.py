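"""Domain types for somatic hotspot mutations and germline variants.

Coordinates are GRCh37, 1-based and fully closed. Chromosome names are
normalised to have no ``chr`` prefix. Missing scores are ``None`` —
never 0, since 0 is a valid REVEL or phyloP value.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

NUCLEOTIDES = frozenset("ACGT")

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: three-letter → one-letter amino-acid codes (for p.Gln61Lys style input)
AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
    "Ter": "*",
}

_PCHANGE_1 = re.compile(r"^(?:p\.)?([A-Z*])(\d+)([A-Z*])$")
_PCHANGE_3 = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and canonicalise mitochondrial naming."""
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return "MT" if c == "M" else c


class ClassLabel(enum.Enum):
    """Germline clinical classification, collapsed to the analysis categories."""

    LP_P = "LP_P"
    VUS = "VUS"
    LB_B = "LB_B"
    CIP = "CIP"
    RISK_FACTOR = "RISK_FACTOR"
    OTHER = "OTHER"


class AlleleOrigin(enum.Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"
    UNKNOWN = "unknown"


@dataclass(frozen=True, order=True)
class GenomicVariant:
    """A single-nucleotide variant on GRCh37 (1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise ValueError(f"ref/alt must be single nucleotides, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True, order=True)
class ProteinChange:
    """A missense amino-acid substitution, e.g. HRAS Q61K."""

    gene: str
    residue: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self) -> None:
        if self.residue < 1:
            raise ValueError(f"residue must be >= 1, got {self.residue}")
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise ValueError(
                f"not a missense substitution: {self.gene} {self.ref_aa}{self.residue}{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise ValueError(f"synonymous change {self.gene} {self.ref_aa}{self.residue}{self.alt_aa}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Grouping key: distinct SNVs causing the same change share this key."""
        return (self.gene, self.residue, self.ref_aa, self.alt_aa)

    def __str__(self) -> str:
        return f"{self.gene} {self.ref_aa}{self.residue}{self.alt_aa}"


def parse_protein_change(gene: str, text: str) -> ProteinChange:
    """Parse ``Q61K`` / ``p.Q61K`` / ``p.Gln61Lys`` into a :class:`ProteinChange`.

    Raises ``ValueError`` for anything that is not a missense substitution
    (nonsense, frameshift, synonymous, splice notation, ...).
    """
    text = text.strip()
    m = _PCHANGE_1.match(text)
    if m:
        ref_aa, residue, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _PCHANGE_3.match(text)
        if not m:
            raise ValueError(f"cannot parse protein change {text!r}")
        try:
            ref_aa = AA3_TO_1[m.group(1)]
            alt_aa = AA3_TO_1[m.group(3)]
        except KeyError as exc:
            raise ValueError(f"unknown amino-acid code in {text!r}") from exc
        residue = int(m.group(2))
    return ProteinChange(gene=gene, residue=residue, ref_aa=ref_aa, alt_aa=alt_aa)


@dataclass(frozen=True)
class HotspotMutation:
    """A recurrent somatic missense mutation with tumor-sample recurrence counts.

    ``tumor_count_change`` counts tumor samples carrying this exact amino-acid
    change; ``tumor_count_residue`` counts samples with any change at the
    residue, so change-level counts can never exceed residue-level counts.
    """

    variant: GenomicVariant
    change: ProteinChange
    tumor_count_change: int
    tumor_count_residue: int

    def __post_init__(self) -> None:
        if not (1 <= self.tumor_count_change <= self.tumor_count_residue):
            raise ValueError(
                f"require 1 <= tumor_count_change <= tumor_count_residue, got "
                f"{self.tumor_count_change}/{self.tumor_count_residue} for {self.change}"
            )


@dataclass(frozen=True)
class GermlineRecord:
    """A germline missense variant with classification and in-silico annotations.

    ``overlaps_hotspot`` is ``None`` until overlap annotation has run, then a
    boolean; tumor counts are copied from the matched hotspot (0 otherwise).
    ``extra_scores`` holds comparator-tool scores (SIFT, CADD, AlphaMissense,
    ...) as plain annotation columns.
    """

    variant: GenomicVariant
    change: ProteinChange
    label: ClassLabel
    allele_origin: AlleleOrigin = AlleleOrigin.GERMLINE
    revel: Optional[float] = None
    phylop_mam20: Optional[float] = None
    phylop_vert7: Optional[float] = None
    phastcons_mam20: Optional[float] = None
    phastcons_vert7: Optional[float] = None
    overlaps_hotspot: Optional[bool] = None
    tumor_count_change: int = 0
    tumor_count_residue: int = 0
    extra_scores: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"REVEL must be in [0,1], got {self.revel}")
        for name in ("phastcons_mam20", "phastcons_vert7"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")

    def with_overlap(
        self, overlaps: bool, tumor_count_change: int = 0, tumor_count_residue: int = 0
    ) -> "GermlineRecord":
        return replace(
            self,
            overlaps_hotspot=overlaps,
            tumor_count_change=tumor_count_change,
            tumor_count_residue=tumor_count_residue,
        )
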