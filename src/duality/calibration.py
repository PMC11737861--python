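"""Overlap annotation, contingency scenarios, odds-ratio/likelihood-ratio
estimation, and evidence-strength calibration.

The central question is whether a germline missense variant that coincides
with a recurrent somatic cancer mutation is more likely to be classified
likely pathogenic / pathogenic (LP/P). Overlap is tabulated against
classification under several comparator scenarios of increasing
conservatism (treating VUS, and then also variants with conflicting
interpretations, as if they were benign), and the resulting positive
likelihood ratio is mapped onto the exponential evidence-point scale in
which supporting / moderate / strong / very-strong evidence correspond to
odds of pathogenicity of O^(1/8), O^(1/4), O^(1/2) and O.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from scipy import stats

from .variants import ClassLabel, GermlineRecord, HotspotMutation

Z_975 = 1.959964  # two-sided 95% normal quantile


class Scenario(enum.Enum):
    """Comparator definitions for the overlap-vs-LP/P contingency table."""

    LPP_vs_LBB = "LPP_vs_LBB"  # only LP/P and LB/B records
    VUS_as_benign = "VUS_as_benign"  # VUS folded into the comparator
    VUS_and_CIP_as_benign = "VUS_and_CIP_as_benign"  # CIP folded in as well
    gene_subset = "gene_subset"  # VUS_as_benign restricted to a gene list


#: labels eligible for each scenario's comparator group (LP/P is always the case group)
_COMPARATOR_LABELS = {
    Scenario.LPP_vs_LBB: {ClassLabel.LB_B},
    Scenario.VUS_as_benign: {ClassLabel.LB_B, ClassLabel.VUS},
    Scenario.VUS_and_CIP_as_benign: {ClassLabel.LB_B, ClassLabel.VUS, ClassLabel.CIP},
    Scenario.gene_subset: {ClassLabel.LB_B, ClassLabel.VUS},
}


def annotate_overlap(
    germline: Sequence[GermlineRecord],
    hotspots: Sequence[HotspotMutation],
    mode: str = "nucleotide",
) -> list[GermlineRecord]:
    """Flag germline records that coincide with a hotspot mutation.

    ``nucleotide`` mode requires an exact (chrom, pos, ref, alt) match;
    ``residue_change`` mode matches on (gene, residue, ref_aa, alt_aa), so
    distinct nucleotide variants encoding the same amino-acid change are
    grouped together. Tumor-sample counts are copied onto matched records
    and left at zero otherwise. When several hotspots share a key the
    maximal counts are kept.
    """
    if mode not in {"nucleotide", "residue_change"}:
        raise ValueError(f"unknown overlap mode {mode!r}")
    index: dict[tuple, tuple[int, int]] = {}
    for h in hotspots:
        key = h.variant.key if mode == "nucleotide" else h.change.key
        prev = index.get(key, (0, 0))
        index[key] = (
            max(prev[0], h.tumor_count_change),
            max(prev[1], h.tumor_count_residue),
        )
    out = []
    for g in germline:
        key = g.variant.key if mode == "nucleotide" else g.change.key
        if key in index:
            out.append(g.with_overlap(True, *index[key]))
        else:
            out.append(g.with_overlap(False))
    return out


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of hotspot overlap against LP/P classification.

    a: overlap & LP/P, b: overlap & comparator,
    c: no overlap & LP/P, d: no overlap & comparator.
    """

    a: int
    b: int
    c: int
    d: int
    scenario: Scenario

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty contingency table")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def build_contingency(
    germline: Sequence[GermlineRecord],
    scenario: Scenario,
    genes: Optional[Sequence[str]] = None,
) -> ContingencyTable:
    """Tabulate annotated germline records under a comparator scenario.

    Records whose label is outside the scenario's case/comparator sets are
    excluded; the four cells partition the eligible records exactly. The
    ``gene_subset`` scenario additionally restricts to ``genes``.
    """
    comparator = _COMPARATOR_LABELS[scenario]
    if scenario is Scenario.gene_subset:
        if not genes:
            raise ValueError("gene_subset scenario requires a gene list")
        gene_set = set(genes)
        germline = [g for g in germline if g.change.gene in gene_set]
    a = b = c = d = 0
    for g in germline:
        if g.overlaps_hotspot is None:
            raise ValueError("records must be overlap-annotated first")
        if g.label is ClassLabel.LP_P:
            if g.overlaps_hotspot:
                a += 1
            else:
                c += 1
        elif g.label in comparator:
            if g.overlaps_hotspot:
                b += 1
            else:
                d += 1
    if (a + c == 0) or (b + d == 0):
        raise ValueError(f"scenario {scenario.value} yields an empty margin")
    return ContingencyTable(a=a, b=b, c=c, d=d, scenario=scenario)


def build_contingency_from_counts(
    overlap_by_class: Mapping[ClassLabel, int],
    total_by_class: Mapping[ClassLabel, int],
    scenario: Scenario,
) -> ContingencyTable:
    """Build the scenario table directly from class-level summary counts
    (overlapping variants per class, and class totals)."""
    comparator = _COMPARATOR_LABELS[scenario]
    a = overlap_by_class.get(ClassLabel.LP_P, 0)
    c = total_by_class.get(ClassLabel.LP_P, 0) - a
    b = sum(overlap_by_class.get(lbl, 0) for lbl in comparator)
    d = sum(total_by_class.get(lbl, 0) for lbl in comparator) - b
    if (a + c == 0) or (b + d == 0):
        raise ValueError(f"scenario {scenario.value} yields an empty margin")
    return ContingencyTable(a=a, b=b, c=c, d=d, scenario=scenario)


@dataclass(frozen=True)
class OREstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    correction_applied: bool = False

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("confidence interval must contain the point estimate")


def odds_ratio(
    table: ContingencyTable, alpha: float = 0.05, method: str = "chi2"
) -> OREstimate:
    """Cross-product odds ratio with a Woolf (log-scale) confidence interval.

    OR = (a*d)/(b*c); CI = exp(ln OR ± z * sqrt(1/a + 1/b + 1/c + 1/d)).
    When any cell is zero, the Haldane–Anscombe correction adds 0.5 to every
    cell before estimation and the result is flagged. The p-value comes from
    a chi-square test with Yates continuity correction by default, or
    Fisher's exact test with ``method="fisher"``.
    """
    a, b, c, d = (float(x) for x in table.cells)
    correction = min(a, b, c, d) == 0
    if correction:
        if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
            raise ValueError("a zero margin leaves the odds ratio undefined")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oratio = (a * d) / (b * c)
    z = stats.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = math.exp(math.log(oratio) - z * se)
    ci_high = math.exp(math.log(oratio) + z * se)
    obs = [[table.a, table.b], [table.c, table.d]]
    if method == "fisher":
        p = float(stats.fisher_exact(obs, alternative="two-sided")[1])
    elif method == "chi2":
        p = float(stats.chi2_contingency(obs, correction=True)[1])
    else:
        raise ValueError(f"unknown p-value method {method!r}")
    return OREstimate(
        odds_ratio=oratio, ci_low=ci_low, ci_high=ci_high, p_value=p,
        correction_applied=correction,
    )


def positive_likelihood_ratio(table: ContingencyTable) -> float:
    """LR+ of the overlap flag for LP/P status: sensitivity / false-positive rate.

    Returns ``math.inf`` when no comparator variant overlaps (b = 0) but
    overlapping LP/P variants exist.
    """
    if table.a + table.c == 0 or table.b + table.d == 0:
        raise ValueError("both margins must be non-empty")
    sens = table.a / (table.a + table.c)
    fpr = table.b / (table.b + table.d)
    if fpr == 0.0:
        return 0.0 if sens == 0.0 else math.inf
    return sens / fpr


_BAND_POINTS = (("supporting", 1), ("moderate", 2), ("strong", 4), ("very_strong", 8))


@dataclass(frozen=True)
class EvidenceScale:
    """Exponential evidence-point scale: a band worth p points corresponds to
    odds of pathogenicity O^(p/8), with O the very-strong odds (350 in the
    original calibration, 1124 in the later computational-evidence one)."""

    odds_very_strong: float = 350.0

    def __post_init__(self) -> None:
        if self.odds_very_strong <= 1.0:
            raise ValueError("odds_very_strong must exceed 1")

    def threshold(self, band: str) -> float:
        points = dict(_BAND_POINTS)[band]
        return self.odds_very_strong ** (points / 8.0)

    @property
    def supporting(self) -> float:
        return self.threshold("supporting")

    @property
    def moderate(self) -> float:
        return self.threshold("moderate")

    @property
    def strong(self) -> float:
        return self.threshold("strong")

    @property
    def very_strong(self) -> float:
        return self.threshold("very_strong")


def evidence_strength(lr: float, scale: EvidenceScale = EvidenceScale()) -> str:
    """Map a positive likelihood ratio to the strongest evidence band whose
    threshold it meets; below the supporting threshold the band is ``none``."""
    if lr <= 0:
        raise ValueError("likelihood ratio must be positive")
    band = "none"
    for name, _ in _BAND_POINTS:
        if lr >= scale.threshold(name):
            band = name
    return band


#: ClinGen-style REVEL cutoffs: supporting-level evidence for pathogenicity
#: (PP3) at >= 0.644 and for benign-ness (BP4) at <= 0.290.
DEFAULT_SCORE_THRESHOLDS: dict[str, dict[str, float]] = {
    "revel": {"pp3": 0.644, "bp4": 0.290},
    "alphamissense": {"pp3": 0.792, "bp4": 0.099},
}


def bin_insilico_scores(
    scores: Sequence[Optional[float]],
    thresholds: Optional[Mapping[str, float]] = None,
    tool: str = "revel",
) -> dict[str, int]:
    """Assign each score to a supporting-evidence band.

    Scores >= the PP3 cutoff count as at-least-supporting evidence toward
    pathogenicity, scores <= the BP4 cutoff toward benign-ness, the rest are
    indeterminate; missing scores are tallied separately.
    """
    if thresholds is None:
        try:
            thresholds = DEFAULT_SCORE_THRESHOLDS[tool.lower()]
        except KeyError:
            raise ValueError(f"no default thresholds for tool {tool!r}")
    pp3, bp4 = thresholds["pp3"], thresholds["bp4"]
    if bp4 >= pp3:
        raise ValueError("overlapping threshold bands: BP4 cutoff must lie below PP3 cutoff")
    counts = {"pp3": 0, "indeterminate": 0, "bp4": 0, "missing": 0}
    for s in scores:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            counts["missing"] += 1
        elif s >= pp3:
            counts["pp3"] += 1
        elif s <= bp4:
            counts["bp4"] += 1
        else:
            counts["indeterminate"] += 1
    return counts
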