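"""Filtering of recurrent somatic mutation tables into the analysis set.

Two filters are provided: the primary hotspot filter (missense-only, with
conservative exclusion of mutations whose germline counterpart carries a
conflicting or risk-factor classification) and a COSMIC-style filter that
retains highly recurrent mutations absent from the hotspot catalogue. A
tumor-sample-count ROC utility supports choosing the recurrence cutoff.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .variants import ClassLabel, GermlineRecord, HotspotMutation

_EXCLUDED_LABELS = frozenset({ClassLabel.CIP, ClassLabel.RISK_FACTOR})


@dataclass
class FilterReport:
    """Telescoping accounting of the hotspot filter.

    ``n_retained`` always equals ``n_missense - n_excluded_cip_risk`` and
    ``n_missense <= n_input``.
    """

    n_input: int
    n_missense: int
    n_excluded_cip_risk: int
    n_retained: int
    per_gene_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_missense > self.n_input:
            raise ValueError("n_missense cannot exceed n_input")
        if self.n_retained != self.n_missense - self.n_excluded_cip_risk:
            raise ValueError("FilterReport identity violated")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_missense": self.n_missense,
            "n_excluded_cip_risk": self.n_excluded_cip_risk,
            "n_retained": self.n_retained,
            "per_gene_counts": dict(self.per_gene_counts),
        }


@dataclass
class RocResult:
    """ROC over integer recurrence counts; AUC via the rank-sum identity."""

    points: list[tuple[float, float, float]]  # (fpr, tpr, threshold), sorted by threshold
    auc: float
    optimal_threshold: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC outside [0,1]")


def filter_hotspots(
    mutations: Sequence[HotspotMutation],
    germline: Sequence[GermlineRecord],
    n_non_missense: int = 0,
) -> tuple[list[HotspotMutation], FilterReport]:
    """Restrict to missense mutations and drop those overlapping CIP/risk-factor
    germline records.

    ``mutations`` are already missense by type invariant; rows rejected at
    parse time for not being missense are accounted through
    ``n_non_missense`` so the report reflects the full input table.
    """
    excluded_keys = {
        g.variant.key for g in germline if g.label in _EXCLUDED_LABELS
    }
    retained = [h for h in mutations if h.variant.key not in excluded_keys]
    n_missense = len(mutations)
    report = FilterReport(
        n_input=n_missense + n_non_missense,
        n_missense=n_missense,
        n_excluded_cip_risk=n_missense - len(retained),
        n_retained=len(retained),
        per_gene_counts=dict(Counter(h.change.gene for h in retained)),
    )
    return retained, report


def sample_count_roc(
    counts: Sequence[int],
    labels: Sequence[int],
    min_count: Optional[int] = None,
) -> RocResult:
    """ROC of tumor-sample counts for discriminating LP/P from other variants.

    AUC is the Mann-Whitney statistic U/(n1*n0), giving tied counts half
    credit — the natural convention for heavily tied integer counts. When
    ``min_count`` is given, pairs with count <= min_count are removed first.
    The optimal threshold maximises the Youden index (tpr - fpr).
    """
    counts = np.asarray(counts, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if counts.shape != labels.shape:
        raise ValueError("counts and labels must have the same length")
    if min_count is not None:
        keep = counts > min_count
        counts, labels = counts[keep], labels[keep]
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC undefined: need at least one example of each class")

    u = stats.mannwhitneyu(counts[labels == 1], counts[labels == 0], alternative="two-sided")
    auc = float(u.statistic) / (n1 * n0)

    # threshold sweep over unique counts: predict positive iff count >= t
    thresholds = np.unique(counts)
    points = []
    best = (-np.inf, thresholds[0])
    for t in thresholds:
        pred = counts >= t
        tpr = float((pred & (labels == 1)).sum()) / n1
        fpr = float((pred & (labels == 0)).sum()) / n0
        points.append((fpr, tpr, float(t)))
        youden = tpr - fpr
        if youden > best[0]:
            best = (youden, float(t))
    return RocResult(points=points, auc=auc, optimal_threshold=best[1])


@dataclass(frozen=True)
class CosmicRow:
    """A pre-aggregated COSMIC-style coding mutation row."""

    gene: str
    protein_change: str  # one-letter missense string, e.g. G12D
    sample_count: int
    confirmed_somatic: bool = True
    missense: bool = True


@dataclass
class CosmicSummary:
    n_input: int
    n_retained: int
    genes: list[str]
    new_genes: list[str]  # genes absent from the hotspot catalogue

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_genes": len(self.genes),
            "n_new_genes": len(self.new_genes),
            "new_genes": list(self.new_genes),
        }


def filter_cosmic(
    rows: Sequence[CosmicRow],
    hotspots: Sequence[HotspotMutation],
    min_samples: int = 25,
) -> tuple[list[CosmicRow], CosmicSummary]:
    """Retain confirmed-somatic missense rows recurring in strictly more than
    ``min_samples`` tumors and absent from the hotspot set.

    Absence is tested at the (gene, protein-change) level, matching how
    hotspots are defined. Genes not represented in the hotspot catalogue at
    all are reported separately as "new" genes.
    """
    hotspot_changes = {
        (h.change.gene, f"{h.change.ref_aa}{h.change.residue}{h.change.alt_aa}")
        for h in hotspots
    }
    hotspot_genes = {h.change.gene for h in hotspots}
    retained = [
        r
        for r in rows
        if r.confirmed_somatic
        and r.missense
        and r.sample_count > min_samples
        and (r.gene, r.protein_change) not in hotspot_changes
    ]
    genes = sorted({r.gene for r in retained})
    summary = CosmicSummary(
        n_input=len(rows),
        n_retained=len(retained),
        genes=genes,
        new_genes=[g for g in genes if g not in hotspot_genes],
    )
    return retained, summary
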