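"""Shared fixtures: programmatic record builders and small synthetic cohorts."""

from __future__ import annotations

import itertools

import pytest

from duality import (
    ClassLabel,
    GenomicVariant,
    GermlineRecord,
    HotspotMutation,
    ProteinChange,
    SyntheticConfig,
    annotate_overlap,
    generate_cohort,
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_germline(
    i: int,
    label: ClassLabel,
    overlap: bool | None = None,
    gene: str | None = None,
    **kwargs,
) -> GermlineRecord:
    """A syntactically valid germline record with unique coordinates."""
    gene = gene or f"G{i % 40:03d}"
    kwargs.setdefault("phylop_mam20", 2.0 + 0.01 * i)
    kwargs.setdefault("phylop_vert7", 1.5 + 0.01 * i)
    kwargs.setdefault("phastcons_mam20", 0.5)
    kwargs.setdefault("phastcons_vert7", 0.5)
    rec = GermlineRecord(
        variant=GenomicVariant(chrom=str(i % 22 + 1), pos=10_000 + i, ref="A", alt="G"),
        change=ProteinChange(
            gene=gene, residue=i + 1, ref_aa=_AA[i % 20], alt_aa=_AA[(i + 1) % 20]
        ),
        label=label,
        **kwargs,
    )
    if overlap is not None:
        rec = rec.with_overlap(overlap, 5 if overlap else 0, 9 if overlap else 0)
    return rec


def make_hotspot(i: int, gene: str | None = None, counts=(5, 9)) -> HotspotMutation:
    return HotspotMutation(
        variant=GenomicVariant(chrom=str(i % 22 + 1), pos=10_000 + i, ref="A", alt="G"),
        change=ProteinChange(
            gene=gene or f"G{i % 40:03d}",
            residue=i + 1,
            ref_aa=_AA[i % 20],
            alt_aa=_AA[(i + 1) % 20],
        ),
        tumor_count_change=counts[0],
        tumor_count_residue=counts[1],
    )


def records_from_counts(overlap_by_class: dict, total_by_class: dict):
    """Expand class-level summary counts into annotated germline records."""
    records = []
    counter = itertools.count()
    for label, total in total_by_class.items():
        n_overlap = overlap_by_class.get(label, 0)
        for j in range(total):
            records.append(make_germline(next(counter), label, overlap=j < n_overlap))
    return records


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with annotation, reused across model tests."""
    config = SyntheticConfig(seed=11, n_genes=30, variants_per_gene=(120.0, 1.2))
    hotspots, germline, truth = generate_cohort(config)
    annotated = annotate_overlap(germline, hotspots, mode="nucleotide")
    return hotspots, annotated, truth
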