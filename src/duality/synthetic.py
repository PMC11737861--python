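"""Synthetic hotspot/germline cohort generator.

Emulates the statistical structure of the real inputs — per-gene variant
counts, clinical-class proportions, class-conditional REVEL and
conservation score distributions, hotspot overlap with a controllable
target odds ratio, and tumor-sample recurrence counts elevated for
pathogenic overlapping variants — so every pipeline stage is testable
without downloads and parameter recovery can be asserted.

Overlap enrichment is parameterised on the odds scale: non-LP/P variants
overlap a hotspot with probability ``overlap_base_rate`` and LP/P variants
with the probability whose odds are ``exp(target_log_or)`` times larger,
so the population log odds ratio of (overlap, LP/P) equals the target
exactly. Default class proportions echo a ClinVar-style composition
(6.1% LP/P, 88.5% VUS, 5.4% LB/B). The four conservation scores share a
latent per-variant constraint draw, making them positively correlated as
real conservation tracks are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .acmg import AcmgCode, Classification, acmg_combine
from .variants import (
    AlleleOrigin,
    ClassLabel,
    GenomicVariant,
    GermlineRecord,
    HotspotMutation,
    ProteinChange,
)

_CLASS_ORDER = (ClassLabel.LP_P, ClassLabel.VUS, ClassLabel.LB_B, ClassLabel.CIP)

_AA = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for cohort generation.

    ``variants_per_gene`` gives negative-binomial (mean, dispersion);
    ``revel_by_class`` maps class to Beta(alpha, beta) parameters;
    ``conservation_effect`` shifts the latent constraint per class;
    ``tumor_count_geom_p`` is the zero-truncated geometric success
    probability for tumor counts, divided by ``pathogenic_count_multiplier``
    for LP/P overlapping variants (larger multiplier, larger counts).
    """

    seed: int = 0
    n_genes: int = 216
    variants_per_gene: tuple[float, float] = (238.0, 1.2)  # (mean, dispersion)
    class_proportions: tuple[float, float, float, float] = (0.0613, 0.8850, 0.0537, 0.0)
    target_log_or: float = math.log(28.3)
    overlap_base_rate: float = 0.0055
    revel_by_class: dict = field(
        default_factory=lambda: {
            ClassLabel.LP_P: (8.0, 2.0),
            ClassLabel.VUS: (1.5, 2.5),
            ClassLabel.LB_B: (1.5, 8.0),
            ClassLabel.CIP: (2.0, 2.0),
        }
    )
    conservation_effect: dict = field(
        default_factory=lambda: {
            ClassLabel.LP_P: 1.5,
            ClassLabel.VUS: 0.0,
            ClassLabel.LB_B: -1.5,
            ClassLabel.CIP: 0.0,
        }
    )
    tumor_count_geom_p: float = 0.25
    pathogenic_count_multiplier: float = 4.0
    duplicate_change_rate: float = 0.02
    extra_hotspot_factor: float = 2.5  # hotspots absent from the germline table

    def __post_init__(self) -> None:
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if not (0.0 < self.overlap_base_rate < 1.0):
            raise ValueError("overlap_base_rate must lie in (0, 1)")
        # on the odds scale the enriched probability is always < 1, but a
        # degenerate base rate can still push it numerically to 1
        if self.overlap_probability_lpp >= 1.0:
            raise ValueError("base rate and log-OR imply overlap probability >= 1")

    @property
    def overlap_probability_lpp(self) -> float:
        odds = self.overlap_base_rate / (1.0 - self.overlap_base_rate)
        odds *= math.exp(self.target_log_or)
        return odds / (1.0 + odds)


def _zt_geometric(rng: np.random.Generator, p: float, size: int) -> np.ndarray:
    """Zero-truncated geometric draw (support starting at 1)."""
    return rng.geometric(min(max(p, 1e-3), 1.0), size=size)


def generate_cohort_frame(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Vectorised core: returns (hotspot frame, germline frame, truth record).

    The germline frame carries the realised ``overlap`` assignment (the
    generator's truth); the corresponding records emitted by
    :func:`generate_cohort` are deliberately un-annotated so the pipeline's
    own overlap annotation can be exercised against the truth.
    """
    rng = np.random.default_rng(config.seed)
    mean, disp = config.variants_per_gene
    p_nb = disp / (disp + mean)
    per_gene = np.maximum(rng.negative_binomial(disp, p_nb, size=config.n_genes), 1)
    genes = np.repeat([f"GENE{i:04d}" for i in range(config.n_genes)], per_gene)
    n = len(genes)

    class_idx = rng.choice(len(_CLASS_ORDER), size=n, p=list(config.class_proportions))
    is_lpp = class_idx == 0

    p_overlap = np.where(is_lpp, config.overlap_probability_lpp, config.overlap_base_rate)
    overlap = rng.random(n) < p_overlap

    alpha = np.array([config.revel_by_class[_CLASS_ORDER[i]][0] for i in class_idx])
    beta = np.array([config.revel_by_class[_CLASS_ORDER[i]][1] for i in class_idx])
    revel = rng.beta(alpha, beta)

    shift = np.array([config.conservation_effect[_CLASS_ORDER[i]] for i in class_idx])
    z = rng.normal(shift, 1.0)
    phylop_mam20 = 2.0 + 1.5 * z + rng.normal(0, 0.8, size=n)
    phylop_vert7 = 1.5 + 1.2 * z + rng.normal(0, 0.8, size=n)
    phastcons_mam20 = np.clip(0.6 + 0.2 * z + rng.normal(0, 0.15, size=n), 0.0, 1.0)
    phastcons_vert7 = np.clip(0.55 + 0.2 * z + rng.normal(0, 0.15, size=n), 0.0, 1.0)

    geom_p = np.where(
        is_lpp & overlap,
        config.tumor_count_geom_p / config.pathogenic_count_multiplier,
        config.tumor_count_geom_p,
    )
    count_change = np.where(overlap, rng.geometric(np.clip(geom_p, 1e-3, 1.0)), 0)
    count_residue = count_change + np.where(
        overlap, rng.geometric(0.5, size=n) - 1, 0
    )

    # unique coordinates and protein changes
    gene_codes = pd.factorize(genes)[0]
    chrom = (gene_codes % 22) + 1
    pos = 1_000_000 + np.arange(n) * 7 + gene_codes * 1_000_000
    residue = np.arange(n) % 800 + 1
    ref_aa_idx = rng.integers(0, len(_AA), size=n)
    alt_aa_idx = (ref_aa_idx + rng.integers(1, len(_AA), size=n)) % len(_AA)
    ref_nt_idx = rng.integers(0, 4, size=n)
    alt_nt_idx = (ref_nt_idx + rng.integers(1, 4, size=n)) % 4

    df = pd.DataFrame(
        {
            "gene": genes,
            "chrom": chrom.astype(str),
            "pos": pos,
            "ref": np.array(list(_NT))[ref_nt_idx],
            "alt": np.array(list(_NT))[alt_nt_idx],
            "residue": residue,
            "ref_aa": np.array(list(_AA))[ref_aa_idx],
            "alt_aa": np.array(list(_AA))[alt_aa_idx],
            "class_idx": class_idx,
            "label": [_CLASS_ORDER[i].value for i in class_idx],
            "overlap": overlap,
            "revel": revel,
            "phylop_mam20": phylop_mam20,
            "phylop_vert7": phylop_vert7,
            "phastcons_mam20": phastcons_mam20,
            "phastcons_vert7": phastcons_vert7,
            "tumor_count_change": count_change,
            "tumor_count_residue": count_residue,
        }
    )

    # synonymous-at-protein-level duplicates: a second nucleotide change
    # causing the same amino-acid change (same class and overlap status)
    if config.duplicate_change_rate > 0:
        dup_mask = rng.random(n) < config.duplicate_change_rate
        dup = df[dup_mask].copy()
        dup["pos"] = dup["pos"] + 1
        swap = dup["ref"].copy()
        dup["ref"] = dup["alt"]
        dup["alt"] = swap
        df = pd.concat([df, dup], ignore_index=True)

    # hotspot table: one entry per overlapping germline variant, plus
    # hotspots with no germline counterpart
    hs = df[df["overlap"]][
        ["gene", "chrom", "pos", "ref", "alt", "residue", "ref_aa", "alt_aa",
         "tumor_count_change", "tumor_count_residue"]
    ].copy()
    n_extra = int(round(config.extra_hotspot_factor * len(hs)))
    if n_extra > 0:
        extra_genes = rng.choice(
            [f"GENE{i:04d}" for i in range(config.n_genes)], size=n_extra
        )
        extra_codes = pd.factorize(extra_genes)[0]
        e_ref_aa = rng.integers(0, len(_AA), size=n_extra)
        e_alt_aa = (e_ref_aa + rng.integers(1, len(_AA), size=n_extra)) % len(_AA)
        e_ref_nt = rng.integers(0, 4, size=n_extra)
        e_alt_nt = (e_ref_nt + rng.integers(1, 4, size=n_extra)) % 4
        counts = _zt_geometric(rng, config.tumor_count_geom_p, n_extra)
        extra = pd.DataFrame(
            {
                "gene": extra_genes,
                "chrom": ((extra_codes % 22) + 1).astype(str),
                "pos": 500_000_000 + np.arange(n_extra) * 3,
                "ref": np.array(list(_NT))[e_ref_nt],
                "alt": np.array(list(_NT))[e_alt_nt],
                "residue": np.arange(n_extra) % 800 + 1,
                "ref_aa": np.array(list(_AA))[e_ref_aa],
                "alt_aa": np.array(list(_AA))[e_alt_aa],
                "tumor_count_change": counts,
                "tumor_count_residue": counts + rng.geometric(0.5, size=n_extra) - 1,
            }
        )
        hs = pd.concat([hs, extra], ignore_index=True)

    truth = {
        "seed": config.seed,
        "n_variants": int(len(df)),
        "n_genes": int(df["gene"].nunique()),
        "target_log_or": config.target_log_or,
        "overlap_base_rate": config.overlap_base_rate,
        "overlap_probability_lpp": config.overlap_probability_lpp,
        "class_counts": {
            _CLASS_ORDER[i].value: int((df["class_idx"] == i).sum())
            for i in range(len(_CLASS_ORDER))
        },
        "overlap_counts": {
            _CLASS_ORDER[i].value: int(df.loc[df["class_idx"] == i, "overlap"].sum())
            for i in range(len(_CLASS_ORDER))
        },
    }
    return hs, df, truth


def cohort_class_counts(germline_df: pd.DataFrame) -> tuple[dict, dict]:
    """(overlap counts per class, total counts per class) from a cohort frame,
    ready for contingency construction from summary counts."""
    overlap_by_class: dict[ClassLabel, int] = {}
    total_by_class: dict[ClassLabel, int] = {}
    for label_value, sub in germline_df.groupby("label"):
        lbl = ClassLabel(label_value)
        total_by_class[lbl] = int(len(sub))
        overlap_by_class[lbl] = int(sub["overlap"].sum())
    return overlap_by_class, total_by_class


def _germline_records(df: pd.DataFrame) -> list[GermlineRecord]:
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GermlineRecord(
                variant=GenomicVariant(row.chrom, int(row.pos), row.ref, row.alt),
                change=ProteinChange(row.gene, int(row.residue), row.ref_aa, row.alt_aa),
                label=ClassLabel(row.label),
                allele_origin=AlleleOrigin.GERMLINE,
                revel=float(row.revel),
                phylop_mam20=float(row.phylop_mam20),
                phylop_vert7=float(row.phylop_vert7),
                phastcons_mam20=float(row.phastcons_mam20),
                phastcons_vert7=float(row.phastcons_vert7),
            )
        )
    return records


def _hotspot_records(hs: pd.DataFrame) -> list[HotspotMutation]:
    records = []
    for row in hs.itertuples(index=False):
        records.append(
            HotspotMutation(
                variant=GenomicVariant(row.chrom, int(row.pos), row.ref, row.alt),
                change=ProteinChange(row.gene, int(row.residue), row.ref_aa, row.alt_aa),
                tumor_count_change=max(int(row.tumor_count_change), 1),
                tumor_count_residue=max(
                    int(row.tumor_count_residue), int(row.tumor_count_change), 1
                ),
            )
        )
    return records


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[HotspotMutation], list[GermlineRecord], dict]:
    """Generate a hotspot catalogue and an (un-annotated) germline cohort.

    Identical seeds give identical output. The truth record stores all
    realised parameters, including per-class overlap counts.
    """
    hs, df, truth = generate_cohort_frame(config)
    return _hotspot_records(hs), _germline_records(df), truth


#: evidence-code sets that classify as uncertain, mixed by the generator
_UNCERTAIN_SETS: tuple[tuple[str, ...], ...] = (
    ("PM2",),
    ("PM2", "PP3"),
    ("PP3",),
    ("PM1", "PM2"),
    ("PS1",),
    ("PS1", "PP3"),
    ("PM2", "PP1", "PP3"),
    ("PP1", "PP2", "PP3"),
    ("PM1", "PM2", "PP3"),
)


def generate_acmg_codebook(n_vus: int, seed: int = 0) -> dict[str, list[AcmgCode]]:
    """Emit ``n_vus`` variants with evidence-code sets that all classify as
    uncertain — the input population for the one-more-criterion upgrade
    simulation."""
    if n_vus < 0:
        raise ValueError("n_vus must be >= 0")
    rng = np.random.default_rng(seed)
    book: dict[str, list[AcmgCode]] = {}
    for i in range(n_vus):
        codes = [AcmgCode(c) for c in _UNCERTAIN_SETS[rng.integers(len(_UNCERTAIN_SETS))]]
        assert acmg_combine(codes) is Classification.UNCERTAIN
        book[f"VUS{i:05d}"] = codes
    return book


def generate_test_split(
    cohort: Sequence[GermlineRecord], fraction: float, seed: int = 0
) -> tuple[list[GermlineRecord], list[GermlineRecord]]:
    """Split a cohort into training and held-out sets by grouped amino-acid
    change, so no protein change appears on both sides."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    keys = sorted({g.change.key for g in cohort})
    rng = np.random.default_rng(seed)
    rng.shuffle(keys)
    n_train = round(fraction * len(keys))
    if n_train == 0 or n_train == len(keys):
        raise ValueError("fraction yields an empty side")
    train_keys = set(keys[:n_train])
    train = [g for g in cohort if g.change.key in train_keys]
    held = [g for g in cohort if g.change.key not in train_keys]
    return train, held
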