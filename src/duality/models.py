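"""Training-set construction and the two supervised pathogenicity models.

The training set is built from overlap-annotated germline records: distinct
nucleotide variants causing the same amino-acid change are grouped, VUS
with REVEL above the benign-supporting cutoff (0.29) are excluded, the
remaining VUS are re-labelled benign with prior weight 1 - REVEL (a VUS
with little in-silico support for pathogenicity counts almost as a full
benign example), and genes are restricted to those with hotspot-overlapping
variants. Two models are fit on eight predictors (hotspot overlap,
change- and residue-level tumor-sample counts, four conservation scores,
and — for the logistic model only — the gene as a categorical factor):
a weighted maximum-likelihood logistic regression and a 350-tree random
forest with four candidate variables per split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier

from .variants import ClassLabel, GermlineRecord

#: numeric predictors shared by both models; the logistic model adds the gene factor
DEFAULT_FEATURES = (
    "overlap",
    "tumor_count_change",
    "tumor_count_residue",
    "phylop_mam20",
    "phylop_vert7",
    "phastcons_mam20",
    "phastcons_vert7",
)

CONSERVATION_FEATURES = (
    "phylop_mam20",
    "phylop_vert7",
    "phastcons_mam20",
    "phastcons_vert7",
)

#: label precedence when grouped nucleotide variants disagree
LABEL_PRECEDENCE = (ClassLabel.LP_P, ClassLabel.LB_B, ClassLabel.VUS)


@dataclass(frozen=True)
class TrainingExample:
    """One grouped amino-acid change with features, binary label and weight."""

    gene: str
    residue: int
    ref_aa: str
    alt_aa: str
    overlap: int
    tumor_count_change: int
    tumor_count_residue: int
    phylop_mam20: float
    phylop_vert7: float
    phastcons_mam20: float
    phastcons_vert7: float
    label: int  # 1 = LP/P, 0 = LB/B or re-labelled VUS
    weight: float  # 1 for LP/P and true LB/B, 1 - REVEL for re-labelled VUS

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight must lie in (0, 1], got {self.weight}")
        if self.overlap == 0 and (self.tumor_count_change or self.tumor_count_residue):
            raise ValueError("non-overlapping variants must have zero tumor counts")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.gene, self.residue, self.ref_aa, self.alt_aa)


@dataclass
class ConstructionReport:
    """Telescoping accounting of training-set construction: each step's
    output is the next step's input."""

    n_input: int = 0
    n_non_germline_dropped: int = 0
    n_groups: int = 0
    n_class_dropped: int = 0  # CIP / risk-factor / other labels
    n_vus_high_revel_dropped: int = 0
    n_vus_missing_revel_dropped: int = 0
    n_gene_dropped: int = 0
    n_missing_feature_dropped: int = 0
    n_final: int = 0
    n_overlap_present: int = 0
    n_label_pathogenic: int = 0
    genes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def build_training_set(
    germline: Sequence[GermlineRecord],
    revel_cutoff: float = 0.29,
    gene_whitelist: Optional[Sequence[str]] = None,
) -> tuple[list[TrainingExample], ConstructionReport]:
    """Construct the grouped, re-weighted training set from annotated records.

    ``gene_whitelist`` defaults to the genes carrying at least one
    hotspot-overlapping grouped variant (how the 66-gene restriction is
    defined); pass a list to override, an empty list is an error. Grouping
    ties are resolved by label precedence LP/P > LB/B > VUS, the maximum
    REVEL, and the presence of any overlap.
    """
    if gene_whitelist is not None and len(gene_whitelist) == 0:
        raise ValueError("gene whitelist is empty")
    report = ConstructionReport(n_input=len(germline))

    from .variants import AlleleOrigin

    germline = [g for g in germline if g.allele_origin is AlleleOrigin.GERMLINE]
    report.n_non_germline_dropped = report.n_input - len(germline)

    # group distinct nucleotide variants causing the same amino-acid change
    groups: dict[tuple, list[GermlineRecord]] = {}
    for g in germline:
        if g.overlaps_hotspot is None:
            raise ValueError("records must be overlap-annotated before training")
        groups.setdefault(g.change.key, []).append(g)
    report.n_groups = len(groups)

    precedence = {lbl: i for i, lbl in enumerate(LABEL_PRECEDENCE)}
    grouped: list[dict] = []
    n_class_dropped = 0
    for key, members in groups.items():
        labels = [m.label for m in members if m.label in precedence]
        if not labels:
            n_class_dropped += 1
            continue
        label = min(labels, key=lambda l: precedence[l])
        revels = [m.revel for m in members if m.revel is not None]
        grouped.append(
            {
                "key": key,
                "label": label,
                "revel": max(revels) if revels else None,
                "overlap": int(any(m.overlaps_hotspot for m in members)),
                "tumor_count_change": max(m.tumor_count_change for m in members),
                "tumor_count_residue": max(m.tumor_count_residue for m in members),
                "phylop_mam20": _first_score(members, "phylop_mam20"),
                "phylop_vert7": _first_score(members, "phylop_vert7"),
                "phastcons_mam20": _first_score(members, "phastcons_mam20"),
                "phastcons_vert7": _first_score(members, "phastcons_vert7"),
            }
        )
    report.n_class_dropped = n_class_dropped

    kept: list[dict] = []
    for row in grouped:
        if row["label"] is ClassLabel.VUS:
            if row["revel"] is None:
                report.n_vus_missing_revel_dropped += 1
                continue
            if row["revel"] > revel_cutoff:
                report.n_vus_high_revel_dropped += 1
                continue
        kept.append(row)

    if gene_whitelist is None:
        gene_whitelist = sorted({r["key"][0] for r in kept if r["overlap"]})
        if not gene_whitelist:
            raise ValueError("no overlapping variants; cannot derive a gene whitelist")
    whitelist = set(gene_whitelist)
    n_before_gene = len(kept)
    kept = [r for r in kept if r["key"][0] in whitelist]
    report.n_gene_dropped = n_before_gene - len(kept)

    examples: list[TrainingExample] = []
    for row in kept:
        scores = {f: row[f] for f in CONSERVATION_FEATURES}
        if any(v is None for v in scores.values()):
            report.n_missing_feature_dropped += 1
            continue
        gene, residue, ref_aa, alt_aa = row["key"]
        is_vus = row["label"] is ClassLabel.VUS
        examples.append(
            TrainingExample(
                gene=gene,
                residue=residue,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
                overlap=row["overlap"],
                tumor_count_change=row["tumor_count_change"] if row["overlap"] else 0,
                tumor_count_residue=row["tumor_count_residue"] if row["overlap"] else 0,
                label=1 if row["label"] is ClassLabel.LP_P else 0,
                weight=(1.0 - row["revel"]) if is_vus else 1.0,
                **scores,
            )
        )
    report.n_final = len(examples)
    report.n_overlap_present = sum(e.overlap for e in examples)
    report.n_label_pathogenic = sum(e.label for e in examples)
    report.genes = sorted(whitelist)
    return examples, report


def _first_score(members, name):
    for m in members:
        v = getattr(m, name)
        if v is not None:
            return v
    return None


@dataclass
class ModelFit:
    """A fitted pathogenicity model with per-example scores and diagnostics."""

    kind: str  # "LRM" or "RFM"
    hyperparams: dict
    scores: np.ndarray
    diagnostics: dict
    feature_names: list[str]
    gene_levels: Optional[list[str]] = None
    params: Optional[pd.Series] = None  # LRM coefficients
    seed: Optional[int] = None
    _forest: Optional[RandomForestClassifier] = None

    def coefficients_json(self) -> dict:
        if self.params is None:
            raise ValueError("only the logistic model has serialisable coefficients")
        return {
            "kind": self.kind,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "gene_levels": self.gene_levels,
            "features": self.feature_names,
            "diagnostics": {k: float(v) for k, v in self.diagnostics.items()},
        }


def _feature_frame(items, features: Sequence[str]) -> pd.DataFrame:
    rows = []
    for it in items:
        if isinstance(it, GermlineRecord):
            if it.overlaps_hotspot is None:
                raise ValueError("records must be overlap-annotated before scoring")
            row = {
                "gene": it.change.gene,
                "overlap": int(it.overlaps_hotspot),
                "tumor_count_change": it.tumor_count_change,
                "tumor_count_residue": it.tumor_count_residue,
                "phylop_mam20": it.phylop_mam20,
                "phylop_vert7": it.phylop_vert7,
                "phastcons_mam20": it.phastcons_mam20,
                "phastcons_vert7": it.phastcons_vert7,
            }
        else:
            row = {
                "gene": it.gene,
                "overlap": it.overlap,
                "tumor_count_change": it.tumor_count_change,
                "tumor_count_residue": it.tumor_count_residue,
                "phylop_mam20": it.phylop_mam20,
                "phylop_vert7": it.phylop_vert7,
                "phastcons_mam20": it.phastcons_mam20,
                "phastcons_vert7": it.phastcons_vert7,
            }
        rows.append(row)
    df = pd.DataFrame(rows)
    for f in features:
        if f not in df.columns:
            raise ValueError(f"missing feature: {f}")
        if df[f].isna().any():
            raise ValueError(f"missing feature: {f}")
    return df


def _lrm_design(
    df: pd.DataFrame, features: Sequence[str], gene_levels: Optional[list[str]]
) -> pd.DataFrame:
    X = df[list(features)].astype(float)
    X.insert(0, "intercept", 1.0)
    if gene_levels is not None:
        unseen = sorted(set(df["gene"]) - set(gene_levels))
        if unseen:
            raise ValueError(f"gene(s) outside the trained levels: {', '.join(unseen)}")
        # treatment contrasts: alphabetically first gene is the reference level
        for level in gene_levels[1:]:
            X[f"gene[{level}]"] = (df["gene"] == level).astype(float)
    return X


def fit_lrm(
    training: Sequence[TrainingExample],
    features: Sequence[str] = DEFAULT_FEATURES,
    include_gene: bool = True,
    weights: Optional[Sequence[float]] = None,
) -> ModelFit:
    """Weighted maximum-likelihood logistic regression.

    Prior weights (taken from the examples unless overridden via
    ``weights``) enter the Bernoulli log-likelihood multiplicatively, so a
    fit with integer weights is identical to one on a row-replicated data
    set. Diagnostics report the AIC and McFadden's pseudo-R-squared,
    1 - l_model / l_null with the null being the weighted intercept-only fit.
    """
    y = np.array([e.label for e in training], dtype=float)
    w = (
        np.asarray(weights, dtype=float)
        if weights is not None
        else np.array([e.weight for e in training], dtype=float)
    )
    if w.shape != y.shape or (w <= 0).any():
        raise ValueError("weights must be positive and match the training length")
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    df = _feature_frame(training, features)
    gene_levels = sorted(df["gene"].unique()) if include_gene else None
    X = _lrm_design(df, features, gene_levels)
    model = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w)
    try:
        res = model.fit(maxiter=200)
    except Exception as exc:  # pragma: no cover - non-convergence surface
        raise RuntimeError(f"logistic regression failed to converge: {exc}") from exc
    if not res.converged:
        warnings.warn("logistic regression hit the iteration cap (possible separation)")
    null = sm.GLM(y, np.ones((len(y), 1)), family=sm.families.Binomial(), freq_weights=w).fit()
    mcfadden = 1.0 - res.llf / null.llf
    return ModelFit(
        kind="LRM",
        hyperparams={"features": list(features), "include_gene": include_gene},
        scores=np.asarray(res.fittedvalues, dtype=float),
        diagnostics={"mcfadden_r2": float(mcfadden), "aic": float(res.aic)},
        feature_names=list(X.columns),
        gene_levels=gene_levels,
        params=pd.Series(res.params.values, index=X.columns),
    )


def fit_rfm(
    training: Sequence[TrainingExample],
    n_trees: int = 350,
    vars_per_split: int = 4,
    seed: int = 0,
    features: Sequence[str] = DEFAULT_FEATURES,
    use_weights: bool = False,
) -> ModelFit:
    """Classification random forest (gene factor excluded).

    Per-example probability is the fraction of trees voting pathogenic; the
    out-of-bag error uses out-of-bag votes only. Example weights are ignored
    by default, matching the reference forest implementation; enable
    ``use_weights`` to pass them as sample weights.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if vars_per_split > len(features):
        raise ValueError("vars_per_split exceeds the number of features")
    y = np.array([e.label for e in training], dtype=int)
    if len(set(y)) < 2:
        raise ValueError("training data must contain both classes")
    df = _feature_frame(training, features)
    X = df[list(features)].astype(float).to_numpy()
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=vars_per_split,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    sample_weight = (
        np.array([e.weight for e in training], dtype=float) if use_weights else None
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*out-of-bag.*")
        rf.fit(X, y, sample_weight=sample_weight)
    scores = _vote_fraction(rf, X)
    return ModelFit(
        kind="RFM",
        hyperparams={"n_trees": n_trees, "vars_per_split": vars_per_split,
                     "features": list(features)},
        scores=scores,
        diagnostics={"oob_error": float(1.0 - rf.oob_score_)},
        feature_names=list(features),
        seed=seed,
        _forest=rf,
    )


def _vote_fraction(rf: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    pos = list(rf.classes_).index(1)
    votes = np.zeros(len(X))
    for tree in rf.estimators_:
        votes += (tree.predict(X) == rf.classes_[pos]).astype(float)
    return votes / len(rf.estimators_)


def predict(model: ModelFit, variants) -> np.ndarray:
    """Score annotated germline records (or training examples) with a fitted
    model, returning probabilities of pathogenicity in [0, 1].

    The logistic model refuses genes outside its trained levels — it is
    only defined on the gene set it was fit to.
    """
    features = (
        model.hyperparams["features"] if model.kind == "LRM" else model.feature_names
    )
    df = _feature_frame(variants, features)
    if model.kind == "LRM":
        X = _lrm_design(df, features, model.gene_levels)
        X = X[model.params.index]
        eta = X.to_numpy(dtype=float) @ model.params.to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))
    if model.kind == "RFM":
        return _vote_fraction(model._forest, df[list(features)].astype(float).to_numpy())
    raise ValueError(f"unknown model kind {model.kind!r}")
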