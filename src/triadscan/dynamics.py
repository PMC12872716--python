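"""Cross-stage stability of bias categories and cross-genotype comparisons.

A triad is *stable* in a genotype when its category is defined and
identical at every developmental stage.  Genotype-unique stable-biased
sets (e.g. triads stably B-suppressed in the recalcitrant cultivar but not
the responsive one) are intersected with DEG tables via the focal
subgenome's gene ids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .triads import CATEGORIES, UNDEFINED

__all__ = [
    "TransitionSummary",
    "StableBiasSet",
    "transition_matrices",
    "stable_triads",
    "overall_unchanged_fraction",
    "per_category_stability",
    "average_stability",
    "unique_stable_biased",
    "deg_overlap",
]

_ALL_LABELS = CATEGORIES + (UNDEFINED,)


def _stage_table(assignment: pd.DataFrame, genotype: str) -> pd.DataFrame:
    """Wide triad x stage category table for one genotype."""
    sub = assignment[assignment["genotype"] == genotype]
    if sub.empty:
        raise ValueError(f"no assignments for genotype {genotype!r}")
    stages = list(sub["stage"].cat.categories) \
        if isinstance(sub["stage"].dtype, pd.CategoricalDtype) \
        else list(dict.fromkeys(sub["stage"]))
    wide = sub.pivot(index="triad_id", columns="stage", values="category")
    wide = wide.reindex(columns=stages)
    missing = [s for s in stages if wide[s].isna().all()]
    if missing:
        raise ValueError(f"genotype {genotype!r} missing stage(s) {missing}")
    return wide.fillna(UNDEFINED)


@dataclass
class TransitionSummary:
    """Stage-pair transition counts and stability fractions for a genotype."""
    genotype: str
    matrices: dict            # (stage_from, stage_to) -> 8x8 count DataFrame
    per_category: pd.DataFrame  # category x stage stability fractions
    overall_unchanged: float


@dataclass
class StableBiasSet:
    """Triads stable in one category for a genotype, with focal gene ids."""
    genotype: str
    category: str
    triad_ids: frozenset
    focal_genes: frozenset


def transition_matrices(assignment: pd.DataFrame, genotype: str) -> dict:
    """8x8 category count matrices for each consecutive stage pair."""
    wide = _stage_table(assignment, genotype)
    stages = list(wide.columns)
    out = {}
    for s1, s2 in zip(stages[:-1], stages[1:]):
        mat = pd.crosstab(wide[s1], wide[s2]).reindex(
            index=_ALL_LABELS, columns=_ALL_LABELS, fill_value=0)
        mat.index.name, mat.columns.name = "from", "to"
        out[(s1, s2)] = mat
    return out


def stable_triads(assignment: pd.DataFrame, genotype: str) -> dict[str, frozenset]:
    """Map category -> triads holding that category at every stage."""
    wide = _stage_table(assignment, genotype)
    first = wide.iloc[:, 0]
    same = wide.eq(first, axis=0).all(axis=1) & (first != UNDEFINED)
    out: dict[str, frozenset] = {c: frozenset() for c in CATEGORIES}
    stable_first = first[same]
    for cat in stable_first.unique():
        out[str(cat)] = frozenset(stable_first.index[stable_first == cat])
    return out


def overall_unchanged_fraction(assignment: pd.DataFrame, genotype: str) -> float:
    """Fraction of always-defined triads whose category never changes."""
    wide = _stage_table(assignment, genotype)
    defined = (wide != UNDEFINED).all(axis=1)
    if defined.sum() == 0:
        return float("nan")
    stable = wide.loc[defined].nunique(axis=1) == 1
    return float(stable.sum() / defined.sum())


def per_category_stability(assignment: pd.DataFrame, genotype: str) -> pd.DataFrame:
    """Per category and stage: of the triads assigned that category at the
    stage, the fraction that are stable (same category at all stages).

    Empty category/stage cells are NaN (undefined, not zero).
    """
    wide = _stage_table(assignment, genotype)
    stable = stable_triads(assignment, genotype)
    out = pd.DataFrame(index=pd.Index(CATEGORIES, name="category"),
                       columns=wide.columns, dtype=float)
    for stage in wide.columns:
        at_stage = wide[stage]
        for cat in CATEGORIES:
            members = wide.index[at_stage == cat]
            if len(members) == 0:
                continue
            out.loc[cat, stage] = len(set(members) & stable[cat]) / len(members)
    return out


def average_stability(assignment: pd.DataFrame, genotype: str, category: str
                      ) -> tuple[float, bool]:
    """Unweighted mean of the per-stage stability fractions for a category.

    Returns ``(mean, partial)``; ``partial`` is True when any stage fraction
    was undefined (mean taken over the defined stages only).
    """
    fractions = per_category_stability(assignment, genotype).loc[category]
    partial = bool(fractions.isna().any())
    if fractions.isna().all():
        return float("nan"), True
    return float(fractions.mean()), partial


def unique_stable_biased(assignment: pd.DataFrame, triads: pd.DataFrame,
                         genotype_a: str, genotype_b: str, category: str
                         ) -> StableBiasSet:
    """Triads stable in ``category`` in genotype_a but not in genotype_b.

    Attaches the focal-subgenome gene ids (the X of ``X_suppressed`` /
    ``X_dominant``).
    """
    if category == "balanced":
        raise ValueError("balanced has no focal subgenome")
    only = frozenset(stable_triads(assignment, genotype_a)[category]
                     - stable_triads(assignment, genotype_b)[category])
    focal = category.split("_")[0]
    lookup = triads.set_index("triad_id")[f"gene_{focal}"]
    genes = frozenset(lookup.loc[sorted(only)]) if only else frozenset()
    return StableBiasSet(genotype=genotype_a, category=category,
                         triad_ids=only, focal_genes=genes)


def deg_overlap(bias_set: StableBiasSet, degs: pd.DataFrame,
                fc_threshold: float = 1.0, padj_threshold: float = 0.01) -> dict:
    """Overlap of a stable-bias set's focal genes with significant DEGs.

    Significance is |log2fc| >= fc_threshold and padj < padj_threshold in
    the union of contrasts.  Returns count, fraction, per-contrast counts
    and an up/down tally (direction of the gene's most significant hit).
    """
    sig = degs[(degs["log2fc"].abs() >= fc_threshold)
               & (degs["padj"] < padj_threshold)]
    hits = sig[sig["gene_id"].isin(bias_set.focal_genes)]
    overlap_genes = set(hits["gene_id"])
    n_set = len(bias_set.focal_genes)
    best = hits.sort_values("padj").drop_duplicates("gene_id")
    tally = {"up": int((best["log2fc"] > 0).sum()),
             "down": int((best["log2fc"] < 0).sum())}
    return {
        "count": len(overlap_genes),
        "fraction": len(overlap_genes) / n_set if n_set else float("nan"),
        "per_contrast": hits.groupby("contrast")["gene_id"].nunique().to_dict(),
        "direction": tally,
        "genes": sorted(overlap_genes),
    }


def summarize_transitions(assignment: pd.DataFrame, genotype: str) -> TransitionSummary:
    """Bundle matrices, per-category stability and the headline fraction."""
    return TransitionSummary(
        genotype=genotype,
        matrices=transition_matrices(assignment, genotype),
        per_category=per_category_stability(assignment, genotype),
        overall_unchanged=overall_unchanged_fraction(assignment, genotype),
    )
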