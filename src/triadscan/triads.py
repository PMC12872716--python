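"""Homoeolog expression-bias classification of wheat triads.

A triad is the 1:1:1 set of A/B/D homoeologs.  Per condition
(genotype x stage) each homoeolog's TPM is divided by the triad total to
give relative expression shares summing to 1, and the triad is assigned
one of seven bias categories:

* ``X_dominant``  — share of X > 0.60 and both other shares <= 0.20
* ``X_suppressed`` — share of X < 0.20 and both other shares < 0.80
* ``balanced``    — anything else

Dominant rules take precedence over suppressed rules where both fire
(the two families overlap on a sliver of the simplex); triads with a
zero TPM sum in a condition are ``undefined`` there.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

__all__ = [
    "SUBGENOMES",
    "CATEGORIES",
    "DOMINANT_HIGH",
    "DOMINANT_OTHER",
    "SUPPRESSED_LOW",
    "SUPPRESSED_OTHER",
    "aggregate_condition_tpm",
    "filter_expressed_triads",
    "relative_expression",
    "classify_triad",
    "categorize_all",
    "category_proportions",
    "ternary_coordinates",
]

SUBGENOMES = ("A", "B", "D")

#: the seven bias categories plus the degenerate label
CATEGORIES = (
    "balanced",
    "A_dominant", "B_dominant", "D_dominant",
    "A_suppressed", "B_suppressed", "D_suppressed",
)
UNDEFINED = "undefined"

# thresholds on the relative-expression (share) scale
DOMINANT_HIGH = 0.60     # focal share strictly above
DOMINANT_OTHER = 0.20    # both other shares at or below
SUPPRESSED_LOW = 0.20    # focal share strictly below
SUPPRESSED_OTHER = 0.80  # both other shares strictly below


def aggregate_condition_tpm(tpm: ExpressionMatrix, samples: pd.DataFrame,
                            triads: pd.DataFrame, agg: str = "mean") -> pd.DataFrame:
    """Aggregate replicate TPM per triad and condition.

    Returns one row per triad x (genotype, stage) with columns
    ``tpm_A, tpm_B, tpm_D`` (replicate mean by default, ``agg='median'``
    optional).
    """
    if tpm.unit != "TPM":
        raise ValueError(f"expected TPM matrix, got unit {tpm.unit!r}")
    if agg not in ("mean", "median"):
        raise ValueError(f"unknown aggregation {agg!r}")
    wanted = pd.concat([triads["gene_A"], triads["gene_B"], triads["gene_D"]])
    missing = wanted[~wanted.isin(tpm.gene_ids)]
    if len(missing):
        raise ValueError(
            f"{len(missing)} triad genes absent from the TPM matrix, "
            f"e.g. {sorted(missing)[:5]}")
    extra = set(samples["sample_id"]) - set(tpm.sample_ids)
    if extra:
        raise ValueError(f"samples missing from the TPM matrix: {sorted(extra)[:5]}")

    rows = []
    grouped = samples.groupby(["genotype", "stage"], observed=True)
    for (genotype, stage), grp in grouped:
        if len(grp) == 0:
            raise ValueError(f"condition ({genotype}, {stage}) has no samples")
        sub = tpm.values[list(grp["sample_id"])]
        pooled = sub.mean(axis=1) if agg == "mean" else sub.median(axis=1)
        rows.append(pd.DataFrame({
            "triad_id": triads["triad_id"].to_numpy(),
            "genotype": genotype,
            "stage": stage,
            "tpm_A": pooled.reindex(triads["gene_A"]).to_numpy(),
            "tpm_B": pooled.reindex(triads["gene_B"]).to_numpy(),
            "tpm_D": pooled.reindex(triads["gene_D"]).to_numpy(),
        }))
    out = pd.concat(rows, ignore_index=True)
    stage_order = list(samples["stage"].cat.categories) \
        if isinstance(samples["stage"].dtype, pd.CategoricalDtype) \
        else list(dict.fromkeys(samples["stage"]))
    out["stage"] = pd.Categorical(out["stage"], categories=stage_order, ordered=True)
    return out


def filter_expressed_triads(expr: pd.DataFrame, threshold: float = 5.0) -> pd.Index:
    """Triads whose A+B+D TPM sum reaches ``threshold`` in any condition.

    The boundary is inclusive (a sum of exactly 5 TPM retains the triad).
    """
    total = expr["tpm_A"] + expr["tpm_B"] + expr["tpm_D"]
    best = total.groupby(expr["triad_id"], sort=False).max()
    return pd.Index(best.index[best >= threshold])


def relative_expression(tpm_a, tpm_b, tpm_d):
    """Per-subgenome shares of the triad total; NaN where the sum is zero."""
    a = np.asarray(tpm_a, dtype=float)
    b = np.asarray(tpm_b, dtype=float)
    d = np.asarray(tpm_d, dtype=float)
    if (a < 0).any() or (b < 0).any() or (d < 0).any():
        raise ValueError("negative TPM input")
    total = a + b + d
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.stack([a / total, b / total, d / total], axis=-1)
    rel[np.asarray(total == 0)] = np.nan
    return rel


def classify_triad(rel) -> np.ndarray:
    """Assign bias categories from relative-expression shares.

    ``rel`` is (..., 3) with A/B/D shares.  Returns an object array of
    category labels; rows with NaN shares yield ``undefined``.  Dominant
    rules are evaluated before suppressed rules.
    """
    rel = np.asarray(rel, dtype=float)
    scalar = rel.ndim == 1
    r = np.atleast_2d(rel)
    out = np.full(r.shape[0], "balanced", dtype=object)
    defined = ~np.isnan(r).any(axis=1)
    out[~defined] = UNDEFINED

    others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    suppressed_hit = np.zeros(r.shape[0], dtype=bool)
    dominant_hit = np.zeros(r.shape[0], dtype=bool)
    for i, sub in enumerate(SUBGENOMES):
        j, k = others[i]
        dom = defined & (r[:, i] > DOMINANT_HIGH) & \
            (r[:, j] <= DOMINANT_OTHER) & (r[:, k] <= DOMINANT_OTHER)
        out[dom] = f"{sub}_dominant"
        dominant_hit |= dom
    for i, sub in enumerate(SUBGENOMES):
        j, k = others[i]
        sup = defined & (r[:, i] < SUPPRESSED_LOW) & \
            (r[:, j] < SUPPRESSED_OTHER) & (r[:, k] < SUPPRESSED_OTHER)
        suppressed_hit |= sup
        out[sup & ~dominant_hit] = f"{sub}_suppressed"
    if scalar:
        return out[0]
    return out


def rule_overlap(rel) -> np.ndarray:
    """True where a dominant and a suppressed rule both fire (flagged output)."""
    rel = np.asarray(rel, dtype=float)
    r = np.atleast_2d(rel)
    others = {0: (1, 2), 1: (0, 2), 2: (0, 1)}
    dom = np.zeros(r.shape[0], dtype=bool)
    sup = np.zeros(r.shape[0], dtype=bool)
    for i in range(3):
        j, k = others[i]
        dom |= (r[:, i] > DOMINANT_HIGH) & (r[:, j] <= DOMINANT_OTHER) & \
            (r[:, k] <= DOMINANT_OTHER)
        sup |= (r[:, i] < SUPPRESSED_LOW) & (r[:, j] < SUPPRESSED_OTHER) & \
            (r[:, k] < SUPPRESSED_OTHER)
    flag = dom & sup
    return flag if rel.ndim > 1 else flag[0]


def categorize_all(expr: pd.DataFrame, expressed: pd.Index) -> pd.DataFrame:
    """Classify every expressed triad in every condition.

    Returns the assignment table (triad_id, genotype, stage, rel_A/B/D,
    category, ambiguous) restricted to ``expressed`` triads.
    """
    sub = expr[expr["triad_id"].isin(expressed)].copy()
    rel = relative_expression(sub["tpm_A"], sub["tpm_B"], sub["tpm_D"])
    sub["rel_A"], sub["rel_B"], sub["rel_D"] = rel[:, 0], rel[:, 1], rel[:, 2]
    sub["category"] = classify_triad(rel)
    sub["ambiguous"] = rule_overlap(rel)
    return sub.reset_index(drop=True)


def category_proportions(assignment: pd.DataFrame) -> pd.DataFrame:
    """Per-condition category proportions.

    The denominator is the number of triads with a defined category in
    that condition; ``undefined`` rows are excluded.
    """
    defined = assignment[assignment["category"] != UNDEFINED]
    counts = (defined.groupby(["genotype", "stage"], observed=True)["category"]
              .value_counts().unstack(fill_value=0))
    for cat in CATEGORIES:
        if cat not in counts.columns:
            counts[cat] = 0
    counts = counts[list(CATEGORIES)]
    return counts.div(counts.sum(axis=1), axis=0)


def ternary_coordinates(rel) -> np.ndarray:
    """Barycentric (A, B, D) shares to planar coordinates.

    A maps to the origin, B to (1, 0) and D to (1/2, sqrt(3)/2):
    ``x = rel_B + rel_D / 2``, ``y = sqrt(3)/2 * rel_D``.
    """
    rel = np.asarray(rel, dtype=float)
    r = np.atleast_2d(rel)
    xy = np.stack([r[:, 1] + r[:, 2] / 2.0, np.sqrt(3.0) / 2.0 * r[:, 2]], axis=-1)
    return xy[0] if rel.ndim == 1 else xy
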