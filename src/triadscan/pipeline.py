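"""End-to-end orchestration: simulate -> classify -> dynamics -> hotspots -> biomarkers.

One global seed fans out to per-stage seeds through a deterministic
``SeedSequence`` spawn order, so any stage can be reproduced in isolation.
All stage outputs are plain TSV/BED/JSON under the run directory, plus a
manifest carrying the configuration hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics, hotspots, nsc, triads
from .io import ExpressionMatrix, cpm_normalize, filter_expressed_genes
from .simulate import (SimulationConfig, contrast_name, simulate_dataset,
                       write_fixture)

__all__ = ["stage_seeds", "run_demo", "interval_jaccard"]

_STAGES = ("simulate", "hotspots", "nsc_split", "nsc_cv")


def log(stage: str, **kv) -> None:
    ts = time.strftime("%Y-%m-%dT%H:%M:%S")
    pairs = " ".join(f"{k}={v}" for k, v in kv.items())
    print(f"{ts} stage={stage} {pairs}", file=sys.stderr)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds (< 2^31) from one global seed."""
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {name: int(c.generate_state(1)[0] % (2 ** 31))
            for name, c in zip(_STAGES, children)}


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard similarity of two closed bp intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else float("nan")


def hotspot_recovery(regions: pd.DataFrame, planted) -> list[dict]:
    """Best same-direction Jaccard of each planted hotspot vs called regions."""
    out = []
    for hs in planted:
        cand = regions[(regions["chrom"] == hs.chrom)
                       & (regions["direction"] == hs.direction)]
        best = max((interval_jaccard((hs.start, hs.end), (r.start, r.end))
                    for r in cand.itertuples(index=False)), default=0.0)
        out.append({"chrom": hs.chrom, "direction": hs.direction,
                    "jaccard": best})
    return out


def run_demo(outdir, seed: int = 0, config: SimulationConfig | None = None,
             n_perm: int = 2000, hotspot_q: float = 0.05,
             triad_threshold: float = 5.0, cv_repeats: int = 2,
             fraction_train: float = 0.6) -> dict:
    """Run the full pipeline on a generated fixture; returns the report dict.

    ``hotspot_q`` defaults to 0.05 because the permutation p floor
    1/(n_perm+1) is coarser than the analytic-mode 1e-5 convention.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed)
    if config is None:
        config = SimulationConfig(seed=seeds["simulate"])
    t0 = time.time()

    log("simulate", seed=config.seed, n_triads=config.n_triads)
    ds = simulate_dataset(config)
    write_fixture(ds, outdir / "fixture")

    # --- triad bias ------------------------------------------------------
    expr = triads.aggregate_condition_tpm(ds.tpm, ds.sample_sheet, ds.triads)
    expressed = triads.filter_expressed_triads(expr, threshold=triad_threshold)
    assignment = triads.categorize_all(expr, expressed)
    proportions = triads.category_proportions(assignment)
    assignment.to_csv(outdir / "triad_assignment.tsv", sep="\t", index=False,
                      float_format="%.6g")
    proportions.to_csv(outdir / "category_proportions.tsv", sep="\t",
                       float_format="%.6g")
    truth_cats = ds.truth.categories.merge(
        assignment[["triad_id", "genotype", "stage", "category"]],
        on=["triad_id", "genotype", "stage"], suffixes=("_true", "_called"))
    recovery = float((truth_cats["category_true"]
                      == truth_cats["category_called"]).mean())
    log("classify", expressed=len(expressed), recovery=f"{recovery:.4f}")

    # --- dynamics --------------------------------------------------------
    g_hi, g_lo = config.genotypes[0], config.genotypes[1]
    unchanged = {g: dynamics.overall_unchanged_fraction(assignment, g)
                 for g in config.genotypes}
    bsup_avg = {g: dynamics.average_stability(assignment, g, "B_suppressed")[0]
                for g in config.genotypes}
    unique_set = dynamics.unique_stable_biased(assignment, ds.triads,
                                               g_lo, g_hi, "B_suppressed")
    overlap = dynamics.deg_overlap(unique_set, ds.deg_tables)
    pd.DataFrame({"gene_id": sorted(unique_set.focal_genes)}).to_csv(
        outdir / "unique_stable_Bsuppressed_genes.tsv", sep="\t", index=False)
    log("dynamics", unchanged=";".join(f"{g}:{v:.3f}" for g, v in unchanged.items()),
        unique=len(unique_set.triad_ids), overlap=overlap["count"])

    # --- hotspots --------------------------------------------------------
    contrast = contrast_name(g_hi, g_lo, config.stages[0])
    scan = hotspots.HotspotScan(ds.annotation, ds.deg_tables, contrast,
                                n_perm=n_perm)
    scan_result = scan.fit(seed=seeds["hotspots"])
    regions = scan_result.regions(q_cutoff=hotspot_q)
    hotspots.regions_to_bed(regions, outdir / "hotspot_regions.bed")
    hs_recovery = hotspot_recovery(regions, ds.truth.hotspots)
    log("hotspots", contrast=contrast, regions=len(regions),
        jaccard=";".join(f"{h['chrom']}:{h['jaccard']:.3f}" for h in hs_recovery))

    # --- biomarkers ------------------------------------------------------
    expressed_genes = filter_expressed_genes(cpm_normalize(ds.counts))
    counts_expr = ExpressionMatrix(ds.counts.values.loc[expressed_genes], "counts")
    X, size_factors, _ = nsc.prepare_counts(counts_expr)
    labels = ds.sample_sheet.set_index("sample_id")["genotype"]
    train, test = nsc.split_train_test(list(X.columns), list(labels[X.columns]),
                                       fraction_train=fraction_train,
                                       seed=seeds["nsc_split"])
    clf = nsc.NSCClassifier(X[train], labels[train])
    fit = clf.fit(cv_repeats=cv_repeats, seed=seeds["nsc_cv"])
    metrics = fit.evaluate(X[test], labels[test], reference=g_lo) if test else None
    selected = fit.selected_features()
    selected.to_csv(outdir / "selected_biomarkers.tsv", sep="\t", index=False,
                    float_format="%.6g")
    planted = set(ds.truth.biomarkers["gene_id"])
    top = set(selected["gene_id"].head(max(2, len(planted))))
    log("biomarkers", delta=f"{fit.delta:.3g}", selected=len(selected),
        planted_in_top=len(planted & top))

    cfg_json = json.dumps(dataclasses.asdict(config), default=str, sort_keys=True)
    report = {
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "n_triads": config.n_triads,
        "expressed_triads": int(len(expressed)),
        "category_recovery": recovery,
        "category_proportions": {
            f"{g}|{s}": {c: round(float(v), 6) for c, v in row.items()}
            for (g, s), row in proportions.iterrows()},
        "overall_unchanged": {g: float(v) for g, v in unchanged.items()},
        "b_suppressed_avg_stability": {g: float(v) for g, v in bsup_avg.items()},
        "unique_stable_b_suppressed": len(unique_set.triad_ids),
        "deg_overlap_count": overlap["count"],
        "deg_overlap_fraction": overlap["fraction"],
        "deg_overlap_direction": overlap["direction"],
        "hotspot_regions": len(regions),
        "hotspot_recovery": hs_recovery,
        "nsc": {
            "delta": fit.delta,
            "n_selected": int(len(selected)),
            "planted_biomarkers_in_top": int(len(planted & top)),
            "test_accuracy": metrics.accuracy if metrics else None,
            "test_sensitivity": metrics.sensitivity if metrics else None,
            "test_specificity": metrics.specificity if metrics else None,
        },
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log("demo", runtime_s=round(time.time() - t0, 2))
    return report
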