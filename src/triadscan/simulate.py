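"""Synthetic hexaploid microspore-embryogenesis experiments with known truth.

The generator emulates the study design the pipeline targets: two wheat
genotypes (a responsive and a recalcitrant cultivar) x three developmental
stages x three replicates, with triads of A/B/D homoeologs placed on 21
chromosomes (groups 1-7 x subgenomes A/B/D).

Per triad and condition a bias category evolves along stages as a sticky
Markov chain (kept with probability ``stability``, else redrawn from the
category mixture).  Subgenome shares are Dirichlet draws centred on the
category's archetype; counts are negative-binomial around
``abundance x length x library-size`` means, and TPM is recomputed from the
counts.  Planted biomarker genes carry a between-genotype shift at every
stage, hotspot blocks carry a positional shift in the first genotype, and
DEG tables label genes by their true expected |log2FC|.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, write_expression_matrix, write_gene_annotation
from .triads import CATEGORIES, classify_triad

__all__ = [
    "Hotspot",
    "SimulationConfig",
    "PlantedTruth",
    "SimulatedDataset",
    "generate_annotation",
    "simulate_dataset",
    "write_fixture",
    "expected_unchanged_fraction",
    "contrast_name",
    "ARCHETYPES",
]

#: Dirichlet centres for the seven categories, strictly inside the
#: classification regions so planted truth is recoverable.
ARCHETYPES: dict[str, tuple[float, float, float]] = {
    "balanced": (1 / 3, 1 / 3, 1 / 3),
    "A_dominant": (0.80, 0.10, 0.10),
    "B_dominant": (0.10, 0.80, 0.10),
    "D_dominant": (0.10, 0.10, 0.80),
    "A_suppressed": (0.05, 0.475, 0.475),
    "B_suppressed": (0.475, 0.05, 0.475),
    "D_suppressed": (0.475, 0.475, 0.05),
}

#: default category mixture: balanced majority, suppression commoner than
#: dominance, B-suppression most and D-suppression least abundant
DEFAULT_PROPORTIONS: dict[str, float] = {
    "balanced": 0.745,
    "A_dominant": 0.025, "B_dominant": 0.030, "D_dominant": 0.025,
    "A_suppressed": 0.060, "B_suppressed": 0.075, "D_suppressed": 0.040,
}


@dataclass(frozen=True)
class Hotspot:
    """A planted chromosomal block of concordant differential expression."""
    chrom: str
    start: int
    end: int
    direction: str  # "up" or "down" (in the first genotype)
    effect: float   # |log2FC| applied to member genes

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError(f"hotspot direction must be up/down, got {self.direction!r}")
        if self.start > self.end:
            raise ValueError("hotspot start > end")


def _default_hotspots() -> tuple[Hotspot, ...]:
    # one large up-block on 1B (mirroring the scale of real wheat DEG
    # hotspots, ~200 Mbp) and a smaller down-block on 6B
    return (Hotspot("1B", 40_000_000, 240_000_000, "up", 3.0),
            Hotspot("6B", 60_000_000, 160_000_000, "down", 3.0))


@dataclass
class SimulationConfig:
    """Full specification of a synthetic experiment; the seed fixes everything."""

    n_triads: int = 1000
    n_nontriad_genes: int = 300
    genotypes: tuple[str, ...] = ("Nanda", "Sadash")
    stages: tuple[str, ...] = ("Day0", "Day7", "Day21")
    replicates: int = 3
    #: category mixture; either one dict over the seven categories or a
    #: per-genotype dict of such dicts
    category_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    #: probability a triad keeps its category between consecutive stages
    #: (scalar or per-genotype dict)
    stability: float | dict = 0.7
    nb_dispersion: float = 0.05
    mean_log_expression: float = 4.0   # natural-log mean of triad abundance
    sd_log_expression: float = 1.0
    gene_length_range: tuple[int, int] = (900, 4500)
    gene_spacing: int = 2_000_000      # mean start-to-start distance, bp
    concentration: float = 200.0       # Dirichlet concentration around archetypes
    lib_size: int = 1_500_000
    hotspot_spec: tuple[Hotspot, ...] = field(default_factory=_default_hotspots)
    #: (gene_id | None, between-genotype log2FC); None picks a non-triad gene
    biomarker_spec: tuple = ((None, 4.0), (None, -4.0))
    n_deg_genes: int = 150
    deg_effect: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_triads < 1:
            raise ValueError("n_triads must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for props in self._proportions_by_genotype().values():
            if set(props) - set(CATEGORIES):
                raise ValueError(f"unknown categories: {set(props) - set(CATEGORIES)}")
            if abs(sum(props.values()) - 1.0) > 1e-8:
                raise ValueError("category proportions must sum to 1")
            if any(p < 0 for p in props.values()):
                raise ValueError("category proportions must be non-negative")
        for g, s in self._stability_by_genotype().items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"stability for {g!r} outside [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.n_deg_genes + len(self.biomarker_spec) > self.n_nontriad_genes:
            raise ValueError("not enough non-triad genes for planted biomarkers + DEGs")
        self.hotspot_spec = tuple(
            h if isinstance(h, Hotspot) else Hotspot(*h) for h in self.hotspot_spec)

    def _proportions_by_genotype(self) -> dict[str, dict[str, float]]:
        cp = self.category_proportions
        if cp and all(isinstance(v, dict) for v in cp.values()):
            return {g: {c: float(v.get(c, 0.0)) for c in CATEGORIES}
                    for g, v in cp.items()}
        full = {c: float(cp.get(c, 0.0)) for c in CATEGORIES}
        return {g: full for g in self.genotypes}

    def _stability_by_genotype(self) -> dict[str, float]:
        if isinstance(self.stability, dict):
            return {g: float(self.stability[g]) for g in self.genotypes}
        return {g: float(self.stability) for g in self.genotypes}


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the matrices."""
    categories: pd.DataFrame     # triad_id, genotype, stage, category (planted),
                                 # rel_A/B/D (expected shares), realized_category
    deg: pd.DataFrame            # gene_id, contrast, log2fc, is_de
    hotspots: tuple[Hotspot, ...]
    biomarkers: pd.DataFrame     # gene_id, effect
    deg_genes: pd.DataFrame      # gene_id, effect (planted extra DE genes)


@dataclass
class SimulatedDataset:
    counts: ExpressionMatrix
    tpm: ExpressionMatrix
    sample_sheet: pd.DataFrame
    triads: pd.DataFrame
    annotation: pd.DataFrame
    deg_tables: pd.DataFrame
    truth: PlantedTruth
    config: SimulationConfig


def contrast_name(genotype_a: str, genotype_b: str, stage: str) -> str:
    """Contrast label, e.g. ('Nanda', 'Sadash', 'Day0') -> 'NS_D0'."""
    return f"{genotype_a[0]}{genotype_b[0]}_{stage.replace('Day', 'D')}"


def expected_unchanged_fraction(proportions: dict[str, float], stability: float,
                                n_stages: int = 3) -> float:
    """Analytic probability a triad's category is identical at all stages.

    Under the sticky Markov rule (keep w.p. ``s``, else redraw from the
    mixture), P(unchanged) = sum_c p_c * (s + (1-s) p_c)^(n_stages-1).
    """
    s = float(stability)
    return float(sum(p * (s + (1.0 - s) * p) ** (n_stages - 1)
                     for p in proportions.values()))


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place triad and filler genes on chromosomes 1A..7D.

    Triad ``i`` goes to chromosome group ``(i mod 7) + 1`` with its A/B/D
    members on the cognate chromosomes; intervals are non-overlapping and
    sorted.  Returns ``(triad_table, annotation)``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lo, hi = config.gene_length_range
    if hi >= 0.5 * config.gene_spacing:
        raise ValueError(
            "chromosome capacity exceeded: max gene length must be below half "
            "the gene spacing to guarantee non-overlapping intervals")

    groups = [str(1 + (i % 7)) for i in range(config.n_triads)]
    chroms = [f"{g}{sub}" for g in map(str, range(1, 8)) for sub in "ABD"]
    # per-chromosome slot lists: (kind, payload) in placement order
    slots: dict[str, list[tuple[str, object]]] = {c: [] for c in chroms}
    for i, g in enumerate(groups):
        for sub in "ABD":
            slots[f"{g}{sub}"].append(("triad", (i, sub)))
    for j in range(config.n_nontriad_genes):
        slots[chroms[j % len(chroms)]].append(("extra", j))

    records = []
    triad_genes: dict[tuple[int, str], str] = {}
    extra_ids: dict[int, str] = {}
    for chrom in chroms:
        entries = slots[chrom]
        if not entries:
            continue
        gaps = rng.uniform(0.5, 1.5, size=len(entries)) * config.gene_spacing
        starts = np.cumsum(gaps).astype(np.int64)
        lengths = rng.integers(lo, hi + 1, size=len(entries))
        strands = rng.choice(["+", "-"], size=len(entries))
        for k, (kind, payload) in enumerate(entries):
            gene_id = f"SYN{chrom}G{k + 1:04d}"
            records.append((gene_id, chrom, int(starts[k]),
                            int(starts[k] + lengths[k] - 1), strands[k]))
            if kind == "triad":
                triad_genes[payload] = gene_id
            else:
                extra_ids[payload] = gene_id

    annotation = pd.DataFrame(records,
                              columns=["gene_id", "chrom", "start", "end", "strand"])
    annotation = annotation.sort_values(["chrom", "start"]).reset_index(drop=True)
    triads = pd.DataFrame({
        "triad_id": [f"TRI{i + 1:05d}" for i in range(config.n_triads)],
        "gene_A": [triad_genes[(i, "A")] for i in range(config.n_triads)],
        "gene_B": [triad_genes[(i, "B")] for i in range(config.n_triads)],
        "gene_D": [triad_genes[(i, "D")] for i in range(config.n_triads)],
    })
    triads.attrs["extra_gene_ids"] = [extra_ids[j] for j in sorted(extra_ids)]
    return triads, annotation


# ---------------------------------------------------------------------------
# full dataset


def _draw_categories(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_triads, n_genotypes, n_stages) array of category indices."""
    n_t = config.n_triads
    props = config._proportions_by_genotype()
    stab = config._stability_by_genotype()
    out = np.empty((n_t, len(config.genotypes), len(config.stages)), dtype=np.int64)
    for gi, g in enumerate(config.genotypes):
        p = np.array([props[g][c] for c in CATEGORIES])
        s = stab[g]
        out[:, gi, 0] = rng.choice(len(CATEGORIES), size=n_t, p=p)
        for si in range(1, len(config.stages)):
            keep = rng.random(n_t) < s
            redraw = rng.choice(len(CATEGORIES), size=n_t, p=p)
            out[:, gi, si] = np.where(keep, out[:, gi, si - 1], redraw)
    return out


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate the complete synthetic experiment for ``config``."""
    ss = np.random.SeedSequence(config.seed)
    rng_ann, rng_cat, rng_expr, rng_counts, rng_deg = (
        np.random.default_rng(c) for c in ss.spawn(5))

    triads, annotation = generate_annotation(config, rng_ann)
    extra_ids: list[str] = triads.attrs["extra_gene_ids"]
    gene_order = annotation["gene_id"].to_numpy()
    gene_pos = {g: i for i, g in enumerate(gene_order)}
    lengths = annotation.set_index("gene_id").loc[gene_order, ["start", "end"]]
    length_bp = (lengths["end"] - lengths["start"] + 1).to_numpy(dtype=float)

    n_genes = len(gene_order)
    n_geno, n_stage = len(config.genotypes), len(config.stages)

    # planted categories and subgenome shares
    cats = _draw_categories(config, rng_cat)
    arch = np.array([ARCHETYPES[c] for c in CATEGORIES])
    shapes = config.concentration * arch[cats]          # (t, g, s, 3)
    gamma = rng_expr.gamma(shape=shapes)
    shares = gamma / gamma.sum(axis=-1, keepdims=True)  # Dirichlet draws

    # baseline abundance: triad total T shared across conditions, filler genes flat
    T = np.exp(rng_expr.normal(config.mean_log_expression, config.sd_log_expression,
                               size=config.n_triads))
    extra_base = np.exp(rng_expr.normal(config.mean_log_expression,
                                        config.sd_log_expression,
                                        size=len(extra_ids)))

    abundance = np.zeros((n_genes, n_geno, n_stage))
    tg_idx = np.array([[gene_pos[g] for g in triads[f"gene_{sub}"]] for sub in "ABD"])
    for k in range(3):  # A, B, D
        abundance[tg_idx[k]] = T[:, None, None] * shares[:, :, :, k]
    for j, g in enumerate(extra_ids):
        abundance[gene_pos[g]] = extra_base[j]

    # planted between-genotype effects (applied to the first genotype)
    mult = np.ones((n_genes, n_geno))
    biomarker_rows = []
    for slot, (gid, eff) in enumerate(config.biomarker_spec):
        if gid is None:
            gid = extra_ids[slot]
        elif gid not in gene_pos:
            raise ValueError(f"biomarker gene {gid!r} not in the generated annotation")
        mult[gene_pos[gid], 0] *= 2.0 ** eff
        biomarker_rows.append((gid, float(eff)))
    biomarkers = pd.DataFrame(biomarker_rows, columns=["gene_id", "effect"])

    deg_pool = [g for g in extra_ids if g not in set(biomarkers["gene_id"])]
    deg_rows = []
    if config.n_deg_genes:
        chosen = rng_deg.choice(len(deg_pool), size=config.n_deg_genes, replace=False)
        signs = rng_deg.choice([-1.0, 1.0], size=config.n_deg_genes)
        for idx, sgn in zip(chosen, signs):
            gid = deg_pool[idx]
            eff = float(sgn * config.deg_effect)
            mult[gene_pos[gid], 0] *= 2.0 ** eff
            deg_rows.append((gid, eff))
    deg_genes = pd.DataFrame(deg_rows, columns=["gene_id", "effect"])

    mids = (lengths["start"] + lengths["end"]).to_numpy() / 2.0
    chrom_arr = annotation["chrom"].to_numpy()
    for hs in config.hotspot_spec:
        member = (chrom_arr == hs.chrom) & (mids >= hs.start) & (mids <= hs.end)
        eff = hs.effect if hs.direction == "up" else -hs.effect
        mult[member, 0] *= 2.0 ** eff
    abundance = abundance * mult[:, :, None]

    # expected subgenome shares after planted effects, and the realized category
    eff_shares = np.empty_like(shares)
    for k in range(3):
        eff_shares[:, :, :, k] = abundance[tg_idx[k]]
    eff_shares = eff_shares / eff_shares.sum(axis=-1, keepdims=True)

    # samples, counts, TPM
    sample_rows = []
    mu_cols = []
    for gi, g in enumerate(config.genotypes):
        for si, st in enumerate(config.stages):
            a = abundance[:, gi, si]
            mu = a * length_bp
            mu = mu / mu.sum() * config.lib_size
            for r in range(1, config.replicates + 1):
                sample_rows.append((f"{g}_{st}_R{r}", g, st, r))
                mu_cols.append(mu)
    sample_sheet = pd.DataFrame(sample_rows,
                                columns=["sample_id", "genotype", "stage", "replicate"])
    sample_sheet["stage"] = pd.Categorical(sample_sheet["stage"],
                                           categories=list(config.stages), ordered=True)
    mu_mat = np.column_stack(mu_cols)
    if config.nb_dispersion == 0:
        counts_arr = np.rint(mu_mat)
    else:
        n_nb = 1.0 / config.nb_dispersion
        counts_arr = rng_counts.negative_binomial(
            n_nb, n_nb / (n_nb + mu_mat)).astype(float)
    counts_df = pd.DataFrame(counts_arr, index=gene_order,
                             columns=sample_sheet["sample_id"].to_numpy())
    counts = ExpressionMatrix(counts_df, "counts")

    rate = counts_arr / length_bp[:, None] * 1000.0   # per kilobase
    colsum = rate.sum(axis=0)
    colsum[colsum == 0] = 1.0
    tpm = ExpressionMatrix(pd.DataFrame(rate / colsum * 1e6, index=gene_order,
                                        columns=counts_df.columns), "TPM")

    # truth tables
    cat_rows = []
    for gi, g in enumerate(config.genotypes):
        for si, st in enumerate(config.stages):
            rel = eff_shares[:, gi, si, :]
            cat_rows.append(pd.DataFrame({
                "triad_id": triads["triad_id"],
                "genotype": g,
                "stage": st,
                "category": [CATEGORIES[c] for c in cats[:, gi, si]],
                "rel_A": rel[:, 0], "rel_B": rel[:, 1], "rel_D": rel[:, 2],
                "realized_category": classify_triad(rel),
            }))
    truth_categories = pd.concat(cat_rows, ignore_index=True)

    deg_frames = []
    g_ref = 1  # second genotype is the reference class
    for si, st in enumerate(config.stages):
        with np.errstate(divide="ignore"):
            lfc = np.log2(abundance[:, 0, si] / abundance[:, g_ref, si])
        is_de = np.abs(lfc) >= 1.0
        padj = np.where(is_de,
                        rng_deg.uniform(1e-8, 0.009, size=n_genes),
                        rng_deg.uniform(0.02, 1.0, size=n_genes))
        deg_frames.append(pd.DataFrame({
            "gene_id": gene_order,
            "log2fc": lfc,
            "padj": padj,
            "contrast": contrast_name(config.genotypes[0], config.genotypes[g_ref], st),
            "is_de": is_de,
        }))
    deg_truth = pd.concat(deg_frames, ignore_index=True)
    deg_tables = deg_truth[["gene_id", "log2fc", "padj", "contrast"]].copy()

    truth = PlantedTruth(categories=truth_categories, deg=deg_truth,
                         hotspots=config.hotspot_spec, biomarkers=biomarkers,
                         deg_genes=deg_genes)
    return SimulatedDataset(counts=counts, tpm=tpm, sample_sheet=sample_sheet,
                            triads=triads.drop(columns=[], errors="ignore"),
                            annotation=annotation, deg_tables=deg_tables,
                            truth=truth, config=config)


# ---------------------------------------------------------------------------
# fixtures on disk


def _config_to_jsonable(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["hotspot_spec"] = [dataclasses.asdict(h) for h in config.hotspot_spec]
    d["biomarker_spec"] = [list(b) for b in config.biomarker_spec]
    return d


def write_fixture(dataset: SimulatedDataset, directory) -> dict[str, str]:
    """Write every pipeline input format plus truth tables and a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = {
        "counts": "counts.tsv", "tpm": "tpm.tsv", "samples": "samples.tsv",
        "triads": "triads.tsv", "annotation": "annotation.gff3",
        "degs": "degs.tsv", "truth_categories": "truth_categories.tsv",
        "truth_deg": "truth_deg.tsv", "truth_biomarkers": "truth_biomarkers.tsv",
        "truth_deg_genes": "truth_deg_genes.tsv",
    }
    write_expression_matrix(dataset.counts, directory / files["counts"])
    write_expression_matrix(dataset.tpm, directory / files["tpm"])
    dataset.sample_sheet.to_csv(directory / files["samples"], sep="\t", index=False)
    dataset.triads.to_csv(directory / files["triads"], sep="\t", index=False)
    write_gene_annotation(dataset.annotation, directory / files["annotation"], "gff3")
    dataset.deg_tables.to_csv(directory / files["degs"], sep="\t", index=False,
                              float_format="%.10g")
    dataset.truth.categories.to_csv(directory / files["truth_categories"], sep="\t",
                                    index=False, float_format="%.10g")
    dataset.truth.deg.to_csv(directory / files["truth_deg"], sep="\t", index=False,
                             float_format="%.10g")
    dataset.truth.biomarkers.to_csv(directory / files["truth_biomarkers"], sep="\t",
                                    index=False)
    dataset.truth.deg_genes.to_csv(directory / files["truth_deg_genes"], sep="\t",
                                   index=False)
    manifest = {
        "config": _config_to_jsonable(dataset.config),
        "seed": dataset.config.seed,
        "files": files,
        "hotspots": [dataclasses.asdict(h) for h in dataset.truth.hotspots],
    }
    with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    files["manifest"] = "manifest.json"
    return files
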