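import numpy as np
import pandas as pd
import pytest

from triadscan import (StableBiasSet, average_stability, deg_overlap,
                       overall_unchanged_fraction, per_category_stability,
                       stable_triads, transition_matrices, unique_stable_biased)
from triadscan.triads import CATEGORIES, UNDEFINED

from conftest import random_assignment


def _mini_assignment(per_stage):
    """per_stage: dict triad -> (cat_d0, cat_d7, cat_d21) for one genotype."""
    rows = []
    stages = ("Day0", "Day7", "Day21")
    for t, cats in per_stage.items():
        for s, c in zip(stages, cats):
            rows.append((t, "G", s, c))
    df = pd.DataFrame(rows, columns=["triad_id", "genotype", "stage", "category"])
    df["stage"] = pd.Categorical(df["stage"], categories=stages, ordered=True)
    return df


class TestStableTriads:
    def test_constant_category_is_stable(self):
        a = _mini_assignment({"t1": ("balanced",) * 3})
        assert stable_triads(a, "G")["balanced"] == {"t1"}

    def test_change_breaks_stability(self):
        a = _mini_assignment({"t1": ("balanced", "balanced", "B_suppressed")})
        assert all(len(v) == 0 for v in stable_triads(a, "G").values())

    def test_undefined_never_stable(self):
        a = _mini_assignment({"t1": (UNDEFINED,) * 3})
        assert all(len(v) == 0 for v in stable_triads(a, "G").values())

    def test_matches_brute_force(self):
        a = random_assignment(seed=20)
        got = stable_triads(a, "G1")
        sub = a[a["genotype"] == "G1"]
        brute = {c: set() for c in CATEGORIES}
        for t, grp in sub.groupby("triad_id"):
            cats = set(grp["category"])
            if len(cats) == 1 and UNDEFINED not in cats:
                brute[cats.pop()].add(t)
        assert {c: set(v) for c, v in got.items()} == brute

    def test_stable_sets_disjoint(self):
        got = stable_triads(random_assignment(seed=21), "G2")
        all_ids = [t for v in got.values() for t in v]
        assert len(all_ids) == len(set(all_ids))

    def test_missing_stage_errors(self):
        a = _mini_assignment({"t1": ("balanced",) * 3})
        with pytest.raises(ValueError, match="Day21"):
            stable_triads(a[a["stage"] != "Day21"], "G")


class TestOverallUnchanged:
    def test_matches_brute_force(self):
        a = random_assignment(seed=22)
        sub = a[a["genotype"] == "G1"]
        num = den = 0
        for _, grp in sub.groupby("triad_id"):
            cats = list(grp["category"])
            if UNDEFINED in cats:
                continue
            den += 1
            num += len(set(cats)) == 1
        assert overall_unchanged_fraction(a, "G1") == pytest.approx(num / den)


class TestPerCategoryStability:
    def test_all_stable_gives_one(self):
        a = _mini_assignment({"t1": ("balanced",) * 3,
                              "t2": ("B_suppressed",) * 3})
        frac = per_category_stability(a, "G")
        assert frac.loc["balanced"].tolist() == [1.0, 1.0, 1.0]
        assert frac.loc["B_suppressed"].tolist() == [1.0, 1.0, 1.0]

    def test_none_stable_gives_zero(self):
        a = _mini_assignment({"t1": ("balanced", "A_dominant", "balanced")})
        frac = per_category_stability(a, "G")
        assert frac.loc["balanced", "Day0"] == 0.0

    def test_empty_category_is_nan_not_zero(self):
        a = _mini_assignment({"t1": ("balanced",) * 3})
        frac = per_category_stability(a, "G")
        assert np.isnan(frac.loc["D_dominant", "Day0"])

    def test_matches_brute_force(self):
        a = random_assignment(seed=23)
        frac = per_category_stability(a, "G2")
        sub = a[a["genotype"] == "G2"]
        wide = sub.pivot(index="triad_id", columns="stage", values="category")
        stable = {c: set() for c in CATEGORIES}
        for t, row in wide.iterrows():
            if row.nunique() == 1 and row.iloc[0] != UNDEFINED:
                stable[row.iloc[0]].add(t)
        for cat in CATEGORIES:
            for stage in wide.columns:
                members = set(wide.index[wide[stage] == cat])
                if not members:
                    assert np.isnan(frac.loc[cat, stage])
                else:
                    assert frac.loc[cat, stage] == pytest.approx(
                        len(members & stable[cat]) / len(members))


class TestAverageStability:
    def test_mean_of_three(self):
        a = random_assignment(seed=24)
        frac = per_category_stability(a, "G1").loc["balanced"]
        mean, partial = average_stability(a, "G1", "balanced")
        assert mean == pytest.approx(frac.mean())
        assert partial == bool(frac.isna().any())

    def test_partial_flag_when_stage_empty(self):
        a = _mini_assignment({"t1": ("balanced", "A_dominant", "balanced")})
        _, partial = average_stability(a, "G", "A_dominant")
        assert partial


class TestTransitions:
    def test_counts_conserved(self):
        a = random_assignment(seed=25)
        mats = transition_matrices(a, "G1")
        n_triads = a[a["genotype"] == "G1"]["triad_id"].nunique()
        for mat in mats.values():
            assert mat.to_numpy().sum() == n_triads

    def test_row_sums_equal_source_counts(self):
        a = random_assignment(seed=26)
        mats = transition_matrices(a, "G1")
        sub = a[a["genotype"] == "G1"]
        for (s1, _), mat in mats.items():
            source = sub[sub["stage"] == s1]["category"].value_counts()
            for cat, n in source.items():
                assert mat.loc[cat].sum() == n


class TestUniqueStable:
    def test_identical_assignments_empty(self):
        a = random_assignment(seed=27, genotypes=("G1",))
        b = a.assign(genotype="G2")
        both = pd.concat([a, b], ignore_index=True)
        both["stage"] = pd.Categorical(both["stage"],
                                       ["Day0", "Day7", "Day21"], ordered=True)
        out = unique_stable_biased(both, _triad_table(), "G1", "G2",
                                   "B_suppressed")
        assert out.triad_ids == frozenset()

    def test_matches_brute_force_difference(self):
        a = random_assignment(seed=28)
        out = unique_stable_biased(a, _triad_table(), "G1", "G2", "B_suppressed")
        brute = set(stable_triads(a, "G1")["B_suppressed"]) \
            - set(stable_triads(a, "G2")["B_suppressed"])
        assert set(out.triad_ids) == brute
        lookup = _triad_table().set_index("triad_id")["gene_B"]
        assert set(out.focal_genes) == set(lookup.loc[sorted(brute)])

    def test_focal_subgenome_follows_category(self):
        a = random_assignment(seed=29)
        out = unique_stable_biased(a, _triad_table(), "G1", "G2", "D_dominant")
        assert all(g.startswith("D_of_") for g in out.focal_genes)

    def test_balanced_has_no_focal(self):
        with pytest.raises(ValueError, match="focal"):
            unique_stable_biased(random_assignment(seed=30), _triad_table(),
                                 "G1", "G2", "balanced")


def _triad_table(n=60):
    return pd.DataFrame({
        "triad_id": [f"T{i:03d}" for i in range(n)],
        "gene_A": [f"A_of_T{i:03d}" for i in range(n)],
        "gene_B": [f"B_of_T{i:03d}" for i in range(n)],
        "gene_D": [f"D_of_T{i:03d}" for i in range(n)],
    })


def _random_degs(seed, genes, contrasts=("C1", "C2", "C3")):
    rng = np.random.default_rng(seed)
    rows = []
    for c in contrasts:
        for g in genes:
            rows.append((g, rng.normal(0, 2), rng.uniform(0, 1), c))
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "padj", "contrast"])


class TestDEGOverlap:
    def _set(self, genes):
        return StableBiasSet("G1", "B_suppressed", frozenset(), frozenset(genes))

    def test_no_hits(self):
        degs = _random_degs(31, [f"other{i}" for i in range(10)])
        out = deg_overlap(self._set(["x1", "x2"]), degs)
        assert out["count"] == 0 and out["fraction"] == 0.0

    def test_all_hit_in_one_contrast(self):
        genes = ["x1", "x2", "x3"]
        degs = pd.DataFrame({"gene_id": genes, "log2fc": 2.0, "padj": 1e-4,
                             "contrast": "C1"})
        out = deg_overlap(self._set(genes), degs)
        assert out["fraction"] == 1.0
        assert out["direction"] == {"up": 3, "down": 0}

    def test_empty_set_fraction_nan(self):
        out = deg_overlap(self._set([]), _random_degs(32, ["g"]))
        assert np.isnan(out["fraction"])

    def test_matches_brute_force(self):
        genes = [f"g{i}" for i in range(40)]
        degs = _random_degs(33, genes)
        focal = genes[::3]
        out = deg_overlap(self._set(focal), degs, fc_threshold=1.5,
                          padj_threshold=0.2)
        brute = {g for g in focal
                 if ((degs["gene_id"] == g) & (degs["log2fc"].abs() >= 1.5)
                     & (degs["padj"] < 0.2)).any()}
        assert out["count"] == len(brute)
        assert set(out["genes"]) == brute

    def test_monotone_in_thresholds(self):
        genes = [f"g{i}" for i in range(50)]
        degs = _random_degs(34, genes)
        focal = genes[:25]
        base = deg_overlap(self._set(focal), degs, 1.0, 0.05)["count"]
        assert deg_overlap(self._set(focal), degs, 2.0, 0.05)["count"] <= base
        assert deg_overlap(self._set(focal), degs, 1.0, 0.5)["count"] >= base
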