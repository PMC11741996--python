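"""Epitope densities, group statistics, permutation test, sweep filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import mhcrep as m
from mhcrep.density import DensityTable


def toy_table(values, groups, totals=None):
    df = pd.DataFrame(values)  # values: {allele: {virus: density}} -> columns=alleles
    return DensityTable(
        values=df,
        groups=groups,
        totals=totals or {v: 10_000 for v in df.index},
        threshold=1.0,
    )


def make_repertoire(n_binders, total, threshold=1.0):
    return m.BinderRepertoire(
        alleles=["A"],
        viruses=["v"],
        binders={("A", "v"): frozenset(f"PEPTIDE{i:03d}" for i in range(n_binders))},
        threshold=threshold,
        total_products={"v": total},
    )


class TestEpitopeDensity:
    def test_observed_equals_expected_gives_one(self):
        rep = make_repertoire(100, 10_000)
        assert m.epitope_density(rep, "v", "A") == pytest.approx(1.0)

    def test_zero_binders_give_zero(self):
        rep = m.BinderRepertoire(
            alleles=["A"], viruses=["v"], binders={("A", "v"): frozenset()},
            threshold=1.0, total_products={"v": 500},
        )
        assert m.epitope_density(rep, "v", "A") == 0.0

    def test_zero_products_is_error(self):
        rep = m.BinderRepertoire(
            alleles=["A"], viruses=["v"], binders={("A", "v"): frozenset()},
            threshold=1.0, total_products={"v": 0},
        )
        with pytest.raises(ValueError, match="zero digestion"):
            m.epitope_density(rep, "v", "A")

    def test_null_mean_density_near_one(self, small_reference):
        """Monte-Carlo: with viral peptides exchangeable with the reference
        pool, the mean density over draws is within 3 SE of 1."""
        from test_binding import make_model

        model = make_model(noise=0.5)
        ref = m.build_rank_reference(model, small_reference, (8, 9), 3000, seed=0)
        cfg = m.GeneratorConfig(seed=77, n_viruses=50, proteins_per_virus=2, protein_length=80)
        viruses, _ = m.generate_virus_set(cfg)
        panel = m.AllelePanel([m.PanelEntry("A", "g", model)])
        rep = m.build_repertoire(panel, viruses, {"A": ref}, lengths=(8, 9), threshold=1.0)
        densities = [m.epitope_density(rep, v, "A") for v in rep.viruses]
        se = np.std(densities, ddof=1) / np.sqrt(len(densities))
        assert abs(np.mean(densities) - 1.0) < 3 * se + 0.02


class TestMeanDensity:
    def test_single_virus_returns_its_density(self):
        t = toy_table({"A": {"v1": 0.7}}, {"A": "g"})
        assert m.mean_density(t, "A") == pytest.approx(0.7)

    def test_two_values_average(self):
        t = toy_table({"A": {"v1": 0.5, "v2": 1.5}}, {"A": "g"})
        assert m.mean_density(t, "A") == pytest.approx(1.0)

    def test_matches_loop_sum_oracle(self, rng):
        vals = {f"v{i}": float(rng.uniform(0, 3)) for i in range(20)}
        t = toy_table({"A": vals}, {"A": "g"})
        assert m.mean_density(t, "A") == pytest.approx(sum(vals.values()) / 20)


def exact_mannwhitney_p(x, y):
    """Exhaustive two-sided enumeration over group assignments (tie-free)."""
    pooled = list(x) + list(y)
    n, nm = len(x), len(x) * len(y)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    dev = abs(u_obs - nm / 2)
    total = hits = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(set(idx)) - nm / 2) >= dev - 1e-12:
            hits += 1
    return hits / total


class TestGroupCompare:
    def test_identical_multisets_give_p_one(self):
        t = toy_table(
            {"A": {f"v{i}": v for i, v in enumerate([1.0, 2.0, 3.0])},
             "B": {f"v{i}": v for i, v in enumerate([1.0, 2.0, 3.0])}},
            {"A": "g1", "B": "g2"},
        )
        (c,) = m.group_compare(t)
        assert c.p_value == pytest.approx(1.0)

    def test_separated_samples_match_exact_enumeration(self):
        t = toy_table(
            {"A": {f"v{i}": v for i, v in enumerate([1.0, 2.0, 3.0])},
             "B": {f"v{i}": v for i, v in enumerate([4.0, 5.0, 6.0])}},
            {"A": "g1", "B": "g2"},
        )
        (c,) = m.group_compare(t)
        # U for group A against B is 0; exact p from full enumeration
        assert min(c.u_statistic, 9 - c.u_statistic) == 0
        assert c.p_value == pytest.approx(exact_mannwhitney_p([1, 2, 3], [4, 5, 6]))

    def test_random_small_groups_match_exact_enumeration(self, rng):
        for _ in range(10):
            x = rng.permutation(np.arange(1.0, 9.0))[: rng.integers(3, 5)]
            y = rng.permutation(np.arange(10.0, 20.0))[: rng.integers(3, 5)]
            y = y + rng.uniform(-9, 0)  # overlap the ranges, keep values distinct
            from scipy import stats

            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            assert res.pvalue == pytest.approx(exact_mannwhitney_p(list(x), list(y)))

    def test_four_groups_make_six_bonferroni_corrected_pairs(self):
        values = {}
        groups = {}
        rng = np.random.default_rng(0)
        for g in range(4):
            for a in range(2):
                name = f"A{g}{a}"
                values[name] = {f"v{i}": float(rng.uniform(0, 2)) for i in range(4)}
                groups[name] = f"g{g}"
        comps = m.group_compare(toy_table(values, groups))
        assert len(comps) == 6
        for c in comps:
            assert c.p_adjusted == pytest.approx(min(1.0, 6 * c.p_value))
            assert c.p_adjusted >= c.p_value

    def test_fewer_than_two_groups_is_error(self):
        t = toy_table({"A": {"v1": 1.0}}, {"A": "g"})
        with pytest.raises(ValueError):
            m.group_compare(t)


class TestPermutationTest:
    def test_exact_enumeration_small_panels(self):
        # 5 alleles, focal of size 2: all C(5,2)=10 assignments enumerable
        vals = {"A1": 0.1, "A2": 0.2, "B1": 1.5, "B2": 1.8, "B3": 2.0}
        groups = {a: ("f" if a.startswith("A") else "o") for a in vals}
        t = toy_table({a: {"v": v} for a, v in vals.items()}, groups)
        p = m.permutation_test(t, "v", "f", n_perm=10_000)
        # observed statistic is the unique minimum over assignments
        assert p == pytest.approx(1 / 10)

    def test_matches_manual_enumeration(self, rng):
        vals = {f"A{i}": float(v) for i, v in enumerate(rng.uniform(0, 2, size=6))}
        groups = {a: ("f" if i < 2 else "o") for i, a in enumerate(vals)}
        t = toy_table({a: {"v": v} for a, v in vals.items()}, groups)
        arr = np.array(list(vals.values()))
        obs = arr[:2].mean() - arr[2:].mean()
        hits = total = 0
        for idx in itertools.combinations(range(6), 2):
            sel = np.zeros(6, dtype=bool)
            sel[list(idx)] = True
            total += 1
            if arr[sel].mean() - arr[~sel].mean() <= obs + 1e-12:
                hits += 1
        assert m.permutation_test(t, "v", "f") == pytest.approx(hits / total)

    def test_extreme_low_focal_group_is_significant(self):
        rng = np.random.default_rng(1)
        vals = {f"F{i}": float(rng.uniform(0.0, 0.1)) for i in range(4)}
        vals |= {f"O{i}": float(rng.uniform(1.5, 2.5)) for i in range(20)}
        groups = {a: ("f" if a.startswith("F") else "o") for a in vals}
        t = toy_table({a: {"v": v} for a, v in vals.items()}, groups)
        assert m.permutation_test(t, "v", "f", n_perm=10_000, seed=0) <= 0.01

    def test_null_p_values_are_roughly_uniform(self, rng):
        """Random labels on exchangeable densities: KS check on p-values."""
        from scipy import stats

        ps = []
        for rep in range(60):
            vals = {f"A{i}": float(v) for i, v in enumerate(rng.normal(1, 0.2, size=12))}
            groups = {a: ("f" if i < 4 else "o") for i, a in enumerate(vals)}
            t = toy_table({a: {"v": v} for a, v in vals.items()}, groups)
            ps.append(m.permutation_test(t, "v", "f", n_perm=400, seed=rep))
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_grouping_is_error(self):
        t = toy_table({"A": {"v": 1.0}, "B": {"v": 2.0}}, {"A": "f", "B": "f"})
        with pytest.raises(ValueError):
            m.permutation_test(t, "v", "f")


class TestSweepFilter:
    def base_table(self, focal_vals, other_vals, n_other=12):
        values = {}
        groups = {}
        for i, v in enumerate(focal_vals):
            values[f"F{i}"] = {"virus": v}
            groups[f"F{i}"] = "f"
        for i in range(n_other):
            values[f"O{i}"] = {"virus": other_vals[i] if i < len(other_vals) else 0.5}
            groups[f"O{i}"] = "o"
        return toy_table(values, groups)

    def test_clear_candidate_passes(self):
        t = self.base_table([0.5, 0.5, 0.5], [2.5] * 12)
        focal = [a for a in t.alleles if a.startswith("F")]
        other = [a for a in t.alleles if a.startswith("O")]
        assert m.sweep_candidate_filter(t, focal, other) == ["virus"]

    def test_boundary_density_exactly_one_fails(self):
        t = self.base_table([0.5, 1.0, 0.5], [2.5] * 12)
        focal = [a for a in t.alleles if a.startswith("F")]
        other = [a for a in t.alleles if a.startswith("O")]
        assert m.sweep_candidate_filter(t, focal, other) == []

    def test_too_few_high_presenters_fails(self):
        t = self.base_table([0.5, 0.5, 0.5], [2.5] * 9)  # only 9 > high
        focal = [a for a in t.alleles if a.startswith("F")]
        other = [a for a in t.alleles if a.startswith("O")]
        assert m.sweep_candidate_filter(t, focal, other, min_count=10) == []

    def test_overlapping_sets_rejected(self):
        t = self.base_table([0.5], [2.5] * 12)
        with pytest.raises(ValueError, match="overlap"):
            m.sweep_candidate_filter(t, ["F0"], ["F0", "O1"])

    def test_matches_brute_force_rule_and_monotonicity(self, rng):
        alleles = [f"F{i}" for i in range(3)] + [f"O{i}" for i in range(12)]
        values = {
            a: {f"v{j}": float(rng.uniform(0, 3)) for j in range(15)} for a in alleles
        }
        t = toy_table(values, {a: ("f" if a.startswith("F") else "o") for a in alleles})
        focal = [a for a in alleles if a.startswith("F")]
        other = [a for a in alleles if a.startswith("O")]
        got = m.sweep_candidate_filter(t, focal, other, low=1.0, high=2.0, min_count=4)
        expected = [
            v
            for v in t.viruses
            if all(values[f][v] < 1.0 for f in focal)
            and sum(values[o][v] > 2.0 for o in other) >= 4
        ]
        assert got == expected
        # monotone: tightening any knob never adds a virus
        for low, high, mc in [(0.8, 2.0, 4), (1.0, 2.4, 4), (1.0, 2.0, 6)]:
            tighter = m.sweep_candidate_filter(t, focal, other, low=low, high=high, min_count=mc)
            assert set(tighter) <= set(got)


class TestSelfPresentation:
    def test_short_protein_yields_zero_zero(self, small_reference):
        from test_binding import make_model

        model = make_model()
        ref = m.build_rank_reference(model, small_reference, (8, 9), 100, seed=0)
        prot = m.ProteomeSet("self", [m.ProteinRecord("tiny", "", "ACDEF")])
        df = m.self_presentation(prot, model, ref, lengths=(8, 9))
        assert df.loc["tiny", "expected"] == 0
        assert df.loc["tiny", "observed"] == 0
        assert math.isnan(df.loc["tiny", "ratio"])

    def test_full_threshold_gives_ratio_one(self, small_reference):
        from test_binding import make_model

        model = make_model(noise=0.2)
        ref = m.build_rank_reference(model, small_reference, (8, 9), 100, seed=0)
        prot = m.ProteomeSet(
            "self", [m.ProteinRecord("p", "", "ACDEFGHIKLMNPQRSTVWY")]
        )
        df = m.self_presentation(prot, model, ref, lengths=(8, 9), threshold=100.0)
        assert df.loc["p", "ratio"] == pytest.approx(1.0)

    def test_null_mean_ratio_near_one(self, small_config, small_reference):
        from test_binding import make_model

        model = make_model(noise=0.5)
        ref = m.build_rank_reference(model, small_reference, (8, 9), 3000, seed=4)
        cfg = m.GeneratorConfig(seed=99, n_self_proteins=200, reference_length_range=(60, 120))
        selfp = m.generate_self_proteome(cfg)
        df = m.self_presentation(selfp, model, ref, lengths=(8, 9), threshold=1.0)
        se = df["ratio"].std(ddof=1) / np.sqrt(len(df))
        assert abs(df["ratio"].mean() - 1.0) < 3 * se + 0.02
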