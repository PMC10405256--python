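"""Resistance calls, Cohen's D, the permutation-FDR estimator and mutation rules."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lineagedep as ld
from lineagedep.resistance import (
    acquired_dependency_scan,
    classify_ccle_mutants,
    classify_cell_lines,
    cohens_d,
    mutation_enrichment,
    permutation_fdr,
)
from lineagedep.lineage import LineageDependencySet
from lineagedep.simulate import DependencySimParams, generate_dependency_bundle


def make_calls(labels, lineage="mel"):
    return pd.DataFrame({
        "cell_line": [f"L{i}" for i in range(len(labels))],
        "lineage": lineage,
        "avg_ceres": [0.0 if l == "resistant" else -1.0 for l in labels],
        "label": labels,
    })


class TestClassification:
    @pytest.mark.parametrize("value,expected", [(-0.44, "resistant"),
                                                (-0.46, "sensitive")])
    def test_boundary_at_cutoff(self, value, expected):
        ceres = pd.DataFrame({"t": [value]}, index=["L0"])
        ann = pd.DataFrame({"cell_line": ["L0"], "lineage": ["x"]})
        sets = {"x": LineageDependencySet(lineage="x", tfs=["t"])}
        calls = classify_cell_lines(ceres, sets, ann)
        assert calls.loc[0, "label"] == expected

    def test_planted_labels_recovered_exactly(self, resistant_bundle):
        bundle, truth = resistant_bundle
        sets = {lin: LineageDependencySet(lineage=lin, tfs=[tf for tf, _ in v])
                for lin, v in truth.planted_ld.items()}
        calls = classify_cell_lines(bundle.ceres, sets, bundle.annotations)
        truth_resistant = {l for v in truth.resistant_lines.values() for l in v}
        predicted = set(calls.loc[calls["label"] == "resistant", "cell_line"])
        assert predicted == truth_resistant

    def test_melanoma_shaped_group_sizes(self):
        """A 49-line lineage splits 30 sensitive / 19 resistant."""
        params = DependencySimParams(resistant_fraction=19 / 49,
                                     n_acquired_per_lineage=0)
        bundle, truth = generate_dependency_bundle(
            n_lineages=1, lines_per_lineage=49, n_genes=30, n_tfs=20,
            params=params, seed=21)
        lin = next(iter(truth.planted_ld))
        sets = {lin: LineageDependencySet(
            lineage=lin, tfs=[tf for tf, _ in truth.planted_ld[lin]])}
        calls = classify_cell_lines(bundle.ceres, sets, bundle.annotations)
        counts = calls["label"].value_counts()
        assert counts["sensitive"] == 30
        assert counts["resistant"] == 19


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_textbook_oracle(self):
        # s_a2 = s_b2 = 2, pooled sd = sqrt(2), d = 2/sqrt(2)
        assert cohens_d([2, 4], [0, 2]) == pytest.approx(2 / math.sqrt(2),
                                                         abs=1e-12)

    def test_zero_variance_unequal_means_is_infinite(self):
        assert cohens_d([1, 1], [0, 0]) == math.inf
        assert cohens_d([0, 0], [1, 1]) == -math.inf

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=8),
           st.lists(st.floats(-10, 10), min_size=2, max_size=8))
    def test_antisymmetry(self, a, b):
        d1, d2 = cohens_d(a, b), cohens_d(b, a)
        if math.isfinite(d1):
            assert d1 == pytest.approx(-d2, abs=1e-9)
        else:
            assert d1 == -d2


def enumeration_oracle(X, resistant, genes):
    """Brute-force FDR/q over ALL label assignments, straight arithmetic."""
    n, n_res = len(X), int(resistant.sum())

    def d_for(mask):
        return np.array([cohens_d(X[mask, j], X[~mask, j])
                         for j in range(X.shape[1])])

    d_obs = d_for(resistant)
    perms = []
    for combo in itertools.combinations(range(n), n_res):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        perms.append(d_for(mask))
    abs_perm = np.abs(np.array(perms))
    abs_obs = np.abs(d_obs)
    n_perm = len(perms)
    fdr = np.empty(len(genes))
    for i in range(len(genes)):
        num = (abs_perm >= abs_obs[i]).sum() / n_perm
        den = (abs_obs >= abs_obs[i]).sum()
        fdr[i] = min(num / den, 1.0)
    q = np.empty(len(genes))
    for i in range(len(genes)):
        q[i] = fdr[abs_obs <= abs_obs[i]].min()
    return d_obs, fdr, q


class TestPermutationFdr:
    def test_matches_full_enumeration(self):
        """4-line, 2-gene fixture: exhaustive mode equals the brute-force oracle."""
        X = np.array([[0.1, -1.2], [0.3, -1.0], [-0.2, 0.2], [0.0, 0.1]])
        ceres = pd.DataFrame(X, index=[f"L{i}" for i in range(4)],
                             columns=["g1", "g2"])
        calls = make_calls(["resistant", "resistant", "sensitive", "sensitive"])
        result = permutation_fdr(ceres, calls, ["g1", "g2"], exhaustive=True)
        d_exp, fdr_exp, q_exp = enumeration_oracle(
            X, np.array([True, True, False, False]), ["g1", "g2"])
        np.testing.assert_allclose(result["d_obs"], d_exp, atol=1e-12)
        np.testing.assert_allclose(result["fdr_hat"], fdr_exp, atol=1e-12)
        np.testing.assert_allclose(result["q_value"], q_exp, atol=1e-12)

    def test_dominant_gene_has_zero_fdr(self):
        """A gene more extreme than every permuted value of every gene."""
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.1, (12, 10))
        X[:6, 0] -= 50.0  # overwhelming separation in gene 0
        ceres = pd.DataFrame(X, index=[f"L{i}" for i in range(12)],
                             columns=[f"g{j}" for j in range(10)])
        calls = make_calls(["resistant"] * 6 + ["sensitive"] * 6)
        res = permutation_fdr(ceres, calls, list(ceres.columns),
                              n_permutations=200, seed=1)
        row = res.set_index("gene").loc["g0"]
        assert row["fdr_hat"] == 0.0
        assert row["q_value"] == 0.0
        assert bool(row["significant"])

    def test_q_monotone_in_abs_d(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 1, (14, 40))
        ceres = pd.DataFrame(X, index=[f"L{i}" for i in range(14)],
                             columns=[f"g{j}" for j in range(40)])
        calls = make_calls(["resistant"] * 7 + ["sensitive"] * 7)
        res = permutation_fdr(ceres, calls, list(ceres.columns),
                              n_permutations=100, seed=2)
        srt = res.reindex(res["d_obs"].abs().sort_values().index)
        assert (np.diff(srt["q_value"]) <= 1e-12).all()
        assert ((res["fdr_hat"] >= 0) & (res["fdr_hat"] <= 1)).all()

    def test_invariant_to_gene_and_call_order(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (10, 6))
        ceres = pd.DataFrame(X, index=[f"L{i}" for i in range(10)],
                             columns=[f"g{j}" for j in range(6)])
        calls = make_calls(["resistant"] * 5 + ["sensitive"] * 5)
        base = permutation_fdr(ceres, calls, list(ceres.columns),
                               n_permutations=50, seed=4)
        rev_genes = permutation_fdr(ceres, calls, list(ceres.columns)[::-1],
                                    n_permutations=50, seed=4)
        merged = base.set_index("gene").join(rev_genes.set_index("gene"),
                                             rsuffix="_rev")
        np.testing.assert_allclose(merged["fdr_hat"], merged["fdr_hat_rev"])
        shuffled_calls = calls.sample(frac=1, random_state=0)
        reordered = permutation_fdr(ceres, shuffled_calls, list(ceres.columns),
                                    n_permutations=50, seed=4)
        np.testing.assert_allclose(base["fdr_hat"], reordered["fdr_hat"])

    def test_planted_acquired_dependency_detected(self, resistant_bundle):
        bundle, truth = resistant_bundle
        sets = {lin: LineageDependencySet(lineage=lin, tfs=[tf for tf, _ in v])
                for lin, v in truth.planted_ld.items()}
        calls = classify_cell_lines(bundle.ceres, sets, bundle.annotations)
        scan = acquired_dependency_scan(bundle.ceres, calls,
                                        n_permutations=300, seed=6)
        for lin, acq in truth.acquired_dep_genes.items():
            sub = scan[scan["lineage"] == lin].set_index("gene")
            for gene, _ in acq:
                assert bool(sub.loc[gene, "significant"])

    def test_rejects_single_class(self):
        ceres = pd.DataFrame(np.zeros((4, 2)), index=[f"L{i}" for i in range(4)],
                             columns=["a", "b"])
        calls = make_calls(["resistant"] * 4)
        with pytest.raises(ValueError):
            permutation_fdr(ceres, calls, ["a", "b"])


class TestMutationEnrichment:
    def fisher_oracle(self, table):
        """Two-sided Fisher p by hypergeometric enumeration."""
        a, b = table[0]
        c, d = table[1]
        row1, col1, n = a + b, a + c, a + b + c + d

        def prob(x):
            return (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                    / math.comb(n, row1))
        p_obs = prob(a)
        return sum(prob(x) for x in range(max(0, row1 + col1 - n),
                                          min(row1, col1) + 1)
                   if prob(x) <= p_obs * (1 + 1e-9))

    def test_matches_enumeration_oracle(self):
        # shaped like a 47% vs 28% mutant-fraction contrast
        labels = ["resistant"] * 19 + ["sensitive"] * 30
        calls = make_calls(labels)
        mutant_lines = [f"L{i}" for i in range(9)] + \
                       [f"L{i}" for i in range(19, 27)]
        mutations = pd.DataFrame({
            "cell_line": mutant_lines, "gene": "TP53",
            "variant_classification": "missense", "is_deleterious": True,
            "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
        })
        odds, p, table = mutation_enrichment(mutations, calls, "TP53")
        assert table.tolist() == [[9, 10], [8, 22]]
        assert p == pytest.approx(self.fisher_oracle(table), abs=1e-9)

    def test_no_mutants_gives_p_one(self):
        calls = make_calls(["resistant"] * 3 + ["sensitive"] * 3)
        mutations = pd.DataFrame(columns=["cell_line", "gene",
                                          "variant_classification",
                                          "is_deleterious", "is_tcga_hotspot",
                                          "is_cosmic_hotspot"])
        odds, p, table = mutation_enrichment(mutations, calls, "TP53")
        assert p == 1.0
        assert math.isnan(odds)

    def test_symmetric_table_odds_one(self):
        calls = make_calls(["resistant"] * 10 + ["sensitive"] * 10)
        mutant = [f"L{i}" for i in range(5)] + [f"L{i}" for i in range(10, 15)]
        mutations = pd.DataFrame({
            "cell_line": mutant, "gene": "X",
            "variant_classification": "missense", "is_deleterious": True,
            "is_tcga_hotspot": False, "is_cosmic_hotspot": False,
        })
        odds, p, table = mutation_enrichment(mutations, calls, "X")
        assert odds == pytest.approx(1.0)
        assert p == pytest.approx(1.0)


class TestCcleMutantRules:
    def make(self, rows, vhl_scores):
        mutations = pd.DataFrame(rows, columns=["cell_line", "gene",
                                                "variant_classification",
                                                "is_deleterious",
                                                "is_tcga_hotspot",
                                                "is_cosmic_hotspot"])
        ceres = pd.DataFrame({"VHL": vhl_scores})
        return mutations, ceres

    def test_ccrcc_requires_disruptive_vhl_and_ko_resistance(self):
        rows = [("L0", "VHL", "damaging", True, False, False),
                ("L1", "VHL", "damaging", True, False, False),
                ("L2", "VHL", "missense", False, False, False)]
        mutations, ceres = self.make(rows, pd.Series(
            [-0.2, -0.8, -0.2], index=["L0", "L1", "L2"]))
        flags = classify_ccle_mutants(mutations, ceres).set_index("cell_line")
        assert bool(flags.loc["L0", "is_ccRCC"])      # damaging + CERES > -0.5
        assert not flags.loc["L1", "is_ccRCC"]        # still VHL-dependent
        assert not flags.loc["L2", "is_ccRCC"]        # not a disruptive class

    def test_functional_mutation_rule(self):
        rows = [("L0", "SMARCB1", "damaging", True, False, False),
                ("L1", "SMARCB1", "missense", False, True, False),
                ("L2", "SMARCB1", "silent", False, True, True),
                ("L3", "SMARCB1", "missense", False, False, False)]
        mutations, ceres = self.make(rows, pd.Series(
            [0.0] * 4, index=["L0", "L1", "L2", "L3"]))
        flags = classify_ccle_mutants(mutations, ceres).set_index("cell_line")
        assert bool(flags.loc["L0", "smarcb1_functional"])   # disruptive class
        assert bool(flags.loc["L1", "smarcb1_functional"])   # hotspot missense
        assert not flags.loc["L2", "smarcb1_functional"]     # silent hotspot
        assert not flags.loc["L3", "smarcb1_functional"]     # plain missense

    def test_generator_flags_recovered(self, resistant_bundle):
        bundle, truth = resistant_bundle
        flags = classify_ccle_mutants(bundle.mutations,
                                      bundle.ceres).set_index("cell_line")
        for line, expected in truth.ccle_flags.items():
            for key, val in expected.items():
                assert bool(flags.loc[line, key]) == val, (line, key)
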