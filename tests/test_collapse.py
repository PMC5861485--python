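import itertools
import math
from collections import Counter

import numpy as np
import pytest

from rvinteract.collapse import (
    MISSING,
    DegenerateGeneWarning,
    GenotypeDataset,
    WeightScheme,
    compute_maf,
    directional_ig,
    effect_collapse,
    functional_collapse,
    maf_collapse,
)
from rvinteract.measures import entropy, information_gain

from conftest import random_dataset


def make_dataset(genotypes, gene_of=None, maf=None, category=None, phenotype=None,
                 conservation=None):
    genotypes = np.asarray(genotypes)
    v = genotypes.shape[1]
    return GenotypeDataset(
        genotypes=genotypes,
        variant_ids=[f"v{j}" for j in range(v)],
        gene_of=gene_of if gene_of is not None else ["GENE"] * v,
        maf=maf,
        category=category,
        phenotype=phenotype,
        conservation=conservation,
    )


class TestComputeMaf:
    def test_all_zero_column(self):
        ds = make_dataset(np.zeros((10, 1), dtype=int))
        assert compute_maf(ds)[0] == 0.0

    def test_hand_count(self):
        ds = make_dataset(np.array([[0], [1], [2], [0]]))
        assert compute_maf(ds)[0] == pytest.approx(0.375)

    def test_folding(self):
        ds = make_dataset(np.full((10, 1), 2))
        assert compute_maf(ds)[0] == 0.0

    def test_missing_excluded_from_denominator(self):
        ds = make_dataset(np.array([[1], [MISSING], [0], [MISSING]]))
        assert compute_maf(ds)[0] == pytest.approx(0.25)  # 1 allele / 4

    def test_all_missing_flagged(self):
        ds = make_dataset(np.full((5, 1), MISSING))
        with pytest.warns(UserWarning, match="missing"):
            maf = compute_maf(ds)
        assert np.isnan(maf[0])


class TestMafCollapse:
    def test_weight_threshold(self):
        # two variants in one gene: rare (weight 1) and common (weight 0)
        geno = np.array([[0, 2], [1, 2], [2, 0]])
        ds = make_dataset(geno, maf=[0.005, 0.02])
        out = maf_collapse(ds, WeightScheme("maf", n_bins=2))
        assert out.values[:, 0].tolist() == [0, 1, 1]

    def test_zero_sum_is_zero_both_binnings(self):
        geno = np.array([[0, 0, 0], [1, 1, 0]])
        ds = make_dataset(geno, maf=[0.004, 0.004, 0.004])
        for bins in (2, 3):
            out = maf_collapse(ds, WeightScheme("maf", n_bins=bins))
            assert out.values[0, 0] == 0

    def test_binning_two_rare_alleles(self):
        geno = np.array([[1, 1, 0]])
        ds = make_dataset(geno, maf=[0.004, 0.004, 0.004])
        assert maf_collapse(ds, WeightScheme("maf", n_bins=2)).values[0, 0] == 1
        assert maf_collapse(ds, WeightScheme("maf", n_bins=3)).values[0, 0] == 2

    def test_degenerate_gene_warns_constant_zero(self):
        ds = make_dataset(np.array([[1], [2]]), maf=[0.3])
        with pytest.warns(DegenerateGeneWarning):
            out = maf_collapse(ds, WeightScheme("maf"))
        assert (out.values == 0).all()

    def test_two_bin_equals_thresholded_three_bin(self, rng):
        ds = random_dataset(rng, n_samples=60, n_genes=4, n_snps=6, maf=0.05)
        ds.maf = np.full(ds.n_variants, 0.005)
        two = maf_collapse(ds, WeightScheme("maf", n_bins=2))
        three = maf_collapse(ds, WeightScheme("maf", n_bins=3))
        assert np.array_equal(two.values, (three.values > 0).astype(int))

    def test_variant_order_invariance(self, rng):
        ds = random_dataset(rng, n_samples=30, n_genes=2, n_snps=5, maf=0.05)
        ds.maf = rng.uniform(0.001, 0.02, ds.n_variants)
        ref = maf_collapse(ds, WeightScheme("maf", n_bins=3))
        perm = rng.permutation(ds.n_variants)
        shuffled = GenotypeDataset(
            genotypes=ds.genotypes[:, perm],
            variant_ids=[ds.variant_ids[j] for j in perm],
            gene_of=ds.gene_of[perm],
            maf=ds.maf[perm],
            phenotype=ds.phenotype,
        )
        out = maf_collapse(shuffled, WeightScheme("maf", n_bins=3))
        for gene in ref.genes:
            assert np.array_equal(ref.column(gene), out.column(gene))

    def test_sample_permutation_equivariance(self, rng):
        ds = random_dataset(rng, n_samples=30, n_genes=2, n_snps=5, maf=0.05)
        ds.maf = np.full(ds.n_variants, 0.005)
        ref = maf_collapse(ds, WeightScheme("maf"))
        perm = rng.permutation(ds.n_samples)
        permuted = GenotypeDataset(
            genotypes=ds.genotypes[perm],
            variant_ids=ds.variant_ids,
            gene_of=ds.gene_of,
            maf=ds.maf,
        )
        out = maf_collapse(permuted, WeightScheme("maf"))
        assert np.array_equal(out.values, ref.values[perm])


class TestFunctionalCollapse:
    def test_high_category_weighted(self):
        geno = np.array([[1, 0], [0, 1], [0, 0]])
        ds = make_dataset(geno, category=["high", "other"])
        out = functional_collapse(ds, WeightScheme("functional"))
        assert out.values[:, 0].tolist() == [1, 0, 0]

    def test_all_other_gene_is_zero(self):
        geno = np.array([[2, 1], [1, 1]])
        ds = make_dataset(geno, category=["other", "low"])
        with pytest.warns(DegenerateGeneWarning):
            out = functional_collapse(ds, WeightScheme("functional"))
        assert (out.values == 0).all()

    def test_moderate_het_carrier(self):
        geno = np.array([[1, 0, 0]])
        ds = make_dataset(geno, category=["moderate", "other", "other"])
        out = functional_collapse(ds, WeightScheme("functional"))
        assert out.values[0, 0] == 1

    def test_conservation_weighting(self):
        geno = np.array([[1, 1], [0, 1]])
        ds = make_dataset(geno, conservation=[0.9, 0.1])
        out = functional_collapse(
            ds, WeightScheme("functional", use_conservation=True)
        )
        assert out.values[:, 0].tolist() == [1, 0]


class TestDirectionalIg:
    def test_equal_rates_zero_both(self):
        y = [1, 1, 0, 0]
        carriers = [1, 0, 1, 0]
        assert directional_ig(carriers, y, "deleterious") == 0.0
        assert directional_ig(carriers, y, "protective") == 0.0

    def test_perfect_association_gating(self):
        y = [1] * 5 + [0] * 5
        carriers = [1] * 5 + [0] * 5
        assert directional_ig(carriers, y, "deleterious") == pytest.approx(1.0)
        assert directional_ig(carriers, y, "protective") == 0.0

    def test_contingency_oracle(self):
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        carriers = np.array([1, 1, 1, 0, 1, 0, 0, 0])  # 3 case + 1 control carriers
        expected = (
            entropy(y)
            + entropy(carriers)
            - entropy([2 * a + b for a, b in zip(y, carriers)])
        )
        assert directional_ig(carriers, y, "deleterious") == pytest.approx(expected, abs=1e-12)
        assert directional_ig(carriers, y, "protective") == 0.0

    def test_constant_phenotype_errors(self):
        with pytest.raises(ValueError):
            directional_ig([1, 0], [1, 1], "deleterious")

    def test_unknown_direction(self):
        with pytest.raises(ValueError):
            directional_ig([1, 0], [1, 0], "sideways")


def brute_force_effect_selection(carriers, y, variant_ids, direction):
    """Exhaustive oracle over all prefix sets of the directional-IG ranking."""
    igs = []
    for j in range(carriers.shape[1]):
        case_rate = carriers[y == 1, j].mean()
        ctrl_rate = carriers[y == 0, j].mean()
        ok = case_rate >= ctrl_rate if direction == "deleterious" else ctrl_rate >= case_rate
        igs.append(information_gain(y, carriers[:, j].astype(int)) if ok else 0.0)
    ranked = sorted(
        (j for j in range(carriers.shape[1]) if igs[j] > 0),
        key=lambda j: (-igs[j], str(variant_ids[j])),
    )
    best, best_ig = [], 0.0
    for m in range(1, len(ranked) + 1):
        joint = carriers[:, ranked[:m]].any(axis=1).astype(int)
        jig = information_gain(y, joint)
        if jig > best_ig + 1e-12:
            best, best_ig = ranked[:m], jig
    return [variant_ids[j] for j in best]


class TestEffectCollapse:
    def test_single_perfect_variant(self):
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        geno = np.zeros((6, 2), dtype=int)
        geno[:3, 0] = 1  # tracks case status exactly
        ds = make_dataset(geno, phenotype=y)
        out = effect_collapse(ds, WeightScheme("effect"))
        assert out.selected_variants["GENE"][0] == ["v0"]
        assert out.values[:, 0].tolist() == [1, 1, 1, 0, 0, 0]

    def test_matches_bruteforce_on_toy(self, rng):
        y = np.array([1] * 6 + [0] * 6, dtype=float)
        # 2 deleterious-leaning + 1 protective-leaning variant
        geno = np.array(
            [
                [1, 0, 0], [1, 1, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1], [1, 1, 0],
                [0, 0, 1], [0, 0, 1], [1, 0, 0], [0, 0, 1], [0, 0, 0], [0, 1, 1],
            ]
        )
        ds = make_dataset(geno, phenotype=y)
        out = effect_collapse(ds, WeightScheme("effect"))
        carriers = (geno >= 1)
        vids = ds.variant_ids
        expected_del = brute_force_effect_selection(carriers, y, vids, "deleterious")
        expected_pro = brute_force_effect_selection(carriers, y, vids, "protective")
        assert out.selected_variants["GENE"] == (expected_del, expected_pro)
        d = carriers[:, [vids.index(v) for v in expected_del]].sum(axis=1) - carriers[
            :, [vids.index(v) for v in expected_pro]
        ].sum(axis=1)
        assert np.array_equal(out.values[:, 0], np.where(d > 0, 1, np.where(d < 0, 2, 0)))

    def test_all_zero_ig_warns(self):
        y = np.array([1, 0, 1, 0], dtype=float)
        geno = np.array([[1], [1], [0], [0]])  # equal carrier rates -> IG gated to 0
        ds = make_dataset(geno, phenotype=y)
        with pytest.warns(DegenerateGeneWarning):
            out = effect_collapse(ds, WeightScheme("effect"))
        assert (out.values == 0).all()

    def test_requires_binary_phenotype(self):
        ds = make_dataset(np.array([[1], [0]]), phenotype=np.array([0.3, 1.7]))
        with pytest.raises(ValueError):
            effect_collapse(ds, WeightScheme("effect"))

    def test_unidirectional_mode_binary_coding(self):
        y = np.array([1, 1, 0, 0], dtype=float)
        geno = np.array([[1, 0], [0, 0], [0, 1], [0, 1]])
        ds = make_dataset(geno, phenotype=y)
        out = effect_collapse(ds, WeightScheme("effect", direction_mode="unidirectional"))
        assert out.values.max() <= 1
        assert out.selected_variants["GENE"][1] == []

    def test_null_labels_give_near_zero_ig(self, rng):
        n = 200
        geno = rng.binomial(2, 0.08, size=(n, 6))
        y = np.array([1] * (n // 2) + [0] * (n // 2), dtype=float)
        igs = []
        import warnings

        for _ in range(100):
            yp = rng.permutation(y)
            ds = make_dataset(geno, phenotype=yp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", DegenerateGeneWarning)
                out = effect_collapse(ds, WeightScheme("effect"))
            igs.append(information_gain(yp.astype(int), out.values[:, 0]))
        assert np.mean(igs) < 0.05


class TestInvariants:
    def test_values_within_bins(self, rng):
        ds = random_dataset(rng, n_samples=50, n_genes=3, n_snps=5, maf=0.1)
        ds.maf = np.full(ds.n_variants, 0.005)
        for bins in (2, 3):
            out = maf_collapse(ds, WeightScheme("maf", n_bins=bins))
            assert out.values.max() <= bins - 1

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            make_dataset(np.array([[3]]))
        with pytest.raises(ValueError):
            GenotypeDataset(np.zeros((2, 2), dtype=int), ["a"], ["g", "g"])
        with pytest.raises(ValueError):
            make_dataset(np.zeros((2, 1), dtype=int), maf=[0.7])
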