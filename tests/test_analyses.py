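import itertools

import numpy as np
import pytest
from scipy import stats

from codonmuse.analyses import (
    DegenerateTestError,
    SpeciesEstimates,
    cpg_tpg_test,
    fdr_adjust,
    gc_fitness_slope,
    mutation_gc_at_difference,
    phylogenetic_contrasts,
    slope_vs_mutation_correlation,
    spearman_correlation,
)
from codonmuse.genetic_code import (
    CODONS,
    CODON_INDEX,
    classify_cpg_tpg,
    codon_nucleotide_counts,
)

GC = np.array([codon_nucleotide_counts(c).gc_content for c in CODONS], dtype=float)


def estimates_from_log_phi(log_phi, species_id="sp", log_beta=None, taxon=None):
    log_phi = np.asarray(log_phi, dtype=float)
    log_phi = log_phi - log_phi[CODON_INDEX["ATG"]]  # enforce the ATG reference
    return SpeciesEstimates(
        species_id=species_id,
        log_beta=log_beta or {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0},
        log_phi_codon=log_phi,
        taxon=taxon,
    )


class TestGcFitnessSlope:
    def test_exact_linear_data_recovers_slope(self):
        est = estimates_from_log_phi(-0.5 * GC)
        assert gc_fitness_slope(est) == pytest.approx(-0.5, abs=1e-12)

    def test_flat_fitness_gives_zero_slope(self):
        est = estimates_from_log_phi(np.zeros(64))
        assert gc_fitness_slope(est) == pytest.approx(0.0, abs=1e-12)

    def test_noisy_data_matches_normal_equations(self, rng):
        y = 0.3 * GC + rng.normal(0, 0.2, 64)
        est = estimates_from_log_phi(y)
        mask = est.sense_mask()
        x1, y1 = GC[mask], est.log_phi_codon[mask]
        design = np.stack([x1, np.ones_like(x1)], axis=1)
        slope_oracle = np.linalg.solve(design.T @ design, design.T @ y1)[0]
        assert gc_fitness_slope(est) == pytest.approx(slope_oracle, abs=1e-10)

    def test_intercept_shift_invariance(self, rng):
        y = rng.normal(0, 0.5, 64)
        a = gc_fitness_slope(estimates_from_log_phi(y))
        b = gc_fitness_slope(estimates_from_log_phi(y + 3.7))
        assert a == pytest.approx(b, abs=1e-10)

    def test_stop_codons_do_not_affect_slope(self, rng):
        y = rng.normal(0, 0.5, 64)
        y2 = y.copy()
        for stop in ("TAA", "TAG", "TGA"):
            y2[CODON_INDEX[stop]] -= 10.0
        assert gc_fitness_slope(estimates_from_log_phi(y)) == pytest.approx(
            gc_fitness_slope(estimates_from_log_phi(y2)), abs=1e-12
        )

    def test_grouped_means_option(self):
        est = estimates_from_log_phi(-0.25 * GC)
        assert gc_fitness_slope(est, grouped=True) == pytest.approx(-0.25, abs=1e-12)


class TestMutationDifference:
    def test_neutral_betas_give_zero(self):
        est = estimates_from_log_phi(np.zeros(64))
        assert mutation_gc_at_difference(est) == 0.0

    @pytest.mark.parametrize(
        "log_beta, expected",
        [
            ({"A": 0.0, "G": 1.0, "C": 1.0, "T": 0.0}, 1.0),
            ({"A": 0.0, "G": 2.0, "C": 0.0, "T": 0.0}, 1.0),
            ({"A": 0.0, "G": 0.0, "C": 0.0, "T": 1.0}, -0.5),
        ],
    )
    def test_arithmetic(self, log_beta, expected):
        est = estimates_from_log_phi(np.zeros(64), log_beta=log_beta)
        assert mutation_gc_at_difference(est) == pytest.approx(expected, abs=1e-12)


class TestSpearman:
    def test_perfect_monotone_relationships(self):
        x = np.arange(10.0)
        rho, _ = spearman_correlation(x, -(x**3))
        assert rho == pytest.approx(-1.0)
        rho, _ = spearman_correlation(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_exact_p_for_perfect_rank_agreement(self):
        # of 5! permutations only identity and reversal reach |rho| = 1
        rho, p = spearman_correlation([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120, abs=1e-12)

    def test_ties_match_brute_force_rank_formula(self, rng):
        x = np.array([1.0, 1.0, 2.0, 3.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 1.0, 3.0, 4.0, 4.0])

        def average_ranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = average_ranks(x), average_ranks(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        rho, _ = spearman_correlation(x, y)
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_large_sample_p_matches_scipy(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho, p = spearman_correlation(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateTestError):
            spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPhylogeneticContrasts:
    def test_two_tip_contrast(self):
        contrasts = phylogenetic_contrasts("(A:1.0,B:1.0);", {"A": 2.0, "B": 0.0})
        assert contrasts.shape == (1,)
        assert abs(contrasts[0]) == pytest.approx(2 / np.sqrt(2), abs=1e-12)

    def test_equal_tip_values_give_zero_contrasts(self):
        tree = "((A:1.0,B:2.0):0.5,(C:1.5,(D:0.7,E:0.3):0.4):1.1);"
        contrasts = phylogenetic_contrasts(tree, dict.fromkeys("ABCDE", 3.5))
        assert np.allclose(contrasts, 0.0)

    def test_three_tip_hand_worked_recursion(self):
        # ((A:1,B:2):0.5,C:3);  contrast(A,B) = (4-1)/sqrt(3)
        # node value = (4/1 + 1/2)/(1/1 + 1/2) = 3, node v = 0.5 + 2/3
        # contrast(node,C) = (3 - 6)/sqrt(0.5 + 2/3 + 3)
        got = phylogenetic_contrasts("((A:1.0,B:2.0):0.5,C:3.0);",
                                     {"A": 4.0, "B": 1.0, "C": 6.0})
        expected = np.array([3 / np.sqrt(3.0), -3 / np.sqrt(0.5 + 2 / 3 + 3)])
        assert np.allclose(got, expected, atol=1e-12)

    def test_matches_ape_pic_on_five_tip_tree(self):
        # frozen oracle from R: ape::pic on the same tree and trait values
        tree = "((A:1.0,B:2.0):0.5,(C:1.5,(D:0.7,E:0.3):0.4):1.1);"
        values = {"A": 2.0, "B": 0.5, "C": -1.0, "D": 3.0, "E": 1.2}
        expected = sorted(
            [0.335997602695457, 0.866025403784439, -1.886293790850949, 1.8]
        )
        got = sorted(phylogenetic_contrasts(tree, values))
        assert np.allclose(got, expected, atol=1e-12)

    def test_shift_invariance(self):
        tree = "((A:1.0,B:2.0):0.5,C:3.0);"
        values = {"A": 4.0, "B": 1.0, "C": 6.0}
        shifted = {k: v + 11.0 for k, v in values.items()}
        assert np.allclose(
            phylogenetic_contrasts(tree, values),
            phylogenetic_contrasts(tree, shifted),
        )

    def test_polytomy_rejected(self):
        with pytest.raises(ValueError):
            phylogenetic_contrasts("(A:1,B:1,C:1);", {"A": 1, "B": 2, "C": 3})

    def test_missing_tip_value_rejected(self):
        with pytest.raises(ValueError):
            phylogenetic_contrasts("(A:1,B:1);", {"A": 1.0})


def synthetic_species(rng, n_species, noise, cpg_shift=0.0):
    """Species whose fitness slope responds to the GC-AT mutation difference."""
    out = []
    for i in range(n_species):
        diff = rng.uniform(-1.0, 1.5)
        slope = -0.4 * diff + rng.normal(0, noise)
        log_phi = slope * GC + rng.normal(0, noise, size=64)
        if cpg_shift:
            for c in CODONS:
                if classify_cpg_tpg(c) == "CpG":
                    log_phi[CODON_INDEX[c]] += cpg_shift
        half = diff / 2.0
        out.append(
            estimates_from_log_phi(
                log_phi,
                species_id=f"sp{i}",
                log_beta={"A": 0.0, "T": rng.normal(0, 0.05),
                          "C": half + rng.normal(0, 0.05),
                          "G": half + rng.normal(0, 0.05)},
            )
        )
    return out


class TestCpgTpgTest:
    def test_exact_gc_line_is_degenerate(self):
        species = [
            estimates_from_log_phi(-0.3 * GC, species_id=f"s{i}") for i in range(8)
        ]
        with pytest.raises(DegenerateTestError):
            cpg_tpg_test(species, "CpG")

    def test_depressed_cpg_codons_detected_with_negative_median(self, rng):
        species = synthetic_species(rng, 15, noise=0.05, cpg_shift=-0.5)
        residuals, _, p = cpg_tpg_test(species, "CpG")
        assert p < 0.01
        assert np.median(residuals) < 0

    def test_null_residuals_not_significant(self, rng):
        species = synthetic_species(rng, 15, noise=0.1, cpg_shift=0.0)
        _, _, p = cpg_tpg_test(species, "CpG")
        assert p > 0.05

    def test_requires_minimum_species(self, rng):
        species = synthetic_species(rng, 4, noise=0.1)
        with pytest.raises(ValueError):
            cpg_tpg_test(species, "TpG")

    def test_unknown_class_rejected(self, rng):
        with pytest.raises(ValueError):
            cpg_tpg_test(synthetic_species(rng, 8, 0.1), "GpC")


class TestWilcoxonExactNull:
    def test_exact_p_matches_sign_flip_enumeration(self):
        values = np.array([0.3, -0.2, 0.8, 1.1, -0.4, 0.6, 0.9, -1.3])
        res = stats.wilcoxon(values, alternative="two-sided", method="exact")
        ranks = stats.rankdata(np.abs(values))
        observed = ranks[values > 0].sum()
        n = len(values)
        total = ranks.sum()
        stat_null = []
        for signs in itertools.product([0, 1], repeat=n):
            stat_null.append(sum(r for r, s in zip(ranks, signs) if s))
        stat_null = np.array(stat_null)
        # two-sided: distance from the mean of the null distribution
        dev = abs(observed - total / 2)
        p_oracle = np.mean(np.abs(stat_null - total / 2) >= dev - 1e-12)
        assert res.pvalue == pytest.approx(p_oracle, abs=1e-12)


class TestFdrAdjust:
    def test_hand_worked_step_up(self):
        adjusted = fdr_adjust([0.002, 0.01, 0.03, 0.04])
        assert np.allclose(adjusted, [0.008, 0.02, 0.04, 0.04], atol=1e-12)

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.123])[0] == pytest.approx(0.123)

    def test_all_ones_stay_one(self):
        assert np.allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_sorted_pvalues(self, rng):
        p = np.sort(rng.uniform(size=30))
        adjusted = fdr_adjust(p)
        assert np.all(np.diff(adjusted) >= -1e-15)
        assert np.all(adjusted >= p - 1e-15)
        assert np.all(adjusted <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


class TestSlopeVsMutationCorrelation:
    def test_negative_correlation_strengthens_as_noise_shrinks(self, rng):
        noisy = synthetic_species(rng, 30, noise=0.25)
        clean = synthetic_species(rng, 30, noise=0.02)
        with pytest.warns(UserWarning):
            rho_noisy, _ = slope_vs_mutation_correlation(noisy)
        with pytest.warns(UserWarning):
            rho_clean, p_clean = slope_vs_mutation_correlation(clean)
        assert rho_noisy < 0 and rho_clean < 0
        assert rho_clean < rho_noisy  # stronger (more negative) with less noise
        assert p_clean < 1e-6

    def test_contrast_based_correlation_with_tree(self, rng):
        species = synthetic_species(rng, 8, noise=0.05)
        ids = [e.species_id for e in species]
        # caterpillar phylogeny over the 8 species
        tree = f"((((((({ids[0]}:1,{ids[1]}:1):1,{ids[2]}:2):1,{ids[3]}:3):1," \
               f"{ids[4]}:4):1,{ids[5]}:5):1,{ids[6]}:6):1,{ids[7]}:7);"
        rho, p = slope_vs_mutation_correlation(species, tree=tree)
        assert -1.0 <= rho < 0
        assert 0 <= p <= 1
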