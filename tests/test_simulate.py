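"""Forward simulator: founder draws, meiosis model, truth consistency."""

import numpy as np
import pytest
from scipy import stats

from founderhap.datamodel import MISSING, Pedigree
from founderhap.simulate import (
    SimConfig,
    TraitArch,
    breeding_design,
    gene_drop_genomes,
    simulate_founders,
    simulate_phenotypes,
    three_generation_design,
)

from helpers import mendelian_consistent


class TestSimulateFounders:
    def test_seven_founders_give_14_labels(self):
        cfg = SimConfig(chromosomes=[(20, 50.0)] * 2, seed=0)
        phased, label_map, _, _ = simulate_founders(cfg)
        labels = sorted(l for pair in label_map.values() for l in pair)
        assert labels == list(range(1, 15))
        assert phased.n_individuals == 7

    def test_degenerate_frequency_gives_monomorphic_haplotypes(self):
        cfg = SimConfig(chromosomes=[(30, 50.0)], allele_freq_range=(1.0, 1.0), seed=1)
        phased, _, _, _ = simulate_founders(cfg)
        assert (phased.alleles == 1).all()

    def test_fixed_seed_is_bit_identical(self):
        cfg = SimConfig(chromosomes=[(40, 50.0)] * 2, seed=5)
        a, _, fa, _ = simulate_founders(cfg)
        b, _, fb, _ = simulate_founders(cfg)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(fa, fb)


class TestGeneDrop:
    def test_zero_length_chromosome_transmits_whole_haplotypes(self):
        design = [("F1", None, None), ("F2", None, None), ("kid", "F1", "F2")]
        cfg = SimConfig(n_founders=2, chromosomes=[(25, 0.0)], pedigree=design, seed=3)
        truth = gene_drop_genomes(cfg)
        k = truth.phased.row("kid")
        for parent, slot in (("F1", 0), ("F2", 1)):
            p = truth.phased.row(parent)
            child_hap = truth.phased.alleles[k, :, slot]
            assert any(
                np.array_equal(child_hap, truth.phased.alleles[p, :, s]) for s in (0, 1)
            )
            # and a single constant truth label from that parent
            assert len(set(truth.assignment.labels[k, :, slot])) == 1

    def test_crossover_count_is_poisson_of_map_length(self):
        # 10,000 meioses at 100 cM: mean within 3 SE of 1.0 and a chi-square
        # goodness-of-fit against Poisson(1) at alpha = 0.01
        n_kids = 5_000  # 2 meioses each
        design = [("F1", None, None), ("F2", None, None)]
        design += [(f"k{i}", "F1", "F2") for i in range(n_kids)]
        cfg = SimConfig(n_founders=2, chromosomes=[(60, 100.0)], pedigree=design, seed=9)
        truth = gene_drop_genomes(cfg)
        counts = np.array([len(pos) for pos in truth.crossovers.values()])
        assert len(counts) == 2 * n_kids
        se = 1.0 / np.sqrt(len(counts))
        assert abs(counts.mean() - 1.0) < 3 * se
        kmax = 5
        obs = np.bincount(np.minimum(counts, kmax), minlength=kmax + 1)
        pmf = stats.poisson.pmf(np.arange(kmax + 1), 1.0)
        pmf[kmax] = 1.0 - pmf[:kmax].sum()
        chi2 = float(((obs - len(counts) * pmf) ** 2 / (len(counts) * pmf)).sum())
        assert chi2 < stats.chi2.ppf(0.99, df=kmax)

    def test_error_free_trios_are_mendelian_consistent(self, small_truth):
        ped, D = small_truth.pedigree, small_truth.observed.dosage
        for i, ind in enumerate(ped.ids):
            mo, fa = ped.mother_idx[i], ped.father_idx[i]
            mother = D[mo] if mo >= 0 else np.full(D.shape[1], MISSING, dtype=np.int8)
            father = D[fa] if fa >= 0 else np.full(D.shape[1], MISSING, dtype=np.int8)
            assert mendelian_consistent(D[i], mother, father).all(), ind

    def test_labels_match_founder_haplotype_alleles(self, small_truth):
        # conservation: before error injection every carried allele equals the
        # founder haplotype's allele at that marker
        truth = small_truth
        ped = truth.pedigree
        founder_hap = {}
        for fid in ped.founder_ids:
            l1, l2 = ped.founder_labels(fid)
            r = truth.phased.row(fid)
            founder_hap[l1] = truth.phased.alleles[r, :, 0]
            founder_hap[l2] = truth.phased.alleles[r, :, 1]
        lab = truth.assignment.labels
        alle = truth.phased.alleles
        m = alle.shape[1]
        for r in range(alle.shape[0]):
            for s in (0, 1):
                for lab_val in np.unique(lab[r, :, s]):
                    if lab_val > 14:
                        continue
                    sel = lab[r, :, s] == lab_val
                    assert np.array_equal(alle[r, sel, s], founder_hap[lab_val][sel])

    def test_seed_reproducibility_and_observed_noise(self):
        cfg = SimConfig(
            chromosomes=[(40, 60.0)] * 2,
            pedigree=three_generation_design(),
            genotype_error_rate=0.01,
            missing_rate=0.02,
            seed=17,
        )
        t1, t2 = gene_drop_genomes(cfg), gene_drop_genomes(cfg)
        assert np.array_equal(t1.observed.dosage, t2.observed.dosage)
        assert t1.observed.missing_rate == pytest.approx(0.02, abs=0.01)
        # error flips show up as dosage differences from truth
        diff = (t1.observed.dosage != t1.phased.dosage()) & (t1.observed.dosage != MISSING)
        assert 0 < diff.mean() < 0.05


class TestPhenotypes:
    def _arch(self, h2, years=(1,), year_sd=0.0, rng=None):
        rng = rng or np.random.default_rng(0)
        qtl = [(int(j), rng.normal(0, 1, 14), False) for j in rng.choice(150, 5, replace=False)]
        return TraitArch("t", qtl=qtl, heritability=h2, years=list(years), year_effect_sd=year_sd)

    def test_h2_one_gives_exact_genetic_values(self):
        cfg = SimConfig(
            chromosomes=[(50, 60.0)] * 3,
            pedigree=three_generation_design(),
            traits=[self._arch(1.0)],
            seed=23,
        )
        truth = gene_drop_genomes(cfg)
        pheno = simulate_phenotypes(cfg, truth)
        g = truth.breeding_values["t"]
        vals = pheno.df.set_index("individual")["value"].reindex(truth.pedigree.ids).to_numpy()
        assert np.allclose(vals, g)

    def test_zero_qtl_effects_give_zero_genetic_variance(self):
        arch = TraitArch("flat", qtl=[(3, np.zeros(14), False)], heritability=0.5)
        cfg = SimConfig(
            chromosomes=[(50, 60.0)] * 3,
            pedigree=three_generation_design(),
            traits=[arch],
            seed=29,
        )
        truth = gene_drop_genomes(cfg)
        simulate_phenotypes(cfg, truth)
        assert np.var(truth.breeding_values["flat"]) == 0.0

    def test_heritability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="heritability"):
            SimConfig(traits=[TraitArch("t", heritability=0.0)])

    def test_regression_slope_of_phenotype_on_genetic_value(self):
        # h2 = 0.5, n ~ 500: slope of phenotype on true genetic value in [0.8, 1.2]
        rng = np.random.default_rng(31)
        design = breeding_design(family_size=26)  # 505 individuals total
        cfg = SimConfig(
            chromosomes=[(50, 60.0)] * 3,
            pedigree=design,
            traits=[self._arch(0.5, rng=rng)],
            seed=31,
        )
        truth = gene_drop_genomes(cfg)
        pheno = simulate_phenotypes(cfg, truth)
        g = truth.breeding_values["t"]
        vals = pheno.df.set_index("individual")["value"].reindex(truth.pedigree.ids).to_numpy()
        slope = np.polyfit(g, vals, 1)[0]
        assert 0.8 < slope < 1.2

    def test_year_effects_shift_years_jointly(self):
        cfg = SimConfig(
            chromosomes=[(50, 60.0)] * 3,
            pedigree=three_generation_design(),
            traits=[self._arch(0.9, years=(1, 2, 3), year_sd=5.0)],
            seed=37,
        )
        truth = gene_drop_genomes(cfg)
        pheno = simulate_phenotypes(cfg, truth)
        shifts = truth.year_effects["t"]
        means = pheno.df.groupby("year")["value"].mean()
        for y in (1, 2, 3):
            assert means[y] == pytest.approx(shifts[y] + truth.breeding_values["t"].mean(), abs=1.0)
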