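"""Generator sanity: marker maps, meiosis, mosaics, calls, design, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from spehet import synthetic_data as sd
from spehet.io import (CLASS_BC_A, CLASS_FOUNDER_A, HET, HOM_ALT, HOM_REF,
                       MISSING, ORIGIN_THIRD)


class TestMarkerMap:
    def test_construction_density_and_bounds(self):
        spec = sd.GenomeSpec((("c1", 10_000_000),), marker_density=10, cm_per_mbp=1.0)
        mm = sd.build_marker_map(spec, 1)
        assert len(mm) == 100
        assert mm["pos"].max() <= 10_000_000
        assert mm["pos"].min() >= 1
        assert (np.diff(mm["pos"]) > 0).all()

    def test_zero_map_rate_gives_zero_genetic_positions(self):
        spec = sd.GenomeSpec((("c1", 5_000_000),), marker_density=10, cm_per_mbp=0.0)
        mm = sd.build_marker_map(spec, 1)
        assert (mm["cm"] == 0).all()
        # downstream: a zero-length map means no recombination, not a crash
        mos = sd.simulate_ril_population(spec, 3, 2, seed=0)
        assert all(len(m.segments) == 1 for m in mos)

    def test_deterministic_under_seed(self):
        spec = sd.GenomeSpec((("c1", 10_000_000),), marker_density=10)
        pd.testing.assert_frame_equal(sd.build_marker_map(spec, 7),
                                      sd.build_marker_map(spec, 7))

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            sd.GenomeSpec((("c1", 0),))


class TestMeiosis:
    def test_crossover_count_is_poisson_at_map_length(self):
        """Gamete from the two founder haplotypes shows every crossover as a
        breakpoint; counts over replicates match Poisson(map Morgans)."""
        spec = sd.GenomeSpec((("c1", 100_000_000),), marker_density=1, cm_per_mbp=2.0)
        l_morgan = spec.map_length_cm("c1") / 100.0
        rng = np.random.default_rng(0)
        h1 = sd._founder_haplotype(spec, 0)
        h2 = sd._founder_haplotype(spec, 1)
        counts = []
        for _ in range(1000):
            gam = sd.meiosis(h1, h2, spec, rng)
            counts.append(len(gam["c1"][0]) - 1)
        counts = np.asarray(counts)
        # mean within 4 SE of the Poisson mean, variance/mean near 1
        se = np.sqrt(l_morgan / len(counts))
        assert abs(counts.mean() - l_morgan) < 4 * se
        assert 0.8 < counts.var() / counts.mean() < 1.2

    def test_population_founder_proportions_balanced(self):
        spec = sd.GenomeSpec((("c1", 50_000_000),), marker_density=2, cm_per_mbp=1.0)
        mos = sd.simulate_ril_population(spec, 200, 4, seed=3)
        frac = np.mean([m.origin_fraction(spec, "B73") for m in mos])
        assert 0.45 <= frac <= 0.55

    def test_single_ril_reproducible(self, genome_spec):
        a = sd.simulate_ril_population(genome_spec, 1, 4, seed=9)[0]
        b = sd.simulate_ril_population(genome_spec, 1, 4, seed=9)[0]
        pd.testing.assert_frame_equal(a.segments, b.segments)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 10_000), gens=st.integers(0, 5))
    def test_segments_tile_genome(self, seed, gens):
        spec = sd.GenomeSpec((("c1", 20_000_000), ("c2", 10_000_000)),
                             marker_density=5, cm_per_mbp=1.5)
        for m in sd.simulate_ril_population(spec, 3, gens, seed=seed):
            m.validate(spec)  # raises on overlap/gap/non-alternation


class TestThirdOrigin:
    def test_fraction_zero_unchanged(self, genome_spec):
        mos = sd.simulate_ril_population(genome_spec, 4, 4, seed=5)
        out = sd.inject_third_origin(mos, genome_spec, 0.0, 3_000_000, seed=6)
        for a, b in zip(mos, out):
            pd.testing.assert_frame_equal(a.segments, b.segments)

    def test_tiling_preserved_after_injection(self, genome_spec):
        mos = sd.simulate_ril_population(genome_spec, 6, 4, seed=5)
        out = sd.inject_third_origin(mos, genome_spec, 1.0, 3_000_000, seed=6)
        for m in out:
            m.validate(genome_spec)
        assert any((m.segments["origin"] == ORIGIN_THIRD).any() for m in out)

    def test_fraction_out_of_range_rejected(self, genome_spec):
        mos = sd.simulate_ril_population(genome_spec, 2, 4, seed=5)
        with pytest.raises(ValueError):
            sd.inject_third_origin(mos, genome_spec, 1.5, 3_000_000)


class TestGenotypeCalls:
    def test_hybrid_calls_are_mendelian_without_noise(self, genome_spec):
        markers = sd.build_marker_map(genome_spec, 1)
        mos = sd.simulate_ril_population(genome_spec, 3, 4, seed=2)
        cs = sd.simulate_genotype_calls(mos, markers, missing_rate=0,
                                        error_rate=0, seed=3)
        for m in mos:
            i = cs.sample_index(f"B73x{m.ril_id}_r0")
            for chrom in ("chr1", "chr2"):
                idx = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
                orig = m.origin_at(chrom, markers["pos"].to_numpy()[idx])
                calls = cs.calls[i, idx]
                assert (calls[orig == 1] == HET).all()
                assert (calls[orig == 0] == HOM_REF).all()

    def test_error_rate_flips_expected_fraction(self, genome_spec):
        markers = sd.build_marker_map(genome_spec, 1)
        mos = sd.simulate_ril_population(genome_spec, 5, 4, seed=2)
        clean = sd.simulate_genotype_calls(mos, markers, missing_rate=0,
                                           error_rate=0, seed=3)
        noisy = sd.simulate_genotype_calls(mos, markers, missing_rate=0,
                                           error_rate=0.05, seed=3)
        flipped = (clean.calls != noisy.calls).mean()
        n = clean.calls.size
        ci = 4 * np.sqrt(0.05 * 0.95 / n)
        assert abs(flipped - 0.05) < ci + 0.002

    def test_founder_homozygosity_bound(self, genome_spec):
        markers = sd.build_marker_map(genome_spec, 1)
        mos = sd.simulate_ril_population(genome_spec, 2, 4, seed=2)
        cs = sd.simulate_genotype_calls(mos, markers, missing_rate=0,
                                        error_rate=0.001, seed=4)
        i = cs.sample_index("B73_r0")
        hi_conf = cs.gq[i] >= 10
        hom_ref = (cs.calls[i] == HOM_REF) & hi_conf
        rate = hom_ref.sum() / hi_conf.sum()
        # binomial bound at error 0.001 over ~1600 loci
        assert rate >= 0.99

    def test_rate_bounds_validated(self, genome_spec):
        markers = sd.build_marker_map(genome_spec, 1)
        mos = sd.simulate_ril_population(genome_spec, 1, 4, seed=2)
        with pytest.raises(ValueError):
            sd.simulate_genotype_calls(mos, markers, error_rate=1.2)


class TestDesignAndPhenotypes:
    def test_full_scale_batch_fills_all_rows(self):
        # 30 RIL triplets + 2 reference triplets per batch: 96 of 96 rows
        design = sd.build_experimental_design(120, seed=0)
        one_batch = design[design["batch"] == "B1.K1"]
        assert one_batch["row"].nunique() == 96

    def test_capacity_exceeded_raises(self):
        with pytest.raises(ValueError, match="capacity"):
            sd.build_experimental_design(200, batches_per_block=1, seed=0)

    def test_layout_deterministic(self):
        a = sd.build_experimental_design(10, seed=4)
        b = sd.build_experimental_design(10, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_factor_nesting(self):
        design = sd.build_experimental_design(10, seed=4)
        for child, parent in (("batch", "block"), ("system", "batch"),
                              ("triplet", "system"), ("row", "system")):
            assert (design.groupby(child)[parent].nunique() == 1).all()

    def test_hybrids_equal_midparent_plus_phi_without_heterosis_noise(self):
        design = sd.build_experimental_design(12, plants_per_row=40, seed=1)
        ped = sd.pedigree_of(design)
        spe = pd.DataFrame(0, index=ped["hybrid"], columns=list("abcd"))
        gm = sd.PhenotypeGenModel(gammas=np.zeros(4), sigma2_het=0.0, phi=2.0,
                                  sigma2_batch=0, sigma2_system=0,
                                  sigma2_triplet=0, sigma2_row=0, sigma2_e=0.05,
                                  block_effects=(0.0, 0.0, 0.0))
        tab, truth = sd.simulate_phenotypes(design, gm, spe, seed=2)
        means = tab.groupby("genotype_id")["value"].mean()
        beta = truth["beta"]
        for h, mo, fa in ped.itertuples(index=False):
            expect = 0.5 * beta[mo] + 0.5 * beta[fa] + 2.0
            assert means[h] == pytest.approx(expect, abs=0.05)

    def test_phenotypes_byte_identical_under_seed(self):
        design = sd.build_experimental_design(5, seed=1)
        ped = sd.pedigree_of(design)
        spe = pd.DataFrame(1, index=ped["hybrid"], columns=list("abcd"))
        gm = sd.PhenotypeGenModel()
        a, _ = sd.simulate_phenotypes(design, gm, spe, seed=3)
        b, _ = sd.simulate_phenotypes(design, gm, spe, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_spe_counts_rejected(self):
        design = sd.build_experimental_design(5, seed=1)
        spe = pd.DataFrame(1, index=["B73xRIL0000"], columns=list("abcd"))
        with pytest.raises(ValueError, match="missing"):
            sd.simulate_phenotypes(design, sd.PhenotypeGenModel(), spe, seed=3)


class TestExpressionCounts:
    def test_spe_capable_gene_construction(self, genome_spec):
        """A gene silenced by the Mo17 allele is expressed in the B73 parent
        and in a hybrid carrying B73 at its cis eQTL, silent in Mo17."""
        genes = sd.build_gene_table(genome_spec, 60, seed=1)
        arch = sd.build_regulatory_architecture(genes, genome_spec, seed=2,
                                                silenced_fraction=1.0,
                                                silencing_bias_b=1.0)
        mos = sd.simulate_ril_population(genome_spec, 2, 4, seed=3)
        genotypes = pd.DataFrame({
            "genotype_id": ["B73", "MO17", f"B73x{mos[0].ril_id}"],
            "klass": ["B73", "MO17", CLASS_BC_A],
            "ril_id": ["", "", mos[0].ril_id]})
        act = sd.true_activity(arch, genotypes, mos)
        assert act.loc["B73"].all()
        assert not act.loc["MO17"].any()
        assert act.loc[f"B73x{mos[0].ril_id}"].all()  # B73 allele always present

    def test_sample_mean_approaches_expectation_at_small_dispersion(self, genome_spec):
        genes = sd.build_gene_table(genome_spec, 60, seed=1)
        arch = sd.build_regulatory_architecture(genes, genome_spec, seed=2,
                                                silenced_fraction=0.0)
        genotypes = pd.DataFrame({"genotype_id": ["B73"], "klass": ["B73"],
                                  "ril_id": [""]})
        eset = sd.simulate_expression_counts(genes, arch, genotypes, [],
                                             nb_dispersion=1e-4, reps=500, seed=4)
        sample_mean = eset.counts.mean(axis=1).to_numpy()
        expected = genes["baseline"].to_numpy()
        rel = np.abs(sample_mean - expected) / expected
        assert np.quantile(rel, 0.95) < 0.05

    def test_non_positive_library_size_rejected(self, genome_spec):
        genes = sd.build_gene_table(genome_spec, 60, seed=1)
        arch = sd.build_regulatory_architecture(genes, genome_spec, seed=2)
        genotypes = pd.DataFrame({"genotype_id": ["B73"], "klass": ["B73"],
                                  "ril_id": [""]})
        with pytest.raises(ValueError, match="library"):
            sd.simulate_expression_counts(genes, arch, genotypes, [],
                                          library_sizes={"B73_e0": 0.0}, reps=1)

    def test_spe_capable_count_matches_enumeration(self, expression, small_cross):
        """Realized SPE-capable genes per hybrid equal the brute-force count
        from architecture x genotypes."""
        act = expression["eset"].truth["activity"]
        arch = expression["arch"]
        mosaics = {m.ril_id: m for m in small_cross["mosaics"]}
        for rid, mos in list(mosaics.items())[:3]:
            hybrid = f"B73x{rid}"
            fast = int((act.loc[hybrid] & (act.loc["B73"] ^ act.loc[rid])).sum())
            brute = 0
            for _, g in arch.iterrows():
                if g["silencing_allele"] == "none":
                    continue
                def active(o1, o2):
                    names = {{0: "B73", 1: "MO17", 2: "THIRD"}[o] for o in (o1, o2)}
                    return g["required_active_allele"] in names
                r = int(mos.origin_at(g["eqtl_chrom"], np.array([g["eqtl_pos"]]))[0])
                a_b73 = active(0, 0)
                a_ril = active(r, r)
                a_hyb = active(0, r)
                if a_hyb and (a_b73 ^ a_ril):
                    brute += 1
            assert fast == brute
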