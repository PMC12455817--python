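"""Region classification: filtering rules, masking, windows, zygosity."""

import numpy as np
import pandas as pd
import pytest

from spehet import genotype_regions as gr
from spehet import synthetic_data as sd
from spehet.io import (CLASS_BC_A, CLASS_BC_B, CLASS_FOUNDER_A,
                       CLASS_FOUNDER_B, CLASS_RIL, GenotypeCallSet, HET,
                       HOM_ALT, HOM_REF, MASKED_THIRD, MISSING, ORIGIN_A,
                       ORIGIN_B, OTHER_HET, OTHER_HOM)


def _callset(markers, sample_rows, calls, gq=None):
    calls = np.asarray(calls, dtype=np.int8)
    if gq is None:
        gq = np.full(calls.shape, 99, dtype=np.int16)
    samples = pd.DataFrame(sample_rows, columns=["sample", "klass", "ril_id"])
    return GenotypeCallSet(markers=markers, samples=samples, calls=calls,
                           gq=np.asarray(gq, dtype=np.int16))


def _markers(positions, chrom="chr1"):
    return pd.DataFrame({
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "cm": np.asarray(positions) / 1e6 * 0.7,
        "ref": "A", "alt": "C", "third": "G"})


class TestHighConfidenceLoci:
    def _founder_panel(self, mo17_calls, b73_calls, mo17_gq=None, b73_gq=None):
        n_mo, n_b = len(mo17_calls), len(b73_calls)
        rows = [(f"MO17_r{i}", CLASS_FOUNDER_B, "") for i in range(n_mo)]
        rows += [(f"B73_r{i}", CLASS_FOUNDER_A, "") for i in range(n_b)]
        calls = np.array(mo17_calls + b73_calls, dtype=np.int8)[:, None]
        gq = np.full(calls.shape, 99)
        if mo17_gq is not None:
            gq[:n_mo, 0] = mo17_gq
        if b73_gq is not None:
            gq[n_mo:, 0] = b73_gq
        return _callset(_markers([100]), rows, calls, gq)

    def test_ninety_percent_rule_retains(self):
        cs = self._founder_panel([HOM_ALT] * 9 + [HOM_REF], [HOM_REF] * 10)
        assert gr.select_high_confidence_loci(cs)[0]

    def test_minimum_three_calls_rejects(self):
        cs = self._founder_panel([HOM_ALT, HOM_ALT], [HOM_REF] * 10)
        assert not gr.select_high_confidence_loci(cs)[0]

    def test_low_gq_calls_excluded_before_counting(self):
        # 3 HOM_ALT calls but one at GQ 9: only 2 qualify -> rejected
        cs = self._founder_panel([HOM_ALT] * 3, [HOM_REF] * 10,
                                 mo17_gq=[99, 99, 9])
        assert not gr.select_high_confidence_loci(cs)[0]

    def test_no_founders_rejected(self):
        cs = _callset(_markers([100]), [("RIL0_r0", CLASS_RIL, "RIL0")],
                      [[HOM_REF]])
        with pytest.raises(ValueError, match="founder"):
            gr.select_high_confidence_loci(cs)


class TestHomozygosityFilter:
    @pytest.mark.parametrize("rate, kept", [(0.96, True), (0.95, True), (0.94, False)])
    def test_threshold_is_strict_less_than(self, rate, kept):
        n = 100
        n_hom = int(round(rate * n))
        calls = np.array([[HOM_REF] * n_hom + [HET] * (n - n_hom)], dtype=np.int8)
        cs = _callset(_markers(np.arange(1, n + 1) * 1000),
                      [("RIL0_r0", CLASS_RIL, "RIL0")], calls)
        rep = gr.filter_samples_by_homozygosity(cs, np.arange(n))
        assert rep.loc[0, "kept"] == kept
        assert rep.loc[0, "homozygosity"] == pytest.approx(rate)

    def test_sample_without_informative_loci_gets_reason(self):
        calls = np.array([[MISSING, MISSING]], dtype=np.int8)
        cs = _callset(_markers([100, 200]), [("RIL0_r0", CLASS_RIL, "RIL0")], calls)
        rep = gr.filter_samples_by_homozygosity(cs, np.arange(2))
        assert not rep.loc[0, "kept"]
        assert rep.loc[0, "reason"] == "no_data"


class TestRilSpecificFlags:
    def _ril_with_calls(self, calls, gq):
        rows = [("RIL0_r0", CLASS_RIL, "RIL0")]
        return _callset(_markers([100, 200, 300]), rows,
                        np.array([calls], dtype=np.int8),
                        np.array([gq]))

    def test_other_flagged_regardless_of_gq_and_others_not(self):
        cs = self._ril_with_calls([OTHER_HOM, HOM_ALT, MISSING], [3, 99, 99])
        flags = gr.flag_ril_specific_loci(cs, "RIL0", np.ones(3, dtype=bool))
        assert flags["locus"].tolist() == [0]      # low-GQ OTHER still flagged
        assert flags["homozygous"].tolist() == [True]


class TestThirdOriginMask:
    def _flags(self, positions, homs):
        return pd.DataFrame({"locus": np.arange(len(positions)),
                             "homozygous": homs, "chrom": "chr1",
                             "pos": positions})

    def test_ten_loci_five_hom_masked(self):
        pos = np.linspace(1_000_000, 3_000_000, 10).astype(int)
        masked = gr.mask_third_origin(self._flags(pos, [True] * 5 + [False] * 5),
                                      "RIL0")
        assert len(masked) == 1
        assert masked.loc[0, ["start", "end"]].tolist() == [pos[0], pos[-1]]
        assert masked.loc[0, "origin"] == MASKED_THIRD

    def test_nine_loci_not_masked(self):
        pos = np.linspace(1_000_000, 3_000_000, 9).astype(int)
        assert gr.mask_third_origin(self._flags(pos, [True] * 9), "RIL0").empty

    def test_four_homozygous_not_masked(self):
        pos = np.linspace(1_000_000, 3_000_000, 10).astype(int)
        assert gr.mask_third_origin(self._flags(pos, [True] * 4 + [False] * 6),
                                    "RIL0").empty

    def test_gap_splits_blocks(self):
        pos = np.concatenate([np.linspace(1e6, 2e6, 10),
                              np.linspace(6e6, 7e6, 10)]).astype(int)
        masked = gr.mask_third_origin(self._flags(pos, [True] * 20), "RIL0")
        assert len(masked) == 2  # 4-Mbp gap >= 2.5 Mbp


class TestWindows:
    def test_twelve_homref_is_b73_window(self):
        pos = np.arange(1, 16) * 10_000
        calls = np.array([HOM_REF] * 12 + [HET] * 3, dtype=np.int8)
        labels = gr.classify_by_windows(pos, calls)
        assert set(labels[calls == HOM_REF]) == {ORIGIN_A}

    def test_eleven_homref_is_ambiguous_for_b73(self):
        pos = np.arange(1, 16) * 10_000
        calls = np.array([HOM_REF] * 11 + [HOM_ALT] * 4, dtype=np.int8)
        labels = gr.classify_by_windows(pos, calls)
        assert (labels == "").all()  # 11 < 12 ref and 4 < 11 alt

    def test_eleven_homalt_is_mo17_window(self):
        pos = np.arange(1, 16) * 10_000
        calls = np.array([HOM_ALT] * 11 + [HET] * 4, dtype=np.int8)
        labels = gr.classify_by_windows(pos, calls)
        assert set(labels[calls == HOM_ALT]) == {ORIGIN_B}

    def test_short_chromosome_all_ambiguous_with_warning(self):
        pos = np.arange(1, 11) * 10_000
        calls = np.full(10, HOM_REF, dtype=np.int8)
        with pytest.warns(UserWarning, match="usable loci"):
            labels = gr.classify_by_windows(pos, calls)
        assert (labels == "").all()


class TestBlockMerging:
    def test_half_mbp_rule_splits_blocks(self):
        pos = np.array([1_000_000, 1_200_000, 1_900_000])
        labels = np.array([ORIGIN_A] * 3, dtype=object)
        reg = gr.merge_allele_blocks(pos, labels, "chr1", "RIL0")
        assert len(reg) == 2
        assert reg.loc[0, ["start", "end"]].tolist() == [1_000_000, 1_200_000]
        assert reg.loc[1, ["start", "end"]].tolist() == [1_900_000, 1_900_000]

    def test_isolated_locus_is_zero_length_block(self):
        reg = gr.merge_allele_blocks(np.array([5_000_000]),
                                     np.array([ORIGIN_B], dtype=object),
                                     "chr1", "RIL0")
        assert len(reg) == 1 and reg.loc[0, "start"] == reg.loc[0, "end"]

    def test_alternating_alleles_break_blocks(self):
        pos = np.array([1_000_000, 1_010_000, 1_020_000])
        labels = np.array([ORIGIN_A, ORIGIN_B, ORIGIN_A], dtype=object)
        assert len(gr.merge_allele_blocks(pos, labels, "chr1", "RIL0")) == 3


class TestContaminationExclusion:
    def _regions(self, masked_len, classified_len):
        return pd.DataFrame([
            ("R0", "chr1", 1, masked_len, MASKED_THIRD),
            ("R0", "chr1", masked_len + 1, masked_len + classified_len, ORIGIN_A),
        ], columns=gr.REGION_COLUMNS)

    def test_sixty_percent_masked_excluded(self):
        kept, excl = gr.exclude_contaminated_rils(self._regions(60, 40))
        assert excl == ["R0"]

    def test_exactly_half_masked_kept(self):
        kept, excl = gr.exclude_contaminated_rils(self._regions(50, 50))
        assert kept == ["R0"]

    def test_unmasked_kept(self):
        kept, excl = gr.exclude_contaminated_rils(self._regions(0, 100))
        assert kept == ["R0"]


class TestGeneZygosity:
    def _regions(self):
        return pd.DataFrame([
            ("R0", "chr1", 1, 10_000_000, ORIGIN_B),
            ("R0", "chr1", 10_000_001, 20_000_000, ORIGIN_A),
            ("R0", "chr2", 1, 5_000_000, MASKED_THIRD),
        ], columns=gr.REGION_COLUMNS)

    def _genes(self):
        return pd.DataFrame({
            "gene_id": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr2", "chr2"],
            "start": [2_000_000, 12_000_000, 1_000_000, 8_000_000],
            "end": [2_002_000, 12_002_000, 1_002_000, 8_002_000]})

    def test_cross_mirroring(self):
        za = gr.annotate_gene_zygosity(self._genes(), self._regions(), CLASS_BC_A)
        zb = gr.annotate_gene_zygosity(self._genes(), self._regions(), CLASS_BC_B)
        assert za["gA"] == gr.ZYG_HET and zb["gA"] == gr.ZYG_HOM_B
        assert za["gB"] == gr.ZYG_HOM_A and zb["gB"] == gr.ZYG_HET
        assert za["gC"] == gr.ZYG_MASKED
        assert za["gD"] == gr.ZYG_NO_INFO

    def test_straddling_gene_no_info_with_warning(self):
        genes = pd.DataFrame({"gene_id": ["gS"], "chrom": ["chr1"],
                              "start": [9_999_000], "end": [10_001_000]})
        with pytest.warns(UserWarning, match="span"):
            z = gr.annotate_gene_zygosity(genes, self._regions(), CLASS_BC_A)
        assert z["gS"] == gr.ZYG_NO_INFO

    def test_complementarity_on_simulated_panel(self, expression, region_set):
        genes = expression["genes"]
        rid = region_set.kept_rils[0]
        za = gr.annotate_gene_zygosity(genes, region_set.for_ril(rid), CLASS_BC_A)
        zb = gr.annotate_gene_zygosity(genes, region_set.for_ril(rid), CLASS_BC_B)
        informative = ~za.isin([gr.ZYG_MASKED, gr.ZYG_NO_INFO])
        assert informative.sum() > 100
        assert ((za[informative] == gr.ZYG_HET)
                == (zb[informative] == gr.ZYG_HOM_B)).all()
        assert ((za[informative] == gr.ZYG_HOM_A)
                == (zb[informative] == gr.ZYG_HET)).all()


class TestHeterozygosityFraction:
    def test_masked_regions_excluded_from_denominator(self):
        regions = pd.DataFrame([
            ("R0", "chr1", 1, 40_000_000, ORIGIN_B),
            ("R0", "chr1", 40_000_001, 80_000_000, ORIGIN_A),
            ("R0", "chr1", 80_000_001, 100_000_000, MASKED_THIRD),
        ], columns=gr.REGION_COLUMNS)
        assert gr.heterozygosity_fraction(regions, CLASS_BC_A) == pytest.approx(0.5)

    def test_all_recurrent_origin_gives_zero(self):
        regions = pd.DataFrame([("R0", "chr1", 1, 1_000_000, ORIGIN_A)],
                               columns=gr.REGION_COLUMNS)
        assert gr.heterozygosity_fraction(regions, CLASS_BC_A) == 0.0


class TestGqMonotonicity:
    def test_raising_gq_threshold_never_adds_classified_loci(self, small_cross):
        """More stringent GQ filtering cannot increase the number of
        window-classified loci on a fixed panel."""
        cs = small_cross["calls"]
        hc = gr.select_high_confidence_loci(cs)
        rid = cs.samples.loc[cs.samples["klass"] == CLASS_RIL, "ril_id"].iloc[0]
        counts = []
        for gq_min in (10, 30, 95):
            params = gr.RegionParams(min_gq=gq_min)
            regions = gr.classify_ril(cs, rid, hc, params)
            founder = regions[regions["origin"].isin([ORIGIN_A, ORIGIN_B])]
            counts.append((founder["end"] - founder["start"] + 1).sum())
        assert counts[0] >= counts[1] >= counts[2]
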