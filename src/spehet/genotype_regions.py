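"""Classify RIL genomes into founder-origin regions from genotype calls.

The pipeline mirrors how RNA-seq-derived SNP calls are turned into
parental haplotype blocks for an intermated RIL population:

1. select high-confidence founder-discriminating loci from founder panels
   (>= 90% and >= 3 qualifying calls homozygous for the expected allele on
   both sides, GQ >= 10),
2. exclude inbred samples with < 95% homozygosity at expectedly
   homozygous loci,
3. flag calls whose allele matches neither founder (regardless of GQ) and
   mask dense blocks of them as third-origin contamination (>= 10 flagged
   loci within 2.5-Mbp gaps, >= 5 homozygous),
4. label the remaining loci by a 15-locus sliding window (>= 11 hom-alt
   for a founder-B window, >= 12 hom-ref for founder-A), dropping loci in
   ambiguous windows or disagreeing with their windows,
5. merge surviving same-allele loci < 0.5 Mbp apart into regions,
6. exclude RILs whose genome is > 50% masked (together with their
   hybrids), and
7. derive per-gene zygosity for each backcross hybrid.

Windows slide by one locus, and the label applies to every locus a window
covers; a locus is dropped if any covering window is ambiguous or
conflicts with its own call (the conservative reading of dropping loci
classified differently from their window).  Regions span from the first
to the last member locus with no extrapolation into gaps; gaps are
no-information territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    CLASS_BC_A, CLASS_BC_B, CLASS_FOUNDER_A, CLASS_FOUNDER_B, CLASS_RIL,
    GenotypeCallSet, HET, HOM_ALT, HOM_REF, MASKED_THIRD, MISSING, NO_INFO,
    ORIGIN_A, ORIGIN_B, OTHER_HET, OTHER_HOM,
)

ZYG_HET = "HET"
ZYG_HOM_A = "HOM_B73"
ZYG_HOM_B = "HOM_MO17"
ZYG_MASKED = "MASKED"
ZYG_NO_INFO = "NO_INFO"

REGION_COLUMNS = ["ril_id", "chrom", "start", "end", "origin"]


@dataclass(frozen=True)
class RegionParams:
    """Thresholds of the region-classification pipeline (defaults as used
    for the IBM-RIL analysis this package reimplements)."""

    min_gq: int = 10
    founder_min_fraction: float = 0.9
    founder_min_count: int = 3
    homozygosity_threshold: float = 0.95
    mask_gap: float = 2.5e6
    mask_min_loci: int = 10
    mask_min_hom: int = 5
    window: int = 15
    mo17_min: int = 11
    b73_min: int = 12
    block_gap: float = 0.5e6
    max_masked_fraction: float = 0.5


# ---------------------------------------------------------------------------
# locus and sample filters

def select_high_confidence_loci(callset: GenotypeCallSet,
                                params: RegionParams = RegionParams()) -> np.ndarray:
    """Boolean mask of loci that reliably discriminate the two founders.

    A locus is retained iff, among founder calls with GQ >= min_gq, at
    least ``founder_min_fraction`` and at least ``founder_min_count`` of
    the founder-B calls are homozygous non-reference AND the same holds
    for homozygous-reference calls in founder-A samples.
    """
    idx_a = callset.samples_of_class(CLASS_FOUNDER_A)
    idx_b = callset.samples_of_class(CLASS_FOUNDER_B)
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError("callset contains no founder samples")

    def side_ok(idx: np.ndarray, want: int) -> np.ndarray:
        calls = callset.calls[idx]
        qual = (callset.gq[idx] >= params.min_gq) & (calls != MISSING)
        n_qual = qual.sum(axis=0)
        n_want = ((calls == want) & qual).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(n_qual > 0, n_want / np.maximum(n_qual, 1), 0.0)
        return (frac >= params.founder_min_fraction) & (n_want >= params.founder_min_count)

    return side_ok(idx_a, HOM_REF) & side_ok(idx_b, HOM_ALT)


def filter_samples_by_homozygosity(callset: GenotypeCallSet,
                                   expected_hom_loci: np.ndarray,
                                   params: RegionParams = RegionParams()
                                   ) -> pd.DataFrame:
    """Per-sample homozygosity report over expectedly homozygous loci.

    Samples with a homozygosity rate strictly below the threshold are
    excluded; samples without informative loci are excluded with reason
    ``no_data``.  Only inbred samples (founders and RILs) are rated;
    hybrids are expected heterozygous and pass through unrated.
    """
    rows = []
    inbred = {CLASS_FOUNDER_A, CLASS_FOUNDER_B, CLASS_RIL}
    for i, (name, klass) in enumerate(zip(callset.samples["sample"], callset.samples["klass"])):
        if klass not in inbred:
            rows.append((name, klass, np.nan, True, "not_rated"))
            continue
        calls = callset.calls[i, expected_hom_loci]
        qual = (callset.gq[i, expected_hom_loci] >= params.min_gq) & (calls != MISSING)
        n = int(qual.sum())
        if n == 0:
            rows.append((name, klass, np.nan, False, "no_data"))
            continue
        hom = np.isin(calls, (HOM_REF, HOM_ALT, OTHER_HOM)) & qual
        rate = hom.sum() / n
        kept = bool(rate >= params.homozygosity_threshold)
        rows.append((name, klass, float(rate), kept, "" if kept else "low_homozygosity"))
    return pd.DataFrame(rows, columns=["sample", "klass", "homozygosity", "kept", "reason"])


# ---------------------------------------------------------------------------
# third-origin masking

def flag_ril_specific_loci(callset: GenotypeCallSet, ril_id: str,
                           hc_mask: np.ndarray) -> pd.DataFrame:
    """Flag calls whose allele matches neither founder, regardless of GQ.

    Calls from the RIL sample(s) and both of its backcross hybrids are
    inspected at high-confidence loci; a flag records whether the
    offending call was homozygous.
    """
    own = np.flatnonzero(((callset.samples["ril_id"] == ril_id)
                          & callset.samples["klass"].isin(
                              [CLASS_RIL, CLASS_BC_A, CLASS_BC_B])).to_numpy())
    loci = np.flatnonzero(hc_mask)
    calls = callset.calls[np.ix_(own, loci)]
    specific = np.isin(calls, (OTHER_HOM, OTHER_HET))
    flagged_cols = specific.any(axis=0)
    hom = (calls == OTHER_HOM).any(axis=0)
    out = pd.DataFrame({
        "locus": loci[flagged_cols],
        "homozygous": hom[flagged_cols],
    })
    out["chrom"] = callset.markers["chrom"].to_numpy()[out["locus"]]
    out["pos"] = callset.markers["pos"].to_numpy()[out["locus"]]
    return out


def mask_third_origin(flagged: pd.DataFrame, ril_id: str,
                      params: RegionParams = RegionParams()) -> pd.DataFrame:
    """Group flagged loci into blocks and mask those that qualify.

    Loci < ``mask_gap`` apart belong to one block; a block becomes a
    masked third-origin region iff it has >= ``mask_min_loci`` flagged
    loci of which >= ``mask_min_hom`` are homozygous.  The region spans
    from the first to the last flagged locus of the block.
    """
    regions = []
    for chrom, grp in flagged.sort_values("pos").groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        hom = grp["homozygous"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) >= params.mask_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            n = e - s + 1
            n_hom = int(hom[s:e + 1].sum())
            if n >= params.mask_min_loci and n_hom >= params.mask_min_hom:
                regions.append((ril_id, chrom, int(pos[s]), int(pos[e]), MASKED_THIRD))
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


# ---------------------------------------------------------------------------
# window classification and block merging

def classify_by_windows(pos: np.ndarray, calls: np.ndarray,
                        params: RegionParams = RegionParams()
                        ) -> np.ndarray:
    """Label usable loci of one chromosome via 15-locus sliding windows.

    ``calls`` are the RIL's genotype calls at the usable loci in position
    order.  Returns an object array of labels ("B73", "MO17") for loci
    that survive; dropped loci get "".
    """
    n = len(pos)
    labels = np.full(n, "", dtype=object)
    w = params.window
    if n < w:
        warnings.warn(f"chromosome with {n} < {w} usable loci: all ambiguous")
        return labels
    is_alt = (calls == HOM_ALT).astype(np.int32)
    is_ref = (calls == HOM_REF).astype(np.int32)
    kern = np.ones(w, dtype=np.int32)
    n_alt = np.convolve(is_alt, kern, mode="valid")
    n_ref = np.convolve(is_ref, kern, mode="valid")
    win_label = np.full(n - w + 1, "", dtype=object)
    win_label[n_alt >= params.mo17_min] = ORIGIN_B
    win_label[n_ref >= params.b73_min] = ORIGIN_A
    for i in range(n):
        lo = max(0, i - w + 1)
        hi = min(len(win_label) - 1, i)
        covering = win_label[lo:hi + 1]
        if (covering == "").any():
            continue  # some covering window ambiguous
        uniq = set(covering)
        if len(uniq) != 1:
            continue  # covering windows disagree
        lab = covering[0]
        own_matches = (lab == ORIGIN_B and calls[i] == HOM_ALT) or \
                      (lab == ORIGIN_A and calls[i] == HOM_REF)
        if own_matches:
            labels[i] = lab
    return labels


def merge_allele_blocks(pos: np.ndarray, labels: np.ndarray, chrom: str,
                        ril_id: str, params: RegionParams = RegionParams()
                        ) -> pd.DataFrame:
    """Merge surviving same-allele loci < block_gap apart into regions.

    Every block is retained, including zero-length singletons; a change of
    allele always starts a new block.
    """
    keep = labels != ""
    pos, labels = pos[keep], labels[keep]
    regions = []
    if len(pos) == 0:
        return pd.DataFrame(regions, columns=REGION_COLUMNS)
    start = prev = int(pos[0])
    cur = labels[0]
    for p, lab in zip(pos[1:], labels[1:]):
        p = int(p)
        if lab != cur or (p - prev) >= params.block_gap:
            regions.append((ril_id, chrom, start, prev, cur))
            start, cur = p, lab
        prev = p
    regions.append((ril_id, chrom, start, prev, cur))
    return pd.DataFrame(regions, columns=REGION_COLUMNS)


# ---------------------------------------------------------------------------
# per-RIL pipeline

def classify_ril(callset: GenotypeCallSet, ril_id: str, hc_mask: np.ndarray,
                 params: RegionParams = RegionParams()) -> pd.DataFrame:
    """Full region classification for one RIL: mask, window-label, merge."""
    flagged = flag_ril_specific_loci(callset, ril_id, hc_mask)
    masked = mask_third_origin(flagged, ril_id, params)

    own = np.flatnonzero(((callset.samples["ril_id"] == ril_id)
                          & (callset.samples["klass"] == CLASS_RIL)).to_numpy())
    if own.size == 0:
        raise KeyError(f"no RIL sample for {ril_id}")
    calls, gq = _consensus(callset, own)

    markers = callset.markers
    in_mask = np.zeros(len(markers), dtype=bool)
    for _, m in masked.iterrows():
        in_mask |= ((markers["chrom"] == m["chrom"])
                    & (markers["pos"] >= m["start"])
                    & (markers["pos"] <= m["end"])).to_numpy()
    flagged_loci = np.zeros(len(markers), dtype=bool)
    flagged_loci[flagged["locus"].to_numpy()] = True
    usable = (hc_mask & ~in_mask & ~flagged_loci
              & (gq >= params.min_gq) & (calls != MISSING))

    frames = [masked]
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    for chrom in markers["chrom"].unique():
        idx = np.flatnonzero((chrom_arr == chrom) & usable)
        if idx.size == 0:
            continue
        labels = classify_by_windows(pos_arr[idx], calls[idx], params)
        frames.append(merge_allele_blocks(pos_arr[idx], labels, chrom, ril_id, params))
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _consensus(callset: GenotypeCallSet, sample_idx: np.ndarray
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus consensus over replicate samples: call of the
    highest-GQ non-missing replicate."""
    calls = callset.calls[sample_idx]
    gq = callset.gq[sample_idx].copy()
    gq[calls == MISSING] = -1
    best = gq.argmax(axis=0)
    cols = np.arange(calls.shape[1])
    return calls[best, cols], callset.gq[sample_idx][best, cols]


def exclude_contaminated_rils(regions: pd.DataFrame,
                              params: RegionParams = RegionParams()
                              ) -> tuple[list[str], list[str]]:
    """Split RILs into kept/excluded by masked-genome fraction (> 50%)."""
    kept, excluded = [], []
    lengths = regions["end"] - regions["start"] + 1
    for ril_id, grp in regions.groupby("ril_id", sort=False):
        ln = lengths.loc[grp.index]
        masked = ln[grp["origin"] == MASKED_THIRD].sum()
        classified = ln[grp["origin"].isin([ORIGIN_A, ORIGIN_B])].sum()
        total = masked + classified
        if total > 0 and masked / total > params.max_masked_fraction:
            excluded.append(ril_id)
        else:
            kept.append(ril_id)
    return kept, excluded


@dataclass
class RegionSet:
    """Classified regions for a RIL panel plus exclusion bookkeeping."""

    regions: pd.DataFrame
    hc_mask: np.ndarray
    kept_rils: list[str]
    excluded_rils: list[str]
    sample_report: pd.DataFrame = field(default_factory=pd.DataFrame)

    def for_ril(self, ril_id: str) -> pd.DataFrame:
        return self.regions[self.regions["ril_id"] == ril_id]


def classify_regions(callset: GenotypeCallSet,
                     params: RegionParams = RegionParams()) -> RegionSet:
    """End-to-end classification over all RILs in a callset."""
    hc_mask = select_high_confidence_loci(callset, params)
    report = filter_samples_by_homozygosity(callset, np.flatnonzero(hc_mask), params)
    ril_ids = [r for r in callset.samples.loc[
        callset.samples["klass"] == CLASS_RIL, "ril_id"].unique() if r]
    frames = [classify_ril(callset, rid, hc_mask, params) for rid in ril_ids]
    regions = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=REGION_COLUMNS)
    kept, excluded = exclude_contaminated_rils(regions, params)
    return RegionSet(regions=regions, hc_mask=hc_mask, kept_rils=kept,
                     excluded_rils=excluded, sample_report=report)


# ---------------------------------------------------------------------------
# gene zygosity and heterozygosity fraction

_ZYG_OF = {
    (CLASS_BC_A, ORIGIN_A): ZYG_HOM_A,
    (CLASS_BC_A, ORIGIN_B): ZYG_HET,
    (CLASS_BC_B, ORIGIN_A): ZYG_HET,
    (CLASS_BC_B, ORIGIN_B): ZYG_HOM_B,
}


def annotate_gene_zygosity(genes: pd.DataFrame, ril_regions: pd.DataFrame,
                           hybrid_cross: str) -> pd.Series:
    """Zygosity of each gene in a backcross hybrid of one RIL.

    A gene belongs to the region containing its start coordinate; genes
    overlapping a second, differently classified region are reported as
    no-information (with a warning), as are genes outside every region.
    ``hybrid_cross`` is the hybrid's class ("B73xRIL" or "MO17xRIL").
    """
    if hybrid_cross not in (CLASS_BC_A, CLASS_BC_B):
        raise ValueError(f"unknown cross {hybrid_cross!r}")
    out = pd.Series(ZYG_NO_INFO, index=genes["gene_id"], dtype=object)
    straddlers = 0
    for chrom, reg in ril_regions.groupby("chrom", sort=False):
        reg = reg.sort_values("start")
        rs = reg["start"].to_numpy()
        re_ = reg["end"].to_numpy()
        ro = reg["origin"].to_numpy()
        gsel = genes[genes["chrom"] == chrom]
        for gid, gstart, gend in zip(gsel["gene_id"], gsel["start"], gsel["end"]):
            overlap = np.flatnonzero((rs <= gend) & (re_ >= gstart))
            if overlap.size == 0:
                continue
            containing = overlap[(rs[overlap] <= gstart) & (re_[overlap] >= gstart)]
            origins = set(ro[overlap])
            if len(origins) > 1:
                straddlers += 1
                continue
            if containing.size == 0:
                continue
            origin = ro[containing[0]]
            if origin == MASKED_THIRD:
                out[gid] = ZYG_MASKED
            else:
                out[gid] = _ZYG_OF[(hybrid_cross, origin)]
    if straddlers:
        warnings.warn(f"{straddlers} genes span differently classified regions; "
                      "set to NO_INFO")
    return out


def heterozygosity_fraction(ril_regions: pd.DataFrame, hybrid_cross: str) -> float:
    """Heterozygous fraction of the classified genome of one hybrid.

    The denominator counts only founder-classified regions (masked and
    no-information regions are not considered).
    """
    if hybrid_cross not in (CLASS_BC_A, CLASS_BC_B):
        raise ValueError(f"unknown cross {hybrid_cross!r}")
    het_origin = ORIGIN_B if hybrid_cross == CLASS_BC_A else ORIGIN_A
    lengths = ril_regions["end"] - ril_regions["start"] + 1
    classified = ril_regions["origin"].isin([ORIGIN_A, ORIGIN_B])
    denom = lengths[classified].sum()
    if denom == 0:
        return float("nan")
    het = lengths[classified & (ril_regions["origin"] == het_origin)].sum()
    return float(het / denom)
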