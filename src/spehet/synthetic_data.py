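"""Ground-truthed simulator for a biparental intermated-RIL backcross study.

Generates every input the analysis consumes: mosaic RIL genomes descended
from two founders (with optional third-origin contamination), noisy
genotype calls with quality scores, negative-binomial expression counts
driven by a cis/trans regulatory architecture with allele-dependent gene
silencing, a nested aeroponic experimental design, and phenotypes drawn
from the heterosis regression model used downstream.

The meiosis model is deliberately simple: crossover counts per chromosome
are Poisson with mean equal to the chromosome map length in Morgans, with
no interference, and crossover positions are uniform on the genetic map
(Haldane).  Selfing to homozygosity is idealized (a final doubled gamete
with map expansion factor 2); genotype-call error supplies the realism of
residual heterozygosity seen in real inbred panels.

All operations are pure functions of their inputs and an integer seed.
Coordinates are 1-based closed bp intervals throughout (see :mod:`spehet.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .io import (
    CLASS_BC_A, CLASS_BC_B, CLASS_F1, CLASS_FOUNDER_A, CLASS_FOUNDER_B,
    CLASS_RIL, GENE_META_COLUMNS, GenotypeCallSet, HET, HOM_ALT, HOM_REF,
    MARKER_COLUMNS, MISSING, ORIGIN_A, ORIGIN_B, ORIGIN_THIRD, OTHER_HET,
    OTHER_HOM, validate_marker_map,
)

_CODE_A, _CODE_B, _CODE_THIRD = 0, 1, 2
_ORIGIN_NAME = {_CODE_A: ORIGIN_A, _CODE_B: ORIGIN_B, _CODE_THIRD: ORIGIN_THIRD}
_ORIGIN_CODE = {v: k for k, v in _ORIGIN_NAME.items()}

_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class GenomeSpec:
    """Physical and genetic layout of the simulated genome.

    ``cm_per_mbp`` defines a linear physical-to-genetic map; 0 is allowed
    and yields a map of length zero (no recombination).
    """

    chromosomes: tuple[tuple[str, int], ...] = (("chr1", 50_000_000), ("chr2", 50_000_000))
    marker_density: float = 20.0   # loci per Mbp
    cm_per_mbp: float = 0.7        # maize-like single-meiosis map rate

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be > 0")
        if self.cm_per_mbp < 0:
            raise ValueError("cm_per_mbp must be >= 0")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    def map_length_cm(self, chrom: str) -> float:
        return self.chrom_lengths[chrom] / 1e6 * self.cm_per_mbp


@dataclass
class TrueMosaic:
    """Founder-origin mosaic of one fully homozygous RIL genome.

    ``segments`` has columns chrom, start, end, origin and tiles each
    chromosome exactly once; adjacent segments differ in origin.
    """

    ril_id: str
    segments: pd.DataFrame

    def validate(self, spec: GenomeSpec) -> None:
        for chrom, length in spec.chromosomes:
            seg = self.segments[self.segments["chrom"] == chrom]
            if len(seg) == 0:
                raise ValueError(f"{self.ril_id}: chromosome {chrom} not covered")
            starts = seg["start"].to_numpy()
            ends = seg["end"].to_numpy()
            if starts[0] != 1 or ends[-1] != length:
                raise ValueError(f"{self.ril_id}: segments do not span {chrom}")
            if not (starts[1:] == ends[:-1] + 1).all():
                raise ValueError(f"{self.ril_id}: segments overlap or leave gaps on {chrom}")
            origins = seg["origin"].to_numpy()
            if (origins[1:] == origins[:-1]).any():
                raise ValueError(f"{self.ril_id}: adjacent segments share an origin on {chrom}")

    def origin_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Founder-origin code (0=A, 1=B, 2=third) at each position."""
        seg = self.segments[self.segments["chrom"] == chrom]
        ends = seg["end"].to_numpy()
        idx = np.searchsorted(ends, np.asarray(pos))
        codes = seg["origin"].map(_ORIGIN_CODE).to_numpy()
        return codes[idx]

    def origin_fraction(self, spec: GenomeSpec, origin: str) -> float:
        seg = self.segments
        total = sum(length for _, length in spec.chromosomes)
        mine = (seg.loc[seg["origin"] == origin, "end"]
                - seg.loc[seg["origin"] == origin, "start"] + 1).sum()
        return float(mine) / total


@dataclass(frozen=True)
class GQModel:
    """Two-component genotype-quality mixture: high-confidence calls near
    GQ 99, a configurable fraction of low-confidence calls below 10."""

    low_fraction: float = 0.05
    high_range: tuple[int, int] = (90, 99)
    low_range: tuple[int, int] = (0, 9)

    def draw(self, rng: np.random.Generator, shape) -> np.ndarray:
        low = rng.random(shape) < self.low_fraction
        gq = rng.integers(self.high_range[0], self.high_range[1] + 1, size=shape)
        gq[low] = rng.integers(self.low_range[0], self.low_range[1] + 1, size=int(low.sum()))
        return gq.astype(np.int16)


@dataclass
class PhenotypeGenModel:
    """Generative parameters for the heterosis phenotype model.

    Hybrid observations receive mid-parent value + ``phi`` + gamma . s
    (s = per-pattern SPE-gene counts) + a hybrid deviation with variance
    ``sigma2_het``; all observations receive the nested design random
    effects and plant-level residual noise.
    """

    parental_effects: dict[str, float] | None = None
    parental_mean: float = 10.0
    parental_sd: float = 1.0
    phi: float = 2.0
    gammas: np.ndarray = field(default_factory=lambda: np.zeros(4))
    block_effects: Sequence[float] = (0.0, 0.2, -0.1)
    sigma2_batch: float = 0.3
    sigma2_system: float = 0.2
    sigma2_triplet: float = 0.2
    sigma2_row: float = 0.15
    sigma2_het: float = 0.2
    sigma2_e: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma2_batch", "sigma2_system", "sigma2_triplet",
                     "sigma2_row", "sigma2_het", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        self.gammas = np.asarray(self.gammas, dtype=float)


@dataclass
class ExpressionSet:
    """Raw (and later normalized) counts with sample manifest and truth."""

    counts: pd.DataFrame            # genes x samples, raw
    samples: pd.DataFrame           # sample, genotype_id, klass, ril_id
    genes: pd.DataFrame             # GENE_META_COLUMNS (+ baseline)
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# marker map

def build_marker_map(spec: GenomeSpec, seed: int) -> pd.DataFrame:
    """Draw marker loci uniformly along each chromosome.

    Returns a frame with columns chrom, pos, cm, ref, alt, third; positions
    are strictly increasing per chromosome and the genetic position is the
    linear map ``pos/1e6 * cm_per_mbp``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in spec.chromosomes:
        n = max(1, round(spec.marker_density * length / 1e6))
        n = min(n, length)
        pos = np.sort(rng.choice(length, size=n, replace=False)) + 1
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        third_idx = np.array([
            (set(range(4)) - {r, a}).pop() for r, a in zip(ref_idx, alt_idx)
        ])
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "cm": pos / 1e6 * spec.cm_per_mbp,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "third": _BASES[third_idx],
        }))
    markers = pd.concat(frames, ignore_index=True)[MARKER_COLUMNS]
    return validate_marker_map(markers)


# ---------------------------------------------------------------------------
# meiosis and RIL population

# a haplotype is {chrom: (ends_bp ascending, origin codes)}, segments implied
Haplotype = dict[str, tuple[np.ndarray, np.ndarray]]


def _founder_haplotype(spec: GenomeSpec, code: int) -> Haplotype:
    return {chrom: (np.array([length], dtype=np.int64), np.array([code], dtype=np.int8))
            for chrom, length in spec.chromosomes}


def _segment_slice(ends: np.ndarray, origins: np.ndarray,
                   lo: int, hi: int) -> tuple[list[int], list[int]]:
    """Origins of (lo, hi] as (ends, origins) pieces."""
    out_ends, out_orig = [], []
    i = int(np.searchsorted(ends, lo + 1))
    while i < len(ends):
        e = int(min(ends[i], hi))
        out_ends.append(e)
        out_orig.append(int(origins[i]))
        if ends[i] >= hi:
            break
        i += 1
    return out_ends, out_orig


def meiosis(h1: Haplotype, h2: Haplotype, spec: GenomeSpec,
            rng: np.random.Generator, expansion: float = 1.0) -> Haplotype:
    """One gamete from two parental haplotypes.

    Crossovers per chromosome are Poisson(map length in Morgans x
    expansion), placed uniformly on the genetic map; with a linear map this
    is uniform in bp.  ``expansion`` > 1 models the extra effective
    recombination of selfing generations.
    """
    gamete: Haplotype = {}
    for chrom, length in spec.chromosomes:
        l_morgan = spec.map_length_cm(chrom) / 100.0 * expansion
        n_x = rng.poisson(l_morgan) if l_morgan > 0 else 0
        xpos = np.sort(rng.integers(1, length, size=n_x)) if n_x else np.array([], dtype=np.int64)
        # drop coincident crossover positions (they cancel pairwise anyway
        # only if even; distinct positions keep the walk simple)
        xpos = np.unique(xpos)
        bounds = np.concatenate([[0], xpos, [length]]).astype(np.int64)
        cur = rng.integers(0, 2)
        ends_out: list[int] = []
        orig_out: list[int] = []
        haps = (h1[chrom], h2[chrom])
        for k in range(len(bounds) - 1):
            lo, hi = int(bounds[k]), int(bounds[k + 1])
            if hi <= lo:
                cur = 1 - cur
                continue
            ends, origins = haps[cur]
            e_piece, o_piece = _segment_slice(ends, origins, lo, hi)
            for e, o in zip(e_piece, o_piece):
                if orig_out and orig_out[-1] == o:
                    ends_out[-1] = e
                else:
                    ends_out.append(e)
                    orig_out.append(o)
            cur = 1 - cur
        gamete[chrom] = (np.array(ends_out, dtype=np.int64), np.array(orig_out, dtype=np.int8))
    return gamete


def _haplotype_to_mosaic(hap: Haplotype, ril_id: str) -> TrueMosaic:
    rows = []
    for chrom, (ends, origins) in hap.items():
        start = 1
        for e, o in zip(ends, origins):
            rows.append((chrom, start, int(e), _ORIGIN_NAME[int(o)]))
            start = int(e) + 1
    return TrueMosaic(ril_id=ril_id, segments=pd.DataFrame(
        rows, columns=["chrom", "start", "end", "origin"]))


def simulate_ril_population(spec: GenomeSpec, n_rils: int,
                            n_intermating_gens: int = 4, seed: int = 0,
                            ) -> list[TrueMosaic]:
    """Simulate fully homozygous intermated RILs from two founders.

    The F1 is selfed to a base population, intermated for
    ``n_intermating_gens`` generations of random mating, and each line is
    then taken to homozygosity as a doubled gamete with map expansion
    factor 2 (the standard expansion of RILs by selfing).
    """
    if n_rils < 1:
        raise ValueError("n_rils must be >= 1")
    rng = np.random.default_rng(seed)
    f1 = (_founder_haplotype(spec, _CODE_A), _founder_haplotype(spec, _CODE_B))
    n_pop = max(n_rils, 30)
    pop = [(meiosis(*f1, spec, rng), meiosis(*f1, spec, rng)) for _ in range(n_pop)]
    for _ in range(max(0, n_intermating_gens - 1)):
        new_pop = []
        for _ in range(n_pop):
            i, j = rng.choice(n_pop, size=2, replace=False)
            new_pop.append((meiosis(*pop[i], spec, rng), meiosis(*pop[j], spec, rng)))
        pop = new_pop
    mosaics = []
    for r in range(n_rils):
        gam = meiosis(*pop[r % n_pop], spec, rng, expansion=2.0)
        mosaics.append(_haplotype_to_mosaic(gam, f"RIL{r:04d}"))
    for m in mosaics:
        m.validate(spec)
    return mosaics


def inject_third_origin(mosaics: Sequence[TrueMosaic], spec: GenomeSpec,
                        fraction_contaminated_rils: float,
                        segment_length_dist: Callable[[np.random.Generator], int] | int | None = None,
                        seed: int = 0, segments_per_ril: int = 1,
                        ) -> list[TrueMosaic]:
    """Overwrite random segments of some RILs with a third founder origin.

    Returns new mosaics; the injected segments are the ground-truth mask
    that downstream region classification must recover.
    """
    if not 0.0 <= fraction_contaminated_rils <= 1.0:
        raise ValueError("fraction_contaminated_rils must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if segment_length_dist is None:
        draw_len = lambda r: int(r.lognormal(math.log(3e6), 0.3))
    elif callable(segment_length_dist):
        draw_len = segment_length_dist
    else:
        fixed = int(segment_length_dist)
        draw_len = lambda r: fixed
    chroms = [c for c, _ in spec.chromosomes]
    lengths = np.array([l for _, l in spec.chromosomes], dtype=float)
    out = []
    n_cont = int(round(fraction_contaminated_rils * len(mosaics)))
    which = set(rng.choice(len(mosaics), size=n_cont, replace=False).tolist())
    for i, mos in enumerate(mosaics):
        if i not in which:
            out.append(TrueMosaic(mos.ril_id, mos.segments.copy()))
            continue
        seg = mos.segments.copy()
        for _ in range(segments_per_ril):
            ci = rng.choice(len(chroms), p=lengths / lengths.sum())
            chrom, clen = chroms[ci], int(lengths[ci])
            seg_len = min(max(1, draw_len(rng)), clen)
            start = int(rng.integers(1, clen - seg_len + 2))
            seg = _overwrite_segment(seg, chrom, start, start + seg_len - 1, ORIGIN_THIRD)
        new = TrueMosaic(mos.ril_id, seg)
        new.validate(spec)
        out.append(new)
    return out


def _overwrite_segment(segments: pd.DataFrame, chrom: str, start: int, end: int,
                       origin: str) -> pd.DataFrame:
    rows = []
    for _, s in segments.iterrows():
        if s["chrom"] != chrom or s["end"] < start or s["start"] > end:
            rows.append(tuple(s[["chrom", "start", "end", "origin"]]))
            continue
        if s["start"] < start:
            rows.append((chrom, s["start"], start - 1, s["origin"]))
        if s["end"] > end:
            rows.append((chrom, end + 1, s["end"], s["origin"]))
    rows.append((chrom, start, end, origin))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "origin"])
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    # merge adjacent same-origin segments created by the overwrite
    merged = []
    for _, s in df.iterrows():
        if merged and merged[-1][0] == s["chrom"] and merged[-1][3] == s["origin"] \
                and merged[-1][2] + 1 == s["start"]:
            merged[-1][2] = s["end"]
        else:
            merged.append([s["chrom"], s["start"], s["end"], s["origin"]])
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "origin"])


# ---------------------------------------------------------------------------
# genotype calls

def _diploid_origins(klass: str, ril: TrueMosaic | None, chrom: str,
                     pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pair of founder-origin code arrays for a sample class at loci."""
    n = len(pos)
    a = np.full(n, _CODE_A, dtype=np.int8)
    b = np.full(n, _CODE_B, dtype=np.int8)
    if klass == CLASS_FOUNDER_A:
        return a, a
    if klass == CLASS_FOUNDER_B:
        return b, b
    if klass == CLASS_F1:
        return a, b
    assert ril is not None
    r = ril.origin_at(chrom, pos)
    if klass == CLASS_RIL:
        return r, r
    if klass == CLASS_BC_A:
        return a, r
    if klass == CLASS_BC_B:
        return b, r
    raise ValueError(f"unknown sample class {klass!r}")


def _calls_from_origins(o1: np.ndarray, o2: np.ndarray,
                        third_allele: np.ndarray) -> np.ndarray:
    """Map diploid founder origins to genotype-call codes.

    ``third_allele`` gives, per locus, which allele the third genome
    carries: 0 = ref, 1 = alt, 2 = novel.
    """
    # resolve third origins into allele identities
    def allele(o):
        al = np.where(o == _CODE_THIRD, third_allele, o).astype(np.int8)
        return al
    a1, a2 = allele(o1), allele(o2)
    calls = np.empty(len(o1), dtype=np.int8)
    both_novel = (a1 == 2) & (a2 == 2)
    one_novel = ((a1 == 2) | (a2 == 2)) & ~both_novel
    plain = ~(both_novel | one_novel)
    calls[both_novel] = OTHER_HOM
    calls[one_novel] = OTHER_HET
    hom = plain & (a1 == a2)
    calls[hom & (a1 == 0)] = HOM_REF
    calls[hom & (a1 == 1)] = HOM_ALT
    calls[plain & (a1 != a2)] = HET
    return calls


def simulate_genotype_calls(mosaics: Sequence[TrueMosaic], markers: pd.DataFrame,
                            gq_model: GQModel | None = None,
                            missing_rate: float = 0.02, error_rate: float = 0.006,
                            seed: int = 0, founder_reps: int = 6,
                            ril_reps: int = 1, hybrid_reps: int = 1,
                            third_novel_fraction: float = 0.6,
                            ) -> GenotypeCallSet:
    """Simulate genotype calls for founders, RILs and both backcross hybrids.

    With zero error, hybrids are heterozygous exactly where the RIL origin
    differs from the recurrent parent; third-origin RIL segments emit
    alleles matching neither founder at a ``third_novel_fraction`` of loci
    (at the remainder the third genome happens to share a founder allele).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must be in [0, 1]")
    gq_model = gq_model or GQModel()
    rng = np.random.default_rng(seed)
    validate_marker_map(markers)
    sample_rows: list[tuple[str, str, str]] = []
    for rep in range(founder_reps):
        sample_rows.append((f"B73_r{rep}", CLASS_FOUNDER_A, ""))
        sample_rows.append((f"MO17_r{rep}", CLASS_FOUNDER_B, ""))
    for mos in mosaics:
        for rep in range(ril_reps):
            sample_rows.append((f"{mos.ril_id}_r{rep}", CLASS_RIL, mos.ril_id))
        for rep in range(hybrid_reps):
            sample_rows.append((f"B73x{mos.ril_id}_r{rep}", CLASS_BC_A, mos.ril_id))
            sample_rows.append((f"MO17x{mos.ril_id}_r{rep}", CLASS_BC_B, mos.ril_id))
    samples = pd.DataFrame(sample_rows, columns=["sample", "klass", "ril_id"])

    by_ril = {m.ril_id: m for m in mosaics}
    n_loci = len(markers)
    # identity of the third-origin allele, fixed per RIL genome
    third_alleles = {
        rid: np.where(rng.random(n_loci) < third_novel_fraction, 2,
                      rng.integers(0, 2, size=n_loci)).astype(np.int8)
        for rid in by_ril
    }
    no_third = np.zeros(n_loci, dtype=np.int8)

    chrom_slices = {}
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    for chrom in markers["chrom"].unique():
        chrom_slices[chrom] = np.flatnonzero(chrom_arr == chrom)

    calls = np.empty((len(samples), n_loci), dtype=np.int8)
    for i, (name, klass, rid) in enumerate(sample_rows):
        ril = by_ril.get(rid)
        third = third_alleles.get(rid, no_third)
        for chrom, idx in chrom_slices.items():
            o1, o2 = _diploid_origins(klass, ril, chrom, pos_arr[idx])
            calls[i, idx] = _calls_from_origins(o1, o2, third[idx])
    # calling noise: flips to a random different plain call, then missingness
    if error_rate > 0:
        err = rng.random(calls.shape) < error_rate
        shift = rng.integers(1, 3, size=calls.shape)
        flipped = (calls + shift) % 3  # cycles within {HOM_REF, HOM_ALT, HET}
        calls = np.where(err, flipped.astype(np.int8), calls)
    if missing_rate > 0:
        calls = np.where(rng.random(calls.shape) < missing_rate,
                         np.int8(MISSING), calls)
    gq = gq_model.draw(rng, calls.shape)
    return GenotypeCallSet(markers=markers, samples=samples, calls=calls, gq=gq)


# ---------------------------------------------------------------------------
# genes and regulatory architecture

def build_gene_table(spec: GenomeSpec, n_genes: int, seed: int = 0,
                     syntenic_fraction: float = 0.6,
                     mean_length: float = 3000.0) -> pd.DataFrame:
    """Random gene models with GC fraction, length, synteny flag and a
    baseline expression level (lognormal across genes)."""
    rng = np.random.default_rng(seed)
    chroms = [c for c, _ in spec.chromosomes]
    lengths = np.array([l for _, l in spec.chromosomes], dtype=float)
    ci = rng.choice(len(chroms), size=n_genes, p=lengths / lengths.sum())
    glen = np.maximum(200, rng.lognormal(math.log(mean_length), 0.6, size=n_genes)).astype(np.int64)
    start = np.array([rng.integers(1, max(2, int(lengths[c]) - int(l)))
                      for c, l in zip(ci, glen)], dtype=np.int64)
    genes = pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(n_genes)],
        "chrom": [chroms[c] for c in ci],
        "start": start,
        "end": start + glen - 1,
        "gc": np.clip(rng.beta(20, 20, size=n_genes), 0.01, 0.99),
        "length": glen,
        "syntenic": rng.random(n_genes) < syntenic_fraction,
        "baseline": rng.lognormal(math.log(100.0), 1.0, size=n_genes),
    })
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def build_regulatory_architecture(genes: pd.DataFrame, spec: GenomeSpec,
                                  seed: int = 0, cis_fraction: float = 0.5,
                                  silenced_fraction: float = 0.3,
                                  cis_window: float = 2.5e6,
                                  silencing_bias_b: float = 0.5,
                                  ) -> pd.DataFrame:
    """Assign each gene a regulatory locus, mode and silencing allele.

    A ``silenced_fraction`` of genes carries a silencing allele (founder A
    or B, B with probability ``silencing_bias_b``): the gene is inactive in
    any genotype homozygous for that allele at the regulatory locus and
    active whenever the other founder allele is present — the generative
    mechanism of single-parent expression.  Cis loci sit within
    ``cis_window`` of the gene start, trans loci on another chromosome (or
    far away when the genome has a single chromosome).
    """
    rng = np.random.default_rng(seed)
    chrom_len = spec.chrom_lengths
    chroms = list(chrom_len)
    n = len(genes)
    mode = np.where(rng.random(n) < cis_fraction, "cis", "trans")
    silenced = rng.random(n) < silenced_fraction
    sil_allele = np.where(rng.random(n) < silencing_bias_b, ORIGIN_B, ORIGIN_A)
    sil_allele = np.where(silenced, sil_allele, "none")
    required = np.where(sil_allele == ORIGIN_B, ORIGIN_A,
                        np.where(sil_allele == ORIGIN_A, ORIGIN_B, "none"))
    eq_chrom, eq_pos = [], []
    for i, g in genes.iterrows():
        if mode[i] == "cis":
            c = g["chrom"]
            off = int(rng.uniform(-0.4 * cis_window, 0.4 * cis_window))
            p = int(np.clip(g["start"] + off, 1, chrom_len[c]))
        else:
            others = [c for c in chroms if c != g["chrom"]]
            if others:
                c = others[int(rng.integers(0, len(others)))]
                p = int(rng.integers(1, chrom_len[c] + 1))
            else:
                c = g["chrom"]
                lo, hi = 1, chrom_len[c]
                far_lo = g["start"] - 4 * cis_window
                far_hi = g["start"] + 4 * cis_window
                choices = []
                if far_lo > lo:
                    choices.append((lo, int(far_lo)))
                if far_hi < hi:
                    choices.append((int(far_hi), hi))
                a, b = choices[int(rng.integers(0, len(choices)))]
                p = int(rng.integers(a, b + 1))
        eq_chrom.append(c)
        eq_pos.append(p)
    return pd.DataFrame({
        "gene_id": genes["gene_id"].to_numpy(),
        "eqtl_chrom": eq_chrom,
        "eqtl_pos": np.array(eq_pos, dtype=np.int64),
        "mode": mode,
        "silencing_allele": sil_allele,
        "required_active_allele": required,
    })


def true_activity(architecture: pd.DataFrame, genotypes: pd.DataFrame,
                  mosaics: Sequence[TrueMosaic]) -> pd.DataFrame:
    """Exhaustive ground-truth activity matrix (genotype x gene).

    A gene is active in a genotype unless the genotype is homozygous for
    the silencing allele at the regulatory locus (third-origin alleles do
    not activate a silenced gene).
    """
    by_ril = {m.ril_id: m for m in mosaics}
    rows = {}
    for _, g in genotypes.iterrows():
        ril = by_ril.get(g["ril_id"])
        active = np.ones(len(architecture), dtype=bool)
        for chrom in architecture["eqtl_chrom"].unique():
            idx = np.flatnonzero((architecture["eqtl_chrom"] == chrom).to_numpy())
            pos = architecture["eqtl_pos"].to_numpy()[idx]
            o1, o2 = _diploid_origins(g["klass"], ril, chrom, pos)
            sil = architecture["silencing_allele"].to_numpy()[idx]
            req = architecture["required_active_allele"].to_numpy()[idx]
            name1 = np.array([_ORIGIN_NAME[int(o)] for o in o1])
            name2 = np.array([_ORIGIN_NAME[int(o)] for o in o2])
            has_req = (name1 == req) | (name2 == req)
            active[idx] = (sil == "none") | has_req
        rows[g["genotype_id"]] = active
    return pd.DataFrame(rows, index=architecture["gene_id"]).T


def simulate_expression_counts(genes: pd.DataFrame, architecture: pd.DataFrame,
                               genotypes: pd.DataFrame, mosaics: Sequence[TrueMosaic],
                               nb_dispersion: float = 0.1, reps: int = 3,
                               library_sizes: dict[str, float] | None = None,
                               gc_length_artifact: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
                               deterministic: bool = False,
                               seed: int = 0) -> ExpressionSet:
    """Negative-binomial counts per gene x sample.

    Expected count = baseline x activity(genotype at regulatory locus) x
    artifact(GC, log length) x library-size factor.  ``genotypes`` has
    columns genotype_id, klass, ril_id; each genotype gets ``reps``
    replicate samples.  ``nb_dispersion`` is the NB alpha
    (var = mu + alpha mu^2); 0 gives Poisson counts.
    """
    rng = np.random.default_rng(seed)
    activity = true_activity(architecture, genotypes, mosaics)
    baseline = genes["baseline"].to_numpy() if "baseline" in genes else \
        np.full(len(genes), 100.0)
    if gc_length_artifact is None:
        artifact = np.ones(len(genes))
    else:
        artifact = np.asarray(gc_length_artifact(
            genes["gc"].to_numpy(), np.log(genes["length"].to_numpy())), dtype=float)
    sample_rows = []
    cols = {}
    for _, g in genotypes.iterrows():
        act = activity.loc[g["genotype_id"]].to_numpy()
        for rep in range(reps):
            name = f"{g['genotype_id']}_e{rep}"
            lib = 1.0 if library_sizes is None else float(library_sizes.get(name, 1.0))
            if lib <= 0:
                raise ValueError(f"non-positive library size for {name}")
            mu = baseline * act * artifact * lib
            if deterministic:
                counts = mu.copy()
            elif nb_dispersion > 0:
                nsize = 1.0 / nb_dispersion
                counts = rng.negative_binomial(nsize, nsize / (nsize + np.maximum(mu, 1e-12)))
                counts[mu == 0] = 0
            else:
                counts = rng.poisson(mu)
            cols[name] = counts
            sample_rows.append((name, g["genotype_id"], g["klass"], g["ril_id"]))
    counts = pd.DataFrame(cols, index=genes["gene_id"])
    samples = pd.DataFrame(sample_rows, columns=["sample", "genotype_id", "klass", "ril_id"])
    return ExpressionSet(counts=counts, samples=samples, genes=genes,
                         truth={"activity": activity, "architecture": architecture})


# ---------------------------------------------------------------------------
# experimental design and phenotypes

def build_experimental_design(n_triplets: int, n_blocks: int = 3,
                              batches_per_block: int = 4, systems_per_batch: int = 8,
                              rows_per_system: int = 12, plants_per_row: int = 8,
                              reference_triplets_per_batch: int = 2,
                              ril_ids: Sequence[str] | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Plant-level layout of the nested aeroponic design.

    ``n_triplets`` RIL triplets (RIL + its two backcross hybrids) are
    distributed over the batches of each block, alongside reference
    triplets (the two founder inbreds plus one reference F1 hybrid per
    triplet).  Each triplet occupies three consecutive rows of one growth
    system; triplet-to-position randomization is redone per block
    (replicate-level randomization).
    """
    if ril_ids is None:
        ril_ids = [f"RIL{i:04d}" for i in range(n_triplets)]
    if len(ril_ids) != n_triplets:
        raise ValueError("ril_ids length must equal n_triplets")
    triplets_per_system = rows_per_system // 3
    per_batch = math.ceil(n_triplets / batches_per_block) + reference_triplets_per_batch
    capacity = systems_per_batch * triplets_per_system
    if per_batch > capacity:
        raise ValueError(
            f"design capacity exceeded: {per_batch} triplets per batch "
            f"but only {capacity} fit ({systems_per_batch} systems x {triplets_per_system})")
    rng = np.random.default_rng(seed)

    trios: list[tuple[str, tuple[tuple[str, str, str], ...]]] = []
    for rid in ril_ids:
        trios.append((rid, ((rid, CLASS_RIL, rid),
                            (f"B73x{rid}", CLASS_BC_A, rid),
                            (f"MO17x{rid}", CLASS_BC_B, rid))))
    ref_trios = [("REF_A", (("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, ""),
                            ("B73xMO17", CLASS_F1, ""))),
                 ("REF_B", (("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, ""),
                            ("MO17xB73", CLASS_F1, "")))]

    records = []
    for j in range(1, n_blocks + 1):
        order = rng.permutation(n_triplets)
        batches: list[list] = [[] for _ in range(batches_per_block)]
        for pos, t in enumerate(order):
            batches[pos % batches_per_block].append(trios[t])
        for k, batch in enumerate(batches, start=1):
            for rr in range(reference_triplets_per_batch):
                batch.append(ref_trios[rr % len(ref_trios)])
            slots = [(l, s) for l in range(1, systems_per_batch + 1)
                     for s in range(triplets_per_system)]
            slot_idx = rng.permutation(len(slots))[: len(batch)]
            for (trio_name, members), si in zip(batch, slot_idx):
                l, s = slots[si]
                row_order = rng.permutation(3)
                for r_off, member in zip(row_order, members):
                    row_n = s * 3 + r_off + 1
                    geno, klass, rid = member
                    batch_id = f"B{j}.K{k}"
                    system_id = f"{batch_id}.S{l}"
                    triplet_id = f"{system_id}.T{trio_name}"
                    row_id = f"{system_id}.R{row_n:02d}"
                    for p in range(1, plants_per_row + 1):
                        records.append((j, batch_id, system_id, triplet_id, row_id,
                                        p, geno, klass, rid, trio_name))
    design = pd.DataFrame(records, columns=[
        "block", "batch", "system", "triplet", "row", "plant",
        "genotype_id", "klass", "ril_id", "trio"])
    design.attrs["n_blocks"] = n_blocks
    return design


def pedigree_of(design: pd.DataFrame) -> pd.DataFrame:
    """Hybrid -> (mother, father) table derived from genotype labels."""
    rows = []
    for geno, klass, rid in design[["genotype_id", "klass", "ril_id"]].drop_duplicates().itertuples(index=False):
        if klass == CLASS_BC_A:
            rows.append((geno, "B73", rid))
        elif klass == CLASS_BC_B:
            rows.append((geno, "MO17", rid))
        elif klass == CLASS_F1:
            m, f = ("B73", "MO17") if geno.startswith("B73") else ("MO17", "B73")
            rows.append((geno, m, f))
    return pd.DataFrame(rows, columns=["hybrid", "mother", "father"])


def gamma_for_target_p_het(spe_counts: pd.DataFrame, sigma2_het: float,
                           target: float, weights: np.ndarray | None = None) -> np.ndarray:
    """Slope vector whose implied explained-variance fraction equals ``target``.

    Given realized per-pattern SPE counts of the hybrids, returns gammas =
    g * w with Var(gammas . s) / (Var(gammas . s) + sigma2_het) = target.
    """
    if not 0.0 <= target < 1.0:
        raise ValueError("target must be in [0, 1)")
    w = np.ones(spe_counts.shape[1]) if weights is None else np.asarray(weights, float)
    if target == 0.0:
        return np.zeros_like(w)
    proj = spe_counts.to_numpy(dtype=float) @ w
    v = proj.var(ddof=1)
    if v <= 0:
        raise ValueError("SPE counts have zero variance; cannot hit a nonzero target")
    g = math.sqrt(target / (1.0 - target) * sigma2_het / v)
    return g * w


def implied_p_het(gen_model: PhenotypeGenModel, spe_counts: pd.DataFrame) -> float:
    """Ground-truth explained-variance fraction for a set of hybrids."""
    proj = spe_counts.to_numpy(dtype=float) @ gen_model.gammas
    v = proj.var(ddof=1)
    denom = v + gen_model.sigma2_het
    return 0.0 if denom == 0 else float(v / denom)


def simulate_phenotypes(design: pd.DataFrame, gen_model: PhenotypeGenModel,
                        spe_counts_per_hybrid: pd.DataFrame, seed: int = 0,
                        ) -> tuple[pd.DataFrame, dict]:
    """Draw plant-level phenotypes from the generative heterosis model.

    ``spe_counts_per_hybrid`` is indexed by hybrid genotype_id with one
    column per SPE pattern (counts).  Returns the phenotype table (one row
    per plant, with all design factors) and a truth dict including the
    implied explained-variance fraction per backcross population.
    """
    rng = np.random.default_rng(seed)
    pedigree = pedigree_of(design)
    parents = sorted(set(design.loc[design["klass"].isin(
        [CLASS_RIL, CLASS_FOUNDER_A, CLASS_FOUNDER_B]), "genotype_id"]))
    if gen_model.parental_effects is None:
        beta = {p: float(rng.normal(gen_model.parental_mean, gen_model.parental_sd))
                for p in parents}
    else:
        beta = dict(gen_model.parental_effects)
    hybrids = pedigree.set_index("hybrid")
    missing = [h for h in hybrids.index if h not in spe_counts_per_hybrid.index]
    if missing:
        raise ValueError(f"SPE counts missing for hybrids: {missing[:5]}...")

    def rand_effects(levels: pd.Series, sigma2: float) -> pd.Series:
        uniq = levels.unique()
        draw = dict(zip(uniq, rng.normal(0.0, math.sqrt(sigma2), size=len(uniq))))
        return levels.map(draw)

    n = len(design)
    blocks = design["block"].to_numpy()
    b_eff = np.asarray(gen_model.block_effects, dtype=float)
    y = b_eff[(blocks - 1) % len(b_eff)].copy()
    y += rand_effects(design["batch"], gen_model.sigma2_batch).to_numpy()
    y += rand_effects(design["system"], gen_model.sigma2_system).to_numpy()
    y += rand_effects(design["triplet"], gen_model.sigma2_triplet).to_numpy()
    y += rand_effects(design["row"], gen_model.sigma2_row).to_numpy()
    y += rng.normal(0.0, math.sqrt(gen_model.sigma2_e), size=n)

    g_dev = {h: float(rng.normal(0.0, math.sqrt(gen_model.sigma2_het)))
             for h in hybrids.index}
    genetic = np.empty(n)
    for geno, grp in design.groupby("genotype_id", sort=False):
        idx = grp.index.to_numpy()
        if geno in beta:
            genetic[idx] = beta[geno]
        else:
            mo, fa = hybrids.loc[geno, ["mother", "father"]]
            s = spe_counts_per_hybrid.loc[geno].to_numpy(dtype=float)
            genetic[idx] = (0.5 * beta[mo] + 0.5 * beta[fa] + gen_model.phi
                            + float(s @ gen_model.gammas) + g_dev[geno])
    y += genetic

    table = design.copy()
    table["value"] = y
    truth = {"beta": beta, "g_dev": g_dev, "phi": gen_model.phi,
             "gammas": gen_model.gammas.tolist()}
    for klass in (CLASS_BC_A, CLASS_BC_B):
        hyb = design.loc[design["klass"] == klass, "genotype_id"].unique()
        hyb = [h for h in hyb if h in spe_counts_per_hybrid.index]
        if len(hyb) >= 2:
            truth[f"p_het_{klass}"] = implied_p_het(
                gen_model, spe_counts_per_hybrid.loc[hyb])
    return table, truth
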