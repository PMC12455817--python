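"""Per-gene eQTL mapping by Haley–Knott regression on HMM genotype
probabilities, with permutation significance, across-gene FDR, peak
merging and cis/trans classification.

The scan works on a two-genotype cross (selfed RILs coded founder-A/
founder-B homozygous, or a backcross coded recurrent-homozygous vs
heterozygous).  Genotype probabilities at markers and at an interleaved
1-cM pseudomarker grid come from a forward–backward pass with Haldane
transition probabilities (map expansion factor 2 for selfed RILs) and a
symmetric genotyping-error emission model.  At every position the
expression phenotype is regressed on the expected genotype dosage and

    LOD = (n/2) log10(RSS0 / RSS1).

Significance per gene uses permutations of the expression values,
recording the genome-wide maximum LOD of each permutation; the adjusted
p-value is the fraction of permutation maxima >= the observed peak LOD
and the significance threshold is the 99.9th percentile of the maxima
(alpha = 0.001).  Across genes, Benjamini–Hochberg FDR is applied with
the effective test count set to the total number of genes plus the
number of secondary peaks.  Support intervals are 1.5-LOD drop regions;
peaks for the same gene are merged unless >= 25 Mbp apart (or on
different chromosomes) with mutually exclusive support intervals.  An
eQTL is cis if it lies < 2.5 Mbp from its gene's start on the same
chromosome or its support interval covers the gene start, else trans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

LOD_CEILING = 300.0  # cap for numerically exact fits


# ---------------------------------------------------------------------------
# cross container and marker preparation

@dataclass
class CrossGeno:
    """Genotypes of one mapping population.

    ``geno`` is (individuals x markers) with codes 1 (A/A, or recurrent
    homozygote in a backcross), 2 (B/B, or heterozygote) and 0 = missing.
    ``markers`` has columns chrom, pos (bp), cm, non-decreasing in cm per
    chromosome.  ``cross_type`` is "rilself" or "bc".
    """

    cross_type: str
    markers: pd.DataFrame
    geno: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        if self.cross_type not in ("rilself", "bc"):
            raise ValueError("cross_type must be 'rilself' or 'bc'")
        for _, grp in self.markers.groupby("chrom", sort=False):
            if (np.diff(grp["cm"].to_numpy()) < 0).any():
                raise ValueError("genetic positions must be non-decreasing")
        if self.geno.shape != (len(self.individuals), len(self.markers)):
            raise ValueError("geno shape mismatch")


@dataclass
class ProbGrid:
    """Genotype probabilities on the marker + pseudomarker grid."""

    positions: pd.DataFrame        # chrom, pos (bp), cm, is_pseudo
    prob: np.ndarray               # (individuals, positions, 2)
    individuals: list[str]

    @property
    def dosage(self) -> np.ndarray:
        """Expected dosage of the second genotype per individual/position."""
        return self.prob[:, :, 1]


def prepare_markers(cross: CrossGeno, max_ind_missing: float = 0.19,
                    max_marker_missing: float = 0.60,
                    min_spacing_cm: float = 1.0,
                    pseudomarker_step_cm: float = 1.0) -> CrossGeno:
    """Drop bad individuals/markers and thin markers to >= 1 cM spacing.

    Individuals with more than 19% missing genotypes and duplicated
    individuals are dropped, then markers with more than 60% missing
    calls; remaining markers are greedily thinned keeping the first
    marker of each run of near-coincident markers.
    """
    geno = cross.geno
    miss_ind = (geno == 0).mean(axis=1)
    keep_ind = miss_ind <= max_ind_missing
    # duplicated genotype rows: keep the first occurrence
    seen: dict[bytes, int] = {}
    for i in np.flatnonzero(keep_ind):
        key = geno[i].tobytes()
        if key in seen:
            keep_ind[i] = False
        else:
            seen[key] = i
    geno = geno[keep_ind]
    individuals = [ind for ind, k in zip(cross.individuals, keep_ind) if k]

    miss_mark = (geno == 0).mean(axis=0)
    keep_mark = miss_mark <= max_marker_missing
    markers = cross.markers.loc[keep_mark.nonzero()[0]].reset_index(drop=True)
    geno = geno[:, keep_mark]

    keep_thin = np.zeros(len(markers), dtype=bool)
    for _, grp in markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["cm"].to_numpy()
        last = -np.inf
        for j, c in zip(idx, cm):
            if c - last >= min_spacing_cm or not np.isfinite(last):
                keep_thin[j] = True
                last = c
    markers = markers.loc[keep_thin].reset_index(drop=True)
    geno = geno[:, keep_thin]
    for chrom, grp in markers.groupby("chrom", sort=False):
        if len(grp) == 0:
            raise ValueError(f"chromosome {chrom} has no markers after filtering")
    return CrossGeno(cross_type=cross.cross_type, markers=markers,
                     geno=geno, individuals=individuals)


def _pseudomarker_grid(markers: pd.DataFrame, step_cm: float) -> pd.DataFrame:
    """Insert pseudomarkers so no gap exceeds ``step_cm`` on the cM map.

    Physical positions of pseudomarkers are linearly interpolated from
    the flanking markers.
    """
    frames = []
    for chrom, grp in markers.groupby("chrom", sort=False):
        cm = grp["cm"].to_numpy()
        bp = grp["pos"].to_numpy().astype(float)
        rows = [(chrom, bp[0], cm[0], False)]
        for j in range(1, len(cm)):
            gap = cm[j] - cm[j - 1]
            n_ins = int(np.ceil(gap / step_cm)) - 1 if gap > 0 else 0
            for t in range(1, n_ins + 1):
                c = cm[j - 1] + gap * t / (n_ins + 1)
                p = np.interp(c, [cm[j - 1], cm[j]], [bp[j - 1], bp[j]])
                rows.append((chrom, p, c, True))
            rows.append((chrom, bp[j], cm[j], False))
        frames.append(pd.DataFrame(rows, columns=["chrom", "pos", "cm", "is_pseudo"]))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# HMM genotype probabilities

def _recomb_fraction(d_cm: np.ndarray, cross_type: str) -> np.ndarray:
    """Haldane recombination fraction over a map distance, with the
    map-expansion factor 2 applied for selfed RILs."""
    r = 0.5 * (1.0 - np.exp(-2.0 * d_cm / 100.0))
    if cross_type == "rilself":
        r = 2.0 * r / (1.0 + 2.0 * r)
    return r


def genotype_probabilities(cross: CrossGeno, error_prob: float = 0.001,
                           pseudomarker_step_cm: float = 1.0) -> ProbGrid:
    """Forward–backward genotype probabilities at markers + pseudomarkers.

    Emission: an observed code is correct with probability 1 - error_prob;
    missing genotypes are uninformative.  Probabilities at every position
    sum to one.
    """
    grid = _pseudomarker_grid(cross.markers, pseudomarker_step_cm)
    n_ind = len(cross.individuals)
    prob = np.empty((n_ind, len(grid), 2))
    obs_col = {}
    j_obs = 0
    for g_idx, row in grid.iterrows():
        if not row["is_pseudo"]:
            obs_col[g_idx] = j_obs
            j_obs += 1
    for chrom, grp in grid.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        cm = grp["cm"].to_numpy()
        n_pos = len(idx)
        # emission matrix per position: (n_ind, n_pos, 2)
        emit = np.ones((n_ind, n_pos, 2))
        for k, g_idx in enumerate(idx):
            if g_idx in obs_col:
                obs = cross.geno[:, obs_col[g_idx]]
                e1 = np.where(obs == 1, 1.0 - error_prob,
                              np.where(obs == 2, error_prob, 1.0))
                e2 = np.where(obs == 2, 1.0 - error_prob,
                              np.where(obs == 1, error_prob, 1.0))
                emit[:, k, 0] = e1
                emit[:, k, 1] = e2
        r = _recomb_fraction(np.diff(cm), cross.cross_type)
        # forward
        fwd = np.empty((n_ind, n_pos, 2))
        a = 0.5 * emit[:, 0, :]
        a /= a.sum(axis=1, keepdims=True)
        fwd[:, 0] = a
        for k in range(1, n_pos):
            stay, sw = 1.0 - r[k - 1], r[k - 1]
            a = np.empty_like(a)
            a[:, 0] = fwd[:, k - 1, 0] * stay + fwd[:, k - 1, 1] * sw
            a[:, 1] = fwd[:, k - 1, 0] * sw + fwd[:, k - 1, 1] * stay
            a *= emit[:, k, :]
            a /= a.sum(axis=1, keepdims=True)
            fwd[:, k] = a
        # backward
        bwd = np.empty((n_ind, n_pos, 2))
        bwd[:, -1] = 1.0
        for k in range(n_pos - 2, -1, -1):
            stay, sw = 1.0 - r[k], r[k]
            b0 = bwd[:, k + 1, 0] * emit[:, k + 1, 0]
            b1 = bwd[:, k + 1, 1] * emit[:, k + 1, 1]
            bwd[:, k, 0] = b0 * stay + b1 * sw
            bwd[:, k, 1] = b0 * sw + b1 * stay
            norm = bwd[:, k].sum(axis=1, keepdims=True)
            bwd[:, k] /= norm
        post = fwd * bwd
        post /= post.sum(axis=2, keepdims=True)
        prob[:, idx, :] = post
    return ProbGrid(positions=grid, prob=prob, individuals=list(cross.individuals))


# ---------------------------------------------------------------------------
# Haley–Knott scan

def hk_scan(phenotypes: np.ndarray, grid: ProbGrid) -> np.ndarray:
    """LOD curves: (genes x positions) single-dosage Haley–Knott regression.

    ``phenotypes`` is (genes x individuals) (a 1-D array is treated as a
    single gene).  Positions with zero dosage variance, or phenotypes
    with zero variance, get LOD 0; numerically exact fits are capped.
    """
    Y = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    n = Y.shape[1]
    D = grid.dosage
    if D.shape[0] != n:
        raise ValueError("phenotype / individual count mismatch")
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Dc = D - D.mean(axis=0, keepdims=True)
    ssy = (Yc ** 2).sum(axis=1)
    ssd = (Dc ** 2).sum(axis=0)
    cross = Yc @ Dc                              # genes x positions
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((ssy[:, None] > 0) & (ssd[None, :] > 0),
                      cross ** 2 / (ssy[:, None] * ssd[None, :]), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    one_minus = np.maximum(1.0 - r2, 10.0 ** (-2.0 * LOD_CEILING / n))
    lod = -(n / 2.0) * np.log10(one_minus)
    return np.minimum(lod, LOD_CEILING)


def permutation_max_lods(phenotype: np.ndarray, grid: ProbGrid, n_perm: int,
                         seed: int) -> np.ndarray:
    """Genome-wide maximum LOD of each expression permutation."""
    if n_perm < 100:
        warnings.warn("fewer than 100 permutations: p-value resolution is coarse")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    perms = np.empty((n_perm, len(y)))
    for b in range(n_perm):
        perms[b] = y[rng.permutation(len(y))]
    return hk_scan(perms, grid).max(axis=1)


def permutation_pvalue(observed_lod: float, max_lods: np.ndarray) -> float:
    """Adjusted p = fraction of permutation maxima >= the observed LOD
    (0 means below the resolution 1/n_perm)."""
    return float((max_lods >= observed_lod).mean())


def permutation_threshold(max_lods: np.ndarray, alpha: float = 0.001) -> float:
    """Significance threshold: the (1 - alpha) percentile of the maxima."""
    return float(np.quantile(max_lods, 1.0 - alpha))


# ---------------------------------------------------------------------------
# peaks

@dataclass
class EqtlPeak:
    gene_id: str
    chrom: str
    pos_bp: float
    pos_cm: float
    lod: float
    ci_lo_bp: float
    ci_hi_bp: float
    adj_p: float = np.nan
    q_value: float = np.nan
    regulation: str = ""
    dataset: str = ""

    def __post_init__(self) -> None:
        if not (self.ci_lo_bp <= self.pos_bp <= self.ci_hi_bp):
            raise ValueError("peak outside its support interval")
        if self.lod < 0:
            raise ValueError("LOD must be >= 0")


def find_peaks(lod: np.ndarray, grid: ProbGrid, threshold: float,
               gene_id: str = "", drop: float = 1.5) -> list[EqtlPeak]:
    """Local maxima above threshold with 1.5-LOD-drop support intervals.

    Within a chromosome, maxima not separated by a valley dropping more
    than ``drop`` below the smaller of the two are merged (the higher
    one is kept; ties break to the lower coordinate).
    """
    peaks: list[EqtlPeak] = []
    pos = grid.positions
    for chrom, grp in pos.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        curve = lod[idx]
        n = len(curve)
        # local maxima; a plateau counts once, at its lowest coordinate
        cand: list[int] = []
        k = 0
        while k < n:
            j = k
            while j + 1 < n and curve[j + 1] == curve[k]:
                j += 1
            left_ok = k == 0 or curve[k - 1] < curve[k]
            right_ok = j == n - 1 or curve[j + 1] < curve[k]
            if left_ok and right_ok and curve[k] >= threshold:
                cand.append(k)
            k = j + 1
        # merge candidates not separated by a deep enough valley
        merged: list[int] = []
        for k in cand:
            if not merged:
                merged.append(k)
                continue
            prev = merged[-1]
            valley = curve[min(prev, k): max(prev, k) + 1].min()
            if valley <= min(curve[prev], curve[k]) - drop:
                merged.append(k)
            elif curve[k] > curve[prev]:
                merged[-1] = k
        for k in merged:
            peak_lod = curve[k]
            lo = k
            while lo > 0 and curve[lo - 1] >= peak_lod - drop:
                lo -= 1
            hi = k
            while hi < n - 1 and curve[hi + 1] >= peak_lod - drop:
                hi += 1
            bp = grp["pos"].to_numpy()
            cm = grp["cm"].to_numpy()
            peaks.append(EqtlPeak(
                gene_id=gene_id, chrom=chrom, pos_bp=float(bp[k]),
                pos_cm=float(cm[k]), lod=float(peak_lod),
                ci_lo_bp=float(bp[lo]), ci_hi_bp=float(bp[hi])))
    return peaks


# ---------------------------------------------------------------------------
# multiple testing, merging, cis/trans

def fdr_across_genes(peaks: list[EqtlPeak], n_genes_total: int,
                     fdr_threshold: float = 0.001) -> list[EqtlPeak]:
    """Benjamini–Hochberg on per-gene adjusted p-values.

    The effective test count is the total number of genes plus the
    number of secondary (second, third, ...) peaks.  Peaks with
    q <= ``fdr_threshold`` are returned.
    """
    if not peaks:
        return []
    per_gene: dict[str, int] = {}
    for pk in peaks:
        per_gene[pk.gene_id] = per_gene.get(pk.gene_id, 0) + 1
    n_extra = sum(c - 1 for c in per_gene.values())
    n_eff = n_genes_total + n_extra
    pvals = np.array([pk.adj_p for pk in peaks])
    order = np.argsort(pvals, kind="stable")
    q = np.empty(len(pvals))
    running = np.inf
    for rank in range(len(pvals), 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n_eff / rank)
        q[i] = running
    out = []
    for pk, qv in zip(peaks, q):
        pk.q_value = float(min(qv, 1.0))
        if pk.q_value <= fdr_threshold:
            out.append(pk)
    return out


def _distinct(a: EqtlPeak, b: EqtlPeak, min_dist: float) -> bool:
    far = a.chrom != b.chrom or abs(a.pos_bp - b.pos_bp) >= min_dist
    a_in_b = a.chrom == b.chrom and b.ci_lo_bp <= a.pos_bp <= b.ci_hi_bp
    b_in_a = a.chrom == b.chrom and a.ci_lo_bp <= b.pos_bp <= a.ci_hi_bp
    return far and not (a_in_b or b_in_a)


def merge_peaks(peaks: list[EqtlPeak], min_dist: float = 25e6) -> list[EqtlPeak]:
    """Collapse same-gene peaks that do not qualify as distinct eQTL.

    Peaks >= 25 Mbp apart (or on different chromosomes) whose positions
    do not lie within each other's support intervals are distinct; of a
    non-distinct group, the peak with the shortest support interval is
    kept, ties broken by the higher LOD.
    """
    out: list[EqtlPeak] = []
    by_gene: dict[str, list[EqtlPeak]] = {}
    for pk in peaks:
        by_gene.setdefault(pk.gene_id, []).append(pk)
    for gene, group in by_gene.items():
        clusters: list[list[EqtlPeak]] = []
        for pk in group:
            home = None
            for cl in clusters:
                if any(not _distinct(pk, other, min_dist) for other in cl):
                    home = cl
                    break
            if home is None:
                clusters.append([pk])
            else:
                home.append(pk)
        for cl in clusters:
            best = min(cl, key=lambda p: (p.ci_hi_bp - p.ci_lo_bp, -p.lod))
            out.append(best)
    return out


def classify_cis_trans(peak: EqtlPeak, gene_chrom: str, gene_start: float,
                       cis_window: float = 2.5e6) -> str:
    """cis if < 2.5 Mbp from the gene start on the same chromosome or if
    the support interval covers the gene start; trans otherwise."""
    if peak.chrom == gene_chrom:
        if abs(peak.pos_bp - gene_start) < cis_window:
            return "cis"
        if peak.ci_lo_bp <= gene_start <= peak.ci_hi_bp:
            return "cis"
    return "trans"


# ---------------------------------------------------------------------------
# per-gene driver

def scan_gene(y: np.ndarray, grid: ProbGrid, gene_id: str, n_perm: int = 1000,
              alpha: float = 0.001, seed: int = 0) -> list[EqtlPeak]:
    """Scan one gene: LOD curve, permutation threshold, significant peaks
    with adjusted p-values."""
    lod = hk_scan(y, grid)[0]
    max_lods = permutation_max_lods(y, grid, n_perm, seed)
    thr = permutation_threshold(max_lods, alpha)
    peaks = find_peaks(lod, grid, thr, gene_id=gene_id)
    for pk in peaks:
        pk.adj_p = permutation_pvalue(pk.lod, max_lods)
    return peaks


def peaks_to_frame(peaks: list[EqtlPeak]) -> pd.DataFrame:
    return pd.DataFrame([{
        "gene_id": p.gene_id, "chrom": p.chrom, "pos_bp": p.pos_bp,
        "pos_cm": p.pos_cm, "lod": p.lod, "ci_lo_bp": p.ci_lo_bp,
        "ci_hi_bp": p.ci_hi_bp, "adj_p": p.adj_p, "q_value": p.q_value,
        "regulation": p.regulation, "dataset": p.dataset,
    } for p in peaks])
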