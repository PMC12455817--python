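"""Count normalization, gene-activity calls and SPE pattern classification.

Normalization has two parts: a gene-specific factor from a penalized
additive smoother of log mean count on GC fraction and log gene length
(the inverse of the smoother's predictive count), and a sample-wise TMM
(trimmed mean of M-values) scale factor.  Activity is thresholded at the
0.25 quantile of the nonzero per-genotype mean normalized expression
levels, strictly: a gene is active in a genotype iff its mean normalized
count exceeds the threshold.

A single-parent-expression (SPE) gene is active in the hybrid and in
exactly one of its two parents.  In a backcross hybrid the pattern (1-8)
records the cross, the gene's zygosity in the hybrid, and which parent is
active:

========  ==========  =========  =============
pattern   cross       zygosity   active parent
========  ==========  =========  =============
1         B73 x RIL   HET        maternal (B73)
2         B73 x RIL   HET        paternal (RIL)
3         B73 x RIL   HOM_B73    maternal (B73)
4         B73 x RIL   HOM_B73    paternal (RIL)
5         Mo17 x RIL  HET        maternal (Mo17)
6         Mo17 x RIL  HET        paternal (RIL)
7         Mo17 x RIL  HOM_MO17   maternal (Mo17)
8         Mo17 x RIL  HOM_MO17   paternal (RIL)
========  ==========  =========  =============
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CLASS_BC_A, CLASS_BC_B, CLASS_F1
from .genotype_regions import ZYG_HET, ZYG_HOM_A, ZYG_HOM_B, ZYG_MASKED, ZYG_NO_INFO

NON_SPE = "NON_SPE"
UNCLASSIFIED = "UNCLASSIFIED"
REF_SPE_MATERNAL = "REF_SPE_MATERNAL"
REF_SPE_PATERNAL = "REF_SPE_PATERNAL"

_PATTERN_OF = {
    (CLASS_BC_A, ZYG_HET, "maternal"): 1,
    (CLASS_BC_A, ZYG_HET, "paternal"): 2,
    (CLASS_BC_A, ZYG_HOM_A, "maternal"): 3,
    (CLASS_BC_A, ZYG_HOM_A, "paternal"): 4,
    (CLASS_BC_B, ZYG_HET, "maternal"): 5,
    (CLASS_BC_B, ZYG_HET, "paternal"): 6,
    (CLASS_BC_B, ZYG_HOM_B, "maternal"): 7,
    (CLASS_BC_B, ZYG_HOM_B, "paternal"): 8,
}


# ---------------------------------------------------------------------------
# gene-specific normalization (GC / length artifact smoother)

def fit_artifact_smoother(mean_counts: np.ndarray, gc: np.ndarray,
                          log_length: np.ndarray, df: int = 8) -> np.ndarray:
    """Predictive count per gene from a penalized additive fit.

    Fits log(mean count + 0.5) on B-spline bases in GC fraction and log
    length with the smoothing parameter chosen by generalized
    cross-validation, and returns the back-transformed (strictly
    positive) predictive counts.  Falls back to the grand mean when a
    covariate is constant.
    """
    mean_counts = np.asarray(mean_counts, dtype=float)
    if len(mean_counts) < 50 or (mean_counts > 0).sum() < 50:
        raise ValueError("need at least 50 genes with nonzero counts")
    z = np.log(mean_counts + 0.5)
    covars = []
    for name, x in (("gc", np.asarray(gc, float)), ("log_length", np.asarray(log_length, float))):
        if np.ptp(x) == 0:
            warnings.warn(f"constant covariate {name}; dropped from smoother")
        else:
            covars.append(x)
    if not covars:
        return np.full(len(z), float(np.exp(z.mean()) - 0.5)).clip(min=1e-8)

    from statsmodels.gam.api import BSplines, GLMGam

    exog = np.column_stack(covars)
    # cap basis size by the support of the covariates
    df_eff = int(min(df, max(4, min(len(np.unique(c)) for c in covars))))
    bs = BSplines(exog, df=[df_eff] * exog.shape[1], degree=[3] * exog.shape[1])
    n = len(z)
    intercept = np.ones((n, 1))  # the spline basis excludes the constant
    best_fit, best_gcv = None, np.inf
    for a in np.logspace(-3, 5, 9):
        try:
            fit = GLMGam(z, exog=intercept, smoother=bs,
                         alpha=[a] * exog.shape[1]).fit()
            tr = float(fit.hat_matrix_trace)
        except Exception:
            continue
        resid = z - fit.fittedvalues
        gcv = n * float(resid @ resid) / (n - min(tr, n - 1)) ** 2
        if gcv < best_gcv:
            best_gcv, best_fit = gcv, fit
    if best_fit is None:
        return np.full(n, float(np.exp(z.mean()))).clip(min=1e-8)
    pred = np.exp(best_fit.fittedvalues) - 0.5
    return np.clip(pred, 1e-8, None)


def gene_norm_factors(predictive_counts: np.ndarray) -> np.ndarray:
    """Gene-specific multiplicative factor: the inverse predictive count."""
    pred = np.asarray(predictive_counts, dtype=float)
    if (pred <= 0).any():
        raise ValueError("predictive counts must be positive")
    return 1.0 / pred


# ---------------------------------------------------------------------------
# TMM sample factors

def tmm_factors(raw: pd.DataFrame, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scale factor per sample.

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples.  Per sample, log2 ratios (M) and
    average abundances (A) against the reference are computed over genes
    expressed in both; the most extreme 30% of M and 5% of A (split
    between both tails) are trimmed, and the factor is the
    precision-weighted mean of the surviving M values.  Factors are
    returned as count multipliers, renormalized to geometric mean 1, so
    that a library with doubled depth gets half the factor of its twin.
    """
    counts = raw.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = raw.columns[lib == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    with np.errstate(divide="ignore", invalid="ignore"):
        uq = np.array([np.quantile(c[c > 0], 0.75) / l if (c > 0).any() else 0.0
                       for c, l in zip(counts.T, lib)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, nr = counts[:, ref], lib[ref]
    log2_factor = np.empty(counts.shape[1])
    for s in range(counts.shape[1]):
        ys, ns = counts[:, s], lib[s]
        both = (ys > 0) & (yr > 0)
        if not both.any():
            raise ValueError(f"no genes expressed in both sample {raw.columns[s]!r} "
                             "and the TMM reference")
        ps, pr = ys[both] / ns, yr[both] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        w = (ns - ys[both]) / (ns * ys[both]) + (nr - yr[both]) / (nr * yr[both])
        lo_m, hi_m = np.quantile(m, [logratio_trim / 2, 1 - logratio_trim / 2])
        lo_a, hi_a = np.quantile(a, [abs_trim / 2, 1 - abs_trim / 2])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        log2_factor[s] = np.average(m[keep], weights=1.0 / w[keep])
    # effective depth = library size x composition bias; the count
    # multiplier is its inverse, centred at geometric mean 1
    log_eff = np.log2(lib) + log2_factor
    log_mult = -(log_eff - log_eff.mean())
    return pd.Series(2.0 ** log_mult, index=raw.columns, name="tmm_factor")


def normalize(raw: pd.DataFrame, gene_factors: np.ndarray,
              sample_factors: pd.Series) -> pd.DataFrame:
    """Normalized count = raw x gene factor x sample factor."""
    return raw.mul(np.asarray(gene_factors), axis=0).mul(sample_factors, axis=1)


def genotype_means(normalized: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean normalized count per gene x genotype over replicate samples."""
    geno_of = samples.set_index("sample")["genotype_id"]
    return normalized.T.groupby(geno_of).mean().T


# ---------------------------------------------------------------------------
# activity

def activity_threshold(means: pd.DataFrame, quantile: float = 0.25) -> float:
    """Threshold = empirical quantile (linear interpolation) of the pooled
    nonzero genotype-mean expression levels."""
    vals = means.to_numpy().ravel()
    nz = vals[vals > 0]
    if nz.size == 0:
        raise ValueError("no nonzero genotype means; cannot set a threshold")
    return float(np.quantile(nz, quantile))


def call_activity(means: pd.DataFrame, tau: float) -> pd.DataFrame:
    """Boolean activity matrix: active iff mean strictly exceeds tau."""
    return means > tau


@dataclass
class ActivityTable:
    means: pd.DataFrame       # gene x genotype mean normalized counts
    active: pd.DataFrame      # gene x genotype boolean
    tau: float


def make_activity_table(normalized: pd.DataFrame, samples: pd.DataFrame,
                        quantile: float = 0.25) -> ActivityTable:
    means = genotype_means(normalized, samples)
    tau = activity_threshold(means, quantile)
    return ActivityTable(means=means, active=call_activity(means, tau), tau=tau)


# ---------------------------------------------------------------------------
# SPE classification

def classify_spe(hybrid: str, maternal: str, paternal: str, cross: str,
                 activity: pd.DataFrame, zygosity: pd.Series | None = None,
                 ) -> pd.DataFrame:
    """Per-gene SPE assignment for one hybrid/parent trio.

    ``cross`` is the hybrid class; for the reference F1 cross, zygosity
    is uniformly heterozygous and patterns collapse to maternal/paternal
    reference SPE.  Genes whose zygosity is masked or unknown but that
    show SPE are reported UNCLASSIFIED.
    """
    for g in (hybrid, maternal, paternal):
        if g not in activity.columns:
            raise KeyError(f"activity unknown for genotype {g!r}")
    act_h = activity[hybrid]
    act_m = activity[maternal]
    act_p = activity[paternal]
    spe = act_h & (act_m ^ act_p)
    which = np.where(act_m, "maternal", "paternal")
    patterns = np.full(len(activity), NON_SPE, dtype=object)
    if cross == CLASS_F1:
        patterns[spe.to_numpy()] = np.where(
            which[spe.to_numpy()] == "maternal", REF_SPE_MATERNAL, REF_SPE_PATERNAL)
    else:
        if zygosity is None:
            raise ValueError("zygosity required for backcross hybrids")
        zyg = zygosity.reindex(activity.index).to_numpy()
        for i in np.flatnonzero(spe.to_numpy()):
            key = (cross, zyg[i], which[i])
            patterns[i] = _PATTERN_OF.get(key, UNCLASSIFIED)
    out = pd.DataFrame({
        "hybrid_id": hybrid,
        "gene_id": activity.index,
        "pattern": patterns,
        "zygosity": zygosity.reindex(activity.index).to_numpy()
        if zygosity is not None else ZYG_HET,
        "active_parent": np.where(spe, which, ""),
    })
    return out


def summarize_spe(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-hybrid SPE counts by pattern plus the total."""
    spe = assignments[~assignments["pattern"].isin([NON_SPE])]
    counts = (spe.groupby(["hybrid_id", "pattern"]).size()
              .unstack(fill_value=0))
    counts = counts.reindex(assignments["hybrid_id"].unique(), fill_value=0)
    counts["total"] = counts.sum(axis=1)
    return counts


def spe_counts_matrix(assignments: pd.DataFrame, patterns: list) -> pd.DataFrame:
    """Hybrid x pattern count matrix over the given pattern labels (absent
    patterns filled with zero) — the SPE covariates of the heterosis model."""
    spe = assignments[assignments["pattern"].isin(patterns)]
    counts = (spe.groupby(["hybrid_id", "pattern"]).size().unstack(fill_value=0))
    counts = counts.reindex(columns=patterns, fill_value=0)
    counts = counts.reindex(assignments["hybrid_id"].unique(), fill_value=0)
    return counts


# ---------------------------------------------------------------------------
# pattern-count test (Gaussian mixed model, diagonal pattern variances)

def pattern_count_test(counts: pd.DataFrame) -> pd.DataFrame:
    """Wald contrasts between SPE patterns from a heteroscedastic mixed model.

    Fits count ~ pattern (fixed) + hybrid (random intercept) with a
    separate residual variance per pattern, then tests all pairwise
    pattern contrasts.  ``counts`` is a hybrid x pattern matrix.
    """
    from .mixedlm import fit_reml

    if counts.shape[0] < 2:
        raise ValueError("need at least 2 hybrids")
    long = counts.stack().rename("count").reset_index()
    long.columns = ["hybrid", "pattern", "count"]
    patterns = list(counts.columns)
    hybrids = {h: i for i, h in enumerate(counts.index)}
    pat_idx = {p: i for i, p in enumerate(patterns)}
    X = np.zeros((len(long), len(patterns)))
    X[np.arange(len(long)), long["pattern"].map(pat_idx)] = 1.0
    res = fit_reml(
        long["count"].to_numpy(dtype=float), X,
        random_factors={"hybrid": long["hybrid"].map(hybrids).to_numpy()},
        resid_groups=long["pattern"].map(pat_idx).to_numpy(),
        beta_names=[str(p) for p in patterns])
    rows = []
    for i in range(len(patterns)):
        for j in range(i + 1, len(patterns)):
            c = np.zeros(len(patterns))
            c[i], c[j] = 1.0, -1.0
            est, se, p = res.wald_contrast(c)
            rows.append((patterns[i], patterns[j], est, se, p))
    return pd.DataFrame(rows, columns=["pattern_a", "pattern_b",
                                       "difference", "se", "p_value"])


# ---------------------------------------------------------------------------
# active-gene summary

def active_gene_summary(activity: pd.DataFrame,
                        het_fractions: pd.Series | None = None) -> dict:
    """Per-genotype active-gene counts and, when heterozygosity fractions
    are supplied, their Pearson correlation with heterozygosity."""
    counts = activity.sum(axis=0)
    out = {"active_counts": counts}
    if het_fractions is not None:
        common = counts.index.intersection(het_fractions.index)
        x = het_fractions.loc[common].to_numpy(dtype=float)
        y = counts.loc[common].to_numpy(dtype=float)
        if len(common) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out["pearson_r"] = float("nan")
            out["pearson_p"] = float("nan")
        else:
            r, p = stats.pearsonr(x, y)
            out["pearson_r"] = float(r)
            out["pearson_p"] = float(p)
    return out
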