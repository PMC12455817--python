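"""Expression–trait association (TWAS-lite), TSG nomination, and synteny
enrichment of cis vs trans regulation.

The association model is a declared simplification of multi-locus mixed
model scans: per gene, a linear model of the genotype-level trait mean on
the gene's rescaled expression adjusting for the first three expression
principal components, Bonferroni-corrected at family-wise 0.05 over the
genes tested.  Genes must be active in at least 5% of the genotypes of
the population to enter the scan; expression is rescaled to [0, 2] per
population.  Kinship adjustment is deliberately omitted, so hit lists
are not expected to match a kinship-aware scan.

A TWAS hit showing SPE complementation in more than 10 hybrids is a
TSG (TWAS + SPE gene); the activity-based trait difference uses an
equal-variance two-sample t-test independent of the association scan.
Synteny enrichment contrasts cis- against trans-regulated genes with a
two-sided Fisher exact test on the 2x2 regulation x synteny table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# TWAS-lite

def rescale_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene rescaling of expression to the range [0, 2]."""
    lo = expr.min(axis=1)
    rng = expr.max(axis=1) - lo
    rng = rng.replace(0, np.nan)
    out = expr.sub(lo, axis=0).div(rng, axis=0) * 2.0
    return out.fillna(0.0)


def expression_pcs(expr_rescaled: pd.DataFrame, n_pcs: int = 3) -> np.ndarray:
    """First principal components of the genotype x gene expression matrix."""
    from sklearn.decomposition import PCA

    mat = expr_rescaled.to_numpy().T  # genotypes x genes
    n_pcs = min(n_pcs, mat.shape[0] - 1, mat.shape[1])
    return PCA(n_components=n_pcs).fit_transform(mat)


def twas_scan(expr: pd.DataFrame, trait_means: pd.Series,
              active: pd.DataFrame, min_active_fraction: float = 0.05,
              n_pcs: int = 3, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene association of a trait with expression.

    ``expr`` and ``active`` are gene x genotype for one population;
    ``trait_means`` is indexed by genotype.  Returns one row per tested
    gene with the expression slope, p-value and Bonferroni call (the
    correction count equals the number of genes passing the activity
    filter, not all genes).
    """
    genotypes = [g for g in expr.columns if g in trait_means.index]
    if len(genotypes) < 4:
        raise ValueError("need at least 4 genotypes with trait values")
    expr = expr[genotypes]
    act_frac = active[genotypes].mean(axis=1)
    tested = expr.loc[act_frac >= min_active_fraction]
    if tested.empty:
        return pd.DataFrame(columns=["gene_id", "slope", "p_value",
                                     "p_bonferroni", "passes_bonferroni"])
    scaled = rescale_expression(tested)
    pcs = expression_pcs(scaled, n_pcs)
    y = trait_means.loc[genotypes].to_numpy(dtype=float)
    n = len(genotypes)
    base = np.column_stack([np.ones(n), pcs])
    E = scaled.to_numpy().T                      # genotypes x genes
    # per-gene OLS t-test on the expression column, vectorized via FWL:
    # residualize y and each expression column on [1, PCs]
    coef_y, *_ = np.linalg.lstsq(base, y, rcond=None)
    ry = y - base @ coef_y
    coef_e, *_ = np.linalg.lstsq(base, E, rcond=None)
    RE = E - base @ coef_e
    see = (RE ** 2).sum(axis=0)
    dof = n - base.shape[1] - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(see > 0, RE.T @ ry / np.where(see > 0, see, 1.0), 0.0)
        rss = (ry ** 2).sum() - slope ** 2 * see
        se = np.sqrt(np.maximum(rss, 0.0) / max(dof, 1) / np.where(see > 0, see, np.inf))
        tstat = np.where(se > 0, slope / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(tstat), df=max(dof, 1))
    pvals[see == 0] = 1.0
    n_tests = len(tested)
    out = pd.DataFrame({
        "gene_id": tested.index,
        "slope": slope,
        "p_value": pvals,
        "p_bonferroni": np.minimum(pvals * n_tests, 1.0),
        "passes_bonferroni": pvals * n_tests <= alpha,
        "n_tests": n_tests,
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# TSG nomination and activity-based trait test

def identify_tsg(twas_hits: pd.DataFrame, assignments: pd.DataFrame,
                 min_hybrids: int = 10) -> pd.DataFrame:
    """TWAS hits with SPE complementation in more than ``min_hybrids``
    hybrids; the dominant SPE pattern per gene is recorded."""
    hits = twas_hits[twas_hits["passes_bonferroni"]]
    spe = assignments[~assignments["pattern"].isin(["NON_SPE"])]
    per_gene = spe.groupby("gene_id")["hybrid_id"].nunique()
    dominant = (spe.groupby(["gene_id", "pattern"]).size()
                .groupby("gene_id").idxmax().map(lambda t: t[1]))
    rows = []
    for _, h in hits.iterrows():
        n_spe = int(per_gene.get(h["gene_id"], 0))
        if n_spe > min_hybrids:
            rows.append((h["gene_id"], n_spe, dominant.get(h["gene_id"], ""),
                         h["p_value"]))
    return pd.DataFrame(rows, columns=["gene_id", "n_hybrids_with_spe",
                                       "dominant_pattern", "twas_p"])


def activity_trait_test(trait_values: pd.Series, gene_active: pd.Series
                        ) -> tuple[float, float]:
    """Equal-variance two-sample t-test of the trait between hybrids with
    the gene on vs off.  Returns (t, p)."""
    common = trait_values.index.intersection(gene_active.index)
    on = trait_values.loc[common][gene_active.loc[common].astype(bool)]
    off = trait_values.loc[common][~gene_active.loc[common].astype(bool)]
    if len(on) < 2 or len(off) < 2:
        raise ValueError("need >= 2 hybrids in both activity groups")
    t, p = stats.ttest_ind(on, off, equal_var=True)
    if np.isnan(p):  # zero pooled variance with equal means
        return 0.0, 1.0
    return float(t), float(p)


# ---------------------------------------------------------------------------
# synteny enrichment

def synteny_enrichment(gene_table: pd.DataFrame) -> dict:
    """Fisher exact test of synteny between cis- and trans-regulated genes.

    ``gene_table`` needs boolean column 'syntenic' and column 'regulation'
    in {cis, trans}.  Returns the 2x2 table, odds ratio and two-sided p.
    """
    cis = gene_table[gene_table["regulation"] == "cis"]
    trans = gene_table[gene_table["regulation"] == "trans"]
    table = np.array([
        [int(cis["syntenic"].sum()), int((~cis["syntenic"].astype(bool)).sum())],
        [int(trans["syntenic"].sum()), int((~trans["syntenic"].astype(bool)).sum())],
    ])
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return {"table": table, "odds_ratio": float(odds), "p_value": float(p)}
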