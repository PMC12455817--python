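"""Heterosis estimation and variance decomposition against SPE-gene counts.

Three REML mixed models are involved, all fitted on plant-level data with
the nested design random effects (batch, system, triplet, row):

* a baseline model with fixed genotype and block effects, yielding
  adjusted genotype means from which mid-parent (MPH) and better-parent
  (BPH) heterosis percentages are computed;
* a "full" regression model in which each observation carries parental
  covariates (1 for an observation on that parent, 0.5/0.5 for a hybrid's
  two parents under MPH, 1/0 at the better parent under BPH), fixed
  slopes gamma_1..gamma_4 on the per-pattern SPE-gene counts (0 for
  parents), a fixed hybrid intercept phi on the hybrid dummy z, and a
  random hybrid deviation g_i z_i switched off for parents; and
* a "null" model identical except for the SPE-count covariates.

The hybrid-deviation variance of the full model (sigma2_Het, heterotic
variance left unexplained by SPE counts) and of the null model (sigma2_G,
total heterotic variance) combine into the explained-variance coefficient

    p_Het = 1 - sigma2_Het / sigma2_G,

which can be negative when the null model happens to place less variance
on the hybrid deviations than the full model; a negative value does not
indicate a negative influence of SPE on heterosis.

With ``collapse="rows"`` the models are fitted on row means: every
covariate is constant within a row, so for balanced rows this leaves all
non-residual variance components (and hence p_Het) unchanged while
shrinking the covariance matrix by the number of plants per row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mixedlm import MixedModelResult, fit_reml

#: traits analyzed on the square-root scale (offset 0.5 added first)
SQRT_TRAITS = frozenset({"root_tips", "total_root_length", "total_root_volume"})

DESIGN_FACTORS = ("batch", "system", "triplet", "row")


# ---------------------------------------------------------------------------
# trait transformation

def transform_trait(values: np.ndarray, trait: str) -> np.ndarray:
    """sqrt(y + 0.5) for the root-count/size traits, identity otherwise."""
    values = np.asarray(values, dtype=float)
    if trait in SQRT_TRAITS:
        return np.sqrt(values + 0.5)
    return values.copy()


def inverse_transform_trait(values: np.ndarray, trait: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if trait in SQRT_TRAITS:
        return values ** 2 - 0.5
    return values.copy()


# ---------------------------------------------------------------------------
# shared design helpers

def _collapse_rows(records: pd.DataFrame, value_col: str) -> pd.DataFrame:
    keys = ["block", "batch", "system", "triplet", "row", "genotype_id", "klass", "ril_id"]
    keys = [k for k in keys if k in records.columns]
    n_per = records.groupby("row")["plant"].count() if "plant" in records else None
    if n_per is not None and n_per.nunique() > 1:
        warnings.warn("unequal plants per row; row means are heteroscedastic")
    return records.groupby(keys, as_index=False, sort=False)[value_col].mean()


def _codes(series: pd.Series) -> np.ndarray:
    return pd.Categorical(series).codes.astype(np.int64)


def _design_randoms(records: pd.DataFrame, include_row: bool = True) -> dict[str, np.ndarray]:
    factors = DESIGN_FACTORS if include_row else DESIGN_FACTORS[:-1]
    return {f: _codes(records[f]) for f in factors if f in records.columns}


# ---------------------------------------------------------------------------
# baseline model (adjusted genotype means)

@dataclass
class BaselineFit:
    adjusted_means: pd.Series
    variance_components: dict[str, float]
    result: MixedModelResult
    unreplicated: list[str] = field(default_factory=list)


def fit_baseline_model(records: pd.DataFrame, value_col: str = "value",
                       collapse: str | None = "rows") -> BaselineFit:
    """REML fit of trait ~ genotype + block with nested design randoms.

    Returns genotype adjusted means (genotype effect plus the average
    block effect) and the design variance components.
    """
    data = _collapse_rows(records, value_col) if collapse == "rows" else records
    genos = pd.Categorical(data["genotype_id"])
    blocks = sorted(data["block"].unique())
    if len(blocks) < 2:
        warnings.warn("single block: block effect not estimable, dropped")
    n = len(data)
    G = np.zeros((n, len(genos.categories)))
    G[np.arange(n), genos.codes] = 1.0
    cols = list(genos.categories)
    B_list = []
    for b in blocks[1:]:
        B_list.append((data["block"] == b).to_numpy(dtype=float))
        cols.append(f"block[{b}]")
    X = np.column_stack([G] + B_list) if B_list else G
    res = fit_reml(data[value_col].to_numpy(dtype=float), X,
                   _design_randoms(data, include_row=collapse != "rows"),
                   beta_names=cols)
    n_geno = len(genos.categories)
    block_effects = np.concatenate([[0.0], res.beta[n_geno:]])
    adj = pd.Series(res.beta[:n_geno] + block_effects.mean(),
                    index=list(genos.categories), name="adjusted_mean")
    counts = data["genotype_id"].value_counts()
    unrep = counts[counts < 2].index.tolist()
    if unrep:
        warnings.warn(f"{len(unrep)} genotypes unreplicated; means have inflated SE")
    return BaselineFit(adjusted_means=adj,
                       variance_components=res.variance_components,
                       result=res, unreplicated=unrep)


# ---------------------------------------------------------------------------
# heterosis percentages

def compute_heterosis(means: pd.Series, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Per-hybrid MPH% and BPH% from genotype means.

    MPH% = 100 (H - MP) / MP with MP the mid-parent mean; BPH% relates to
    the better (larger-mean) parent instead.
    """
    rows = []
    for hybrid, mother, father in pedigree[["hybrid", "mother", "father"]].itertuples(index=False):
        h, p1, p2 = means[hybrid], means[mother], means[father]
        mp = 0.5 * (p1 + p2)
        bp = max(p1, p2)
        rows.append((hybrid,
                     100.0 * (h - mp) / mp if mp != 0 else np.nan,
                     100.0 * (h - bp) / bp if bp != 0 else np.nan))
    return pd.DataFrame(rows, columns=["hybrid", "mph_pct", "bph_pct"]).set_index("hybrid")


# ---------------------------------------------------------------------------
# covariate construction for models 2/3

@dataclass
class HeterosisCovariates:
    X: np.ndarray
    names: list[str]
    parent_cols: list[str]
    spe_cols: list[str]
    z_col: str
    random_factors: dict[str, np.ndarray]
    data: pd.DataFrame
    value_col: str


def build_heterosis_covariates(records: pd.DataFrame, pedigree: pd.DataFrame,
                               spe_counts: pd.DataFrame, mode: str = "MPH",
                               parent_means: pd.Series | None = None,
                               shared_slope: bool = False,
                               value_col: str = "value",
                               collapse: str | None = "rows",
                               ) -> HeterosisCovariates:
    """Observation-level design for the full/null heterosis models.

    ``spe_counts`` is hybrid x pattern (the regression covariates); under
    BPH, ``parent_means`` decides which parent of each hybrid is the
    better one.  The intercept is removed and block enters as fixed
    effects for blocks 2..J.
    """
    mode = mode.upper()
    if mode not in ("MPH", "BPH"):
        raise ValueError("mode must be 'MPH' or 'BPH'")
    if mode == "BPH" and parent_means is None:
        raise ValueError("BPH covariates need parent means to pick the better parent")
    data = _collapse_rows(records, value_col) if collapse == "rows" else records.copy()
    ped = pedigree.set_index("hybrid")
    hybrids = [h for h in data["genotype_id"].unique() if h in ped.index]
    parents_of = {}
    for h in hybrids:
        mo, fa = ped.loc[h, ["mother", "father"]]
        if pd.isna(mo) or pd.isna(fa):
            raise ValueError(f"hybrid {h!r} has unknown parentage")
        parents_of[h] = (mo, fa)
    parent_set = sorted({p for pair in parents_of.values() for p in pair}
                        | set(data.loc[~data["genotype_id"].isin(hybrids), "genotype_id"]))
    missing = [h for h in hybrids if h not in spe_counts.index]
    if missing:
        raise ValueError(f"SPE counts missing for hybrids {missing[:5]}")

    n = len(data)
    p_idx = {p: i for i, p in enumerate(parent_set)}
    Xp = np.zeros((n, len(parent_set)))
    z = np.zeros(n)
    spe_names = [f"spe[{c}]" for c in spe_counts.columns] if not shared_slope else ["spe[total]"]
    S = np.zeros((n, len(spe_names)))
    hyb_labels = np.full(n, -1, dtype=np.int64)
    hyb_idx = {h: i for i, h in enumerate(hybrids)}
    for i, geno in enumerate(data["genotype_id"]):
        if geno in parents_of:
            mo, fa = parents_of[geno]
            if mode == "MPH":
                Xp[i, p_idx[mo]] = 0.5
                Xp[i, p_idx[fa]] = 0.5
            else:
                better = mo if parent_means[mo] >= parent_means[fa] else fa
                Xp[i, p_idx[better]] = 1.0
            z[i] = 1.0
            s = spe_counts.loc[geno].to_numpy(dtype=float)
            S[i] = s.sum() if shared_slope else s
            hyb_labels[i] = hyb_idx[geno]
        elif geno in p_idx:
            Xp[i, p_idx[geno]] = 1.0
        else:
            raise ValueError(f"genotype {geno!r} is neither hybrid nor parent")
    blocks = sorted(data["block"].unique())
    B_list, b_names = [], []
    for b in blocks[1:]:
        B_list.append((data["block"] == b).to_numpy(dtype=float))
        b_names.append(f"block[{b}]")
    X = np.column_stack([Xp] + B_list + [S, z[:, None]])
    names = list(parent_set) + b_names + spe_names + ["z"]
    randoms = _design_randoms(data, include_row=collapse != "rows")
    randoms["hybrid"] = hyb_labels
    return HeterosisCovariates(X=X, names=names, parent_cols=list(parent_set),
                               spe_cols=spe_names, z_col="z",
                               random_factors=randoms, data=data,
                               value_col=value_col)


# ---------------------------------------------------------------------------
# full and null models

@dataclass
class HeterosisModelFit:
    sigma2_hybrid: float
    phi: float
    gammas: pd.Series
    betas: pd.Series
    variance_components: dict[str, float]
    result: MixedModelResult


def _fit(cov: HeterosisCovariates, drop_spe: bool,
         theta0: np.ndarray | None = None) -> HeterosisModelFit:
    keep = [j for j, nm in enumerate(cov.names)
            if not (drop_spe and nm in cov.spe_cols)]
    X = cov.X[:, keep]
    names = [cov.names[j] for j in keep]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy import linalg as sla
        _, _, piv = sla.qr(X, pivoting=True, mode="economic")
        dropped = [names[j] for j in piv[rank:]]
        warnings.warn(f"dropping collinear covariates {dropped}; design rank {rank}")
        keep2 = sorted(piv[:rank])
        X, names = X[:, keep2], [names[j] for j in keep2]
    y = cov.data[cov.value_col].to_numpy(dtype=float)
    res = fit_reml(y, X, cov.random_factors, beta_names=names, theta0=theta0)
    beta = pd.Series(res.beta, index=names)
    gam = beta[beta.index.isin(cov.spe_cols)]
    return HeterosisModelFit(
        sigma2_hybrid=res.variance_components["hybrid"],
        phi=float(beta["z"]),
        gammas=gam,
        betas=beta[beta.index.isin(cov.parent_cols)],
        variance_components=res.variance_components,
        result=res)


def fit_full_model(cov: HeterosisCovariates,
                   theta0: np.ndarray | None = None) -> HeterosisModelFit:
    """Model with SPE-count slopes; its hybrid variance is sigma2_Het."""
    if len(set(cov.random_factors["hybrid"]) - {-1}) < 10:
        warnings.warn("fewer than 10 hybrids; SPE slopes weakly identified")
    return _fit(cov, drop_spe=False, theta0=theta0)


def fit_null_model(cov: HeterosisCovariates,
                   theta0: np.ndarray | None = None) -> HeterosisModelFit:
    """Model without SPE-count slopes; its hybrid variance is sigma2_G."""
    return _fit(cov, drop_spe=True, theta0=theta0)


def compute_p_het(sigma2_het: float, sigma2_g: float) -> float:
    """Explained fraction of heterotic variance, 1 - s2_Het / s2_G.

    May be negative; that indicates the null model outperformed the full
    model, not a negative influence of SPE on heterosis.
    """
    if sigma2_g <= 0:
        raise ValueError("sigma2_G must be > 0 for p_Het")
    if sigma2_het < 0:
        raise ValueError("variance components must be >= 0")
    return 1.0 - sigma2_het / sigma2_g


@dataclass
class VarianceDecomposition:
    sigma2_het: float
    sigma2_g: float
    p_het: float
    gammas: pd.Series
    phi: float
    full: HeterosisModelFit
    null: HeterosisModelFit


def p_het_analysis(records: pd.DataFrame, pedigree: pd.DataFrame,
                   spe_counts: pd.DataFrame, mode: str = "MPH",
                   parent_means: pd.Series | None = None,
                   shared_slope: bool = False, value_col: str = "value",
                   collapse: str | None = "rows") -> VarianceDecomposition:
    """Fit full and null heterosis models and derive p_Het."""
    cov = build_heterosis_covariates(records, pedigree, spe_counts, mode=mode,
                                     parent_means=parent_means,
                                     shared_slope=shared_slope,
                                     value_col=value_col, collapse=collapse)
    full = fit_full_model(cov)
    null = fit_null_model(cov, theta0=getattr(full.result, "theta", None))
    # p_Het is a ratio estimator: when the null model finds practically no
    # hybrid variance there is no heterotic variance to decompose and the
    # coefficient is undefined, not a huge negative number
    total_var = sum(null.result.variance_components.values())
    if null.sigma2_hybrid > 1e-3 * total_var:
        p = compute_p_het(full.sigma2_hybrid, null.sigma2_hybrid)
    else:
        warnings.warn("null-model hybrid variance is negligible; "
                      "p_Het undefined")
        p = float("nan")
    return VarianceDecomposition(sigma2_het=full.sigma2_hybrid,
                                 sigma2_g=null.sigma2_hybrid, p_het=p,
                                 gammas=full.gammas, phi=full.phi,
                                 full=full, null=null)
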