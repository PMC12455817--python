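"""Ground-truth recovery experiments on the synthetic cross.

These are the package's calibration studies: each function simulates data
with known truth, runs the corresponding analysis stage, and measures how
well the truth is recovered.  They back both the test suite and the
reproduction script, so the problem sizes here are the sizes those checks
run at.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd

from . import eqtl_mapping as eqm
from . import expression_spe as es
from . import genotype_regions as gr
from . import heterosis_model as hm
from . import synthetic_data as sd
from .io import (CLASS_BC_A, CLASS_BC_B, CLASS_F1, CLASS_FOUNDER_A,
                 CLASS_FOUNDER_B, CLASS_RIL, MASKED_THIRD, ORIGIN_A, ORIGIN_B,
                 ORIGIN_THIRD)


# ---------------------------------------------------------------------------
# region-classification recovery

def region_recovery_experiment(seed: int = 0, n_rils: int = 30,
                               chrom_mbp: float = 40.0, n_chrom: int = 3,
                               marker_density: float = 20.0,
                               error_rate: float = 0.006,
                               fraction_contaminated: float = 0.3,
                               third_mbp: float = 3.0,
                               grid_step: int = 5_000) -> dict:
    """Classify simulated RIL genomes and score against the true mosaics.

    Returns the fraction of assigned (founder-classified) genome length
    carrying its true origin, the coverage of the non-third genome, and
    the masked-coverage of every injected third-origin segment >= 2 Mbp.
    """
    spec = sd.GenomeSpec(tuple((f"chr{i+1}", int(chrom_mbp * 1e6))
                               for i in range(n_chrom)),
                         marker_density=marker_density)
    markers = sd.build_marker_map(spec, seed)
    mosaics = sd.simulate_ril_population(spec, n_rils, 4, seed=seed + 1)
    mosaics = sd.inject_third_origin(mosaics, spec, fraction_contaminated,
                                     int(third_mbp * 1e6), seed=seed + 2)
    calls = sd.simulate_genotype_calls(mosaics, markers, missing_rate=0.02,
                                       error_rate=error_rate, seed=seed + 3)
    regs = gr.classify_regions(calls)
    n_correct = n_assigned = n_nonthird = 0
    third_masked_frac: list[float] = []
    origin_name = {0: ORIGIN_A, 1: ORIGIN_B}
    for mos in mosaics:
        reg = regs.for_ril(mos.ril_id)
        for chrom, length in spec.chromosomes:
            gridp = np.arange(1, length, grid_step)
            true_o = mos.origin_at(chrom, gridp)
            lab = np.full(len(gridp), "", dtype=object)
            for _, r in reg[reg["chrom"] == chrom].iterrows():
                lab[(gridp >= r["start"]) & (gridp <= r["end"])] = r["origin"]
            nonthird = true_o != 2
            assigned = np.isin(lab, [ORIGIN_A, ORIGIN_B])
            ok = np.array([origin_name.get(o) == l for o, l in zip(true_o, lab)])
            n_nonthird += int(nonthird.sum())
            n_assigned += int((nonthird & assigned).sum())
            n_correct += int((nonthird & assigned & ok).sum())
            for _, s in mos.segments[(mos.segments["chrom"] == chrom)
                                     & (mos.segments["origin"] == ORIGIN_THIRD)].iterrows():
                if s["end"] - s["start"] + 1 >= 2e6:
                    sel = (gridp >= s["start"]) & (gridp <= s["end"])
                    third_masked_frac.append(float((lab[sel] == MASKED_THIRD).mean()))
    return {
        "correct_of_assigned": n_correct / n_assigned,
        "coverage_of_nonthird": n_assigned / n_nonthird,
        "third_segments_checked": len(third_masked_frac),
        "third_masked_fractions": third_masked_frac,
        "all_third_masked": bool(third_masked_frac) and
                            min(third_masked_frac) > 0.5,
        "n_excluded_rils": len(regs.excluded_rils),
    }


# ---------------------------------------------------------------------------
# SPE oracle equivalence

def spe_oracle_experiment(seed: int = 0, n_rils: int = 10,
                          n_genes: int = 400) -> dict:
    """Compare pipeline SPE calls against exhaustive enumeration from the
    regulatory truth, with expression noise off (deterministic counts,
    no artifact, equal libraries) and true gene zygosity.

    The oracle enumerates, per hybrid and gene: active means the
    regulatory truth allows expression AND the gene's normalized baseline
    clears the activity threshold; SPE requires the hybrid plus exactly
    one parent active, and the pattern follows from the cross, the
    mosaic-derived zygosity and which parent is active.
    """
    spec = sd.GenomeSpec()
    mosaics = sd.simulate_ril_population(spec, n_rils, 4, seed=seed + 1)
    genes = sd.build_gene_table(spec, n_genes, seed=seed + 2)
    arch = sd.build_regulatory_architecture(genes, spec, seed=seed + 3,
                                            silenced_fraction=0.4)
    rows = [("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, "")]
    for m in mosaics:
        rows += [(m.ril_id, CLASS_RIL, m.ril_id),
                 (f"B73x{m.ril_id}", CLASS_BC_A, m.ril_id),
                 (f"MO17x{m.ril_id}", CLASS_BC_B, m.ril_id)]
    genotypes = pd.DataFrame(rows, columns=["genotype_id", "klass", "ril_id"])
    eset = sd.simulate_expression_counts(genes, arch, genotypes, mosaics,
                                         deterministic=True, seed=seed + 4)
    pred = es.fit_artifact_smoother(eset.counts.mean(axis=1).to_numpy(),
                                    genes["gc"].to_numpy(),
                                    np.log(genes["length"].to_numpy()))
    gene_f = es.gene_norm_factors(pred)
    tmm = es.tmm_factors(eset.counts)
    norm = es.normalize(eset.counts, gene_f, tmm)
    at = es.make_activity_table(norm, eset.samples)

    truth_act = eset.truth["activity"]          # genotype x gene, regulatory truth
    baseline = genes["baseline"].to_numpy()
    # oracle normalized level per genotype: with deterministic counts the
    # raw count IS baseline x truth activity, so the expected normalized
    # mean is baseline x gene factor x (mean TMM factor of the genotype's
    # replicates)
    tmm_mean = {g: float(np.mean([tmm[s] for s, gg in
                                  zip(eset.samples["sample"],
                                      eset.samples["genotype_id"]) if gg == g]))
                for g in truth_act.index}
    level = baseline * gene_f
    oracle_pattern_map = {
        (CLASS_BC_A, "HET", "maternal"): 1, (CLASS_BC_A, "HET", "paternal"): 2,
        (CLASS_BC_A, "HOM_B73", "maternal"): 3, (CLASS_BC_A, "HOM_B73", "paternal"): 4,
        (CLASS_BC_B, "HET", "maternal"): 5, (CLASS_BC_B, "HET", "paternal"): 6,
        (CLASS_BC_B, "HOM_MO17", "maternal"): 7, (CLASS_BC_B, "HOM_MO17", "paternal"): 8,
    }
    n_checked = n_mismatch = 0
    for mos in mosaics:
        # true zygosity from the mosaic origin at the gene start
        for cross, mat in ((CLASS_BC_A, "B73"), (CLASS_BC_B, "MO17")):
            hybrid = f"{'B73x' if cross == CLASS_BC_A else 'MO17x'}{mos.ril_id}"
            zyg_vals = []
            for chrom, grp in genes.groupby("chrom", sort=False):
                orig = mos.origin_at(chrom, grp["start"].to_numpy())
                for o in orig:
                    if o == 2:
                        zyg_vals.append("MASKED")
                    elif cross == CLASS_BC_A:
                        zyg_vals.append("HET" if o == 1 else "HOM_B73")
                    else:
                        zyg_vals.append("HET" if o == 0 else "HOM_MO17")
            zyg = pd.Series(zyg_vals, index=genes.sort_values(
                ["chrom", "start"], kind="stable")["gene_id"])
            zyg = zyg.reindex(genes["gene_id"])
            asg = es.classify_spe(hybrid, mat, mos.ril_id, cross, at.active, zyg)
            called = asg.set_index("gene_id")["pattern"]
            for gi, gid in enumerate(genes["gene_id"]):
                act = {g: truth_act.loc[g].iloc[gi]
                       and level[gi] * tmm_mean[g] > at.tau
                       for g in (hybrid, mat, mos.ril_id)}
                if act[hybrid] and (act[mat] ^ act[mos.ril_id]):
                    which = "maternal" if act[mat] else "paternal"
                    expect = oracle_pattern_map.get((cross, zyg.iloc[gi], which),
                                                    "UNCLASSIFIED")
                else:
                    expect = "NON_SPE"
                n_checked += 1
                if called.loc[gid] != expect:
                    n_mismatch += 1
    return {"n_checked": n_checked, "n_mismatch": n_mismatch,
            "agreement": 1.0 - n_mismatch / n_checked}


# ---------------------------------------------------------------------------
# p_Het parameter recovery

def _one_p_het_replicate(seed: int, target: float, n_hybrids: int,
                         sigma2_het: float, plants_per_row: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    design = sd.build_experimental_design(n_hybrids, seed=seed,
                                          plants_per_row=plants_per_row)
    ped = sd.pedigree_of(design)
    hybs = ped["hybrid"].tolist()
    mean_counts = np.array([400.0, 300.0, 250.0, 280.0])
    spe = pd.DataFrame(
        rng.negative_binomial(20, 20 / (20 + mean_counts), size=(len(hybs), 4)),
        index=hybs, columns=["s1", "s2", "s3", "s4"])
    pop_hybs = [h for h in hybs if h.startswith("B73xRIL")]
    gammas = sd.gamma_for_target_p_het(spe.loc[pop_hybs], sigma2_het, target)
    gm = sd.PhenotypeGenModel(gammas=gammas, sigma2_het=sigma2_het)
    tab, truth = sd.simulate_phenotypes(design, gm, spe, seed=seed + 50_000)
    recs = tab[tab["klass"].isin([CLASS_RIL, CLASS_FOUNDER_A, CLASS_BC_A])]
    vd = hm.p_het_analysis(recs, ped[ped["hybrid"].isin(pop_hybs)],
                           spe.loc[pop_hybs])
    return truth["p_het_B73xRIL"], vd.p_het


def p_het_recovery_experiment(targets: Sequence[float] = (0.0, 0.15, 0.3),
                              n_reps: int = 100, n_hybrids: int = 80,
                              sigma2_het: float = 0.2,
                              plants_per_row: int = 4,
                              seed: int = 0) -> dict:
    """Recover p_Het from phenotypes generated at known explained fractions.

    For each target, ``n_reps`` independent designs/populations are
    simulated and analyzed; reported per target are the mean truth (the
    realized implied fraction varies slightly with the drawn SPE counts),
    the mean estimate and their absolute difference.  Rare replicates
    where the null model estimates no hybrid variance leave p_Het
    undefined and are excluded from the mean (their count is reported).
    """
    import warnings as _w

    out = {}
    for t_i, target in enumerate(targets):
        truths, ests = [], []
        for r in range(n_reps):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                tr, est = _one_p_het_replicate(seed + 1000 * t_i + r, target,
                                               n_hybrids, sigma2_het,
                                               plants_per_row)
            truths.append(tr)
            ests.append(est)
        ests = np.asarray(ests)
        out[target] = {
            "mean_truth": float(np.mean(truths)),
            "mean_estimate": float(np.nanmean(ests)),
            "sd_estimate": float(np.nanstd(ests)),
            "n_defined": int(np.isfinite(ests).sum()),
            "abs_error_of_mean": float(abs(np.nanmean(ests) - np.mean(truths))),
        }
    out["max_abs_error"] = max(v["abs_error_of_mean"]
                               for k, v in out.items() if isinstance(k, float))
    return out


# ---------------------------------------------------------------------------
# eQTL calibration and cis/trans recovery

def _simulated_cross(seed: int, n_ind: int, n_chrom: int = 3,
                     chrom_cm: float = 60.0, markers_per_chrom: int = 70,
                     cm_per_mbp: float = 0.7, missing: float = 0.03
                     ) -> eqm.CrossGeno:
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(n_chrom):
        cm = np.sort(rng.uniform(0, chrom_cm, size=markers_per_chrom))
        for m in cm:
            rows.append((f"chr{c+1}", m / cm_per_mbp * 1e6, m))
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "cm"])
    geno = np.empty((n_ind, len(markers)), dtype=int)
    for i in range(n_ind):
        g = []
        for _, grp in markers.groupby("chrom", sort=False):
            r = eqm._recomb_fraction(np.diff(grp["cm"].to_numpy()), "rilself")
            state = int(rng.integers(1, 3))
            g.append(state)
            for rr in r:
                if rng.random() < rr:
                    state = 3 - state
                g.append(state)
        geno[i] = g
    geno[rng.random(geno.shape) < missing] = 0
    return eqm.CrossGeno("rilself", markers, geno,
                         [f"ril{i:03d}" for i in range(n_ind)])


def eqtl_null_calibration(seed: int = 0, n_genes: int = 500, n_ind: int = 150,
                          n_perm: int = 1000, alpha: float = 0.001) -> dict:
    """Genome-wide type-I error of the permutation threshold on null genes.

    Each null gene gets its own permutation distribution; a false
    positive is an observed genome-wide maximum LOD strictly above the
    gene's (1 - alpha) permutation threshold.
    """
    cross = eqm.prepare_markers(_simulated_cross(seed, n_ind))
    grid = eqm.genotype_probabilities(cross)
    rng = np.random.default_rng(seed + 7)
    n_fp = 0
    pvals = []
    for g in range(n_genes):
        y = rng.normal(size=n_ind)
        lod_max = float(eqm.hk_scan(y, grid).max())
        max_lods = eqm.permutation_max_lods(y, grid, n_perm,
                                            seed=int(rng.integers(0, 2 ** 31)))
        if lod_max > eqm.permutation_threshold(max_lods, alpha):
            n_fp += 1
        pvals.append(eqm.permutation_pvalue(lod_max, max_lods))
    return {"n_genes": n_genes, "n_false_positives": n_fp,
            "type1_rate": n_fp / n_genes, "adjusted_p": np.asarray(pvals)}


def cis_trans_recovery(seed: int = 0, n_genes: int = 100, n_ind: int = 150,
                       effect_sd: float = 1.5, n_perm: int = 1000,
                       cis_window: float = 2.5e6) -> dict:
    """Label-recovery of cis/trans classification on simulated eQTL.

    Half the genes get a cis eQTL (regulatory marker within 1 Mbp of the
    gene start), half a trans eQTL on another chromosome; expression is
    ``effect_sd`` x dosage + standard normal noise.  Reported: the
    fraction of detected eQTL labelled with their true mode, and the
    fraction whose label changes when the cis window is varied by
    +-0.5 Mbp.  True eQTL are placed <= 1 Mbp (cis) or on another
    chromosome (trans), so flips can only come from peak-localization
    error moving a detected peak into the window-sensitive band; the
    classification is insensitive to the window when that fraction is
    small.
    """
    rng = np.random.default_rng(seed)
    cross = eqm.prepare_markers(_simulated_cross(seed + 1, n_ind))
    grid = eqm.genotype_probabilities(cross)
    markers = cross.markers
    chroms = markers["chrom"].unique()
    n_detected = n_correct = n_flips = 0
    for g in range(n_genes):
        mode = "cis" if g < n_genes // 2 else "trans"
        mi = int(rng.integers(0, len(markers)))
        m = markers.iloc[mi]
        if mode == "cis":
            gene_chrom = m["chrom"]
            gene_start = max(1.0, m["pos"] + rng.uniform(-1e6, 1e6))
        else:
            gene_chrom = str(rng.choice([c for c in chroms if c != m["chrom"]]))
            gene_start = rng.uniform(1, markers.loc[markers["chrom"] == gene_chrom,
                                                    "pos"].max())
        dos = (cross.geno[:, mi] == 2).astype(float)
        y = effect_sd * dos + rng.normal(size=n_ind)
        peaks = eqm.scan_gene(y, grid, f"g{g}", n_perm=n_perm,
                              seed=int(rng.integers(0, 2 ** 31)))
        if not peaks:
            continue
        best = max(peaks, key=lambda p: p.lod)
        n_detected += 1
        label = eqm.classify_cis_trans(best, gene_chrom, gene_start, cis_window)
        if label == mode:
            n_correct += 1
        labels = {eqm.classify_cis_trans(best, gene_chrom, gene_start, w)
                  for w in (cis_window - 0.5e6, cis_window, cis_window + 0.5e6)}
        if len(labels) > 1:
            n_flips += 1
    return {"n_genes": n_genes, "n_detected": n_detected,
            "label_accuracy": n_correct / max(n_detected, 1),
            "n_window_flips": n_flips,
            "window_flip_fraction": n_flips / max(n_detected, 1)}


# ---------------------------------------------------------------------------
# directional study-level findings on synthetic data

def directional_findings(seed: int = 0, n_rils: int = 25,
                         n_genes: int = 600) -> dict:
    """Three qualitative findings the synthetic cross must reproduce.

    1. hybrids express more genes than their parental average (SPE
       complementation adds expressed genes);
    2. SPE genes are counted more often in heterozygous than homozygous
       regions when SPE-capable genes are uniformly placed and silencing
       is allele-dependent;
    3. the number of active genes in a hybrid correlates positively with
       its heterozygosity fraction.
    """
    spec = sd.GenomeSpec()
    markers = sd.build_marker_map(spec, seed)
    mosaics = sd.simulate_ril_population(spec, n_rils, 4, seed=seed + 1)
    genes = sd.build_gene_table(spec, n_genes, seed=seed + 2)
    arch = sd.build_regulatory_architecture(genes, spec, seed=seed + 3,
                                            silenced_fraction=0.4)
    rows = [("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, "")]
    for m in mosaics:
        rows += [(m.ril_id, CLASS_RIL, m.ril_id),
                 (f"B73x{m.ril_id}", CLASS_BC_A, m.ril_id),
                 (f"MO17x{m.ril_id}", CLASS_BC_B, m.ril_id)]
    genotypes = pd.DataFrame(rows, columns=["genotype_id", "klass", "ril_id"])
    eset = sd.simulate_expression_counts(genes, arch, genotypes, mosaics,
                                         nb_dispersion=0.05, seed=seed + 4)
    pred = es.fit_artifact_smoother(eset.counts.mean(axis=1).to_numpy(),
                                    genes["gc"].to_numpy(),
                                    np.log(genes["length"].to_numpy()))
    norm = es.normalize(eset.counts, es.gene_norm_factors(pred),
                        es.tmm_factors(eset.counts))
    at = es.make_activity_table(norm, eset.samples)
    calls = sd.simulate_genotype_calls(mosaics, markers, seed=seed + 5)
    regs = gr.classify_regions(calls)

    extra_active = []
    spe_het = []
    spe_hom = []
    het_fracs = {}
    active_counts = {}
    for mos in mosaics:
        reg = regs.for_ril(mos.ril_id)
        for cross, mat, prefix in ((CLASS_BC_A, "B73", "B73x"),
                                   (CLASS_BC_B, "MO17", "MO17x")):
            hybrid = f"{prefix}{mos.ril_id}"
            n_h = int(at.active[hybrid].sum())
            n_parents = 0.5 * (at.active[mat].sum() + at.active[mos.ril_id].sum())
            extra_active.append(n_h - float(n_parents))
            zyg = gr.annotate_gene_zygosity(genes, reg, cross)
            asg = es.classify_spe(hybrid, mat, mos.ril_id, cross, at.active, zyg)
            pats = asg["pattern"]
            het_patterns = {1, 2} if cross == CLASS_BC_A else {5, 6}
            hom_patterns = {3, 4} if cross == CLASS_BC_A else {7, 8}
            spe_het.append(int(pats.isin(het_patterns).sum()))
            spe_hom.append(int(pats.isin(hom_patterns).sum()))
            het_fracs[hybrid] = gr.heterozygosity_fraction(reg, cross)
            active_counts[hybrid] = n_h
    summary = es.active_gene_summary(at.active[list(active_counts)],
                                     pd.Series(het_fracs))
    return {
        "mean_extra_active_vs_midparent": float(np.mean(extra_active)),
        "mean_spe_het_regions": float(np.mean(spe_het)),
        "mean_spe_hom_regions": float(np.mean(spe_hom)),
        "active_het_pearson_r": summary["pearson_r"],
        "active_het_pearson_p": summary["pearson_p"],
    }
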