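"""End-to-end orchestration: simulate -> regions -> spe -> heterosis ->
eqtl -> assoc, from a single config, with plain-file stage outputs and a
provenance manifest.

Every stage reads only files written by earlier stages (plus the config),
so any stage can be rerun in isolation; deterministic stages are
byte-identical under the same config and seed.  All thresholds default to
the values of the study the pipeline reimplements.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association_synteny as assoc
from . import eqtl_mapping as eqm
from . import expression_spe as es
from . import genotype_regions as gr
from . import heterosis_model as hm
from . import synthetic_data as sd
from .io import (CLASS_BC_A, CLASS_BC_B, CLASS_F1, CLASS_FOUNDER_A,
                 CLASS_FOUNDER_B, CLASS_RIL, HOM_ALT, HOM_REF, file_sha256,
                 read_vcf, write_gff3, write_json, write_regions_bed, write_vcf)


# ---------------------------------------------------------------------------
# configuration

@dataclass
class RunConfig:
    """All knobs of the pipeline; defaults are the study's values where
    the study fixes one, otherwise the synthetic fixture's scale."""

    seed: int = 0
    # genome / population
    n_chromosomes: int = 2
    chromosome_mbp: float = 40.0
    marker_density: float = 20.0
    cm_per_mbp: float = 0.7
    n_rils: int = 30
    n_intermating_gens: int = 4
    fraction_contaminated: float = 0.2
    third_segment_mbp: float = 3.0
    # genotype calls
    error_rate: float = 0.006
    missing_rate: float = 0.02
    gq_low_fraction: float = 0.05
    # expression
    n_genes: int = 400
    silenced_fraction: float = 0.3
    cis_fraction: float = 0.5
    nb_dispersion: float = 0.05
    expression_reps: int = 3
    # region classification
    min_gq: int = 10
    window: int = 15
    mo17_min: int = 11
    b73_min: int = 12
    block_gap: float = 0.5e6
    mask_gap: float = 2.5e6
    # activity / SPE
    activity_quantile: float = 0.25
    # phenotypes / heterosis
    n_blocks: int = 3
    plants_per_row: int = 8
    target_p_het: float = 0.25
    sigma2_het: float = 0.2
    heterosis_mode: str = "MPH"
    # eQTL
    n_perm: int = 10_000
    eqtl_alpha: float = 0.001
    fdr_threshold: float = 0.001
    cis_window: float = 2.5e6
    eqtl_max_genes: int = 200
    # TWAS
    twas_min_active_fraction: float = 0.05
    twas_n_pcs: int = 3
    twas_alpha: float = 0.05

    def region_params(self) -> gr.RegionParams:
        return gr.RegionParams(min_gq=self.min_gq, window=self.window,
                               mo17_min=self.mo17_min, b73_min=self.b73_min,
                               block_gap=self.block_gap, mask_gap=self.mask_gap)

    def genome_spec(self) -> sd.GenomeSpec:
        return sd.GenomeSpec(
            chromosomes=tuple((f"chr{i + 1}", int(self.chromosome_mbp * 1e6))
                              for i in range(self.n_chromosomes)),
            marker_density=self.marker_density, cm_per_mbp=self.cm_per_mbp)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        data = dataclasses.asdict(self)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            path.write_text(yaml.safe_dump(data, sort_keys=True))
        else:
            path.write_text(json.dumps(data, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(path.read_text())
        else:
            data = json.loads(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    pass


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise StageError(f"stage '{stage}' needs missing input {path}; "
                         "run the upstream stage first")
    return path


# ---------------------------------------------------------------------------
# stages

def stage_simulate(cfg: RunConfig, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    spec = cfg.genome_spec()
    rng_seed = cfg.seed
    markers = sd.build_marker_map(spec, rng_seed)
    mosaics = sd.simulate_ril_population(spec, cfg.n_rils,
                                         cfg.n_intermating_gens, seed=rng_seed + 1)
    mosaics = sd.inject_third_origin(mosaics, spec, cfg.fraction_contaminated,
                                     int(cfg.third_segment_mbp * 1e6),
                                     seed=rng_seed + 2)
    calls = sd.simulate_genotype_calls(
        mosaics, markers, gq_model=sd.GQModel(low_fraction=cfg.gq_low_fraction),
        missing_rate=cfg.missing_rate, error_rate=cfg.error_rate,
        seed=rng_seed + 3)
    write_vcf(calls, out / "calls.vcf")
    calls.samples.to_csv(out / "sample_manifest.tsv", sep="\t", index=False)
    markers.to_csv(out / "markers.tsv", sep="\t", index=False)

    genes = sd.build_gene_table(spec, cfg.n_genes, seed=rng_seed + 4)
    write_gff3(genes, out / "genes.gff3")
    genes.to_csv(out / "gene_meta.tsv", sep="\t", index=False)
    arch = sd.build_regulatory_architecture(
        genes, spec, seed=rng_seed + 5, cis_fraction=cfg.cis_fraction,
        silenced_fraction=cfg.silenced_fraction, cis_window=cfg.cis_window)
    arch.to_csv(out / "architecture_truth.tsv", sep="\t", index=False)

    geno_rows = [("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, ""),
                 ("B73xMO17", CLASS_F1, ""), ("MO17xB73", CLASS_F1, "")]
    for m in mosaics:
        geno_rows += [(m.ril_id, CLASS_RIL, m.ril_id),
                      (f"B73x{m.ril_id}", CLASS_BC_A, m.ril_id),
                      (f"MO17x{m.ril_id}", CLASS_BC_B, m.ril_id)]
    genotypes = pd.DataFrame(geno_rows, columns=["genotype_id", "klass", "ril_id"])
    eset = sd.simulate_expression_counts(
        genes, arch, genotypes, mosaics, nb_dispersion=cfg.nb_dispersion,
        reps=cfg.expression_reps,
        gc_length_artifact=lambda gc, ll: np.exp(1.0 * (gc - 0.5)
                                                 + 0.2 * (ll - np.mean(ll))),
        seed=rng_seed + 6)
    eset.counts.to_csv(out / "counts.tsv", sep="\t")
    eset.samples.to_csv(out / "expression_samples.tsv", sep="\t", index=False)
    eset.truth["activity"].to_csv(out / "activity_truth.tsv", sep="\t")

    # ground-truth SPE counts feed the generative phenotype model
    act = eset.truth["activity"]
    design = sd.build_experimental_design(
        cfg.n_rils, n_blocks=cfg.n_blocks, plants_per_row=cfg.plants_per_row,
        ril_ids=[m.ril_id for m in mosaics], seed=rng_seed + 7)
    ped = sd.pedigree_of(design)
    spe_counts = {}
    for hybrid, mother, father in ped.itertuples(index=False):
        if hybrid not in act.index:
            continue
        spe = act.loc[hybrid] & (act.loc[mother] ^ act.loc[father])
        # split by the true zygosity of the gene at its regulatory locus
        spe_counts[hybrid] = [int(spe.sum()), 0, 0, 0]
    spe_df = pd.DataFrame.from_dict(spe_counts, orient="index",
                                    columns=["s1", "s2", "s3", "s4"])
    gammas = np.zeros(4)
    hyb_a = [h for h in spe_df.index if h.startswith("B73xRIL")]
    if cfg.target_p_het > 0 and len(hyb_a) >= 2:
        gammas = sd.gamma_for_target_p_het(spe_df.loc[hyb_a], cfg.sigma2_het,
                                           cfg.target_p_het)
    gen_model = sd.PhenotypeGenModel(gammas=gammas, sigma2_het=cfg.sigma2_het)
    phen, truth = sd.simulate_phenotypes(design, gen_model, spe_df,
                                         seed=rng_seed + 8)
    phen.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
    ped.to_csv(out / "pedigree.tsv", sep="\t", index=False)
    spe_df.to_csv(out / "spe_counts_truth.tsv", sep="\t")
    mosaic_truth = pd.concat([m.segments.assign(ril_id=m.ril_id) for m in mosaics])
    mosaic_truth.to_csv(out / "mosaic_truth.tsv", sep="\t", index=False)
    write_json({k: v for k, v in truth.items() if not isinstance(v, dict)},
               out / "phenotype_truth.json")


def stage_regions(cfg: RunConfig, out: Path) -> None:
    manifest = pd.read_csv(_need(out / "sample_manifest.tsv", "regions"), sep="\t",
                           keep_default_na=False)
    markers = pd.read_csv(_need(out / "markers.tsv", "regions"), sep="\t")
    try:
        calls = read_vcf(out / "calls.vcf", manifest, markers)
    except Exception as exc:
        raise StageError(f"cannot parse {out / 'calls.vcf'}: {exc}") from exc
    params = cfg.region_params()
    regs = gr.classify_regions(calls, params)
    write_regions_bed(regs.regions, out / "regions.bed")
    genes = pd.read_csv(out / "gene_meta.tsv", sep="\t")
    zyg_rows = {}
    het_rows = []
    for rid in regs.kept_rils:
        rr = regs.for_ril(rid)
        for cross, prefix in ((CLASS_BC_A, "B73x"), (CLASS_BC_B, "MO17x")):
            zyg = gr.annotate_gene_zygosity(genes, rr, cross)
            zyg_rows[f"{prefix}{rid}"] = zyg
            het_rows.append((f"{prefix}{rid}",
                             gr.heterozygosity_fraction(rr, cross)))
    pd.DataFrame(zyg_rows).to_csv(out / "gene_zygosity.tsv", sep="\t")
    pd.DataFrame(het_rows, columns=["hybrid", "het_fraction"]).to_csv(
        out / "het_fraction.tsv", sep="\t", index=False)
    write_json({"kept": regs.kept_rils, "excluded": regs.excluded_rils},
               out / "ril_exclusions.json")


def stage_spe(cfg: RunConfig, out: Path) -> None:
    counts = pd.read_csv(_need(out / "counts.tsv", "spe"), sep="\t", index_col=0)
    samples = pd.read_csv(_need(out / "expression_samples.tsv", "spe"), sep="\t",
                          keep_default_na=False)
    genes = pd.read_csv(out / "gene_meta.tsv", sep="\t")
    zyg = pd.read_csv(_need(out / "gene_zygosity.tsv", "spe"), sep="\t", index_col=0)
    pred = es.fit_artifact_smoother(counts.mean(axis=1).to_numpy(),
                                    genes["gc"].to_numpy(),
                                    np.log(genes["length"].to_numpy()))
    norm = es.normalize(counts, es.gene_norm_factors(pred), es.tmm_factors(counts))
    at = es.make_activity_table(norm, samples, quantile=cfg.activity_quantile)
    at.active.to_csv(out / "activity.tsv", sep="\t")
    at.means.to_csv(out / "genotype_means.tsv", sep="\t")
    frames = []
    for hybrid in zyg.columns:
        if hybrid not in at.active.columns:
            continue
        if hybrid.startswith("B73x"):
            cross, mat, pat = CLASS_BC_A, "B73", hybrid[len("B73x"):]
        else:
            cross, mat, pat = CLASS_BC_B, "MO17", hybrid[len("MO17x"):]
        if pat not in at.active.columns:
            continue
        frames.append(es.classify_spe(hybrid, mat, pat, cross, at.active,
                                      zyg[hybrid]))
    for f1, mat, pat in (("B73xMO17", "B73", "MO17"), ("MO17xB73", "MO17", "B73")):
        if f1 in at.active.columns:
            frames.append(es.classify_spe(f1, mat, pat, CLASS_F1, at.active))
    assignments = pd.concat(frames, ignore_index=True)
    assignments.to_csv(out / "spe_assignments.tsv", sep="\t", index=False)
    es.summarize_spe(assignments).to_csv(out / "spe_summary.tsv", sep="\t")
    write_json({"tau": at.tau}, out / "activity_threshold.json")


def stage_heterosis(cfg: RunConfig, out: Path) -> None:
    phen = pd.read_csv(_need(out / "phenotypes.tsv", "heterosis"), sep="\t",
                       keep_default_na=False)
    ped = pd.read_csv(_need(out / "pedigree.tsv", "heterosis"), sep="\t",
                      keep_default_na=False)
    assignments = pd.read_csv(_need(out / "spe_assignments.tsv", "heterosis"),
                              sep="\t", keep_default_na=False)
    report = {}
    for klass, patterns, founder in ((CLASS_BC_A, ["1", "2", "3", "4"], CLASS_FOUNDER_A),
                                     (CLASS_BC_B, ["5", "6", "7", "8"], CLASS_FOUNDER_B)):
        sub = assignments[assignments["hybrid_id"].str.startswith(
            "B73x" if klass == CLASS_BC_A else "MO17x")]
        sub = sub[~sub["hybrid_id"].isin(["B73xMO17", "MO17xB73"])]
        if sub.empty:
            continue
        spe = es.spe_counts_matrix(sub.assign(pattern=sub["pattern"].astype(str)),
                                   patterns)
        recs = phen[phen["klass"].isin([CLASS_RIL, founder, klass])]
        recs = recs[recs["genotype_id"].isin(
            set(spe.index) | set(recs.loc[recs["klass"] != klass, "genotype_id"]))]
        ped_pop = ped[ped["hybrid"].isin(spe.index)]
        vd = hm.p_het_analysis(recs, ped_pop, spe, mode=cfg.heterosis_mode)
        bl = hm.fit_baseline_model(recs)
        heterosis = hm.compute_heterosis(bl.adjusted_means, ped_pop)
        report[klass] = {
            "sigma2_het": vd.sigma2_het, "sigma2_g": vd.sigma2_g,
            "p_het": vd.p_het, "phi": vd.phi,
            "gammas": vd.gammas.to_dict(),
            "mean_mph_pct": float(heterosis["mph_pct"].mean()),
            "mean_bph_pct": float(heterosis["bph_pct"].mean()),
        }
    write_json(report, out / "heterosis_report.json")


def stage_eqtl(cfg: RunConfig, out: Path) -> None:
    manifest = pd.read_csv(_need(out / "sample_manifest.tsv", "eqtl"), sep="\t",
                           keep_default_na=False)
    markers = pd.read_csv(out / "markers.tsv", sep="\t")
    calls = read_vcf(out / "calls.vcf", manifest, markers)
    means = pd.read_csv(_need(out / "genotype_means.tsv", "eqtl"), sep="\t",
                        index_col=0)
    genes = pd.read_csv(out / "gene_meta.tsv", sep="\t").set_index("gene_id")
    ril_idx = calls.samples_of_class(CLASS_RIL)
    ril_ids = calls.samples["ril_id"].to_numpy()[ril_idx]
    geno = np.zeros((len(ril_idx), len(calls.markers)), dtype=int)
    geno[calls.calls[ril_idx] == HOM_REF] = 1
    geno[calls.calls[ril_idx] == HOM_ALT] = 2
    cross = eqm.CrossGeno("rilself", calls.markers[["chrom", "pos", "cm"]],
                          geno, list(ril_ids))
    cross = eqm.prepare_markers(cross)
    grid = eqm.genotype_probabilities(cross)
    rng = np.random.default_rng(cfg.seed + 100)
    gene_ids = list(means.index[:cfg.eqtl_max_genes])
    peaks = []
    for gi, gid in enumerate(gene_ids):
        y = means.loc[gid, cross.individuals].to_numpy(dtype=float)
        pk = eqm.scan_gene(y, grid, gid, n_perm=cfg.n_perm, alpha=cfg.eqtl_alpha,
                           seed=int(rng.integers(0, 2 ** 31)))
        peaks.extend(pk)
    sig = eqm.fdr_across_genes(peaks, n_genes_total=len(gene_ids),
                               fdr_threshold=cfg.fdr_threshold)
    sig = eqm.merge_peaks(sig)
    for pk in sig:
        g = genes.loc[pk.gene_id]
        pk.regulation = eqm.classify_cis_trans(pk, g["chrom"], g["start"],
                                               cis_window=cfg.cis_window)
    eqm.peaks_to_frame(sig).to_csv(out / "eqtl_peaks.tsv", sep="\t", index=False)


def stage_assoc(cfg: RunConfig, out: Path) -> None:
    means = pd.read_csv(_need(out / "genotype_means.tsv", "assoc"), sep="\t",
                        index_col=0)
    active = pd.read_csv(_need(out / "activity.tsv", "assoc"), sep="\t",
                         index_col=0)
    phen = pd.read_csv(out / "phenotypes.tsv", sep="\t", keep_default_na=False)
    assignments = pd.read_csv(out / "spe_assignments.tsv", sep="\t",
                              keep_default_na=False)
    peaks = pd.read_csv(_need(out / "eqtl_peaks.tsv", "assoc"), sep="\t")
    genes = pd.read_csv(out / "gene_meta.tsv", sep="\t").set_index("gene_id")
    results = {}
    tsg_frames = []
    for klass, prefix in ((CLASS_BC_A, "B73x"), (CLASS_BC_B, "MO17x")):
        recs = phen[phen["klass"] == klass]
        if recs.empty:
            continue
        bl = hm.fit_baseline_model(phen[phen["klass"].isin(
            [klass, CLASS_RIL, CLASS_FOUNDER_A, CLASS_FOUNDER_B])])
        hybs = [g for g in recs["genotype_id"].unique() if g in means.columns]
        trait = bl.adjusted_means.reindex(hybs).dropna()
        hits = assoc.twas_scan(means[hybs], trait, active[hybs],
                               min_active_fraction=cfg.twas_min_active_fraction,
                               n_pcs=cfg.twas_n_pcs, alpha=cfg.twas_alpha)
        tsg = assoc.identify_tsg(hits, assignments[
            assignments["hybrid_id"].str.startswith(prefix)])
        results[klass] = {"n_tested": int(hits["n_tests"].iloc[0]) if len(hits) else 0,
                          "n_hits": int(hits["passes_bonferroni"].sum()),
                          "n_tsg": len(tsg)}
        hits.to_csv(out / f"twas_{klass}.tsv", sep="\t", index=False)
        tsg_frames.append(tsg)
    pd.concat(tsg_frames, ignore_index=True).to_csv(out / "tsg.tsv", sep="\t",
                                                    index=False)
    if len(peaks):
        tab = peaks[["gene_id", "regulation"]].merge(
            genes["syntenic"].reset_index(), on="gene_id")
        enr = assoc.synteny_enrichment(tab)
        results["synteny"] = {"odds_ratio": enr["odds_ratio"],
                              "p_value": enr["p_value"],
                              "table": enr["table"].tolist()}
    write_json(results, out / "assoc_report.json")


STAGES = {
    "simulate": stage_simulate,
    "regions": stage_regions,
    "spe": stage_spe,
    "heterosis": stage_heterosis,
    "eqtl": stage_eqtl,
    "assoc": stage_assoc,
}
STAGE_ORDER = list(STAGES)


def run_all(cfg: RunConfig, outdir: str | Path,
            stages: list[str] | None = None) -> Path:
    """Run the requested stages (default: all, in dependency order) and
    write a provenance manifest stamping outputs with config hash, seed
    and file digests."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for stage in stages or STAGE_ORDER:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        STAGES[stage](cfg, out)
    manifest = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "outputs": {p.name: file_sha256(p) for p in sorted(out.iterdir())
                    if p.is_file() and p.name != "manifest.json"},
    }
    cfg.to_file(out / "config.json")
    manifest["outputs"]["config.json"] = file_sha256(out / "config.json")
    write_json(manifest, out / "manifest.json")
    return out
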