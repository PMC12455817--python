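"""Shared simulated fixtures: one small but complete synthetic cross used
across the unit tests (session-scoped; everything is seeded)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spehet import expression_spe as es
from spehet import genotype_regions as gr
from spehet import synthetic_data as sd
from spehet.io import (CLASS_BC_A, CLASS_BC_B, CLASS_F1, CLASS_FOUNDER_A,
                       CLASS_FOUNDER_B, CLASS_RIL)


@pytest.fixture(scope="session")
def genome_spec():
    return sd.GenomeSpec((("chr1", 40_000_000), ("chr2", 40_000_000)),
                         marker_density=20.0, cm_per_mbp=0.7)


@pytest.fixture(scope="session")
def small_cross(genome_spec):
    """Markers, mosaics (with third-origin contamination) and genotype calls."""
    markers = sd.build_marker_map(genome_spec, 11)
    mosaics = sd.simulate_ril_population(genome_spec, 15, 4, seed=12)
    mosaics = sd.inject_third_origin(mosaics, genome_spec, 0.2, 3_000_000, seed=13)
    calls = sd.simulate_genotype_calls(mosaics, markers, missing_rate=0.02,
                                       error_rate=0.006, seed=14)
    return {"markers": markers, "mosaics": mosaics, "calls": calls}


@pytest.fixture(scope="session")
def region_set(small_cross):
    return gr.classify_regions(small_cross["calls"])


@pytest.fixture(scope="session")
def expression(genome_spec, small_cross):
    """Genes, regulatory architecture and a noisy expression set."""
    genes = sd.build_gene_table(genome_spec, 400, seed=21)
    arch = sd.build_regulatory_architecture(genes, genome_spec, seed=22,
                                            silenced_fraction=0.35)
    rows = [("B73", CLASS_FOUNDER_A, ""), ("MO17", CLASS_FOUNDER_B, ""),
            ("B73xMO17", CLASS_F1, ""), ("MO17xB73", CLASS_F1, "")]
    for m in small_cross["mosaics"]:
        rows += [(m.ril_id, CLASS_RIL, m.ril_id),
                 (f"B73x{m.ril_id}", CLASS_BC_A, m.ril_id),
                 (f"MO17x{m.ril_id}", CLASS_BC_B, m.ril_id)]
    genotypes = pd.DataFrame(rows, columns=["genotype_id", "klass", "ril_id"])
    eset = sd.simulate_expression_counts(genes, arch, genotypes,
                                         small_cross["mosaics"],
                                         nb_dispersion=0.05, seed=23)
    return {"genes": genes, "arch": arch, "genotypes": genotypes, "eset": eset}


@pytest.fixture(scope="session")
def activity(expression):
    eset = expression["eset"]
    genes = expression["genes"]
    pred = es.fit_artifact_smoother(eset.counts.mean(axis=1).to_numpy(),
                                    genes["gc"].to_numpy(),
                                    np.log(genes["length"].to_numpy()))
    norm = es.normalize(eset.counts, es.gene_norm_factors(pred),
                        es.tmm_factors(eset.counts))
    return es.make_activity_table(norm, eset.samples)
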