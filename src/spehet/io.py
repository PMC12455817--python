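"""Shared containers and on-disk formats.

Coordinate convention, used by every module in the package: genomic
coordinates are 1-based, closed intervals, in base pairs.  The only
exception is the BED writer, which converts to BED's 0-based half-open
convention on output.

Genotype calls are stored as small integer codes in dense
(sample x locus) matrices; the codes distinguish calls whose allele
matches neither founder ("other"), because downstream masking needs to
know whether such a call is homozygous.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# genotype-call codes

HOM_REF = 0  # homozygous founder-A (reference) allele
HOM_ALT = 1  # homozygous founder-B (non-reference) allele
HET = 2      # heterozygous ref/alt
OTHER_HOM = 3  # homozygous for an allele matching neither founder
OTHER_HET = 4  # heterozygous with one allele matching neither founder
MISSING = 5

CALL_NAMES = {
    HOM_REF: "HOM_REF", HOM_ALT: "HOM_ALT", HET: "HET",
    OTHER_HOM: "OTHER_HOM", OTHER_HET: "OTHER_HET", MISSING: "MISSING",
}

#: sample classes used in the sample manifest
CLASS_FOUNDER_A = "B73"
CLASS_FOUNDER_B = "MO17"
CLASS_RIL = "RIL"
CLASS_BC_A = "B73xRIL"   # backcross hybrid with founder A recurrent
CLASS_BC_B = "MO17xRIL"  # backcross hybrid with founder B recurrent
CLASS_F1 = "F1"          # full reference hybrid (B73xMo17 / Mo17xB73)

#: segment / region origin labels
ORIGIN_A = "B73"
ORIGIN_B = "MO17"
ORIGIN_THIRD = "THIRD"
MASKED_THIRD = "MASKED_THIRD"
NO_INFO = "NO_INFO"


MARKER_COLUMNS = ["chrom", "pos", "cm", "ref", "alt", "third"]


def validate_marker_map(markers: pd.DataFrame) -> pd.DataFrame:
    """Check marker-map invariants: 1-based, strictly increasing per chromosome."""
    for col in ("chrom", "pos", "cm"):
        if col not in markers.columns:
            raise ValueError(f"marker map missing column {col!r}")
    if (markers["pos"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based bp)")
    for _, grp in markers.groupby("chrom", sort=False):
        if not (np.diff(grp["pos"].to_numpy()) > 0).all():
            raise ValueError("marker positions must be strictly increasing per chromosome")
    return markers


@dataclass
class GenotypeCallSet:
    """Per-sample genotype calls with quality at a fixed set of loci.

    ``calls`` is (n_samples, n_loci) int8 using the call codes above;
    ``gq`` is the phred-scaled genotype quality, same shape.
    ``samples`` has columns sample, klass, ril_id (ril_id = "" for
    founders and reference hybrids).
    """

    markers: pd.DataFrame
    samples: pd.DataFrame
    calls: np.ndarray
    gq: np.ndarray

    def __post_init__(self) -> None:
        validate_marker_map(self.markers)
        n_s, n_l = self.calls.shape
        if n_s != len(self.samples) or n_l != len(self.markers):
            raise ValueError("calls matrix shape does not match samples/markers")
        if self.gq.shape != self.calls.shape:
            raise ValueError("gq shape must match calls")
        if (self.gq < 0).any():
            raise ValueError("GQ must be >= 0")

    def sample_index(self, sample: str) -> int:
        idx = np.flatnonzero((self.samples["sample"] == sample).to_numpy())
        if idx.size == 0:
            raise KeyError(sample)
        return int(idx[0])

    def samples_of_class(self, klass: str) -> np.ndarray:
        return np.flatnonzero((self.samples["klass"] == klass).to_numpy())

    def subset_samples(self, index: np.ndarray) -> "GenotypeCallSet":
        return GenotypeCallSet(
            markers=self.markers,
            samples=self.samples.iloc[index].reset_index(drop=True),
            calls=self.calls[index],
            gq=self.gq[index],
        )


# ---------------------------------------------------------------------------
# VCF v4.2

_GT_OF_CODE = {
    HOM_REF: "0/0", HOM_ALT: "1/1", HET: "0/1",
    OTHER_HOM: "2/2", OTHER_HET: "0/2", MISSING: "./.",
}


def write_vcf(callset: GenotypeCallSet, path: str | Path) -> None:
    """Write calls as VCF v4.2 with GT and GQ FORMAT fields.

    A second ALT allele is emitted only at loci where some sample carries
    the third-origin allele.
    """
    path = Path(path)
    markers = callset.markers
    sample_names = callset.samples["sample"].tolist()
    uses_third = np.isin(callset.calls, [OTHER_HOM, OTHER_HET]).any(axis=0)
    chrom_lengths = markers.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spehet\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={int(length)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_names) + "\n")
        chroms = markers["chrom"].to_numpy()
        poss = markers["pos"].to_numpy()
        refs = markers["ref"].to_numpy()
        alts = markers["alt"].to_numpy()
        thirds = markers["third"].to_numpy() if "third" in markers else np.full(len(markers), "N")
        for j in range(len(markers)):
            alt_field = alts[j] if not uses_third[j] else f"{alts[j]},{thirds[j]}"
            fields = [
                str(chroms[j]), str(int(poss[j])), f"m{j}", str(refs[j]), alt_field,
                ".", "PASS", ".", "GT:GQ",
            ]
            col = callset.calls[:, j]
            gqs = callset.gq[:, j]
            fields += [f"{_GT_OF_CODE[int(c)]}:{int(q)}" for c, q in zip(col, gqs)]
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path, manifest: pd.DataFrame,
             marker_cm: pd.DataFrame | None = None) -> GenotypeCallSet:
    """Read a VCF v4.2 with GT/GQ into a :class:`GenotypeCallSet`.

    ``manifest`` maps sample -> klass (and optional ril_id).  Genetic
    positions are taken from ``marker_cm`` (columns chrom, pos, cm) when
    given, else set to 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    rows = []
    call_rows = []
    gq_rows = []
    for var in vcf:
        alts = var.ALT or []
        rows.append((var.CHROM, int(var.POS), var.REF,
                     alts[0] if alts else "N",
                     alts[1] if len(alts) > 1 else "N"))
        geno = var.genotypes  # list of [a1, a2, phased]
        codes = np.empty(len(vcf_samples), dtype=np.int8)
        for i, g in enumerate(geno):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                codes[i] = MISSING
            elif a == 0 and b == 0:
                codes[i] = HOM_REF
            elif a == 1 and b == 1:
                codes[i] = HOM_ALT
            elif {a, b} == {0, 1}:
                codes[i] = HET
            elif a == b:
                codes[i] = OTHER_HOM
            else:
                codes[i] = OTHER_HET
        call_rows.append(codes)
        gq = var.format("GQ")
        gq_rows.append(np.zeros(len(vcf_samples), dtype=np.int16) if gq is None
                       else np.asarray(gq).reshape(-1).astype(np.int16))
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "third"])
    if marker_cm is not None:
        markers = markers.merge(marker_cm[["chrom", "pos", "cm"]], on=["chrom", "pos"], how="left")
        markers["cm"] = markers["cm"].fillna(0.0)
    else:
        markers["cm"] = 0.0
    markers = markers[MARKER_COLUMNS]
    manifest = manifest.copy()
    if "ril_id" not in manifest:
        manifest["ril_id"] = ""
    manifest = manifest.set_index("sample").loc[vcf_samples].reset_index()
    return GenotypeCallSet(
        markers=markers,
        samples=manifest,
        calls=np.vstack(call_rows).T.astype(np.int8),
        gq=np.vstack(gq_rows).T,
    )


# ---------------------------------------------------------------------------
# GFF3 / gene metadata

GENE_META_COLUMNS = ["gene_id", "chrom", "start", "end", "gc", "length", "syntenic"]


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes.iterrows():
            fh.write(f"{g['chrom']}\tspehet\tgene\t{int(g['start'])}\t{int(g['end'])}\t"
                     f".\t+\t.\tID={g['gene_id']}\n")


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            rows.append((attrs.get("ID", ""), parts[0], int(parts[3]), int(parts[4])))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


# ---------------------------------------------------------------------------
# BED (regions)

def write_regions_bed(regions: pd.DataFrame, path: str | Path) -> None:
    """Write classified regions as BED6 (0-based half-open on disk)."""
    with open(path, "w") as fh:
        for _, r in regions.iterrows():
            fh.write(f"{r['chrom']}\t{int(r['start']) - 1}\t{int(r['end'])}\t"
                     f"{r['ril_id']}:{r['origin']}\t0\t+\n")


def read_regions_bed(path: str | Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name = line.split("\t")[:4]
            ril_id, origin = name.rsplit(":", 1)
            rows.append((ril_id, chrom, int(start) + 1, int(end), origin))
    return pd.DataFrame(rows, columns=["ril_id", "chrom", "start", "end", "origin"])


# ---------------------------------------------------------------------------
# misc

def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
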