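"""Readers and writers for every on-disk format the pipeline touches.

Formats: minimal VCF v4.2 (GT only, unphased) and additive-dosage TSV for
genotypes; TSV with header row for cohort and connectivity tables; an
OFF-style text format for meshes (vertex count + edge list); YAML for
simulation configs; plain-text provenance logs.  All writers emit a fixed
column order; readers tolerate arbitrary column order by name; every
writer round-trips bit-exactly through its reader.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cluster import SurfaceMesh
from .containers import COHORT_COLUMNS, COMPONENTS, MISSING, GenotypeMatrix
from .simulate import EffectSpec, SimulationConfig, SNPSpec

log = logging.getLogger("dmnassoc")

_GT_TO_DOSAGE = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": MISSING}


# ----------------------------------------------------------------------
# Genotypes


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal unphased-GT VCF (ALT = minor allele)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dmnassoc\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.subject_ids)
            + "\n"
        )
        inv = {v: k for k, v in _GT_TO_DOSAGE.items() if k != "1/0"}
        for j, snp in enumerate(geno.snp_ids):
            gts = "\t".join(inv[int(d)] for d in geno.dosage[:, j])
            gene = geno.gene[j] if geno.gene else None
            info = f"GENE={gene}" if gene else "."
            fh.write(f"1\t{j + 1}\t{snp}\tA\tC\t.\t.\t{info}\tGT\t{gts}\n")


def _prevalidate_vcf_text(path: Path) -> None:
    """Cheap structural pass so malformed records fail with a line number."""
    n_fields = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                n_fields = len(fields)
                continue
            if len(fields) < 10 or (n_fields and len(fields) != n_fields):
                raise ValueError(
                    f"{path}: malformed VCF record at line {lineno} "
                    f"({len(fields)} fields)"
                )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read an unphased-GT VCF into a minor-allele dosage matrix.

    The minor allele is determined from the sample allele frequencies in
    the file itself: sites where ALT is the major allele are flipped so
    that dosage 2 always means minor-allele homozygote (flips are logged).
    Multiallelic records are rejected.
    """
    from cyvcf2 import VCF

    path = Path(path)
    _prevalidate_vcf_text(path)
    vcf = VCF(str(path))
    subjects = list(vcf.samples)
    snp_ids, genes, columns = [], [], []
    for rec in vcf:
        if rec.ALT and len(rec.ALT) > 1:
            raise ValueError(
                f"{path}: multiallelic site {rec.ID or rec.POS} not supported"
            )
        dos = np.empty(len(subjects), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a1, a2 = gt[0], gt[1]
            dos[i] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
        called = dos[dos != MISSING]
        if called.size and called.mean() / 2.0 > 0.5:
            flipped = np.where(dos == MISSING, MISSING, 2 - dos).astype(np.int8)
            log.info("flipped %s: ALT is the major allele in sample", rec.ID)
            dos = flipped
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        gene = dict(rec.INFO).get("GENE") if rec.INFO else None
        genes.append(gene)
        columns.append(dos)
    if not columns:
        raise ValueError(f"{path}: no variant records")
    dosage = np.column_stack(columns)
    gene_list = genes if any(g is not None for g in genes) else None
    return GenotypeMatrix(dosage, subjects, snp_ids, gene=gene_list)


def write_dosage_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV (subject_id + one column per SNP, NA missing)."""
    df = geno.to_frame().replace(MISSING, "NA")
    df.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: dosage TSV lacks a subject_id column")
    snps = [c for c in df.columns if c != "subject_id"]
    dosage = df[snps].to_numpy(dtype=float)
    dosage = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(dosage, df["subject_id"].tolist(), snps)


def read_genotypes(path: str | Path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on format ('vcf' or 'dosage'), inferred from the suffix."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "dosage"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage":
        return read_dosage_tsv(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ----------------------------------------------------------------------
# Cohort / connectivity tables


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a subject table as TSV in canonical column order."""
    cols = ["subject_id"]
    cols += [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in COMPONENTS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError(f"{path}: table lacks a subject_id column")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dup}")
    return df


def read_long_timeseries(path: str | Path) -> pd.DataFrame:
    """Read the long-format ROI time-series TSV.

    Columns: subject, run, roi, frame, value, motion.
    """
    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "run": str, "roi": str})
    required = {"subject", "run", "roi", "frame", "value", "motion"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: long time-series TSV missing {sorted(missing)}")
    return df


# ----------------------------------------------------------------------
# Mesh and vertex maps


def write_mesh(mesh: SurfaceMesh, path: str | Path) -> None:
    """OFF-style text: 'n_vertices n_edges' then one 'i j' line per edge."""
    with Path(path).open("w") as fh:
        fh.write(f"{mesh.n_vertices} {len(mesh.edges)}\n")
        for i, j in mesh.edges:
            fh.write(f"{i} {j}\n")


def read_mesh(path: str | Path) -> SurfaceMesh:
    with Path(path).open() as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: mesh header must be 'n_vertices n_edges'")
        nv, ne = int(header[0]), int(header[1])
        edges = np.loadtxt(fh, dtype=np.intp, ndmin=2) if ne else np.empty((0, 2), np.intp)
    if len(edges) != ne:
        raise ValueError(f"{path}: expected {ne} edges, found {len(edges)}")
    return SurfaceMesh(nv, edges)


def write_vertex_maps(maps: np.ndarray, path: str | Path, labels=None) -> None:
    """Vertex maps as TSV: vertex index + one column per map."""
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    if labels is None:
        labels = [f"map{i + 1}" for i in range(maps.shape[0])]
    df = pd.DataFrame(maps.T, columns=list(labels))
    df.insert(0, "vertex", np.arange(maps.shape[1]))
    df.to_csv(path, sep="\t", index=False)


def read_vertex_maps(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "vertex" not in df.columns:
        raise ValueError(f"{path}: vertex-map TSV lacks a vertex column")
    df = df.sort_values("vertex")
    labels = [c for c in df.columns if c != "vertex"]
    return df[labels].to_numpy(dtype=float).T, labels


# ----------------------------------------------------------------------
# Simulation config (YAML)


def write_config(config: SimulationConfig, path: str | Path) -> None:
    d = dataclasses.asdict(config)
    if isinstance(d["component_corr"], np.ndarray):
        d["component_corr"] = d["component_corr"].tolist()
    with Path(path).open("w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path: str | Path) -> SimulationConfig:
    with Path(path).open() as fh:
        d = yaml.safe_load(fh)
    d["snp_specs"] = [SNPSpec(**s) for s in d.get("snp_specs", [])]
    d["effect_specs"] = [EffectSpec(**e) for e in d.get("effect_specs", [])]
    if isinstance(d.get("component_corr"), list):
        d["component_corr"] = np.asarray(d["component_corr"], dtype=float)
    return SimulationConfig(**d)


# ----------------------------------------------------------------------
# Provenance


def write_provenance(path: str | Path, command: str, params: dict) -> None:
    """Record the command, parameters, seed and package version alongside
    every output."""
    from . import __version__

    record = {"command": command, "version": __version__, **params}
    with Path(path).open("w") as fh:
        json.dump(record, fh, indent=2, default=str)
        fh.write("\n")
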