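"""Readers and writers for the delimited/VCF formats used by the package.

Formats:

* VCF 4.x (read via cyvcf2, written as plain text): biallelic SNPs only,
  phased genotypes use ``|``, unphased ``/``.
* marker map CSV: ``marker,chrom,pos_bp[,pos_cM]``.
* dosage matrix CSV: first column ``individual``, one column per marker;
  a ``#coding=alt-dosage`` header line declares the allele coding.
* pedigree CSV: ``id,mother,father`` with unknown parents empty or ``0``.
* founder assignment CSV: one row per individual, two columns per marker
  (``<marker>_1``, ``<marker>_2``).
* phenotype long CSV: ``individual,trait,year,value``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (
    MISSING,
    FounderAssignment,
    GenotypeMatrix,
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

DOSAGE_HEADER = "#coding=alt-dosage"


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    cM = df["pos_cM"].to_numpy() if "pos_cM" in df.columns else None
    return MarkerMap(df["marker"], df["chrom"], df["pos_bp"], cM)


def write_marker_map(markers: MarkerMap, path) -> None:
    markers.to_frame().to_csv(path, index=False)


def read_genotypes(path, format: str = "vcf"):
    """Read genotypes from a VCF or a dosage-matrix CSV.

    Returns :class:`PhasedGenotypes` when every called genotype in a VCF is
    phased, otherwise :class:`GenotypeMatrix`.  Non-biallelic sites are
    skipped with a logged count.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_dosage_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path):
    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, poss = [], [], []
    gts = []
    n_skipped = 0
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        g = np.array(var.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        called = g[:, 0] >= 0
        if called.any() and not np.all(g[called, 2] == 1):
            all_phased = False
        gts.append(g[:, :2])
    if n_skipped:
        logger.warning("skipped %d non-biallelic site(s) in %s", n_skipped, path)
    if not ids:
        raise ValueError(f"no biallelic sites found in {path}")
    markers = MarkerMap(ids, chroms, poss)
    raw = np.stack(gts, axis=1)  # (n, m_input, 2)
    # reorder to the sorted marker order
    order = np.array([ids.index(m) for m in markers.marker_id], dtype=np.intp)
    raw = raw[:, order, :]
    raw[raw < 0] = MISSING
    if all_phased:
        alleles = raw.astype(np.int8)
        # one missing allele makes the whole genotype missing
        anymiss = (alleles == MISSING).any(axis=2)
        alleles[anymiss] = MISSING
        return PhasedGenotypes(individuals, markers, alleles)
    dos = raw[:, :, 0].astype(np.int16) + raw[:, :, 1].astype(np.int16)
    dos[(raw == MISSING).any(axis=2)] = MISSING
    return GenotypeMatrix(individuals, markers, dos.astype(np.int8))


def write_vcf(data, path) -> None:
    """Write a GenotypeMatrix (unphased) or PhasedGenotypes (phased) VCF."""
    phased = isinstance(data, PhasedGenotypes)
    markers = data.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=founderhap\n")
        for c in markers.chromosomes:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(data.individuals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        if phased:
            alle = data.alleles
        else:
            dos = data.dosage
        gt_unphased = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(markers.n_markers):
            row = [
                str(markers.chromosome[j]),
                str(markers.position_bp[j]),
                str(markers.marker_id[j]),
                "A",
                "G",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            if phased:
                for i in range(data.n_individuals):
                    a0, a1 = alle[i, j]
                    row.append(".|." if a0 == MISSING else f"{a0}|{a1}")
            else:
                for i in range(data.n_individuals):
                    row.append(gt_unphased[int(dos[i, j])])
            fh.write("\t".join(row) + "\n")


def _read_dosage_matrix(path) -> GenotypeMatrix:
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith(DOSAGE_HEADER):
            raise ValueError(
                f"{path}: line 1: dosage matrix must declare its coding "
                f"({DOSAGE_HEADER!r})"
            )
        map_path = None
        for part in first.split()[1:]:
            if part.startswith("map="):
                map_path = part[4:]
        df = pd.read_csv(fh, dtype={"individual": str})
    marker_ids = [c for c in df.columns if c != "individual"]
    if map_path is None:
        markers = MarkerMap(marker_ids, ["0"] * len(marker_ids), np.arange(1, len(marker_ids) + 1))
    else:
        import os

        markers = read_marker_map(os.path.join(os.path.dirname(str(path)), map_path))
    dos = df[list(markers.marker_id)].to_numpy()
    dos = np.where(pd.isna(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(list(df["individual"]), markers, dos)


def write_dosage_matrix(geno: GenotypeMatrix, path, map_filename: str | None = None) -> None:
    header = DOSAGE_HEADER + (f" map={map_filename}" if map_filename else "")
    df = pd.DataFrame(geno.dosage, columns=list(geno.markers.marker_id))
    df.insert(0, "individual", geno.individuals)
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_pedigree(path, founders=None) -> Pedigree:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"id", "mother", "father"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: pedigree file needs columns id,mother,father")
    return Pedigree(list(df["id"]), list(df["mother"]), list(df["father"]), founders=founders)


def write_pedigree(ped: Pedigree, path) -> None:
    df = pd.DataFrame(
        {
            "id": ped.ids,
            "mother": [ped.mother_of(i) or "" for i in ped.ids],
            "father": [ped.father_of(i) or "" for i in ped.ids],
        }
    )
    df.to_csv(path, index=False)


def write_founder_assignment(fa: FounderAssignment, path) -> None:
    """Delimited label matrix: one row per individual, two columns per marker."""
    cols: list[str] = []
    for m in fa.markers.marker_id:
        cols.extend((f"{m}_1", f"{m}_2"))
    flat = fa.labels.reshape(len(fa.individuals), -1)
    df = pd.DataFrame(flat, columns=cols)
    df.insert(0, "individual", fa.individuals)
    df.to_csv(path, index=False)


def read_founder_assignment(path, markers: MarkerMap, n_founders: int) -> FounderAssignment:
    df = pd.read_csv(path, dtype={"individual": str})
    cols: list[str] = []
    for m in markers.marker_id:
        cols.extend((f"{m}_1", f"{m}_2"))
    labels = df[cols].to_numpy(dtype=np.int16).reshape(len(df), markers.n_markers, 2)
    return FounderAssignment(list(df["individual"]), markers, labels, n_founders)


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"individual": str, "trait": str})
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.df.to_csv(path, index=False)
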