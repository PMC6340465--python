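"""Reading and writing the on-disk formats: VCF, metadata TSV, depth and
truth tables.

VCF handling is intentionally narrow: phased, biallelic SNPs for a known
sample set. Anything else is skipped (with a count) or raises. Reading
goes through cyvcf2 so both plain and bgzip files work; writing emits
plain VCF 4.2 text with deterministic formatting.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import (MISSING, HaplotypeMatrix, MetadataTable,
                        SampleMetadata, Sex, Species, Window)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> MetadataTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    return MetadataTable(
        SampleMetadata(r.sample_id, Species(r.species), Sex(r.sex))
        for r in df.itertuples())


def write_metadata(metadata: MetadataTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies\tsex\n")
        for r in metadata:
            fh.write(f"{r.sample_id}\t{r.species.value}\t{r.sex.value}\n")


def _hap_ids_for(metadata: MetadataTable, sample_ids: Sequence[str]) -> list[str]:
    """Haplotype columns: two per diploid sample, one for the outgroup."""
    out = []
    for s in sample_ids:
        if metadata[s].species is Species.outgroup:
            out.append(f"{s}_A")
        else:
            out.extend((f"{s}_A", f"{s}_B"))
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, metadata: MetadataTable, region: Window | None = None,
             allow_unphased: bool = False) -> HaplotypeMatrix:
    """Load phased biallelic SNPs for the samples listed in ``metadata``.

    Returns a HaplotypeMatrix whose ancestral_state column is the outgroup
    sample's allele when the metadata contains an outgroup, else the REF
    allele (0). Non-SNP / multi-allelic records are skipped and counted in
    the result's ``skipped_records`` attribute. Unphased heterozygous
    genotypes raise unless ``allow_unphased``; then the written order is
    kept and the site index is recorded in ``unphased_sites``.
    """
    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    for s in metadata.sample_ids:
        if s not in vcf_samples:
            raise ValueError(f"sample {s!r} missing from VCF header")
    col_of = {s: i for i, s in enumerate(vcf_samples)}
    sample_ids = metadata.sample_ids
    hap_ids = _hap_ids_for(metadata, sample_ids)

    positions: list[int] = []
    rows: list[np.ndarray] = []
    refs: list[str] = []
    alts: list[str] = []
    unphased_sites: list[int] = []
    skipped = 0
    chrom = None
    for v in vcf:
        if region is not None and v.CHROM != region.chromosome:
            continue
        pos0 = v.POS - 1
        if region is not None and not (region.start <= pos0 < region.end):
            continue
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        if chrom is None:
            chrom = v.CHROM
        elif v.CHROM != chrom:
            raise ValueError(
                f"multiple chromosomes in input ({chrom}, {v.CHROM}); "
                "read one chromosome or pass a region")
        gts = v.genotypes  # [allele0, allele1, phased] per sample
        row = np.empty(len(hap_ids), dtype=np.int8)
        j = 0
        for s in sample_ids:
            g = gts[col_of[s]]
            a0 = MISSING if g[0] < 0 else np.int8(g[0])
            if metadata[s].species is Species.outgroup:
                row[j] = a0
                j += 1
                continue
            a1 = MISSING if g[1] < 0 else np.int8(g[1])
            if not g[2] and a0 != a1:
                if not allow_unphased:
                    raise ValueError(
                        f"unphased heterozygote for {s} at {v.CHROM}:{v.POS}")
                if not unphased_sites or unphased_sites[-1] != len(positions):
                    unphased_sites.append(len(positions))
            row[j], row[j + 1] = a0, a1
            j += 2
        positions.append(pos0)
        rows.append(row)
        refs.append(v.REF)
        alts.append(v.ALT[0])
    vcf.close()
    if skipped:
        logger.info("skipped %d non-biallelic-SNP records", skipped)

    alleles = (np.vstack(rows) if rows
               else np.empty((0, len(hap_ids)), dtype=np.int8))
    pos_arr = np.asarray(positions, dtype=np.int64)

    out_samples = metadata.select(species=Species.outgroup)
    if out_samples:
        out_col = hap_ids.index(f"{out_samples[0]}_A")
        ancestral = alleles[:, out_col].copy()
        logger.info("ancestral state taken from outgroup sample %s",
                    out_samples[0])
    else:
        ancestral = np.zeros(len(pos_arr), dtype=np.int8)
        logger.info("no outgroup sample: ancestral state = REF allele")

    hm = HaplotypeMatrix(chrom or (region.chromosome if region else "unknown"),
                         pos_arr, alleles, hap_ids, ancestral,
                         ref=refs, alt=alts)
    hm.skipped_records = skipped
    hm.unphased_sites = unphased_sites
    return hm


def write_vcf_multi(haps: Sequence[HaplotypeMatrix], metadata: MetadataTable,
                    path, extra_header: Sequence[str] = ()) -> None:
    """Write one plain phased VCF 4.2 (byte-stable formatting) covering one
    or more chromosomes, one HaplotypeMatrix each, in the order given."""
    if not haps:
        raise ValueError("no haplotype matrices to write")
    first = haps[0]
    sample_ids = [s for s in metadata.sample_ids
                  if f"{s}_A" in set(first.hap_ids)]

    def fmt(a: int) -> str:
        return "." if a < 0 else str(int(a))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for hap in haps:
            fh.write(f"##contig=<ID={hap.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for hap in haps:
            if hap.hap_ids != first.hap_ids:
                raise ValueError("all chromosomes must share haplotype columns")
            cols = {s: [hap.hap_ids.index(f"{s}_A")] for s in sample_ids}
            for s in sample_ids:
                if metadata[s].species is not Species.outgroup:
                    cols[s].append(hap.hap_ids.index(f"{s}_B"))
            A = hap.alleles
            for i in range(hap.n_sites):
                gts = []
                for s in sample_ids:
                    c = cols[s]
                    if len(c) == 1:
                        gts.append(fmt(A[i, c[0]]))
                    else:
                        gts.append(f"{fmt(A[i, c[0]])}|{fmt(A[i, c[1]])}")
                fh.write(f"{hap.chromosome}\t{hap.positions[i] + 1}\t.\t"
                         f"{hap.ref[i]}\t{hap.alt[i]}\t.\tPASS\t.\tGT\t"
                         + "\t".join(gts) + "\n")


def write_vcf(hap: HaplotypeMatrix, metadata: MetadataTable, path,
              extra_header: Sequence[str] = ()) -> None:
    """Write a single-chromosome plain phased VCF 4.2."""
    write_vcf_multi([hap], metadata, path, extra_header)


def write_haploid_vcf(hap: HaplotypeMatrix, path,
                      extra_header: Sequence[str] = ()) -> None:
    """Write every haplotype column as its own haploid VCF sample.

    Used for rebuilt X/Y haplotypes, whose columns (``<male>_X`` /
    ``<male>_Y``) are synthetic chromosomes rather than diploid samples.
    """
    def fmt(a: int) -> str:
        return "." if a < 0 else str(int(a))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={hap.chromosome}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for line in extra_header:
            fh.write(line.rstrip("\n") + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(hap.hap_ids) + "\n")
        A = hap.alleles
        for i in range(hap.n_sites):
            fh.write(f"{hap.chromosome}\t{hap.positions[i] + 1}\t.\t"
                     f"{hap.ref[i]}\t{hap.alt[i]}\t.\tPASS\t.\tGT\t"
                     + "\t".join(fmt(A[i, j]) for j in range(A.shape[1]))
                     + "\n")


# ---------------------------------------------------------------------------
# depth table & truth table
# ---------------------------------------------------------------------------

def read_depth_table(path) -> pd.DataFrame:
    """Long-format per-window per-sample mean depth.

    Columns: chrom, start, end, sample_id, depth (0-based half-open).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "sample_id", "depth"}
    if not required.issubset(df.columns):
        raise ValueError(f"depth table must have columns {sorted(required)}")
    return df


def write_truth_table(path, window_classes: Sequence[tuple[int, str]],
                      y_haps: dict[str, str]) -> None:
    """Simulation ground truth: window class labels and per-male Y haplotype."""
    with open(path, "w") as fh:
        fh.write("#windows\nwindow_index\tclass\n")
        for idx, cls in window_classes:
            fh.write(f"{idx}\t{cls}\n")
        fh.write("#y_haplotypes\nsample_id\ty_hap\n")
        for sid in sorted(y_haps):
            fh.write(f"{sid}\t{y_haps[sid]}\n")


def read_truth_table(path) -> tuple[list[tuple[int, str]], dict[str, str]]:
    window_classes: list[tuple[int, str]] = []
    y_haps: dict[str, str] = {}
    section = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                section = line[1:]
                continue
            a, b = line.split("\t")
            if a in ("window_index", "sample_id"):
                continue
            if section == "windows":
                window_classes.append((int(a), b))
            elif section == "y_haplotypes":
                y_haps[a] = b
            else:
                raise ValueError(f"truth table line outside a section: {line!r}")
    return window_classes, y_haps
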