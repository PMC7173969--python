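"""Readers/writers: phased VCF in, VCF/TSV/BED out.

Reading goes through cyvcf2; only biallelic SNPs with phased diploid GTs are
accepted. Writing produces a minimal VCF 4.2 text file that round-trips
through :func:`read_vcf` (genotypes, positions and sample order preserved).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datamodel import MISSING, HaplotypeMatrix, PopulationMap, haplotype_index

log = logging.getLogger(__name__)


def read_vcf(path, popmap: PopulationMap, force_haploidize: bool = False):
    """Load phased biallelic SNPs for all mapped samples.

    Returns (HaplotypeMatrix, per-population haplotype index). Samples in
    the VCF but absent from the map are dropped; a mapped sample missing
    from the VCF is an error. Non-biallelic / non-SNP records are skipped
    (count logged). Unphased genotypes raise unless `force_haploidize`,
    in which case the two alleles are taken in file order.
    """
    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    wanted = popmap.sample_ids
    missing = [s for s in wanted if s not in vcf_samples]
    if missing:
        raise KeyError(f"samples in population map absent from VCF: {missing}")
    cols = np.array([vcf_samples.index(s) for s in wanted])

    rows, positions, scaffolds, ref_alt = [], [], [], []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            n_skipped += 1
            continue
        gts = np.asarray(v.genotype.array())[cols]  # (N, 3): a1, a2, phased
        if not force_haploidize and np.any((gts[:, 2] == 0) & (gts[:, 0] >= 0)):
            bad = wanted[int(np.flatnonzero((gts[:, 2] == 0) & (gts[:, 0] >= 0))[0])]
            raise ValueError(
                f"unphased genotype at {v.CHROM}:{v.POS} (sample {bad}); "
                "pass force_haploidize=True to accept allele order as given"
            )
        h = gts[:, :2].astype(np.int8).reshape(-1)
        h[h < 0] = MISSING
        rows.append(h)
        positions.append(v.POS)
        scaffolds.append(v.CHROM)
        ref_alt.append((v.REF, v.ALT[0]))
    if n_skipped:
        log.info("read_vcf: skipped %d non-biallelic/non-SNP records", n_skipped)
    if not rows:
        raise ValueError(f"no biallelic SNPs found in {path}")
    matrix = HaplotypeMatrix(
        alleles=np.stack(rows, axis=1),
        positions=np.array(positions),
        scaffold=np.array(scaffolds, dtype=object),
        ref_alt=np.array(ref_alt, dtype=object),
        sample_ids=list(wanted),
    )
    return matrix, haplotype_index(matrix, popmap)


def write_vcf(matrix: HaplotypeMatrix, path, scaffold_lengths: dict | None = None):
    """Write the matrix as a phased VCF 4.2 text file."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=migrascan\n")
        for scaf in matrix.scaffolds():
            length = (
                int(scaffold_lengths[scaf])
                if scaffold_lengths
                else int(matrix.positions[matrix.scaffold == scaf].max())
            )
            fh.write(f"##contig=<ID={scaf},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        sym = {0: "0", 1: "1", MISSING: "."}
        for j in range(matrix.n_sites):
            col = matrix.alleles[:, j]
            gts = "\t".join(
                f"{sym[int(col[2*i])]}|{sym[int(col[2*i+1])]}"
                for i in range(matrix.n_samples)
            )
            fh.write(
                f"{matrix.scaffold[j]}\t{matrix.positions[j]}\t.\t"
                f"{matrix.ref_alt[j][0]}\t{matrix.ref_alt[j][1]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_window_table(windows, values: dict, path):
    """Window TSV: scaffold, start, end plus one column per statistic."""
    df = windows.table.copy()
    for name, v in values.items():
        df[name] = v
    df.to_csv(path, sep="\t", index=False)


def write_regions_bed(regions, path):
    """Regions as BED6 (name=statistic:population, score=peak x1000, clamped)."""
    with open(path, "w") as fh:
        for r in regions:
            fh.write(r.to_bed6() + "\n")


def write_ancestral_table(matrix: HaplotypeMatrix, calls, path):
    """Per-site ancestral table TSV: scaffold, pos, ancestral, reason."""
    df = pd.DataFrame(
        {
            "scaffold": matrix.scaffold,
            "pos": matrix.positions,
            "ancestral": calls.ancestral,
            "reason": calls.reason,
        }
    )
    df.to_csv(path, sep="\t", index=False)
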