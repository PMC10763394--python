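"""Read, validate and filter the genotype panel.

The analysis set is defined the way common resequencing pipelines define
it: biallelic SNPs only, minor allele frequency strictly above a cutoff
(default 0.05) and per-site call rate strictly above a cutoff (default
0.9).  MAF is computed over non-missing alleles; call rate is called
genotypes over samples.
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .panel import MISSING, GenotypePanel, PopulationMap  # noqa: F401  (re-export)
from .synthetic import write_vcf  # noqa: F401  (re-export: the panel writer)

logger = logging.getLogger(__name__)

MAF_MIN_DEFAULT = 0.05
CALL_RATE_MIN_DEFAULT = 0.9


def read_vcf(path) -> GenotypePanel:
    """Load a VCF into a :class:`GenotypePanel`.

    Multiallelic and non-SNP records are skipped (count logged).  Phase
    is captured only if every genotype separator in the file is ``|``;
    otherwise the panel is unphased.

    Raises
    ------
    ValueError
        If the VCF has no GT format field, or positions are not strictly
        increasing within a chromosome.
    """
    vcf = VCF(str(path), gts012=True)
    if "##FORMAT=<ID=GT" not in vcf.raw_header and "FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    samples = list(vcf.samples)
    n_sam = len(samples)

    chrom, pos, ref, alt = [], [], [], []
    gcols, h0cols, h1cols = [], [], []
    all_phased = True
    skipped = 0
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or not v.is_snp:
            skipped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(
                f"{path}: positions not strictly increasing at {v.CHROM}:{v.POS}"
            )
        last[v.CHROM] = v.POS
        gts = v.genotype.array()  # (n_sam, 3): allele0, allele1, phased flag
        a0 = gts[:, 0].astype(np.int16)
        a1 = gts[:, 1].astype(np.int16)
        phased_flags = gts[:, 2] != 0
        called = (a0 >= 0) & (a1 >= 0)
        if not np.all(phased_flags[called]) and called.any():
            all_phased = False
        g = np.where(called, a0 + a1, MISSING).astype(np.int8)
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        gcols.append(g)
        h0cols.append(np.where(called, a0, MISSING).astype(np.int8))
        h1cols.append(np.where(called, a1, MISSING).astype(np.int8))
    if skipped:
        logger.info("read_vcf: skipped %d multiallelic/non-SNP records", skipped)
    n_sites = len(pos)
    genotypes = (np.stack(gcols, axis=1) if n_sites
                 else np.empty((n_sam, 0), dtype=np.int8))
    haplotypes = None
    if all_phased and n_sites:
        haplotypes = np.empty((n_sam, 2, n_sites), dtype=np.int8)
        haplotypes[:, 0, :] = np.stack(h0cols, axis=1)
        haplotypes[:, 1, :] = np.stack(h1cols, axis=1)
    panel = GenotypePanel(
        samples=samples,
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
        genotypes=genotypes,
        haplotypes=haplotypes,
    )
    panel.skipped_records = skipped  # type: ignore[attr-defined]
    return panel


def filter_variants(
    panel: GenotypePanel,
    maf_min: float = MAF_MIN_DEFAULT,
    call_rate_min: float = CALL_RATE_MIN_DEFAULT,
) -> GenotypePanel:
    """Retain sites with MAF > ``maf_min`` and call rate > ``call_rate_min``.

    Both inequalities are strict.  MAF is computed from non-missing
    alleles only; a site with zero called genotypes is removed.  Returns
    a new panel; the input is untouched.
    """
    if panel.n_sites == 0:
        raise ValueError("cannot filter an empty panel")
    maf = panel.maf()
    cr = panel.call_rate()
    keep = np.flatnonzero(
        np.nan_to_num(maf, nan=-1.0) > maf_min,
    )
    keep = keep[cr[keep] > call_rate_min]
    if len(keep) == 0:
        raise ValueError(
            f"all {panel.n_sites} sites removed by maf_min={maf_min}, "
            f"call_rate_min={call_rate_min}; relax the thresholds"
        )
    logger.info("filter_variants: kept %d of %d sites", len(keep), panel.n_sites)
    return panel.take_sites(keep)
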