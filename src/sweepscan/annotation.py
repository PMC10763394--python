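"""Region and SNP annotation against a GFF3 gene set and reference FASTA.

Three functional layers: gene-span overlap for candidate regions,
per-SNP region classes (intergenic / intronic / exonic, with coding
SNPs split into synonymous and nonsynonymous by strand-aware codon
translation), and interval overlap with chromatin-accessibility peaks
(BED) for regulatory context.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import gffutils
from Bio.Seq import Seq
from intervaltree import IntervalTree
from pyfaidx import Fasta

logger = logging.getLogger(__name__)


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    transcripts: dict[str, dict] = field(default_factory=dict)
    # per transcript: {"exons": [(start0, end0)...], "cds": [(start0, end0, frame)...]}


class GenomeAnnotation:
    """Parsed GFF3 gene models with per-chromosome interval indexes."""

    def __init__(self, gff_path):
        db = gffutils.create_db(
            str(gff_path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        self.genes: dict[str, GeneModel] = {}
        self.gene_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.cds_trees: dict[str, IntervalTree] = {}
        for g in db.features_of_type("gene"):
            gm = GeneModel(
                gene_id=g.id, chrom=g.seqid,
                start=g.start - 1, end=g.end, strand=g.strand,
            )
            for t in db.children(g, featuretype=("mRNA", "transcript")):
                exons = sorted(
                    (e.start - 1, e.end) for e in db.children(t, featuretype="exon")
                )
                cds = sorted(
                    (c.start - 1, c.end, int(c.frame) if c.frame != "." else 0)
                    for c in db.children(t, featuretype="CDS")
                )
                gm.transcripts[t.id] = {"exons": exons, "cds": cds}
            self.genes[gm.gene_id] = gm
            self.gene_trees.setdefault(gm.chrom, IntervalTree())[gm.start:gm.end] = gm.gene_id
            for tid, tr in gm.transcripts.items():
                for a, b in tr["exons"]:
                    self.exon_trees.setdefault(gm.chrom, IntervalTree())[a:b] = (gm.gene_id, tid)
                for a, b, _ in tr["cds"]:
                    self.cds_trees.setdefault(gm.chrom, IntervalTree())[a:b] = (gm.gene_id, tid)

    def chromosomes(self) -> set[str]:
        return set(self.gene_trees)


def genes_in_regions(regions, annotation: GenomeAnnotation) -> dict[tuple, list[str]]:
    """Genes whose span intersects each region (half-open interval overlap).

    ``regions`` are ``(chrom, start0, end0)`` triples or objects with
    those attributes.  Raises if no region chromosome matches any
    annotation chromosome.
    """
    triples = [
        (r.chrom, r.start, r.end) if hasattr(r, "chrom") else tuple(r)
        for r in regions
    ]
    if triples:
        region_chroms = {t[0] for t in triples}
        if not region_chroms & annotation.chromosomes():
            raise ValueError(
                f"no shared chromosome names: regions use {sorted(region_chroms)}, "
                f"annotation uses {sorted(annotation.chromosomes())}"
            )
    out = {}
    for chrom, start, end in triples:
        tree = annotation.gene_trees.get(chrom)
        hits = sorted(iv.data for iv in tree[start:end]) if tree is not None else []
        out[(chrom, start, end)] = hits
    return out


def unique_genes(region_genes: dict[tuple, list[str]]) -> list[str]:
    """Every gene hit by at least one region, counted once genome-wide."""
    seen: dict[str, None] = {}
    for genes in region_genes.values():
        for g in genes:
            seen.setdefault(g, None)
    return list(seen)


# ----------------------------------------------------------------------
# SNP classification


def _codon_change(annotation, fasta, gm, tid, chrom, pos0, ref, alt):
    """(ref_aa, alt_aa) for a CDS SNP in one transcript, or None if the
    transcript is unusable (CDS length not divisible by three)."""
    tr = annotation.genes[gm].transcripts[tid]
    cds = tr["cds"]
    total = sum(b - a for a, b, _ in cds)
    if total % 3 != 0:
        warnings.warn(
            f"transcript {tid}: CDS length {total} not divisible by 3; skipped",
            stacklevel=2,
        )
        return None
    spliced = "".join(str(fasta[chrom][a:b]) for a, b, _ in cds).upper()
    offset = 0
    within = None
    for a, b, _ in cds:
        if a <= pos0 < b:
            within = offset + (pos0 - a)
            break
        offset += b - a
    if within is None:
        return None
    if spliced[within] != ref.upper():
        raise ValueError(
            f"reference base mismatch at {chrom}:{pos0 + 1}: "
            f"FASTA has {spliced[within]}, site says {ref}"
        )
    strand = annotation.genes[gm].strand
    if strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
        within = total - 1 - within
        ref_c = str(Seq(ref).reverse_complement())
        alt_c = str(Seq(alt).reverse_complement())
    else:
        ref_c, alt_c = ref.upper(), alt.upper()
    ci = (within // 3) * 3
    codon = spliced[ci:ci + 3]
    k = within - ci
    alt_codon = codon[:k] + alt_c + codon[k + 1:]
    return str(Seq(codon).translate()), str(Seq(alt_codon).translate())


def classify_snp(
    site: tuple[str, int, str, str],
    annotation: GenomeAnnotation,
    fasta: Fasta,
) -> str:
    """Region class of one SNP: ``intergenic``, ``intronic``,
    ``exonic_noncoding``, ``synonymous`` or ``nonsynonymous``.

    ``site`` is (chrom, 1-based pos, ref, alt).  Precedence across
    overlapping transcripts is exonic > intronic > intergenic; within
    exonic, nonsynonymous > synonymous > non-coding.
    """
    chrom, pos, ref, alt = site
    pos0 = pos - 1
    cds_hits = annotation.cds_trees.get(chrom, IntervalTree())[pos0]
    effects = set()
    for iv in sorted(cds_hits, key=lambda v: v.data):
        gm, tid = iv.data
        change = _codon_change(annotation, fasta, gm, tid, chrom, pos0, ref, alt)
        if change is not None:
            effects.add("nonsynonymous" if change[0] != change[1] else "synonymous")
    if "nonsynonymous" in effects:
        return "nonsynonymous"
    if "synonymous" in effects:
        return "synonymous"
    if annotation.exon_trees.get(chrom, IntervalTree())[pos0]:
        return "exonic_noncoding"
    if annotation.gene_trees.get(chrom, IntervalTree())[pos0]:
        return "intronic"
    return "intergenic"


def classify_panel(panel, annotation: GenomeAnnotation, fasta: Fasta) -> dict[str, int]:
    """Class counts over every site of a panel."""
    counts: dict[str, int] = {}
    for j in range(panel.n_sites):
        c = classify_snp(
            (panel.chrom[j], int(panel.pos[j]), panel.ref[j], panel.alt[j]),
            annotation, fasta,
        )
        counts[c] = counts.get(c, 0) + 1
    return counts


# ----------------------------------------------------------------------
# peak overlap


def read_bed(path) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees from a BED file (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has < 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty or inverted interval")
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            trees.setdefault(parts[0], IntervalTree())[start:end] = name
    return trees


def peak_overlap(regions, peaks: dict[str, IntervalTree]) -> list[dict]:
    """Per-region overlap with a peak track: total bp, fraction, peak ids."""
    out = []
    for r in regions:
        chrom, start, end = (
            (r.chrom, r.start, r.end) if hasattr(r, "chrom") else tuple(r)
        )
        tree = peaks.get(chrom, IntervalTree())
        bp = 0
        ids = []
        for iv in sorted(tree[start:end]):
            bp += min(end, iv.end) - max(start, iv.begin)
            ids.append(iv.data)
        out.append({
            "chrom": chrom, "start": start, "end": end,
            "overlap_bp": bp,
            "overlap_fraction": bp / (end - start) if end > start else 0.0,
            "peaks": ids,
        })
    return out
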