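"""Synthetic multi-breed genotype panels with planted, known structure.

The generator emulates the shape of a multi-breed resequencing panel:
several breeds drawn from a common ancestral gene pool with breed-level
drift, an optional selective-sweep haplotype fixed in designated breeds,
optional long autozygosity tracts in designated samples, and random
genotype missingness.  Because every feature is planted, downstream
statistics (windowed Fst, XP-EHH, LSBL, ROH) can be checked against the
exact truth records the generator returns.

Drift model
-----------
Per-site ancestral allele frequencies are drawn uniformly from a
configurable range, and each breed's frequency is drawn from the
Balding-Nichols Beta distribution

    p_breed ~ Beta(p(1-F)/F, (1-p)(1-F)/F)

whose mean is the ancestral ``p`` and whose differentiation parameter
``F`` equals the expected Weir-Cockerham Fst between breeds — giving a
closed-form oracle for estimator tests.  Haplotypes are sampled i.i.d.
from the breed frequency; there is no recombination map, so extended
haplotype homozygosity decays through haplotype diversity alone, which
is what creates the contrast between a swept (homogeneous) region and a
neutral (diverse) background.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .panel import MISSING, GenotypePanel, PopulationMap

_BASES = np.array(list("ACGT"))


@dataclass
class SweepTruth:
    """A planted sweep: a haplotype fixed in the designated breeds.

    ``start``/``end`` are 0-based half-open base-pair coordinates.  After
    generation (before missingness), every haplotype of every sample in a
    swept breed equals ``swept_haplotype`` over the sweep sites.
    """

    chrom: str
    start: int
    end: int
    swept_breeds: tuple[str, ...]
    swept_haplotype: str | None = None  # filled at generation if None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("sweep interval must satisfy end > start")
        self.swept_breeds = tuple(self.swept_breeds)


@dataclass
class SimConfig:
    """Parameters of one synthetic panel.

    samples_per_breed gives each breed's diploid sample count; drift_F is
    the per-breed Balding-Nichols differentiation parameter (a scalar is
    broadcast to all breeds).  roh_spec plants homozygous tracts as
    ``(sample, chrom, start0, end0)`` half-open bp intervals.
    """

    n_breeds: int
    samples_per_breed: list[int]
    n_chromosomes: int = 1
    chrom_length: int = 2_000_000
    snp_density: float = 1 / 1000.0  # SNPs per bp
    drift_F: float | list[float] = 0.05
    breed_names: list[str] | None = None
    breed_groups: dict[str, str] = field(default_factory=dict)
    sweep_spec: SweepTruth | None = None
    roh_spec: list[tuple[str, str, int, int]] = field(default_factory=list)
    missing_rate: float = 0.0
    freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.samples_per_breed) != self.n_breeds:
            raise ValueError("samples_per_breed must have n_breeds entries")
        if sum(self.samples_per_breed) <= 0:
            raise ValueError("need at least one sample")
        if self.chrom_length <= 0:
            raise ValueError("chrom_length must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if np.isscalar(self.drift_F):
            self.drift_F = [float(self.drift_F)] * self.n_breeds
        if len(self.drift_F) != self.n_breeds:
            raise ValueError("drift_F must be scalar or one value per breed")
        for f in self.drift_F:
            if not 0.0 < f < 1.0:
                raise ValueError("each drift_F must lie in (0, 1)")
        if self.breed_names is None:
            self.breed_names = [f"breed_{i + 1}" for i in range(self.n_breeds)]
        if len(self.breed_names) != self.n_breeds:
            raise ValueError("breed_names must have n_breeds entries")

    def population_map(self) -> PopulationMap:
        sample_breed = {}
        for b, n in zip(self.breed_names, self.samples_per_breed):
            for k in range(n):
                sample_breed[f"{b}_s{k + 1}"] = b
        return PopulationMap(sample_breed, dict(self.breed_groups))


def _draw_positions(rng: np.random.Generator, length: int, n: int) -> np.ndarray:
    """n distinct sorted 1-based positions, uniform on [1, length]."""
    if n > length:
        raise ValueError("more SNPs requested than base pairs")
    pool = np.unique(rng.integers(1, length + 1, size=min(length, 3 * n + 16)))
    while len(pool) < n:
        extra = rng.integers(1, length + 1, size=2 * n)
        pool = np.unique(np.concatenate([pool, extra]))
    keep = rng.choice(len(pool), size=n, replace=False)
    return np.sort(pool[keep])


def simulate_panel(
    config: SimConfig,
) -> tuple[GenotypePanel, SweepTruth | None, list[tuple[str, str, int, int]]]:
    """Generate a phased panel plus the truth records of planted features.

    Returns ``(panel, sweep_truth, planted_roh)``; the truth objects refer
    to the pre-missingness state (masking is applied last).  Identical
    configs (including the seed) produce byte-identical panels.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.population_map()
    samples = list(pops.sample_breed)
    n_sam = len(samples)

    chrom_names = [str(c + 1) for c in range(config.n_chromosomes)]
    n_per_chrom = max(1, int(round(config.chrom_length * config.snp_density)))

    chrom_col, pos_col = [], []
    for c in chrom_names:
        p = _draw_positions(rng, config.chrom_length, n_per_chrom)
        chrom_col.append(np.full(len(p), c, dtype=object))
        pos_col.append(p)
    chrom = np.concatenate(chrom_col)
    pos = np.concatenate(pos_col)
    n_sites = len(pos)

    lo, hi = config.freq_range
    p_anc = rng.uniform(lo, hi, size=n_sites)

    ref_i = rng.integers(0, 4, size=n_sites)
    alt_i = (ref_i + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)

    haps = np.empty((n_sam, 2, n_sites), dtype=np.int8)
    row = 0
    for b, n_b, F in zip(config.breed_names, config.samples_per_breed, config.drift_F):
        a = p_anc * (1.0 - F) / F
        bpar = (1.0 - p_anc) * (1.0 - F) / F
        p_breed = rng.beta(a, bpar)
        draws = rng.random((n_b, 2, n_sites)) < p_breed
        haps[row:row + n_b] = draws.astype(np.int8)
        row += n_b

    # plant the sweep haplotype: overwrite every chromosome of every
    # swept-breed sample over the sweep sites
    sweep = config.sweep_spec
    if sweep is not None:
        unknown = set(sweep.swept_breeds) - set(config.breed_names)
        if unknown:
            raise ValueError(f"swept breeds not in panel: {sorted(unknown)}")
        if sweep.chrom not in chrom_names or sweep.end > config.chrom_length:
            raise ValueError(
                f"sweep interval {sweep.chrom}:{sweep.start}-{sweep.end} outside "
                f"simulated coordinates"
            )
        in_sweep = (chrom == sweep.chrom) & (pos - 1 >= sweep.start) & (pos - 1 < sweep.end)
        sweep_idx = np.flatnonzero(in_sweep)
        if sweep.swept_haplotype is None:
            hap_alleles = rng.integers(0, 2, size=len(sweep_idx)).astype(np.int8)
        else:
            if len(sweep.swept_haplotype) != len(sweep_idx):
                raise ValueError(
                    f"swept_haplotype has {len(sweep.swept_haplotype)} alleles but the "
                    f"interval contains {len(sweep_idx)} sites"
                )
            hap_alleles = np.array([int(x) for x in sweep.swept_haplotype], dtype=np.int8)
        sam_idx = [
            i for i, s in enumerate(samples) if pops.sample_breed[s] in sweep.swept_breeds
        ]
        for i in sam_idx:
            haps[i, 0, sweep_idx] = hap_alleles
            haps[i, 1, sweep_idx] = hap_alleles
        sweep = SweepTruth(
            chrom=sweep.chrom, start=sweep.start, end=sweep.end,
            swept_breeds=sweep.swept_breeds,
            swept_haplotype="".join(str(int(x)) for x in hap_alleles),
        )

    # plant autozygosity tracts by copying one haplotype onto the other
    by_sample: dict[str, list[tuple[str, int, int]]] = {}
    for s, c, start, end in config.roh_spec:
        if s not in samples:
            raise ValueError(f"roh_spec sample {s!r} not in panel")
        if c not in chrom_names or end > config.chrom_length or start < 0:
            raise ValueError(f"planted ROH {c}:{start}-{end} outside coordinates")
        for c2, s2, e2 in by_sample.get(s, []):
            if c2 == c and start < e2 and s2 < end:
                raise ValueError(f"overlapping planted ROH for sample {s}")
        by_sample.setdefault(s, []).append((c, start, end))
    sample_row = {s: i for i, s in enumerate(samples)}
    for s, c, start, end in config.roh_spec:
        tract = (chrom == c) & (pos - 1 >= start) & (pos - 1 < end)
        i = sample_row[s]
        haps[i, 1, tract] = haps[i, 0, tract]

    genotypes = haps.sum(axis=1, dtype=np.int8)

    if config.missing_rate > 0:
        mask = rng.random((n_sam, n_sites)) < config.missing_rate
        genotypes[mask] = MISSING
        haps[:, 0, :][mask] = MISSING
        haps[:, 1, :][mask] = MISSING

    panel = GenotypePanel(
        samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
        genotypes=genotypes, haplotypes=haps,
    )
    return panel, sweep, list(config.roh_spec)


# ----------------------------------------------------------------------
# fixture writing


def write_vcf(
    panel: GenotypePanel,
    path,
    contig_lengths: dict[str, int] | None = None,
    phased: bool = True,
) -> None:
    """Write the panel as a plain-text VCFv4.2 with GT genotypes.

    ``phased=False`` exports with ``/`` separators (losing phase), which
    downstream haplotype-based operations must reject.
    """
    if phased and not panel.is_phased:
        raise ValueError("panel has no haplotypes; use phased=False")
    sep = "|" if phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan-synthetic\n")
        lengths = contig_lengths or {}
        for c in panel.chromosomes():
            length = lengths.get(c, int(panel.pos[panel.chrom == c].max()))
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples) + "\n")
        for j in range(panel.n_sites):
            if panel.is_phased:
                a0 = panel.haplotypes[:, 0, j]
                a1 = panel.haplotypes[:, 1, j]
            else:
                g = panel.genotypes[:, j]
                a0 = np.where(g == MISSING, MISSING, (g == 2).astype(np.int8))
                a1 = np.where(g == MISSING, MISSING, (g >= 1).astype(np.int8))
            gts = [
                "." + sep + "." if x == MISSING else f"{x}{sep}{y}"
                for x, y in zip(a0, a1)
            ]
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t.\t{panel.ref[j]}\t{panel.alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_toy_gff3(chrom_lengths: dict[str, int], path, n_genes_per_chrom: int = 20) -> None:
    """A deterministic toy annotation: genes tiling each chromosome.

    Each tile holds one plus-strand gene covering the first 60% of the
    tile, with two exons; the first exon's interior is CDS.  The layout
    guarantees intergenic gaps, introns and coding sequence all exist, so
    SNP classification and region-gene overlap are exercised end to end.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c, length in chrom_lengths.items():
            tile = max(length // n_genes_per_chrom, 300)
            k = 0
            for start in range(0, length - tile + 1, tile):
                k += 1
                gid = f"gene{c}_{k}"
                g1 = start + 1  # GFF3 is 1-based inclusive
                g2 = start + int(tile * 0.6)
                e1a, e1b = g1, g1 + (g2 - g1) // 3
                e2a, e2b = g1 + 2 * (g2 - g1) // 3, g2
                cds_a = e1a
                cds_b = e1a + ((e1b - e1a + 1) // 3) * 3 - 1  # multiple of 3
                fh.write(f"{c}\tsweepscan\tgene\t{g1}\t{g2}\t.\t+\t.\tID={gid}\n")
                fh.write(f"{c}\tsweepscan\tmRNA\t{g1}\t{g2}\t.\t+\t.\t"
                         f"ID={gid}.t1;Parent={gid}\n")
                fh.write(f"{c}\tsweepscan\texon\t{e1a}\t{e1b}\t.\t+\t.\t"
                         f"ID={gid}.e1;Parent={gid}.t1\n")
                fh.write(f"{c}\tsweepscan\texon\t{e2a}\t{e2b}\t.\t+\t.\t"
                         f"ID={gid}.e2;Parent={gid}.t1\n")
                fh.write(f"{c}\tsweepscan\tCDS\t{cds_a}\t{cds_b}\t.\t+\t0\t"
                         f"ID={gid}.c1;Parent={gid}.t1\n")


def write_reference_fasta(
    panel: GenotypePanel, chrom_lengths: dict[str, int], path, seed: int = 0
) -> None:
    """A reference genome consistent with the panel's REF alleles.

    Filler bases are drawn deterministically from ``seed``; each SNP
    position carries the panel's reference allele.
    """
    rng = np.random.default_rng(seed)
    with open(path, "w") as fh:
        for c, length in chrom_lengths.items():
            seq = _BASES[rng.integers(0, 4, size=length)].astype("U1")
            on_c = panel.chrom == c
            seq[panel.pos[on_c] - 1] = np.asarray(panel.ref, dtype=object)[on_c]
            fh.write(f">{c}\n")
            s = "".join(seq)
            for i in range(0, length, 70):
                fh.write(s[i:i + 70] + "\n")


def write_fixture(
    panel: GenotypePanel,
    pops: PopulationMap,
    out_dir,
    sweep: SweepTruth | None = None,
    roh: list[tuple[str, str, int, int]] | None = None,
    chrom_lengths: dict[str, int] | None = None,
    phased: bool = True,
    with_fasta: bool = False,
) -> dict[str, Path]:
    """Write a complete on-disk fixture: VCF, population map, truth JSON, toy GFF3.

    Returns the paths written, keyed by role.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lengths = chrom_lengths or {
        c: int(panel.pos[panel.chrom == c].max()) for c in panel.chromosomes()
    }
    paths = {
        "vcf": out / "panel.vcf",
        "popmap": out / "popmap.tsv",
        "truth": out / "truth.json",
        "gff": out / "genes.gff3",
    }
    write_vcf(panel, paths["vcf"], contig_lengths=lengths, phased=phased)
    pops.write_tsv(paths["popmap"])
    truth = {
        "sweep": None if sweep is None else {
            "chrom": sweep.chrom, "start": sweep.start, "end": sweep.end,
            "swept_breeds": list(sweep.swept_breeds),
            "swept_haplotype": sweep.swept_haplotype,
        },
        "roh": [list(r) for r in (roh or [])],
        "chrom_lengths": lengths,
    }
    paths["truth"].write_text(json.dumps(truth, indent=1))
    write_toy_gff3(lengths, paths["gff"])
    if with_fasta:
        paths["fasta"] = out / "reference.fa"
        write_reference_fasta(panel, lengths, paths["fasta"])
    return paths
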