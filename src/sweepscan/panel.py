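"""Core in-memory containers: the genotype panel and the population map.

A :class:`GenotypePanel` holds biallelic SNP genotypes as an alt-allele
dosage matrix (samples x sites, values 0/1/2, ``-1`` for missing) plus,
when the source data were phased, a haplotype tensor
(samples x 2 x sites, values 0/1, ``-1`` for missing).  Positions are
stored 1-based as read from VCF; every exported interval is 0-based
half-open, and the conversion happens only at I/O boundaries.

A :class:`PopulationMap` assigns each sample to a breed and each breed to
a phenotype group (e.g. ``TEB`` / ``black`` / ``white`` / ``wild``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1

#: Chromosome names excluded from autosomal scans by default.
NON_AUTOSOMES = frozenset({"X", "Y", "MT", "M", "chrX", "chrY", "chrM", "chrMT"})


@dataclass
class GenotypePanel:
    """Biallelic SNP genotypes with site and sample metadata.

    Parameters
    ----------
    samples : list of str
        Ordered sample identifiers.
    chrom : ndarray of str, shape (n_sites,)
        Chromosome name per site.
    pos : ndarray of int, shape (n_sites,)
        1-based physical position per site, strictly increasing within
        each chromosome.
    ref, alt : ndarray of str
        Reference / alternate allele (single bases).
    genotypes : ndarray of int8, shape (n_samples, n_sites)
        Alt-allele dosage 0/1/2, ``MISSING`` (-1) where uncalled.
    haplotypes : ndarray of int8, shape (n_samples, 2, n_sites), optional
        Phased alleles 0/1, ``MISSING`` where uncalled; ``None`` for
        unphased panels.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_phased(self) -> bool:
        return self.haplotypes is not None

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes() if c not in NON_AUTOSOMES]

    def sites_of(self, chrom: str) -> np.ndarray:
        """Indices of the sites on one chromosome."""
        return np.flatnonzero(self.chrom == chrom)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n_sam, n_sites = self.genotypes.shape
        if n_sam != len(self.samples):
            raise ValueError(
                f"genotype matrix has {n_sam} rows but {len(self.samples)} samples"
            )
        for arr, name in ((self.chrom, "chrom"), (self.pos, "pos"),
                          (self.ref, "ref"), (self.alt, "alt")):
            if len(arr) != n_sites:
                raise ValueError(f"{name} has length {len(arr)}, expected {n_sites}")
        for c in set(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                bad = p[np.flatnonzero(np.diff(p) <= 0)[0] + 1]
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c} near pos {bad}"
                )
        g = self.genotypes
        if g.size and (g.min() < MISSING or g.max() > 2):
            raise ValueError("genotype dosages must be in {0,1,2} or -1 (missing)")
        if self.haplotypes is not None:
            h = self.haplotypes
            if h.shape != (n_sam, 2, n_sites):
                raise ValueError(
                    f"haplotype tensor shape {h.shape} != {(n_sam, 2, n_sites)}"
                )
            called = (h[:, 0, :] != MISSING) & (h[:, 1, :] != MISSING)
            dosage = (h[:, 0, :] + h[:, 1, :]).astype(np.int8)
            ok = ~called | (g == dosage)
            if not np.all(ok[g != MISSING]):
                raise ValueError("dosage inconsistent with haplotypes")

    # ------------------------------------------------------------------
    def take_sites(self, idx: np.ndarray) -> "GenotypePanel":
        """New panel restricted to the given site indices (kept in order)."""
        idx = np.asarray(idx)
        return GenotypePanel(
            samples=list(self.samples),
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=np.asarray(self.ref, dtype=object)[idx],
            alt=np.asarray(self.alt, dtype=object)[idx],
            genotypes=self.genotypes[:, idx].copy(),
            haplotypes=None if self.haplotypes is None
            else self.haplotypes[:, :, idx].copy(),
        )

    def take_samples(self, names: list[str]) -> "GenotypePanel":
        order = {s: i for i, s in enumerate(self.samples)}
        idx = np.array([order[s] for s in names])
        return GenotypePanel(
            samples=list(names),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=np.asarray(self.ref, dtype=object).copy(),
            alt=np.asarray(self.alt, dtype=object).copy(),
            genotypes=self.genotypes[idx].copy(),
            haplotypes=None if self.haplotypes is None
            else self.haplotypes[idx].copy(),
        )

    # ------------------------------------------------------------------
    def allele_counts(self, sample_idx: np.ndarray | None = None):
        """(alt allele count, called allele count) per site over a sample subset."""
        g = self.genotypes if sample_idx is None else self.genotypes[sample_idx]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def maf(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Minor allele frequency per site over non-missing alleles (NaN if uncalled).

        Computed from integer allele counts so boundary comparisons
        (e.g. a strict > 0.05 filter) behave identically for reference-
        and alternate-minor sites.
        """
        alt, tot = self.allele_counts(sample_idx)
        minor = np.minimum(alt, tot - alt)
        return np.where(tot > 0, minor / np.maximum(tot, 1), np.nan)

    def call_rate(self) -> np.ndarray:
        """Fraction of samples with a called genotype, per site."""
        return (self.genotypes != MISSING).mean(axis=0)


@dataclass
class PopulationMap:
    """Sample-to-breed and breed-to-group assignments.

    Groups label coat-color phenotype classes used by the three-population
    branch-length design (``TEB``, ``black``, ``white``, ``wild``,
    ``commercial``); any label set is accepted as long as each breed has
    exactly one group.
    """

    sample_breed: dict[str, str]
    breed_group: dict[str, str] = field(default_factory=dict)

    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.sample_breed.values():
            seen.setdefault(b, None)
        return list(seen)

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.sample_breed.items() if b == breed]

    def breeds_of_group(self, group: str) -> list[str]:
        return [b for b in self.breeds() if self.breed_group.get(b) == group]

    def samples_of_group(self, group: str) -> list[str]:
        out = []
        for b in self.breeds_of_group(group):
            out.extend(self.samples_of(b))
        return out

    def breed_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for b in self.sample_breed.values():
            sizes[b] = sizes.get(b, 0) + 1
        return sizes

    def indices(self, panel: GenotypePanel, breeds_or_samples) -> np.ndarray:
        """Panel sample indices for a breed name, group name, or explicit list."""
        if isinstance(breeds_or_samples, str):
            name = breeds_or_samples
            if name in set(self.sample_breed.values()):
                wanted = set(self.samples_of(name))
            elif name in set(self.breed_group.values()):
                wanted = set(self.samples_of_group(name))
            else:
                raise KeyError(f"unknown breed or group: {name!r}")
        else:
            wanted = set(breeds_or_samples)
            unknown = wanted - set(panel.samples)
            if unknown:
                raise KeyError(f"samples not in panel: {sorted(unknown)}")
        return np.array(
            [i for i, s in enumerate(panel.samples) if s in wanted], dtype=np.int64
        )

    def validate_against(self, panel: GenotypePanel) -> None:
        missing = [s for s in panel.samples if s not in self.sample_breed]
        if missing:
            raise ValueError(f"samples without breed assignment: {missing[:5]}")
        if self.breed_group:
            unassigned = [b for b in self.breeds() if b not in self.breed_group]
            if unassigned:
                raise ValueError(f"breeds without group: {unassigned}")

    # ------------------------------------------------------------------
    @classmethod
    def read_tsv(cls, path) -> "PopulationMap":
        """Read a ``sample<TAB>breed[<TAB>group]`` map (no header)."""
        sample_breed: dict[str, str] = {}
        breed_group: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >=2 tab-separated fields")
                sample, breed = parts[0], parts[1]
                sample_breed[sample] = breed
                if len(parts) >= 3:
                    prev = breed_group.get(breed)
                    if prev is not None and prev != parts[2]:
                        raise ValueError(
                            f"{path}:{lineno}: breed {breed} mapped to two groups"
                        )
                    breed_group[breed] = parts[2]
        return cls(sample_breed, breed_group)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s, b in self.sample_breed.items():
                g = self.breed_group.get(b, "")
                fh.write(f"{s}\t{b}\t{g}\n" if g else f"{s}\t{b}\n")
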