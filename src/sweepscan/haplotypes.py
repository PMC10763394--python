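"""Region haplotype analysis: extraction, LD blocks, frequencies, networks.

Given a phased panel and a genomic region (for example the candidate
interval around a coat-color gene), this module extracts the distinct
haplotypes carried by each breed, finds haplotype blocks by the Gabriel
D'-confidence-interval rule, tabulates breed-stratified haplotype
frequencies and homozygous carriers, builds a minimum-spanning network
of the common haplotypes, and computes a chromosome-by-chromosome
allele-sharing matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .panel import MISSING, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class HaplotypeSet:
    """All chromosomes of a region, with breed/group labels per chromosome.

    ``matrix`` is (n_chromosomes, n_sites) of 0/1 alleles; one diploid
    sample contributes two rows.  Samples with any missing call in the
    region were dropped at extraction.
    """

    chrom: str
    start: int  # 0-based half-open bp
    end: int
    positions: np.ndarray
    matrix: np.ndarray
    chrom_samples: list[str]   # source sample per row
    chrom_breeds: list[str]
    chrom_groups: list[str]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_chromosomes(self) -> int:
        return self.matrix.shape[0]

    def strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.matrix]

    def counts(self) -> dict[str, int]:
        """Distinct haplotype strings with total chromosome counts."""
        out: dict[str, int] = {}
        for s in self.strings():
            out[s] = out.get(s, 0) + 1
        return out

    def counts_by(self, level: str = "breed") -> pd.DataFrame:
        """Haplotype x breed (or group) count table."""
        labels = self.chrom_breeds if level == "breed" else self.chrom_groups
        df = pd.DataFrame({"hap": self.strings(), "label": labels})
        return df.groupby(["hap", "label"]).size().unstack(fill_value=0)


@dataclass
class HaploBlock:
    """A Gabriel haplotype block over contiguous region sites (indices inclusive)."""

    first: int
    last: int
    start: int  # 0-based half-open bp of member SNP span
    end: int

    @property
    def n_snps(self) -> int:
        return self.last - self.first + 1

    @property
    def span(self) -> int:
        return self.end - self.start


# ----------------------------------------------------------------------
def extract_haplotypes(
    panel: GenotypePanel,
    region: tuple[str, int, int],
    pops: PopulationMap,
) -> HaplotypeSet:
    """Phased haplotypes of every sample over a 0-based half-open region.

    Samples with any missing call inside the region are excluded
    (count logged); haplotype counts therefore sum to 2 x included
    samples.  Raises on unphased panels.
    """
    if not panel.is_phased:
        raise ValueError("haplotype extraction needs a phased panel")
    chrom, start, end = region
    on = (panel.chrom == chrom) & (panel.pos - 1 >= start) & (panel.pos - 1 < end)
    idx = np.flatnonzero(on)
    if len(idx) == 0:
        raise ValueError(f"region {chrom}:{start}-{end} contains no sites")
    h = panel.haplotypes[:, :, idx]
    full = ~(h == MISSING).any(axis=(1, 2))
    dropped = int((~full).sum())
    if dropped:
        logger.info("extract_haplotypes: dropped %d samples with missing calls", dropped)
    rows, samples, breeds, groups = [], [], [], []
    for i in np.flatnonzero(full):
        s = panel.samples[i]
        b = pops.sample_breed.get(s, "?")
        g = pops.breed_group.get(b, "?")
        for k in (0, 1):
            rows.append(h[i, k])
            samples.append(s)
            breeds.append(b)
            groups.append(g)
    return HaplotypeSet(
        chrom=chrom, start=start, end=end,
        positions=panel.pos[idx].copy(),
        matrix=np.array(rows, dtype=np.int8),
        chrom_samples=samples, chrom_breeds=breeds, chrom_groups=groups,
    )


# ----------------------------------------------------------------------
# linkage disequilibrium


def ld_pair(hapset: HaplotypeSet, i: int, j: int) -> tuple[float, float]:
    """(r^2, D') for two region sites from phased two-locus haplotype counts."""
    a = hapset.matrix[:, i].astype(float)
    b = hapset.matrix[:, j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return np.nan, np.nan
    p11 = (a * b).mean()
    d = p11 - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else np.nan
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return float(r2), float(dprime)


def _dprime_ci(
    hapset: HaplotypeSet, i: int, j: int, grid: int = 200
) -> tuple[float, float] | None:
    """90% likelihood interval on |D'| (Wall & Pritchard style grid).

    Allele frequencies are fixed at their observed values; the
    multinomial likelihood of the four phased two-locus haplotype counts
    is evaluated on a |D'| grid in [0, 1] (sign taken from the point
    estimate), normalized, and the central 90% mass bounds returned.
    ``None`` for monomorphic pairs.
    """
    a = hapset.matrix[:, i]
    b = hapset.matrix[:, j]
    n11 = int(((a == 1) & (b == 1)).sum())
    n10 = int(((a == 1) & (b == 0)).sum())
    n01 = int(((a == 0) & (b == 1)).sum())
    n00 = int(((a == 0) & (b == 0)).sum())
    n = n11 + n10 + n01 + n00
    pa = (n11 + n10) / n
    pb = (n11 + n01) / n
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        return None
    d_hat = n11 / n - pa * pb
    if d_hat >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    if dmax <= 0:
        return None
    dp = np.linspace(0.0, 1.0, grid + 1)
    d = np.sign(d_hat) * dp * dmax if d_hat != 0 else dp * dmax
    f11 = np.clip(pa * pb + d, 1e-12, 1.0)
    f10 = np.clip(pa * (1 - pb) - d, 1e-12, 1.0)
    f01 = np.clip((1 - pa) * pb - d, 1e-12, 1.0)
    f00 = np.clip((1 - pa) * (1 - pb) + d, 1e-12, 1.0)
    ll = (n11 * np.log(f11) + n10 * np.log(f10)
          + n01 * np.log(f01) + n00 * np.log(f00))
    lik = np.exp(ll - ll.max())
    cdf = np.cumsum(lik) / lik.sum()
    low = float(dp[int(np.searchsorted(cdf, 0.05))])
    high = float(dp[min(int(np.searchsorted(cdf, 0.95)), grid)])
    return low, high


def find_blocks(
    hapset: HaplotypeSet,
    ci_low_strong: float = 0.70,
    ci_high_strong: float = 0.98,
    ci_high_recomb: float = 0.90,
    min_strong_fraction: float = 0.95,
) -> list[HaploBlock]:
    """Gabriel confidence-interval haplotype blocks.

    A site pair is "strong LD" if its |D'| 90% CI has lower bound >=
    0.70 and upper bound >= 0.98; "strong recombination" if the upper
    bound is < 0.90; other pairs are uninformative.  A candidate block
    [i..j] requires its outermost pair to be strong LD and at least 95%
    of its informative pairs to be strong LD.  Candidates are accepted
    greedily by decreasing bp span (ties: leftmost), non-overlapping.
    """
    m = hapset.n_sites
    if m < 2:
        return []
    STRONG, RECOMB, NONE = 1, -1, 0
    klass = np.zeros((m, m), dtype=np.int8)
    for i in range(m):
        for j in range(i + 1, m):
            ci = _dprime_ci(hapset, i, j)
            if ci is None:
                k = NONE
            elif ci[0] >= ci_low_strong and ci[1] >= ci_high_strong:
                k = STRONG
            elif ci[1] < ci_high_recomb:
                k = RECOMB
            else:
                k = NONE
            klass[i, j] = klass[j, i] = k
    candidates = []
    for i in range(m):
        for j in range(i + 1, m):
            if klass[i, j] != STRONG:
                continue
            sub = klass[i:j + 1, i:j + 1]
            iu = np.triu_indices(j - i + 1, k=1)
            strong = int((sub[iu] == STRONG).sum())
            informative = strong + int((sub[iu] == RECOMB).sum())
            if informative == 0:
                continue
            if strong / informative >= min_strong_fraction:
                span = int(hapset.positions[j] - hapset.positions[i] + 1)
                candidates.append((span, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken = np.zeros(m, dtype=bool)
    blocks = []
    for span, i, j in candidates:
        if taken[i:j + 1].any():
            continue
        taken[i:j + 1] = True
        blocks.append(HaploBlock(
            first=i, last=j,
            start=int(hapset.positions[i] - 1), end=int(hapset.positions[j]),
        ))
    blocks.sort(key=lambda b: b.first)
    return blocks


# ----------------------------------------------------------------------
# frequencies, network, sharing


def haplotype_table(hapset: HaplotypeSet, min_count: int = 2) -> pd.DataFrame:
    """Common haplotypes (total count strictly > ``min_count``) with
    per-breed chromosome counts and homozygous-carrier counts.

    Rows are labeled ``hap_1, hap_2, ...`` by descending total count
    (ties broken by haplotype string).  Columns: ``haplotype``,
    ``total``, one count column per breed, and ``hom_<breed>`` columns
    counting samples homozygous for the haplotype.
    """
    counts = hapset.counts()
    kept = sorted(
        ((c, s) for s, c in counts.items() if c > min_count),
        key=lambda t: (-t[0], t[1]),
    )
    by_breed = hapset.counts_by("breed")
    breeds = list(dict.fromkeys(hapset.chrom_breeds))
    strings = hapset.strings()
    # homozygotes: samples whose two rows are identical and equal the haplotype
    sample_haps: dict[str, list[str]] = {}
    for s, hap in zip(hapset.chrom_samples, strings):
        sample_haps.setdefault(s, []).append(hap)
    sample_breed = dict(zip(hapset.chrom_samples, hapset.chrom_breeds))
    rows = []
    for rank, (c, hap) in enumerate(kept, 1):
        row = {"label": f"hap_{rank}", "haplotype": hap, "total": c}
        for b in breeds:
            row[b] = int(by_breed.loc[hap, b]) if b in by_breed.columns and hap in by_breed.index else 0
        for b in breeds:
            row[f"hom_{b}"] = sum(
                1 for s, haps in sample_haps.items()
                if sample_breed[s] == b and len(haps) == 2 and haps[0] == haps[1] == hap
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.set_index("label")
    return df


def haplotype_network(table: pd.DataFrame) -> nx.Graph:
    """Minimum spanning network over the table's haplotypes.

    Nodes are haplotype labels (node attributes: ``haplotype`` string,
    ``size`` = total count); edges are all minimum-spanning-tree edges
    under Hamming distance plus every alternative edge of equal weight
    (an edge joins the network iff its weight equals the bottleneck
    weight between its endpoints).  Deterministic under label order.
    """
    haps = list(table["haplotype"])
    if len(haps) != len(set(haps)):
        raise ValueError("duplicate haplotype strings; aggregate counts first")
    if len(haps) < 2:
        raise ValueError("need at least two haplotypes")
    labels = list(table.index)
    arrs = {lab: np.frombuffer(h.encode(), dtype=np.uint8)
            for lab, h in zip(labels, haps)}
    full = nx.Graph()
    for lab, h in zip(labels, haps):
        full.add_node(lab, haplotype=h, size=int(table.loc[lab, "total"]))
    for i, u in enumerate(labels):
        for v in labels[i + 1:]:
            w = int((arrs[u] != arrs[v]).sum())
            full.add_edge(u, v, weight=w)
    mst = nx.minimum_spanning_tree(full, algorithm="kruskal")
    net = nx.Graph()
    net.add_nodes_from(full.nodes(data=True))
    for u, v, data in full.edges(data=True):
        path = nx.shortest_path(mst, u, v)
        bottleneck = max(
            mst[a][b]["weight"] for a, b in zip(path, path[1:])
        )
        if data["weight"] == bottleneck:
            net.add_edge(u, v, weight=data["weight"])
    return net


def sharing_matrix(hapset: HaplotypeSet) -> np.ndarray:
    """Chromosome x chromosome fraction of region sites with identical alleles."""
    h = hapset.matrix
    n = h.shape[0]
    out = np.ones((n, n))
    for i in range(n):
        eq = (h[i] == h).mean(axis=1)
        out[i] = eq
    return out


def write_haplotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t")


def write_network(net: nx.Graph, edge_path, graphml_path=None) -> None:
    with open(edge_path, "w") as fh:
        fh.write("hap_a\thap_b\thamming\n")
        for u, v, data in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{data['weight']}\n")
    if graphml_path is not None:
        nx.write_graphml(net, graphml_path)
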