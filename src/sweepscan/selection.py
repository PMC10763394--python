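"""Windowed selection-signature scans: Fst, XP-EHH, LSBL, candidate calling.

Three complementary statistics localize selective sweeps:

* **Windowed Fst** — per-site Weir-Cockerham (1984) variance components,
  combined per window as a ratio of sums (the vcftools "weighted"
  convention): Fst_win = sum(a) / sum(a+b+c) over member sites.
* **XP-EHH** — the log-ratio of integrated extended-haplotype-homozygosity
  between two populations at each core SNP, z-standardized genome-wide
  and averaged per window.  Extreme positive values mean long, homogeneous
  haplotypes (a sweep) in the first population.
* **LSBL** — the locus-specific branch length of population A in a
  three-population star: (Fst_AB + Fst_AC - Fst_BC) / 2, computed per
  window; it isolates differentiation private to A.

Candidate windows are the empirical right tail (default 3%) of each
statistic; two-method candidates are intersected and merged into regions.

All windows tile each chromosome from position 0 at a fixed step
(default 40 kb windows, 20 kb step); coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .panel import MISSING, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)

WINDOW_BP_DEFAULT = 40_000
STEP_BP_DEFAULT = 20_000
TAIL_DEFAULT = 0.03
EHH_CUTOFF_DEFAULT = 0.05
MAX_EXTEND_BP_DEFAULT = 1_000_000


@dataclass
class WindowStat:
    chrom: str
    start: int  # 0-based half-open bp
    end: int
    n_snps: int
    value: float  # NaN when no usable site
    candidate: bool = False


@dataclass
class Region:
    chrom: str
    start: int
    end: int
    sources: frozenset = frozenset()
    windows: list[WindowStat] = field(default_factory=list)
    best_values: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


# ----------------------------------------------------------------------
# Weir-Cockerham variance components (two populations)


def _pop_site_stats(g: np.ndarray):
    """Per-site (n called, alt freq, het fraction) for one population's dosages."""
    called = g != MISSING
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
        h = (g == 1).sum(axis=0) / n
    return n, p, h


def wc_site_terms(panel: GenotypePanel, idx_a: np.ndarray, idx_b: np.ndarray):
    """Weir-Cockerham (1984) per-site variance components for two populations.

    Returns ``(num, den, mono)`` arrays over all sites: the numerator
    ``a`` (among-population component) and denominator ``a + b + c``.
    Sites where either population has no called genotype, or fewer than
    two called genotypes in total, are NaN.  Sites monomorphic across
    both populations get terms (0, 0) and are flagged in ``mono``.
    """
    n1, p1, h1 = _pop_site_stats(panel.genotypes[idx_a])
    n2, p2, h2 = _pop_site_stats(panel.genotypes[idx_b])
    usable = (n1 > 0) & (n2 > 0) & (n1 + n2 > 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2) - (n1**2 + n2**2) / (n1 + n2)
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar  # r-1 = 1
        hbar = (n1 * h1 + n2 * h2) / (n1 + n2)
        inner = pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
    num = np.where(usable, a, np.nan)
    den = np.where(usable, a + b + c, np.nan)
    mono = usable & np.isclose(pbar * (1 - pbar), 0.0) & (hbar == 0)
    num = np.where(mono, 0.0, num)
    den = np.where(mono, 0.0, den)
    return num, den, mono


def site_fst_terms(panel: GenotypePanel, pops: PopulationMap, pop_a, pop_b, site: int):
    """Single-site W&C numerator and denominator for two populations.

    ``pop_a`` / ``pop_b`` are breed names, group names or sample lists.
    """
    ia = pops.indices(panel, pop_a)
    ib = pops.indices(panel, pop_b)
    num, den, _ = wc_site_terms(panel.take_sites(np.array([site])), ia, ib)
    return float(num[0]), float(den[0])


# ----------------------------------------------------------------------
# windows


def make_windows(
    chrom_lengths: dict[str, int],
    window_bp: int = WINDOW_BP_DEFAULT,
    step_bp: int = STEP_BP_DEFAULT,
) -> list[tuple[str, int, int]]:
    """Sliding-window grid anchored at 0 per chromosome.

    Windows start at 0, step, 2*step, ... while the start lies inside the
    chromosome; the final partial windows are kept (they are dropped
    later only if empty of SNPs).
    """
    grid = []
    for c, length in chrom_lengths.items():
        start = 0
        while start < length:
            grid.append((c, start, start + window_bp))
            start += step_bp
    return grid


def _panel_chrom_lengths(panel: GenotypePanel, autosomes_only: bool = True):
    chroms = panel.autosomes() if autosomes_only else panel.chromosomes()
    return {c: int(panel.pos[panel.sites_of(c)].max()) for c in chroms}


def _aggregate_windows(
    panel: GenotypePanel,
    site_values: tuple[np.ndarray, ...],
    combine,
    window_bp: int,
    step_bp: int,
    chrom_lengths: dict[str, int] | None = None,
    autosomes_only: bool = True,
) -> list[WindowStat]:
    """Tile chromosomes and combine per-site arrays into window values."""
    lengths = chrom_lengths or _panel_chrom_lengths(panel, autosomes_only)
    out: list[WindowStat] = []
    for c, length in lengths.items():
        sites = panel.sites_of(c)
        pos0 = panel.pos[sites] - 1  # 0-based
        start = 0
        while start < length:
            end = start + window_bp
            in_win = (pos0 >= start) & (pos0 < end)
            members = sites[in_win]
            value, n_used = combine(*(v[members] for v in site_values))
            if len(members) == 0 and end > length:
                start += step_bp
                continue  # empty trailing partial window
            out.append(WindowStat(c, start, end, int(n_used), value))
            start += step_bp
    return out


def windowed_fst(
    panel: GenotypePanel,
    pops: PopulationMap,
    pop_a,
    pop_b,
    window_bp: int = WINDOW_BP_DEFAULT,
    step_bp: int = STEP_BP_DEFAULT,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Averaged Weir-Cockerham Fst per sliding window (ratio of sums)."""
    ia = pops.indices(panel, pop_a)
    ib = pops.indices(panel, pop_b)
    if set(ia) & set(ib):
        raise ValueError("populations overlap")
    num, den, _ = wc_site_terms(panel, ia, ib)

    def combine(num_w, den_w):
        ok = np.isfinite(num_w) & np.isfinite(den_w)
        d = den_w[ok].sum()
        if ok.sum() == 0 or d == 0:
            return np.nan, int(ok.sum())
        return float(num_w[ok].sum() / d), int(ok.sum())

    return _aggregate_windows(panel, (num, den), combine, window_bp, step_bp,
                              chrom_lengths)


# ----------------------------------------------------------------------
# EHH / XP-EHH


def _hap_matrix(panel: GenotypePanel, sample_idx: np.ndarray, site_idx: np.ndarray):
    if not panel.is_phased:
        raise ValueError("haplotype statistics need a phased panel")
    h = panel.haplotypes[np.ix_(sample_idx, [0, 1], site_idx)]
    return h.reshape(-1, len(site_idx))


def _homozygosity(group_ids: np.ndarray) -> float:
    """sum over groups of C(n_g, 2) / C(n, 2)."""
    n = len(group_ids)
    if n < 2:
        return np.nan
    counts = np.bincount(group_ids)
    return float((counts * (counts - 1)).sum() / (n * (n - 1)))


def ehh(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    core: int,
    direction: str,
    cutoff: float = EHH_CUTOFF_DEFAULT,
    max_extend_bp: float = np.inf,
    max_steps: int | None = None,
) -> list[tuple[int, float]]:
    """Extended haplotype homozygosity decay from a core site.

    ``haplotypes`` is a (n_haplotypes, n_sites) 0/1 matrix for one
    population and chromosome; ``positions`` the matching physical
    positions.  EHH at distance-ordered site x is the probability that
    two random chromosomes carry identical alleles at every site between
    the core (exclusive) and x (inclusive): sum_g C(n_g,2) / C(n,2) over
    distinct extended haplotypes g.  EHH at the core itself is 1 by
    definition.  The curve is truncated after the first value below
    ``cutoff``, at ``max_extend_bp`` from the core, or at the chromosome
    end.  Missing alleles never merge: a haplotype with a missing call
    forms its own extension group from that site on.

    Returns [(pos, EHH), ...] starting with (core position, 1.0).
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    n, m = haplotypes.shape
    step = 1 if direction == "right" else -1
    out = [(int(positions[core]), 1.0)]
    ids = np.zeros(n, dtype=np.int64)
    x = core + step
    while (0 <= x < m
           and abs(int(positions[x]) - int(positions[core])) <= max_extend_bp
           and (max_steps is None or abs(x - core) <= max_steps)):
        allele = haplotypes[:, x].astype(np.int64)
        missing = allele == MISSING
        code = np.where(missing, 2 + np.arange(n), allele)  # missing never merges
        _, ids = np.unique(ids * (n + 3) + code, return_inverse=True)
        e = _homozygosity(ids)
        out.append((int(positions[x]), e))
        if e < cutoff:
            break
        x += step
    return out


def _ihh(curve: list[tuple[int, float]]) -> float:
    """Trapezoidal integral of one EHH decay curve over physical distance."""
    if len(curve) < 2:
        return 0.0
    pos = np.array([p for p, _ in curve], dtype=float)
    val = np.array([v for _, v in curve], dtype=float)
    return float(abs(np.trapezoid(val, pos)))


def xpehh(
    panel: GenotypePanel,
    pops: PopulationMap,
    pop_a,
    pop_b,
    core_site: int,
    cutoff: float = EHH_CUTOFF_DEFAULT,
    max_extend_bp: float = MAX_EXTEND_BP_DEFAULT,
) -> float:
    """Unstandardized XP-EHH score ln(iHH_A / iHH_B) at one core SNP.

    Both populations' EHH curves are truncated at a shared boundary per
    side — where the pooled-sample EHH falls below the cutoff — so the
    two integrals cover the same physical span.  NaN if either
    integrated EHH is zero (degenerate haplotype sets) or the core is
    monomorphic across the pooled populations.
    """
    ia = pops.indices(panel, pop_a)
    ib = pops.indices(panel, pop_b)
    if set(ia) & set(ib):
        raise ValueError("populations overlap")
    chrom = panel.chrom[core_site]
    sites = panel.sites_of(chrom)
    local_core = int(np.flatnonzero(sites == core_site)[0])
    positions = panel.pos[sites]
    ha = _hap_matrix(panel, ia, sites)
    hb = _hap_matrix(panel, ib, sites)
    pooled = np.vstack([ha, hb])
    core_alleles = pooled[:, local_core]
    called = core_alleles != MISSING
    if called.sum() == 0 or len(set(core_alleles[called].tolist())) < 2:
        return np.nan

    score_parts = {"A": 0.0, "B": 0.0}
    for direction in ("left", "right"):
        pooled_curve = ehh(pooled, positions, local_core, direction,
                           cutoff=cutoff, max_extend_bp=max_extend_bp)
        span = len(pooled_curve) - 1  # sites to extend, shared by both pops
        ca = ehh(ha, positions, local_core, direction, cutoff=-1.0,
                 max_extend_bp=max_extend_bp, max_steps=span)
        cb = ehh(hb, positions, local_core, direction, cutoff=-1.0,
                 max_extend_bp=max_extend_bp, max_steps=span)
        score_parts["A"] += _ihh(ca)
        score_parts["B"] += _ihh(cb)
    if score_parts["A"] <= 0 or score_parts["B"] <= 0:
        logger.info("xpehh: zero iHH at site %d; score undefined", core_site)
        return np.nan
    return float(np.log(score_parts["A"] / score_parts["B"]))


def xpehh_scan(
    panel: GenotypePanel,
    pops: PopulationMap,
    pop_a,
    pop_b,
    cutoff: float = EHH_CUTOFF_DEFAULT,
    max_extend_bp: float = MAX_EXTEND_BP_DEFAULT,
    autosomes_only: bool = True,
) -> np.ndarray:
    """Raw per-SNP XP-EHH scores over the whole panel (NaN where undefined)."""
    scores = np.full(panel.n_sites, np.nan)
    chroms = panel.autosomes() if autosomes_only else panel.chromosomes()
    for c in chroms:
        for s in panel.sites_of(c):
            scores[s] = xpehh(panel, pops, pop_a, pop_b, int(s),
                              cutoff=cutoff, max_extend_bp=max_extend_bp)
    return scores


def standardize_and_window_xpehh(
    panel: GenotypePanel,
    scores: np.ndarray,
    window_bp: int = WINDOW_BP_DEFAULT,
    step_bp: int = STEP_BP_DEFAULT,
    chrom_lengths: dict[str, int] | None = None,
    absolute: bool = False,
) -> list[WindowStat]:
    """Genome-wide z-normalization of per-SNP scores, averaged per window.

    ``absolute=True`` averages |z| instead of signed z.  Raises if fewer
    than two finite scores or if they have zero variance.
    """
    finite = np.isfinite(scores)
    if finite.sum() < 2:
        raise ValueError("need at least two finite scores to standardize")
    mu = scores[finite].mean()
    sd = scores[finite].std()
    if sd == 0:
        raise ValueError("scores have zero variance; cannot standardize")
    z = (scores - mu) / sd
    if absolute:
        z = np.abs(z)

    def combine(z_w):
        ok = np.isfinite(z_w)
        if ok.sum() == 0:
            return np.nan, 0
        return float(z_w[ok].mean()), int(ok.sum())

    return _aggregate_windows(panel, (z,), combine, window_bp, step_bp,
                              chrom_lengths)


# ----------------------------------------------------------------------
# LSBL


def _check_same_grid(*tracks: list[WindowStat]) -> None:
    grids = [[(w.chrom, w.start, w.end) for w in t] for t in tracks]
    if any(g != grids[0] for g in grids[1:]):
        raise ValueError("window grids differ between tracks")


def lsbl(
    fst_ab: list[WindowStat],
    fst_ac: list[WindowStat],
    fst_bc: list[WindowStat],
) -> list[WindowStat]:
    """Locus-specific branch length of population A, per window.

    x_A = (Fst_AB + Fst_AC - Fst_BC) / 2.  NaN propagates from any
    input track.  The three tracks must share one window grid.
    """
    _check_same_grid(fst_ab, fst_ac, fst_bc)
    out = []
    for wab, wac, wbc in zip(fst_ab, fst_ac, fst_bc):
        value = (wab.value + wac.value - wbc.value) / 2.0
        n = min(wab.n_snps, wac.n_snps, wbc.n_snps)
        out.append(WindowStat(wab.chrom, wab.start, wab.end, n, value))
    return out


# ----------------------------------------------------------------------
# candidate calling and merging


def call_candidates(
    windows: list[WindowStat], tail: float = TAIL_DEFAULT
) -> tuple[list[WindowStat], float]:
    """Flag the empirical right tail of the window statistic.

    The threshold is the (1 - tail) quantile of finite window values
    using the "higher" interpolation, so with all-distinct values exactly
    ceil(tail * N) windows are flagged; windows with value >= threshold
    are flagged (ties at the threshold all flag, which can exceed that
    count).  Returns (flagged windows, threshold).
    """
    if not 0.0 < tail < 0.5:
        raise ValueError("tail must lie in (0, 0.5)")
    values = np.array([w.value for w in windows], dtype=float)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        raise ValueError("no finite window values")
    vals = values[finite]
    threshold = float(np.quantile(vals, 1.0 - tail, method="higher"))
    if np.all(vals == vals[0]):
        warnings.warn("all window values equal; every window flagged", stacklevel=2)
    out = []
    for w in windows:
        flag = bool(np.isfinite(w.value) and w.value >= threshold)
        out.append(WindowStat(w.chrom, w.start, w.end, w.n_snps, w.value, flag))
    return out, threshold


def intersect_and_merge(
    cand_a: list[WindowStat],
    cand_b: list[WindowStat],
    source_a: str = "fst",
    source_b: str = "xpehh",
) -> list[Region]:
    """Two-method candidate regions: windows flagged by both scans,
    merged where they overlap or abut (with a step smaller than the
    window size, neighbors overlap).  Coordinates are the 0-based
    half-open union of member windows."""
    _check_same_grid(cand_a, cand_b)
    both = [
        (wa, wb) for wa, wb in zip(cand_a, cand_b) if wa.candidate and wb.candidate
    ]
    regions: list[Region] = []
    for wa, wb in both:
        if regions and regions[-1].chrom == wa.chrom and wa.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, wa.end)
            r.windows.append(wa)
            r.best_values[source_a] = max(r.best_values[source_a], wa.value)
            r.best_values[source_b] = max(r.best_values[source_b], wb.value)
        else:
            regions.append(Region(
                chrom=wa.chrom, start=wa.start, end=wa.end,
                sources=frozenset({source_a, source_b}),
                windows=[wa],
                best_values={source_a: wa.value, source_b: wb.value},
            ))
    return regions


def write_window_tsv(windows: list[WindowStat], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart0\tend0\tn_snps\tvalue\tflagged\n")
        for w in windows:
            val = "NA" if not np.isfinite(w.value) else f"{w.value:.6g}"
            fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_snps}\t{val}\t"
                     f"{int(w.candidate)}\n")


def write_region_bed(regions: list[Region], path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{'+'.join(sorted(r.sources))}\n")
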