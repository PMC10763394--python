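"""Per-breed heterozygosity, runs of homozygosity, and the F_ROH coefficient.

The ROH detector follows the PLINK sliding-window algorithm with the
four-rule parameterization common in livestock resequencing studies:
50-SNP windows, at most one heterozygous and five missing calls per
window, at least 100 consecutive SNPs per run, and a 1 Mb minimum
length.  PLINK's remaining defaults — the 5% window hit-rate threshold,
the 1 SNP / 50 kb density rule and the 1 Mb maximum gap — are applied
and configurable.

F_ROH is the summed ROH length divided by the autosomal genome length
covered by the SNPs (per chromosome, last minus first SNP position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import MISSING, GenotypePanel, PopulationMap

logger = logging.getLogger(__name__)


@dataclass
class ROHParams:
    """PLINK-style ROH rules; lengths in bp, coordinates 0-based half-open."""

    window_snps: int = 50
    max_het_per_window: int = 1
    max_miss_per_window: int = 5
    min_snps: int = 100
    min_length_bp: float = 1e6
    hom_window_fraction: float = 0.05  # PLINK --homozyg-window-threshold
    max_gap_bp: float = 1e6            # PLINK --homozyg-gap
    density_bp_per_snp: float = 50e3   # PLINK --homozyg-density (50 kb/SNP)


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start: int  # 0-based half-open bp
    end: int
    n_snps: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DiversitySummary:
    breed: str
    n_samples: int
    ho: float = np.nan
    he: float = np.nan
    f_roh: float = np.nan
    n_roh: int = 0
    total_roh_length: int = 0


# ----------------------------------------------------------------------
def heterozygosity(panel: GenotypePanel, pops: PopulationMap) -> list[DiversitySummary]:
    """Observed and expected heterozygosity per breed.

    Per site within a breed, Ho = heterozygous / called genotypes and
    He = 2p(1-p) from the breed allele frequency (plug-in, no
    small-sample correction, so He <= 0.5 exactly); the breed value is
    the mean over sites with at least one called genotype.
    """
    pops.validate_against(panel)
    out = []
    for breed in pops.breeds():
        idx = pops.indices(panel, breed)
        g = panel.genotypes[idx]
        called = g != MISSING
        n_called = called.sum(axis=0)
        usable = n_called > 0
        if not usable.any():
            raise ValueError(f"breed {breed!r} has no called genotypes at any site")
        het = (g == 1).sum(axis=0)
        ho_site = het[usable] / n_called[usable]
        alt = np.where(called, g, 0).sum(axis=0)
        p = alt[usable] / (2 * n_called[usable])
        he_site = 2.0 * p * (1.0 - p)
        out.append(DiversitySummary(
            breed=breed, n_samples=len(idx),
            ho=float(ho_site.mean()), he=float(he_site.mean()),
        ))
    return out


# ----------------------------------------------------------------------
def _roh_one_chrom(
    gt: np.ndarray, pos: np.ndarray, params: ROHParams
) -> list[tuple[int, int, int]]:
    """Candidate runs on one chromosome: (first_idx, last_idx, n_snps)."""
    n = len(gt)
    w = params.window_snps
    het = (gt == 1).astype(np.int64)
    miss = (gt == MISSING).astype(np.int64)
    # window i spans SNPs [i, i+w); counts via cumulative sums
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    n_win = n - w + 1
    win_het = chet[w:] - chet[:-w]
    win_miss = cmiss[w:] - cmiss[:-w]
    hom_win = ((win_het <= params.max_het_per_window)
               & (win_miss <= params.max_miss_per_window)).astype(np.int64)
    # SNP j is covered by windows i in [max(0, j-w+1), min(j, n_win-1)]
    chom = np.concatenate([[0], np.cumsum(hom_win)])
    j = np.arange(n)
    lo = np.maximum(0, j - w + 1)
    hi = np.minimum(j, n_win - 1)
    hits = chom[hi + 1] - chom[lo]
    covering = hi - lo + 1
    hit_rate = hits / covering
    eligible = hit_rate >= params.hom_window_fraction
    # split eligible stretches at physical gaps wider than max_gap_bp
    runs: list[tuple[int, int, int]] = []
    start = None
    for k in range(n):
        if eligible[k]:
            if start is None:
                start = k
            elif pos[k] - pos[k - 1] > params.max_gap_bp:
                runs.append((start, k - 1, k - start))
                start = k
        elif start is not None:
            runs.append((start, k - 1, k - start))
            start = None
    if start is not None:
        runs.append((start, n - 1, n - start))
    return runs


def detect_roh(
    panel: GenotypePanel,
    sample: str,
    params: ROHParams | None = None,
    autosomes_only: bool = True,
) -> list[ROHSegment]:
    """PLINK-style ROH segments for one sample, sorted by chromosome and start.

    Chromosomes with fewer SNPs than one window are skipped (logged).
    """
    if sample not in panel.samples:
        raise KeyError(f"sample {sample!r} not in panel")
    params = params or ROHParams()
    row = panel.samples.index(sample)
    chroms = panel.autosomes() if autosomes_only else panel.chromosomes()
    segments: list[ROHSegment] = []
    for c in chroms:
        idx = panel.sites_of(c)
        if len(idx) < params.window_snps:
            logger.info("detect_roh: chromosome %s has %d < %d SNPs; skipped",
                        c, len(idx), params.window_snps)
            continue
        gt = panel.genotypes[row, idx]
        pos = panel.pos[idx]
        for first, last, n_snps in _roh_one_chrom(gt, pos, params):
            start0 = int(pos[first] - 1)
            end0 = int(pos[last])
            length = end0 - start0
            if n_snps < params.min_snps or length < params.min_length_bp:
                continue
            if length / n_snps > params.density_bp_per_snp:
                continue
            segments.append(ROHSegment(sample, c, start0, end0, n_snps))
    return segments


# ----------------------------------------------------------------------
def covered_autosome_length(panel: GenotypePanel) -> int:
    """Autosomal genome length covered by the SNPs: per chromosome,
    last minus first SNP position, summed."""
    total = 0
    for c in panel.autosomes():
        p = panel.pos[panel.sites_of(c)]
        if len(p) >= 2:
            total += int(p.max() - p.min())
    return total


def froh(segments: list[ROHSegment], covered_autosome_length: float) -> float:
    """Summed ROH length over covered autosomal length."""
    if covered_autosome_length <= 0:
        raise ValueError("covered_autosome_length must be positive")
    total = sum(s.length for s in segments)
    if total > covered_autosome_length:
        raise ValueError(
            f"ROH total {total} bp exceeds covered length {covered_autosome_length}"
        )
    return total / covered_autosome_length


def summarize(
    panel: GenotypePanel,
    pops: PopulationMap,
    roh_params: ROHParams | None = None,
) -> list[DiversitySummary]:
    """Full per-breed table: Ho, He, F_ROH (breed mean over samples), ROH counts."""
    summaries = {s.breed: s for s in heterozygosity(panel, pops)}
    covered = covered_autosome_length(panel)
    for breed, summ in summaries.items():
        froh_vals, n_roh, total_len = [], 0, 0
        for s in pops.samples_of(breed):
            segs = detect_roh(panel, s, roh_params)
            froh_vals.append(froh(segs, covered) if covered > 0 else 0.0)
            n_roh += len(segs)
            total_len += sum(x.length for x in segs)
        summ.f_roh = float(np.mean(froh_vals)) if froh_vals else 0.0
        summ.n_roh = n_roh
        summ.total_roh_length = total_len
    return list(summaries.values())
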