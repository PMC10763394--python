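"""Fst / EHH / XP-EHH / LSBL and candidate calling against independent oracles."""

import numpy as np
import pytest

from sweepscan import PopulationMap, SimConfig, SweepTruth, simulate_panel
from sweepscan.selection import (
    WindowStat,
    call_candidates,
    ehh,
    intersect_and_merge,
    lsbl,
    site_fst_terms,
    standardize_and_window_xpehh,
    wc_site_terms,
    windowed_fst,
    xpehh,
    xpehh_scan,
)

from conftest import hap_panel, make_panel


# ----------------------------------------------------------------------
# Weir-Cockerham site terms


def wc_oracle(g1, g2):
    """Independent transcription of the 1984 two-population variance
    components, written symbol by symbol from the general-r formulas."""
    r = 2
    pops = []
    for g in (g1, g2):
        g = np.asarray(g)
        called = g[g >= 0]
        n_i = len(called)
        p_i = called.sum() / (2 * n_i)
        h_i = (called == 1).sum() / n_i
        pops.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = pops
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, a + b + c


@pytest.mark.parametrize("seed", range(5))
def test_wc_terms_match_independent_transcription(seed):
    rng = np.random.default_rng(seed)
    g1 = rng.choice([0, 1, 2, -1], size=6, p=[0.3, 0.3, 0.3, 0.1])
    g2 = rng.choice([0, 1, 2, -1], size=6, p=[0.3, 0.3, 0.3, 0.1])
    if (g1 >= 0).sum() == 0 or (g2 >= 0).sum() == 0:
        return
    panel = make_panel(np.concatenate([g1, g2])[:, None].astype(np.int8))
    idx_a, idx_b = np.arange(6), np.arange(6, 12)
    num, den, _ = wc_site_terms(panel, idx_a, idx_b)
    a, total = wc_oracle(g1, g2)
    if np.isfinite(num[0]):
        assert num[0] == pytest.approx(a, abs=1e-12)
        assert den[0] == pytest.approx(total, abs=1e-12)


def test_equal_frequencies_give_near_zero_numerator():
    # identical allele frequency and het fraction in both populations:
    # the among-population component vanishes up to its small-sample bias
    g = np.tile(np.array([0, 1, 2], dtype=np.int8), 20)
    panel = make_panel(g[:, None])
    num, den, _ = wc_site_terms(panel, np.arange(30), np.arange(30, 60))
    assert abs(num[0]) < 0.01
    assert abs(num[0] / den[0]) < 0.03


def test_fixed_difference_gives_unit_ratio():
    g = np.array([2, 2, 2, 0, 0, 0], dtype=np.int8)
    panel = make_panel(g[:, None])
    num, den, _ = wc_site_terms(panel, np.arange(3), np.arange(3, 6))
    assert num[0] / den[0] == pytest.approx(1.0)


def test_monomorphic_site_flagged_zero_terms(two_breed_map):
    g = np.zeros((4, 1), dtype=np.int8)
    panel = make_panel(g)
    num, den, mono = wc_site_terms(panel, np.arange(2), np.arange(2, 4))
    assert mono[0] and num[0] == 0.0 and den[0] == 0.0
    assert site_fst_terms(panel, two_breed_map, "A", "B", 0) == (0.0, 0.0)


# ----------------------------------------------------------------------
# windowed Fst


def test_windowed_fst_equals_site_term_recompute():
    cfg = SimConfig(n_breeds=2, samples_per_breed=[8, 8], chrom_length=100_000,
                    snp_density=1 / 1000, drift_F=0.1, seed=4)
    panel, _, _ = simulate_panel(cfg)
    pops = cfg.population_map()
    windows = windowed_fst(panel, pops, "breed_1", "breed_2",
                           window_bp=40_000, step_bp=20_000,
                           chrom_lengths={"1": 100_000})
    ia = pops.indices(panel, "breed_1")
    ib = pops.indices(panel, "breed_2")
    num, den, _ = wc_site_terms(panel, ia, ib)
    for w in windows:
        members = np.flatnonzero((panel.pos - 1 >= w.start) & (panel.pos - 1 < w.end))
        ok = members[np.isfinite(num[members])]
        if len(ok) == 0 or den[ok].sum() == 0:
            assert not np.isfinite(w.value)
        else:
            assert w.value == pytest.approx(num[ok].sum() / den[ok].sum(), abs=1e-12)


def test_split_panmictic_pool_scans_near_zero():
    cfg = SimConfig(n_breeds=1, samples_per_breed=[20], chrom_length=500_000,
                    snp_density=1 / 500, drift_F=0.05, seed=8)
    panel, _, _ = simulate_panel(cfg)
    pops = PopulationMap({s: ("L" if i < 10 else "R")
                          for i, s in enumerate(panel.samples)})
    windows = windowed_fst(panel, pops, "L", "R", chrom_lengths={"1": 500_000})
    vals = np.array([w.value for w in windows if np.isfinite(w.value)])
    assert np.abs(vals.mean()) < 0.02


def test_overlapping_populations_rejected(sweep_sim):
    _, panel, _, pops = sweep_sim
    with pytest.raises(ValueError, match="overlap"):
        windowed_fst(panel, pops, "breed_1", "breed_1")


def test_sweep_windows_are_global_fst_maximum(sweep_sim):
    cfg, panel, sweep, pops = sweep_sim
    windows = windowed_fst(panel, pops, "breed_1", "breed_2",
                           chrom_lengths={"1": cfg.chrom_length})
    best = max(windows, key=lambda w: w.value if np.isfinite(w.value) else -np.inf)
    assert best.start < sweep.end and sweep.start < best.end


# ----------------------------------------------------------------------
# EHH


def ehh_oracle(haps, positions, core, direction):
    """Group haplotypes by their literal allele strings past the core."""
    n, m = haps.shape
    step = 1 if direction == "right" else -1
    out = [(positions[core], 1.0)]
    x = core + step
    while 0 <= x < m:
        strings = ["".join(str(a) for a in
                           (haps[i, core + step:x + 1] if step == 1
                            else haps[i, x:core][::-1]))
                   for i in range(n)]
        from collections import Counter
        num = sum(c * (c - 1) // 2 for c in Counter(strings).values())
        out.append((positions[x], num / (n * (n - 1) // 2)))
        x += step
    return out


def test_identical_haplotypes_keep_ehh_at_one():
    haps = np.tile(np.array([0, 1, 0, 1, 1], dtype=np.int8), (6, 1))
    pos = np.array([10, 20, 30, 40, 50])
    curve = ehh(haps, pos, 2, "right", cutoff=0.0)
    assert [v for _, v in curve] == [1.0, 1.0, 1.0]


def test_two_two_split_closed_form():
    haps = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
    pos = np.array([100, 200])
    curve = ehh(haps, pos, 0, "right", cutoff=0.0)
    assert curve[1][1] == pytest.approx(1 / 3)  # (C(2,2)+C(2,2)) / C(4,2)


@pytest.mark.parametrize("direction", ["left", "right"])
@pytest.mark.parametrize("seed", [0, 1, 2])
def test_ehh_matches_group_enumeration_oracle(direction, seed):
    rng = np.random.default_rng(seed)
    haps = rng.integers(0, 2, size=(20, 15)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 10_000), size=15, replace=False))
    core = 7
    got = ehh(haps, pos, core, direction, cutoff=-1.0)
    want = ehh_oracle(haps, pos, core, direction)
    assert len(got) == len(want)
    for (pg, vg), (pw, vw) in zip(got, want):
        assert pg == pw and vg == pytest.approx(vw, abs=1e-12)


def test_ehh_is_non_increasing_and_one_at_core():
    rng = np.random.default_rng(3)
    haps = rng.integers(0, 2, size=(30, 40)).astype(np.int8)
    pos = np.arange(1, 41) * 100
    for direction in ("left", "right"):
        vals = [v for _, v in ehh(haps, pos, 20, direction, cutoff=-1.0)]
        assert vals[0] == 1.0
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


# ----------------------------------------------------------------------
# XP-EHH


def toy_pops(n_a=8, n_b=8):
    samples = {f"a{i}": "A" for i in range(n_a)}
    samples.update({f"b{i}": "B" for i in range(n_b)})
    return PopulationMap(samples)


def test_xpehh_antisymmetry_is_exact():
    rng = np.random.default_rng(9)
    haps = rng.integers(0, 2, size=(8, 2, 30)).astype(np.int8)
    panel = hap_panel(haps, samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    pops = toy_pops(4, 4)
    for core in range(5, 25, 5):
        ab = xpehh(panel, pops, "A", "B", core)
        ba = xpehh(panel, pops, "B", "A", core)
        if np.isfinite(ab):
            assert ab == pytest.approx(-ba, abs=1e-9)


def test_xpehh_zero_for_identical_haplotype_multisets():
    rng = np.random.default_rng(10)
    block = rng.integers(0, 2, size=(4, 2, 20)).astype(np.int8)
    haps = np.concatenate([block, block], axis=0)
    panel = hap_panel(haps, samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    score = xpehh(panel, toy_pops(4, 4), "A", "B", 10)
    assert score == pytest.approx(0.0, abs=1e-12)


def test_xpehh_positive_when_first_pop_is_homogeneous():
    rng = np.random.default_rng(11)
    hom = np.tile(rng.integers(0, 2, size=20).astype(np.int8), (4, 2, 1))
    div = rng.integers(0, 2, size=(4, 2, 20)).astype(np.int8)
    # make the core polymorphic in the pooled sample
    hom[:, :, 10] = 1
    div[:, :, 10] = 0
    panel = hap_panel(np.concatenate([hom, div], axis=0),
                      samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    score = xpehh(panel, toy_pops(4, 4), "A", "B", 10)
    assert score > 0.5


def test_xpehh_matches_hand_integrated_curves():
    rng = np.random.default_rng(12)
    haps = rng.integers(0, 2, size=(16, 2, 10)).astype(np.int8)
    pos = np.sort(rng.choice(np.arange(1, 5_000), size=10, replace=False))
    panel = hap_panel(haps, pos=pos,
                      samples=[f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)])
    pops = toy_pops()
    core = 4
    got = xpehh(panel, pops, "A", "B", core, cutoff=0.05)
    ha = haps[:8].reshape(16, 10)
    hb = haps[8:].reshape(16, 10)
    pooled = np.vstack([ha, hb])

    def ihh(hmat, span_left, span_right):
        total = 0.0
        for direction, span in (("left", span_left), ("right", span_right)):
            curve = ehh_oracle(hmat, pos, core, direction)[: span + 1]
            ps = [p for p, _ in curve]
            vs = [v for _, v in curve]
            for k in range(len(ps) - 1):
                total += abs(ps[k + 1] - ps[k]) * (vs[k] + vs[k + 1]) / 2
        return total

    def pooled_span(direction):
        curve = ehh_oracle(pooled, pos, core, direction)
        span = 0
        for k in range(1, len(curve)):
            span = k
            if curve[k][1] < 0.05:
                break
        return span

    sl, sr = pooled_span("left"), pooled_span("right")
    want = np.log(ihh(ha, sl, sr) / ihh(hb, sl, sr))
    assert got == pytest.approx(want, abs=1e-9)


def test_unphased_panel_rejected_for_haplotype_statistics():
    g = np.array([[1, 1], [1, 1], [0, 2], [2, 0]], dtype=np.int8)
    panel = make_panel(g, samples=["a0", "a1", "b0", "b1"])
    with pytest.raises(ValueError, match="phased"):
        xpehh(panel, toy_pops(2, 2), "A", "B", 0)


# ----------------------------------------------------------------------
# standardization and windowing


def test_standardized_scores_have_zero_mean_unit_sd(sweep_sim):
    cfg, panel, _, pops = sweep_sim
    scores = xpehh_scan(panel, pops, "breed_1", "breed_2")
    finite = scores[np.isfinite(scores)]
    z = (finite - finite.mean()) / finite.std()
    assert abs(z.mean()) < 1e-9 and abs(z.std() - 1) < 1e-9
    windows = standardize_and_window_xpehh(panel, scores,
                                           chrom_lengths={"1": cfg.chrom_length})
    best = max(windows, key=lambda w: w.value if np.isfinite(w.value) else -np.inf)
    assert best.start < 940_000 and 900_000 < best.end  # sweep window on top


def test_single_snp_windows_reproduce_their_score():
    rng = np.random.default_rng(13)
    haps = rng.integers(0, 2, size=(8, 2, 5)).astype(np.int8)
    pos = np.array([100, 50_100, 100_100, 150_100, 190_000])
    panel = hap_panel(haps, pos=pos,
                      samples=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)])
    scores = rng.normal(size=5)
    windows = standardize_and_window_xpehh(panel, scores, window_bp=40_000,
                                           step_bp=40_000,
                                           chrom_lengths={"1": 200_000})
    z = (scores - scores.mean()) / scores.std()
    per_window = [w.value for w in windows if w.n_snps == 1]
    assert per_window == pytest.approx(list(z), abs=1e-9)


def test_zero_variance_scores_rejected():
    panel = hap_panel(np.zeros((2, 2, 3), dtype=np.int8) + np.array([0, 1])[None, :, None])
    with pytest.raises(ValueError, match="variance"):
        standardize_and_window_xpehh(panel, np.ones(3))


# ----------------------------------------------------------------------
# LSBL


def _wins(values, start=0):
    return [WindowStat("1", start + 20_000 * i, start + 20_000 * i + 40_000, 5, v)
            for i, v in enumerate(values)]


def test_lsbl_printed_formula():
    out = lsbl(_wins([0.3]), _wins([0.2]), _wins([0.1]))
    assert out[0].value == pytest.approx(0.2)
    sym = lsbl(_wins([0.4]), _wins([0.4]), _wins([0.4]))
    assert sym[0].value == pytest.approx(0.2)  # f/2 in the symmetric star


def test_lsbl_branch_additivity():
    rng = np.random.default_rng(14)
    ab, ac, bc = (list(rng.uniform(0, 0.5, 20)) for _ in range(3))
    la = lsbl(_wins(ab), _wins(ac), _wins(bc))
    lb = lsbl(_wins(ab), _wins(bc), _wins(ac))  # permuted: branch of B
    for wa, wb, fab in zip(la, lb, ab):
        assert wa.value + wb.value == pytest.approx(fab, abs=1e-12)


def test_lsbl_grid_mismatch_rejected():
    with pytest.raises(ValueError, match="grid"):
        lsbl(_wins([0.1, 0.2]), _wins([0.1, 0.2], start=20_000), _wins([0.1, 0.2]))


def test_lsbl_isolates_the_swept_branch():
    cfg = SimConfig(n_breeds=3, samples_per_breed=[8, 8, 8], chrom_length=1_000_000,
                    snp_density=1 / 1000, drift_F=0.05,
                    sweep_spec=SweepTruth("1", 500_000, 540_000, ("A",)),
                    seed=15, breed_names=["A", "B", "C"])
    panel, sweep, _ = simulate_panel(cfg)
    pops = cfg.population_map()
    lengths = {"1": cfg.chrom_length}
    ab = windowed_fst(panel, pops, "A", "B", chrom_lengths=lengths)
    ac = windowed_fst(panel, pops, "A", "C", chrom_lengths=lengths)
    bc = windowed_fst(panel, pops, "B", "C", chrom_lengths=lengths)
    branch_a = lsbl(ab, ac, bc)
    best = max(branch_a, key=lambda w: w.value if np.isfinite(w.value) else -np.inf)
    assert best.start < sweep.end and sweep.start < best.end
    # branches of B and C are not elevated at the sweep
    branch_b = lsbl(ab, bc, ac)
    branch_c = lsbl(ac, bc, ab)
    for track in (branch_b, branch_c):
        sweep_vals = [w.value for w in track
                      if w.start < sweep.end and sweep.start < w.end]
        assert max(sweep_vals) < best.value


# ----------------------------------------------------------------------
# candidate calling and merging


def test_exactly_three_percent_flagged_for_distinct_values():
    rng = np.random.default_rng(42)
    windows = _wins(list(rng.standard_normal(10_000)))
    flagged, thr = call_candidates(windows, tail=0.03)
    n = sum(w.candidate for w in flagged)
    assert n == 300
    assert all(w.value >= thr for w in flagged if w.candidate)


def test_all_equal_values_flag_everything_with_warning():
    windows = _wins([0.5] * 50)
    with pytest.warns(UserWarning):
        flagged, _ = call_candidates(windows, tail=0.03)
    assert all(w.candidate for w in flagged)


def test_na_windows_excluded_from_quantile():
    vals = list(np.linspace(0, 1, 100)) + [np.nan] * 50
    flagged, thr = call_candidates(_wins(vals), tail=0.03)
    assert sum(w.candidate for w in flagged) == 3
    assert not any(w.candidate for w in flagged if not np.isfinite(w.value))


@pytest.mark.parametrize("tail", [0.0, 0.5, -0.1, 1.0])
def test_invalid_tail_rejected(tail):
    with pytest.raises(ValueError):
        call_candidates(_wins([1.0, 2.0]), tail=tail)


def test_disjoint_candidates_give_no_regions():
    a = _wins([1, 0, 0, 0])
    b = _wins([0, 0, 0, 1])
    fa, _ = call_candidates(a, tail=0.3)
    fb, _ = call_candidates(b, tail=0.3)
    assert intersect_and_merge(fa, fb) == []


def test_three_consecutive_windows_merge_to_80kb():
    vals = [0.0] * 10
    for k in (4, 5, 6):
        vals[k] = 1.0
    fa, _ = call_candidates(_wins(vals), tail=0.3)
    fb, _ = call_candidates(_wins(vals), tail=0.3)
    regions = intersect_and_merge(fa, fb)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start, r.end) == (80_000, 160_000) and r.length == 80_000
    assert r.sources == frozenset({"fst", "xpehh"})


def test_mismatched_grids_rejected():
    fa, _ = call_candidates(_wins([1, 2, 3]), tail=0.3)
    fb, _ = call_candidates(_wins([1, 2, 3], start=10_000), tail=0.3)
    with pytest.raises(ValueError, match="grid"):
        intersect_and_merge(fa, fb)
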