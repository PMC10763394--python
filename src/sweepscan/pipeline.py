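"""End-to-end orchestration: simulate -> filter -> diversity -> structure ->
scan -> haplotypes -> annotate, from a single YAML config.

Every stage writes plain-text outputs into a run directory, and a
manifest records parameters, derived seeds and per-stage row counts.
Re-running an identical config reproduces identical outputs (the
manifest differs only in its timestamp).
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import annotation as ann
from . import diversity as div
from . import haplotypes as hap
from . import selection as sel
from . import structure as struct
from . import variants
from .panel import PopulationMap
from .synthetic import SimConfig, SweepTruth, simulate_panel, write_fixture

logger = logging.getLogger(__name__)

#: Analysis defaults: 40 kb windows / 20 kb step, 3% right tail,
#: MAF > 0.05, call rate > 0.9, ROH rules as in :class:`~sweepscan.diversity.ROHParams`,
#: haplotype count strictly > 2.
DEFAULTS = {
    "filter": {"maf_min": 0.05, "call_rate_min": 0.9},
    "scan": {"window_bp": 40_000, "step_bp": 20_000, "tail": 0.03},
    "haplo": {"min_count": 2},
}


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def demo_config() -> dict:
    """The bundled four-breed demo configuration (planted sweep + ROH)."""
    from importlib.resources import files

    text = files("sweepscan").joinpath("data/demo.yaml").read_text()
    return yaml.safe_load(text)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


def _sim_config_from(cfg: dict, seed: int) -> SimConfig:
    sim = dict(cfg)
    sweep = None
    if sim.get("sweep"):
        s = sim.pop("sweep")
        sweep = SweepTruth(
            chrom=str(s["chrom"]), start=int(s["start"]), end=int(s["end"]),
            swept_breeds=tuple(s["swept_breeds"]),
            swept_haplotype=s.get("swept_haplotype"),
        )
    roh = [tuple(r) for r in sim.pop("roh", [])]
    return SimConfig(
        n_breeds=sim["n_breeds"],
        samples_per_breed=list(sim["samples_per_breed"]),
        breed_names=sim.get("breed_names"),
        breed_groups=dict(sim.get("breed_groups", {})),
        n_chromosomes=sim.get("n_chromosomes", 1),
        chrom_length=int(sim.get("chrom_length", 2_000_000)),
        snp_density=float(sim.get("snp_density", 1e-3)),
        drift_F=sim.get("drift_F", 0.05),
        missing_rate=float(sim.get("missing_rate", 0.0)),
        sweep_spec=sweep,
        roh_spec=roh,
        seed=seed,
    )


def run(config: dict, out_dir) -> Path:
    """Execute all configured stages in dependency order.

    Returns the run directory.  A stage failure raises with the stage
    name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(config.get("seed", 0))
    manifest: dict = {"version": __version__, "seed": master, "stages": {}}
    stage = "init"
    try:
        # ---------------- input or simulation
        truth = None
        chrom_lengths = None
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = _sim_config_from(config["simulate"], stage_seed(master, "simulate"))
            panel, truth, roh_truth = simulate_panel(sim_cfg)
            pops = sim_cfg.population_map()
            chrom_lengths = {str(c + 1): sim_cfg.chrom_length
                             for c in range(sim_cfg.n_chromosomes)}
            write_fixture(panel, pops, out / "simulate", sweep=truth, roh=roh_truth,
                          chrom_lengths=chrom_lengths)
            manifest["stages"]["simulate"] = {
                "seed": sim_cfg.seed, "n_samples": panel.n_samples,
                "n_sites": panel.n_sites,
            }
        elif "input" in config:
            stage = "input"
            panel = variants.read_vcf(config["input"]["vcf"])
            pops = PopulationMap.read_tsv(config["input"]["popmap"])
            manifest["stages"]["input"] = {
                "n_samples": panel.n_samples, "n_sites": panel.n_sites,
            }
        else:
            raise ValueError("config needs a 'simulate' or 'input' section")
        pops.validate_against(panel)
        if chrom_lengths is None:
            chrom_lengths = {c: int(panel.pos[panel.sites_of(c)].max())
                             for c in panel.chromosomes()}

        # ---------------- filtering
        stage = "filter"
        fcfg = {**DEFAULTS["filter"], **config.get("filter", {})}
        panel = variants.filter_variants(panel, fcfg["maf_min"], fcfg["call_rate_min"])
        variants.write_vcf(panel, out / "filtered.vcf", contig_lengths=chrom_lengths)
        manifest["stages"]["filter"] = {**fcfg, "n_sites": panel.n_sites}

        # ---------------- diversity
        stage = "diversity"
        roh_params = div.ROHParams(**config.get("roh", {}))
        summaries = div.summarize(panel, pops, roh_params)
        with open(out / "diversity.tsv", "w") as fh:
            fh.write("breed\tn\tHo\tHe\tF_ROH\tn_roh\ttotal_roh_bp\n")
            for s in summaries:
                fh.write(f"{s.breed}\t{s.n_samples}\t{s.ho:.6f}\t{s.he:.6f}\t"
                         f"{s.f_roh:.6f}\t{s.n_roh}\t{s.total_roh_length}\n")
        with open(out / "roh.tsv", "w") as fh:
            fh.write("sample\tchrom\tstart0\tend0\tn_snps\tlength_bp\n")
            for sample in panel.samples:
                for seg in div.detect_roh(panel, sample, roh_params):
                    fh.write(f"{seg.sample}\t{seg.chrom}\t{seg.start}\t{seg.end}\t"
                             f"{seg.n_snps}\t{seg.length}\n")
        manifest["stages"]["diversity"] = {"n_breeds": len(summaries)}

        # ---------------- structure
        stage = "structure"
        ibs = struct.ibs_distance(panel)
        ibs.write_tsv(out / "ibs_matrix.tsv")
        fst_m = struct.pairwise_fst_matrix(panel, pops)
        fst_m.write_tsv(out / "fst_matrix.tsv")
        if len(fst_m.labels) >= 3:
            tree = struct.neighbor_joining(fst_m)
            (out / "nj_breeds.nwk").write_text(tree.to_newick() + "\n")
        n_pc = min(10, panel.n_samples - 1)
        coords, evr = struct.pca(panel, n_pc)
        with open(out / "pca.tsv", "w") as fh:
            fh.write("sample\t" + "\t".join(f"PC{k + 1}" for k in range(n_pc)) + "\n")
            for s, row in zip(panel.samples, coords):
                fh.write(s + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
        manifest["stages"]["structure"] = {
            "explained_variance": [round(float(x), 6) for x in evr]
        }

        # ---------------- selection scan
        stage = "scan"
        scfg = {**DEFAULTS["scan"], **config.get("scan", {})}
        pop_a, pop_b = scfg["pop_a"], scfg["pop_b"]
        w, st, tail = scfg["window_bp"], scfg["step_bp"], scfg["tail"]
        fst_w = sel.windowed_fst(panel, pops, pop_a, pop_b, w, st, chrom_lengths)
        scores = sel.xpehh_scan(panel, pops, pop_a, pop_b)
        xp_w = sel.standardize_and_window_xpehh(panel, scores, w, st, chrom_lengths)
        fst_c, fst_thr = sel.call_candidates(fst_w, tail)
        xp_c, xp_thr = sel.call_candidates(xp_w, tail)
        sel.write_window_tsv(fst_c, out / "fst_windows.tsv")
        sel.write_window_tsv(xp_c, out / "xpehh_windows.tsv")
        regions = sel.intersect_and_merge(fst_c, xp_c)
        sel.write_region_bed(regions, out / "regions.bed")
        manifest["stages"]["scan"] = {
            **{k: scfg[k] for k in ("window_bp", "step_bp", "tail")},
            "fst_threshold": round(float(fst_thr), 6),
            "xpehh_threshold": round(float(xp_thr), 6),
            "n_regions": len(regions),
            "total_region_bp": sum(r.length for r in regions),
        }
        lsbl_cfg = scfg.get("lsbl")
        if lsbl_cfg:
            a, b, c = lsbl_cfg["a"], lsbl_cfg["b"], lsbl_cfg["c"]
            ab = sel.windowed_fst(panel, pops, a, b, w, st, chrom_lengths)
            ac = sel.windowed_fst(panel, pops, a, c, w, st, chrom_lengths)
            bc = sel.windowed_fst(panel, pops, b, c, w, st, chrom_lengths)
            lsbl_w, _ = sel.call_candidates(sel.lsbl(ab, ac, bc), tail)
            sel.write_window_tsv(lsbl_w, out / "lsbl_windows.tsv")
            manifest["stages"]["scan"]["lsbl_pops"] = [a, b, c]

        # ---------------- haplotypes
        stage = "haplo"
        hcfg = {**DEFAULTS["haplo"], **config.get("haplo", {})}
        region = hcfg.get("region")
        if region is None and truth is not None:
            region = [truth.chrom, truth.start, truth.end]
        if region is not None and panel.is_phased:
            region = (str(region[0]), int(region[1]), int(region[2]))
            hs = hap.extract_haplotypes(panel, region, pops)
            table = hap.haplotype_table(hs, hcfg["min_count"])
            hap.write_haplotype_table(table, out / "haplotypes.tsv")
            if len(table) >= 2:
                net = hap.haplotype_network(table)
                hap.write_network(net, out / "network_edges.tsv")
            np.savetxt(out / "sharing.tsv", hap.sharing_matrix(hs),
                       delimiter="\t", fmt="%.6f")
            blocks = hap.find_blocks(hs)
            with open(out / "blocks.tsv", "w") as fh:
                fh.write("first\tlast\tstart0\tend0\tn_snps\tspan_bp\n")
                for blk in blocks:
                    fh.write(f"{blk.first}\t{blk.last}\t{blk.start}\t{blk.end}\t"
                             f"{blk.n_snps}\t{blk.span}\n")
            manifest["stages"]["haplo"] = {
                "region": list(region), "n_haplotypes": len(table),
                "n_blocks": len(blocks),
            }

        # ---------------- annotation
        stage = "annotate"
        gff = config.get("annotate", {}).get("gff")
        if gff is None and "simulate" in config:
            gff = out / "simulate" / "genes.gff3"
        if gff is not None:
            ga = ann.GenomeAnnotation(gff)
            hits = ann.genes_in_regions(regions, ga) if regions else {}
            with open(out / "region_genes.tsv", "w") as fh:
                fh.write("chrom\tstart0\tend0\tgenes\n")
                for (c2, s2, e2), genes in hits.items():
                    fh.write(f"{c2}\t{s2}\t{e2}\t{','.join(genes)}\n")
            manifest["stages"]["annotate"] = {
                "n_genes": len(ann.unique_genes(hits))
            }
            peaks_path = config.get("annotate", {}).get("peaks")
            if peaks_path:
                peaks = ann.read_bed(peaks_path)
                rep = ann.peak_overlap(regions, peaks)
                with open(out / "peak_overlap.tsv", "w") as fh:
                    fh.write("chrom\tstart0\tend0\toverlap_bp\tfraction\tpeaks\n")
                    for row in rep:
                        fh.write(f"{row['chrom']}\t{row['start']}\t{row['end']}\t"
                                 f"{row['overlap_bp']}\t{row['overlap_fraction']:.4f}\t"
                                 f"{','.join(row['peaks'])}\n")

        manifest["covered_autosome_bp"] = div.covered_autosome_length(panel)
        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def report(run_dir) -> dict:
    """Summary of a completed run: per-breed diversity table, candidate-region
    totals with genome fraction, and the haplotype frequency table."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}; run incomplete")
    manifest = json.loads(manifest_path.read_text())
    for stage_name, fname in (("diversity", "diversity.tsv"), ("scan", "regions.bed")):
        if not (run_dir / fname).exists():
            raise FileNotFoundError(f"stage {stage_name!r} output missing: {fname}")
    breeds = []
    with open(run_dir / "diversity.tsv") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            breeds.append(dict(zip(header, line.rstrip("\n").split("\t"))))
    regions = []
    with open(run_dir / "regions.bed") as fh:
        for line in fh:
            c, s, e, src = line.rstrip("\n").split("\t")
            regions.append({"chrom": c, "start": int(s), "end": int(e), "sources": src})
    total_bp = sum(r["end"] - r["start"] for r in regions)
    covered = manifest.get("covered_autosome_bp", 0)
    out = {
        "breeds": breeds,
        "n_regions": len(regions),
        "total_region_bp": total_bp,
        "genome_fraction": (total_bp / covered) if covered else 0.0,
        "regions": regions,
    }
    hap_path = run_dir / "haplotypes.tsv"
    if hap_path.exists():
        out["haplotypes"] = hap_path.read_text()
    return out


def format_report(rep: dict) -> str:
    lines = ["Per-breed diversity", "breed\tn\tHo\tHe\tF_ROH"]
    for b in rep["breeds"]:
        lines.append(f"{b['breed']}\t{b['n']}\t{b['Ho']}\t{b['He']}\t{b['F_ROH']}")
    lines.append("")
    lines.append(
        f"Candidate regions: {rep['n_regions']} "
        f"(total {rep['total_region_bp'] / 1e6:.2f} Mb, "
        f"{100 * rep['genome_fraction']:.2f}% of covered autosomes)"
    )
    for r in rep["regions"]:
        lines.append(f"  {r['chrom']}:{r['start']}-{r['end']}\t{r['sources']}")
    if "haplotypes" in rep:
        lines.append("")
        lines.append("Haplotype table")
        lines.append(rep["haplotypes"].rstrip("\n"))
    return "\n".join(lines) + "\n"
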