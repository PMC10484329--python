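"""End-to-end orchestration of the analysis stages on one configuration.

Stages run in dependency order — simulate, filter, stats, centromeres,
peaks, null, ancestry — each seeded deterministically from a master seed,
and the report aggregates the headline numbers (mean F_ST, split time T,
enrichment ratio, peak count, ancestry means, test p-values).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ancestry, centromeres, coalescent, peaks, popgen, simdata, variant_filter
from .matrix import read_vcf, load_populations

log = logging.getLogger("apiscan")

DEFAULT_STAGES = (
    "simulate", "filter", "stats", "centromeres", "peaks", "null", "ancestry",
)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    sim_config: simdata.SimConfig | None = None,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    fst_threshold: float = 0.255,
    null_loci: int = 50_000,
) -> dict:
    """Run the enabled stages and write report.json under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": seed, "stages": list(stages)}

    if sim_config is None:
        sim_config = simdata.SimConfig(seed=stage_seed(seed, "simulate"))

    arts = None
    if "simulate" in stages:
        log.info("stage simulate: %d SNPs", sim_config.n_snps)
        arts = simdata.generate_all(sim_config, out / "sim")
        report["simulate"] = {
            "n_snps": sim_config.n_snps,
            "n_samples": arts["matrix"].n_samples,
            "het_drone_sites": arts["het_log"],
        }
    else:
        report["simulate"] = "skipped"
        return _finish(report, out)

    matrix, ann = read_vcf(out / "sim" / "panel.vcf",
                           load_populations(out / "sim" / "pops.tsv"))

    if "filter" in stages:
        drones = [s for s, p in zip(matrix.samples, matrix.populations) if p == "M"]
        filtered, flog = variant_filter.run_filter_cascade(matrix, ann, drones)
        report["filter"] = {
            "input_sites": flog.input_sites,
            "output_sites": flog.output_sites,
            "removed": flog.removed,
        }
    else:
        filtered = matrix
        report["filter"] = "skipped"

    per_snp = None
    windows = None
    if "stats" in stages:
        _, pi_low = popgen.nucleotide_diversity_windows(
            filtered, "lowland", chrom_lengths=sim_config.chrom_lengths)
        _, pi_high = popgen.nucleotide_diversity_windows(
            filtered, "highland", chrom_lengths=sim_config.chrom_lengths)
        per_snp = popgen.wc_fst_components(filtered, "highland", "lowland")
        windows = popgen.wc_fst_windowed(
            per_snp, sim_config.window_bp, sim_config.chrom_lengths)
        reynolds = popgen.reynolds_fst_genomewide(filtered, "highland", "lowland")
        report["stats"] = {
            "pi_lowland": pi_low, "pi_highland": pi_high,
            "reynolds_fst": reynolds,
            "split_time_T": coalescent.fst_to_split_time(max(reynolds, 0.0)),
        }
        popgen.windows_to_frame(windows).to_csv(
            out / "fst_windows.tsv", sep="\t", index=False)
    else:
        report["stats"] = "skipped"

    if "centromeres" in stages:
        regions, mean_gc = centromeres.detect_all(
            out / "sim" / "ref.fa", sim_config.window_bp)
        centromeres.regions_to_bed(regions).to_csv(
            out / "centromeres.bed", sep="\t", header=False, index=False)
        report["centromeres"] = {
            "genome_mean_gc": mean_gc,
            "regions": {
                c: None if r is None else [r.start, r.end]
                for c, r in regions.items()
            },
        }
    else:
        regions = {}
        report["centromeres"] = "skipped"

    called = []
    if "peaks" in stages and windows is not None:
        vals = np.array([w.value for w in windows])
        thr = peaks.quantile_thresholds(vals)
        called = peaks.call_peaks(windows, thr)
        genes = arts["genes"]
        for p in called:
            peaks.annotate_peak_genes(p, genes)
            r = regions.get(p.chrom)
            if r is not None and not (p.end < r.start or p.start > r.end):
                p.pericentromeric = True
        peaks.peaks_to_frame(called).to_csv(out / "peaks.tsv", sep="\t", index=False)
        report["peaks"] = {
            "thresholds": thr.__dict__,
            "n_peaks": len(called),
            "n_pericentromeric": sum(p.pericentromeric for p in called),
        }
    else:
        report["peaks"] = "skipped"

    if "null" in stages and per_snp is not None:
        model = coalescent.SplitModel(
            n_loci=null_loci, seed=stage_seed(seed, "null"),
            t_split=report["stats"]["split_time_T"] / 2.0
            if isinstance(report.get("stats"), dict) else 0.0150,
        )
        panel = coalescent.simulate_snp_panel(model, threshold=fst_threshold)
        emp = per_snp["fst"].to_numpy()
        enr = coalescent.enrichment_test(emp, panel.fst, fst_threshold)
        report["null"] = {
            "model": {"n1": model.n1, "n2": model.n2,
                      "t_split": model.t_split, "n_loci": model.n_loci},
            "mean_sim_fst": panel.mean_fst,
            "enrichment": enr,
        }
    else:
        report["null"] = "skipped"

    if "ancestry" in stages:
        post = arts["posteriors"]
        pops = dict(zip(matrix.samples, matrix.populations))
        track = ancestry.population_ancestry_track(post, pops)
        positions = pd.DataFrame({
            "snp": np.arange(arts["matrix"].n_sites),
            "chrom": arts["matrix"].chrom,
            "pos": arts["matrix"].pos,
        })
        res = {
            "mean_pA_lowland": float(track["pA_lowland"].mean()),
            "mean_pA_highland": float(track["pA_highland"].mean()),
            "mean_delta": float(track["delta"].mean()),
        }
        if windows is not None:
            wf = popgen.windows_to_frame(windows)
            rho, p_rho = ancestry.correlate_fst_ancestry(
                wf, track, positions, sim_config.window_bp)
            res["spearman_fst_delta"] = {"rho": rho, "p": p_rho}
        r, p_r, n_int = ancestry.correlate_clines(track, arts["clines"])
        res["pearson_cline"] = {"r": r, "p": p_r, "n": n_int}
        report["ancestry"] = res
    else:
        report["ancestry"] = "skipped"

    return _finish(report, out)


def _finish(report: dict, out: Path) -> dict:
    path = out / "report.json"
    path.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
    return report


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
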