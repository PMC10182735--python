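"""End-to-end orchestration: simulate -> scan -> overlap -> stats -> age.

A single :class:`RunConfig` drives all stages; every stochastic quantity
in the outputs is reproducible from (config, seed).  Per-stage tables are
written as TSV/BED next to a machine-readable ``metrics.json`` and a
plain-text summary report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import divergence_stats, introgression_clock, overlap_model, synthetic_data
from .genomic_io import read_gff_exons, read_phased_vcf, read_recomb_map
from .hsr_scan import (
    ScanConfig,
    call_hsrs,
    call_thresholds,
    calls_to_frame,
    evaluate_calls,
    genomewide_mean_ratio,
    score_windows,
)
from .introgression_clock import ClockConfig
from .synthetic_data import SimConfig

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    clock: ClockConfig = field(default_factory=ClockConfig)
    fst_window_bp: int = 5_000
    callable_fst_threshold: float = 0.15
    high_fst_threshold: float = 0.6
    max_aged_hsrs: int = 40  # cap the dating stage for tractable runtimes
    seed: int = 0
    out_dir: str = "hsrscan_run"

    def __post_init__(self) -> None:
        # one global seed drives every stage
        self.sim = replace_seed(self.sim, self.seed)
        self.clock = replace_seed(self.clock, self.seed)

    def to_dict(self) -> dict:
        return {
            "sim": dataclasses.asdict(self.sim),
            "scan": dataclasses.asdict(self.scan),
            "clock": dataclasses.asdict(self.clock),
            "fst_window_bp": self.fst_window_bp,
            "callable_fst_threshold": self.callable_fst_threshold,
            "high_fst_threshold": self.high_fst_threshold,
            "max_aged_hsrs": self.max_aged_hsrs,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        scan = ScanConfig(**d.pop("scan", {}))
        clock = ClockConfig(**d.pop("clock", {}))
        return cls(sim=sim, scan=scan, clock=clock, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def replace_seed(cfg, seed: int):
    return dataclasses.replace(cfg, seed=seed)


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the metrics dict.

    Any stage failure aborts with the stage name in the exception message;
    outputs of completed stages are retained on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"config": config.to_dict()}
    stage = "simulate"
    try:
        t0 = time.time()
        data_dir = out / "data"
        manifest = synthetic_data.generate_dataset(config.sim, data_dir)
        logger.info("stage %s: %d sites, %.1fs", stage, manifest["realized"]["n_sites"], time.time() - t0)

        stage = "load"
        groups = {}
        for line in (data_dir / "groups.tsv").read_text().splitlines():
            sample, group = line.split("\t")
            groups[sample] = group
        panel = read_phased_vcf(data_dir / manifest["files"]["vcf"], groups)
        rmap = read_recomb_map(data_dir / manifest["files"]["recomb_map"])
        exons = read_gff_exons(data_dir / manifest["files"]["gff"])
        chrom_lengths = {c: int(v) for c, v in manifest["chrom_lengths"].items()}

        stage = "scan"
        t0 = time.time()
        query = panel.subset_group("query")
        ref_a = panel.subset_group("ref_A")
        ref_b = panel.subset_group("ref_B")
        scores = score_windows(query, ref_a, ref_b, config.scan, chrom_lengths)
        mean_ratio = genomewide_mean_ratio(scores)
        low, high = call_thresholds(mean_ratio, config.scan.fold_threshold)
        calls = call_hsrs(scores, mean_ratio, config.scan)
        scores.to_csv(out / "window_scores.tsv", sep="\t", index=False)
        calls_df = calls_to_frame(calls)
        calls_df.to_csv(out / "hsr_calls.tsv", sep="\t", index=False)
        n_filtered = int(scores["filtered"].sum())
        logger.info(
            "stage %s: mean ratio %.3f, %d calls, %d/%d windows filtered, %.1fs",
            stage, mean_ratio, len(calls), n_filtered, len(scores), time.time() - t0,
        )
        metrics["scan"] = {
            "mean_ratio": mean_ratio,
            "threshold_low": low,
            "threshold_high": high,
            "n_windows_scored": len(scores),
            "n_windows_filtered": n_filtered,
            "n_hsrs_A": int((calls_df["origin"] == "A").sum()),
            "n_hsrs_B": int((calls_df["origin"] == "B").sum()),
            "hsr_bases_A": int(calls_df.loc[calls_df["origin"] == "A", "size_bp"].sum()),
            "hsr_bases_B": int(calls_df.loc[calls_df["origin"] == "B", "size_bp"].sum()),
        }

        stage = "truth-evaluation"
        truth_path = data_dir / manifest["files"]["truth_bed"]
        if truth_path.stat().st_size > 0:
            # BED columns: chrom start end origin hap; relabel by haplotype id
            import pandas as pd

            from .genomic_io import IntervalSet

            bed = pd.read_csv(truth_path, sep="\t", header=None,
                              names=["chrom", "start", "end", "origin", "hap"])
            truth_iv = IntervalSet(
                bed["chrom"].to_numpy(object), bed["start"].to_numpy(),
                bed["end"].to_numpy(), bed["hap"].to_numpy(object),
            )
            ev = evaluate_calls(calls, truth_iv, origin="A",
                                min_truth_bp=2 * config.scan.window_size_bp)
            metrics["truth"] = {
                **{k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in ev.items()},
                "admix_fraction_mean": manifest["realized"]["admix_fraction_mean"],
            }

        stage = "diversity"
        t0 = time.time()
        div = divergence_stats.windowed_diversity(
            panel, "ref_A", "ref_B", config.fst_window_bp, chrom_lengths
        )
        div.to_csv(out / "diversity_windows.tsv", sep="\t", index=False)
        s_callable, callable_mask = overlap_model.callable_genome_size(
            div, config.callable_fst_threshold
        )
        metrics["diversity"] = {
            "mean_pi_ref_A": float(div["pi_ref_A"].mean()),
            "mean_pi_ref_B": float(div["pi_ref_B"].mean()),
            "mean_dxy": float(div["dxy"].mean()),
            "mean_fst": float(div["fst"].mean(skipna=True)),
            "s_callable": s_callable,
        }
        logger.info("stage %s: S_callable=%d bp, %.1fs", stage, s_callable, time.time() - t0)

        stage = "overlap"
        n_q = config.sim.n_query_haps
        hap_ids = query.hap_ids
        overlap_out = {}
        tracks = {}
        for origin in ("A", "B"):
            track = overlap_model.overlap_track(calls, n_q, chrom_lengths, origin)
            tracks[origin] = track
            fracs = overlap_model.haplotype_fractions(calls, callable_mask, hap_ids, origin)
            table = overlap_model.overlap_table(track, fracs, s_callable)
            table.to_csv(out / f"overlap_{origin}.tsv", sep="\t", index=False)
            full = overlap_model.recurrent_regions(track, n_q)
            obs_full = track.bases_at(n_q)
            exp_full = table.attrs["expected_full_overlap_product"]
            overlap_out[origin] = {
                "fractions": fracs,
                "observed_full_overlap_bases": obs_full,
                "expected_full_overlap_bases": exp_full,
                "n_full_overlap_regions": len(full),
                "m_full_overlap": (
                    overlap_model.m_value(obs_full, exp_full)
                    if obs_full > 0 and exp_full > 0
                    else None
                ),
            }
        metrics["overlap"] = overlap_out

        stage = "enrichment"
        enrich = {}
        for origin in ("A", "B"):
            try:
                table = divergence_stats.hsr_fst_enrichment(
                    tracks[origin], div, config.high_fst_threshold
                )
                table.to_csv(out / f"enrichment_{origin}.tsv", sep="\t", index=False)
                enrich[origin] = {
                    "genome_fraction_high_fst": table.attrs["genome_fraction_high"],
                }
            except ValueError:
                enrich[origin] = None
        full_a = overlap_model.recurrent_regions(tracks["A"], n_q)
        if len(full_a):
            enrich["exon_density_full_A"] = divergence_stats.exon_density(full_a, exons)
            rc = divergence_stats.rate_contrast(full_a, rmap)
            enrich["rate_contrast_full_A"] = rc
        enrich["exon_density_genome"] = exons.exon_bases / sum(chrom_lengths.values())
        metrics["enrichment"] = enrich

        stage = "age"
        t0 = time.time()
        aged = [c for c in calls if c.origin == "A"]
        aged = aged[: config.max_aged_hsrs]
        estimates = [
            introgression_clock.estimate_age(c, rmap, config.clock, i)
            for i, c in enumerate(aged)
        ]
        if estimates:
            summary = introgression_clock.summarize_ages(estimates)
            ages_df = introgression_clock.ages_to_frame(estimates, config.clock)
            ages_df.to_csv(out / "hsr_ages.tsv", sep="\t", index=False)
            med_years = introgression_clock.generations_to_years(
                summary["median_generations"], config.clock.generation_time_years
            )
            metrics["age"] = {
                **summary,
                "median_years": med_years,
                "median_kya": introgression_clock.years_to_kya_display(med_years),
            }
        else:
            metrics["age"] = None
        logger.info("stage %s: %d HSRs dated, %.1fs", stage, len(estimates), time.time() - t0)
    except Exception as exc:  # annotate with failing stage, keep partial outputs
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    _write_report(metrics, out / "report.txt")
    return metrics


def _write_report(metrics: dict, path: Path) -> None:
    lines = ["hsrscan pipeline report", "=" * 23, ""]
    sc = metrics.get("scan", {})
    lines.append(f"mean distance ratio     : {sc.get('mean_ratio', float('nan')):.3f}")
    lines.append(f"call thresholds (lo/hi) : {sc.get('threshold_low', 0):.3f} / {sc.get('threshold_high', 0):.3f}")
    lines.append(f"HSR calls (A/B)         : {sc.get('n_hsrs_A')} / {sc.get('n_hsrs_B')}")
    lines.append(f"HSR bases (A/B)         : {sc.get('hsr_bases_A')} / {sc.get('hsr_bases_B')}")
    dv = metrics.get("diversity", {})
    lines.append(f"mean pi A / pi B        : {dv.get('mean_pi_ref_A', 0):.5f} / {dv.get('mean_pi_ref_B', 0):.5f}")
    lines.append(f"mean dxy / FST          : {dv.get('mean_dxy', 0):.5f} / {dv.get('mean_fst', 0):.3f}")
    lines.append(f"S_callable              : {dv.get('s_callable')}")
    tr = metrics.get("truth")
    if tr:
        lines.append(f"truth F1 (origin A)     : {tr.get('f1'):.3f}")
        lines.append(f"true admixture fraction : {tr.get('admix_fraction_mean'):.3f}")
    ag = metrics.get("age")
    if ag:
        lines.append(f"median age              : {ag['median_generations']:.0f} generations"
                     f" (~{ag['median_kya']} kYA)")
    path.write_text("\n".join(lines) + "\n")
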