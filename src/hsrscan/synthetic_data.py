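"""Synthetic phased-haplotype datasets with known introgression truth.

The generator emulates the statistical structure the scan assumes: two
deeply diverged species reference panels (A and B), an admixed query
population of species-B descent carrying species-A blocks at known
positions, a heterogeneous 100 kb recombination map, and toy exon
annotation.

Allele-frequency model
----------------------
Each biallelic site falls into one of two classes:

* a **species-fixed difference** (probability ``fixed_diff_fraction``):
  the two species carry opposite alleles, contributing 1 per site to
  between-species divergence and 0 to within-species diversity;
* a **shared polymorphism**: an ancestral frequency ``p ~ Beta(1, 1)`` is
  drawn, and each species' frequency is drawn from the Balding–Nichols
  construction ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` with ``F =
  divergence_fst`` (``F = 0`` means both species share ``p``).

``fixed_diff_fraction`` defaults to the value that makes the expected
per-site d_xy equal ``target_dxy`` given the SNP density: with ancestral
``Beta(1,1)`` a polymorphic site contributes ``2 E[p(1-p)] = 1/3`` to
d_xy, so ``phi = (target_dxy/snp_density - 1/3) / (1 - 1/3)``.

Query haplotypes are species-B draws: outside introgressed blocks each
allele is Bernoulli in the realized species-B panel frequency, except at
species-diagnostic sites (opposite fixation in the two panels) where the
query carries the species-A allele with probability ``ils_fraction``,
emulating incomplete lineage sorting and the old divergence between the
admixed population and the B reference panel.  Inside a block the
haplotype copies a randomly chosen species-A panel haplotype with a small
per-site copy-error probability, so blocks are near-identical, not
identical, to a donor.

Introgressed blocks form a stationary Boolean process: Poisson starts
with exponential lengths, the start rate set to ``-ln(1 - admix_prop) /
block_length_mean_bp`` so the expected covered fraction is exactly
``admix_prop``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genomic_io import (
    IntervalSet,
    PhasedPanel,
    RecombMap,
    concat_panels,
    union_intervals,
    write_bed,
    write_phased_vcf,
    write_recomb_map,
)

_ANCESTRAL_BETA_MEAN_2PQ = 1.0 / 3.0  # 2 E[p(1-p)] under Beta(1, 1)
_NUCS = np.array(["A", "C", "G", "T"], dtype=object)


@dataclass
class SimConfig:
    """Parameters of the synthetic hybrid-population generator.

    Defaults emulate the study design the pipeline targets: a 10 Mb
    chromosome, ~5 SNPs/kb (an expected 100 SNPs per 20 kb scan window),
    between-species d_xy ~ 0.43%, reference panels of 16 (species A) and
    8 (species B) haplotypes, 8 admixed query haplotypes with ~25%
    species-A ancestry in blocks of mean 100 kb, and a background
    recombination rate of 2.1 cM/Mb on a 100 kb gamma-heterogeneous map.
    """

    n_chrom: int = 1
    chrom_length_bp: int = 10_000_000
    snp_density: float = 5e-3
    divergence_fst: float = 0.2
    target_dxy: float = 0.0043
    fixed_diff_fraction: float | None = None  # derived from target_dxy when None
    ils_fraction: float = 0.4
    n_ref_a_haps: int = 16
    n_ref_b_haps: int = 8
    n_query_haps: int = 8
    admix_prop: float = 0.25
    block_length_mean_bp: float = 100_000.0
    copy_error_rate: float = 1e-4
    map_total_cM: float | None = None  # default: 2.1 cM/Mb x chromosome length
    map_resolution_bp: int = 100_000
    map_profile: str = "gamma"  # "gamma" or "uniform"
    map_gamma_shape: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_chrom", "chrom_length_bp", "n_ref_a_haps", "n_ref_b_haps",
                     "n_query_haps", "map_resolution_bp"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        if not 0.0 <= self.admix_prop <= 1.0:
            raise ValueError("admix_prop must be in [0, 1]")
        if not 0.0 <= self.divergence_fst < 1.0:
            raise ValueError("divergence_fst must be in [0, 1)")
        if not 0.0 <= self.ils_fraction < 0.5:
            raise ValueError("ils_fraction must be in [0, 0.5)")
        if self.target_dxy <= 0:
            raise ValueError("target_dxy must be > 0")
        if self.fixed_diff_fraction is not None and not 0.0 <= self.fixed_diff_fraction <= 1.0:
            raise ValueError("fixed_diff_fraction must be in [0, 1]")
        if self.block_length_mean_bp <= 0:
            raise ValueError("block_length_mean_bp must be > 0")
        if not 0.0 <= self.copy_error_rate < 1.0:
            raise ValueError("copy_error_rate must be in [0, 1)")
        if self.map_total_cM is not None and self.map_total_cM <= 0:
            raise ValueError("map_total_cM must be > 0")
        if self.map_profile not in ("gamma", "uniform"):
            raise ValueError("map_profile must be 'gamma' or 'uniform'")

    @property
    def resolved_fixed_fraction(self) -> float:
        if self.fixed_diff_fraction is not None:
            return self.fixed_diff_fraction
        per_snp = self.target_dxy / self.snp_density
        phi = (per_snp - _ANCESTRAL_BETA_MEAN_2PQ) / (1.0 - _ANCESTRAL_BETA_MEAN_2PQ)
        if not 0.0 <= phi <= 1.0:
            raise ValueError(
                "target_dxy unreachable at this snp_density: "
                f"implied fixed-difference fraction {phi:.3f} outside [0, 1]"
            )
        return phi

    @property
    def resolved_map_total_cm(self) -> float:
        if self.map_total_cM is not None:
            return self.map_total_cM
        return 2.1 * self.chrom_length_bp / 1e6

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def chrom_lengths(self) -> dict[str, int]:
        return {c: self.chrom_length_bp for c in self.chrom_names()}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthBlocks:
    """Known species-A intervals per query haplotype (non-overlapping, sorted)."""

    blocks: dict[str, list[tuple[str, int, int]]]  # hap_id -> [(chrom, start, end)]
    chrom_lengths: dict[str, int]

    def fraction(self, hap_id: str) -> float:
        total = sum(e - s for _, s, e in self.blocks.get(hap_id, []))
        return total / sum(self.chrom_lengths.values())

    def mean_fraction(self) -> float:
        if not self.blocks:
            return 0.0
        return float(np.mean([self.fraction(h) for h in self.blocks]))

    def to_intervalset(self) -> IntervalSet:
        recs = [
            (chrom, s, e, hap)
            for hap, ivs in self.blocks.items()
            for chrom, s, e in ivs
        ]
        return IntervalSet.from_records(recs)


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def simulate_reference_panels(config: SimConfig) -> PhasedPanel:
    """Draw the two species reference panels over a shared Poisson site set."""
    config.validate()
    rng = _rng(config, 0)
    phi = config.resolved_fixed_fraction
    F = config.divergence_fst

    chroms, poss, refs, alts = [], [], [], []
    freqs_a, freqs_b = [], []
    for chrom in config.chrom_names():
        n_sites = rng.poisson(config.chrom_length_bp * config.snp_density)
        pos = np.unique(rng.integers(0, config.chrom_length_bp, size=n_sites))
        m = pos.size
        fixed = rng.random(m) < phi
        orient = rng.random(m) < 0.5
        p = np.clip(rng.beta(1.0, 1.0, size=m), 1e-6, 1 - 1e-6)
        if F > 0:
            nu = (1.0 - F) / F
            pa = rng.beta(p * nu, (1 - p) * nu)
            pb = rng.beta(p * nu, (1 - p) * nu)
        else:
            pa = p.copy()
            pb = p.copy()
        pa[fixed] = np.where(orient[fixed], 1.0, 0.0)
        pb[fixed] = np.where(orient[fixed], 0.0, 1.0)
        ref_nuc = rng.integers(0, 4, size=m)
        alt_nuc = (ref_nuc + rng.integers(1, 4, size=m)) % 4
        chroms.append(np.full(m, chrom, dtype=object))
        poss.append(pos)
        refs.append(_NUCS[ref_nuc])
        alts.append(_NUCS[alt_nuc])
        freqs_a.append(pa)
        freqs_b.append(pb)

    pa = np.concatenate(freqs_a)
    pb = np.concatenate(freqs_b)
    m = pa.size
    haps_a = (rng.random((config.n_ref_a_haps, m)) < pa).astype(np.uint8)
    haps_b = (rng.random((config.n_ref_b_haps, m)) < pb).astype(np.uint8)

    def labels(prefix: str, n_haps: int, group: str):
        n_ind = (n_haps + 1) // 2
        samples = np.repeat([f"{prefix}{i + 1}" for i in range(n_ind)], 2)[:n_haps]
        phases = np.tile([0, 1], n_ind)[:n_haps]
        return samples.astype(object), phases, np.full(n_haps, group, dtype=object)

    sa, pha, ga = labels("a", config.n_ref_a_haps, "ref_A")
    sb, phb, gb = labels("b", config.n_ref_b_haps, "ref_B")
    site_args = dict(
        chrom=np.concatenate(chroms),
        pos=np.concatenate(poss),
        ref=np.concatenate(refs),
        alt=np.concatenate(alts),
    )
    panel_a = PhasedPanel(haplotypes=haps_a, samples=sa, phases=pha, groups=ga, **site_args)
    panel_b = PhasedPanel(haplotypes=haps_b, samples=sb, phases=phb, groups=gb, **site_args)
    return concat_panels([panel_a, panel_b])


def _draw_blocks(config: SimConfig, rng: np.random.Generator, chrom: str) -> list[tuple[str, int, int]]:
    """Stationary Boolean process of species-A blocks on one chromosome."""
    L = config.chrom_length_bp
    if config.admix_prop == 0.0:
        return []
    if config.admix_prop >= 1.0:
        return [(chrom, 0, L)]
    mean_len = config.block_length_mean_bp
    rate = -np.log1p(-config.admix_prop) / mean_len  # per-bp start rate
    pad = 8.0 * mean_len  # allow blocks overlapping the left edge
    n = rng.poisson(rate * (L + pad))
    starts = rng.uniform(-pad, L, size=n)
    lengths = rng.exponential(mean_len, size=n)
    ivs = []
    for s, l in zip(starts, lengths):
        a, b = max(0, int(s)), min(L, int(s + l))
        if b > a:
            ivs.append((chrom, a, b))
    if not ivs:
        return []
    merged = union_intervals(IntervalSet.from_records(ivs))
    return merged.records()


def simulate_admixed_haplotypes(
    config: SimConfig, panels: PhasedPanel
) -> tuple[PhasedPanel, TruthBlocks]:
    """Draw admixed query haplotypes over the panels' site set, with truth."""
    config.validate()
    rng = _rng(config, 1)
    ref_a = panels.subset_group("ref_A")
    ref_b = panels.subset_group("ref_B")
    if not ref_a.same_sites(ref_b) or not ref_a.same_sites(panels):
        raise ValueError("reference panels do not share the site set")

    pa_hat = ref_a.allele_freq()
    pb_hat = ref_b.allele_freq()
    diagnostic = ((pa_hat == 0) & (pb_hat == 1)) | ((pa_hat == 1) & (pb_hat == 0))
    a_allele = np.where(pa_hat >= 0.5, 1, 0).astype(np.uint8)

    m = panels.n_sites
    n_q = config.n_query_haps
    haps = np.empty((n_q, m), dtype=np.uint8)
    blocks: dict[str, list[tuple[str, int, int]]] = {}

    n_ind = (n_q + 1) // 2
    samples = np.repeat([f"q{i + 1}" for i in range(n_ind)], 2)[:n_q].astype(object)
    phases = np.tile([0, 1], n_ind)[:n_q]
    hap_ids = [f"{s}_{p}" for s, p in zip(samples, phases)]

    for h in range(n_q):
        # species-B background draw
        bg = (rng.random(m) < pb_hat).astype(np.uint8)
        flip_to_a = diagnostic & (rng.random(m) < config.ils_fraction)
        bg[flip_to_a] = a_allele[flip_to_a]
        hap = bg
        hap_blocks: list[tuple[str, int, int]] = []
        for chrom in config.chrom_names():
            for chrom_, s, e in _draw_blocks(config, rng, chrom):
                donor = int(rng.integers(0, ref_a.n_haps))
                sl = panels.site_range(chrom, s, e)
                copied = ref_a.haplotypes[donor, sl].copy()
                if config.copy_error_rate > 0:
                    err = rng.random(copied.size) < config.copy_error_rate
                    copied[err] = 1 - copied[err]
                hap[sl] = copied
                hap_blocks.append((chrom, s, e))
        haps[h] = hap
        blocks[hap_ids[h]] = sorted(hap_blocks, key=lambda t: (t[0], t[1]))

    query = PhasedPanel(
        chrom=panels.chrom,
        pos=panels.pos,
        ref=panels.ref,
        alt=panels.alt,
        haplotypes=haps,
        samples=samples,
        phases=phases,
        groups=np.full(n_q, "query", dtype=object),
    )
    truth = TruthBlocks(blocks=blocks, chrom_lengths=config.chrom_lengths())
    return query, truth


def simulate_recombination_map(config: SimConfig) -> RecombMap:
    """Windowed map: rates per 100 kb, rescaled so each chromosome's genetic
    length equals ``map_total_cM`` exactly."""
    config.validate()
    total_cm = config.resolved_map_total_cm
    if total_cm <= 0:
        raise ValueError("map total must be positive")
    rng = _rng(config, 2)
    starts, ends, rates = {}, {}, {}
    for chrom in config.chrom_names():
        L = config.chrom_length_bp
        s = np.arange(0, L, config.map_resolution_bp, dtype=np.int64)
        e = np.minimum(s + config.map_resolution_bp, L)
        span_mb = (e - s) / 1e6
        if config.map_profile == "uniform":
            raw = np.ones(s.size)
        else:
            raw = rng.gamma(config.map_gamma_shape, 1.0, size=s.size)
            if raw.sum() == 0:
                raw = np.ones(s.size)
        r = raw / (raw * span_mb).sum() * total_cm  # cM/Mb, exact total
        starts[chrom], ends[chrom], rates[chrom] = s, e, r
    return RecombMap(starts=starts, ends=ends, rates=rates)


def _toy_exons(config: SimConfig, rng: np.random.Generator) -> IntervalSet:
    """Toy exon annotation: ~8.9% of each chromosome in short exons."""
    recs = []
    for chrom in config.chrom_names():
        L = config.chrom_length_bp
        n = max(1, int(0.089 * L / 250))
        starts = np.sort(rng.integers(0, L - 300, size=n))
        lengths = np.maximum(30, rng.poisson(250, size=n))
        for s, l in zip(starts, lengths):
            recs.append((chrom, int(s), int(min(s + l, L))))
    return union_intervals(IntervalSet.from_records(recs))


def generate_dataset(config: SimConfig, out_dir: str | Path) -> dict:
    """Write the full synthetic dataset to ``out_dir`` and return a manifest.

    Files: phased VCF, per-haplotype truth BED (origin label + haplotype
    id), recombination map TSV, toy exon GFF3, group-assignment TSV, and a
    YAML manifest with realized summary parameters.  Accessible bases per
    window equal the window length (every base is accessible), recorded in
    the manifest so diversity denominators need no invariant VCF records.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    panels = simulate_reference_panels(config)
    query, truth = simulate_admixed_haplotypes(config, panels)
    rmap = simulate_recombination_map(config)
    full = concat_panels([query, panels])

    vcf_path = out_dir / "panel.vcf"
    write_phased_vcf(full, vcf_path)

    groups_path = out_dir / "groups.tsv"
    pd.DataFrame(
        {"sample": list(dict.fromkeys(full.samples)),
         "group": [full.groups[np.flatnonzero(full.samples == s)[0]]
                   for s in dict.fromkeys(full.samples)]}
    ).to_csv(groups_path, sep="\t", index=False, header=False)

    truth_path = out_dir / "truth_blocks.bed"
    recs = truth.to_intervalset()
    if len(recs):
        labeled = IntervalSet(recs.chrom, recs.start, recs.end, np.array(["A"] * len(recs), dtype=object))
        write_bed(labeled, truth_path, extra=pd.DataFrame({"hap": recs.label}))
    else:
        truth_path.write_text("")

    map_path = out_dir / "recomb_map.tsv"
    write_recomb_map(rmap, map_path)

    gff_path = out_dir / "exons.gff3"
    exons = _toy_exons(config, _rng(config, 3))
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in config.chrom_names():
            fh.write(f"##sequence-region {chrom} 1 {config.chrom_length_bp}\n")
        for i, (chrom, s, e) in enumerate(exons.records()):
            fh.write(f"{chrom}\ttoy\texon\t{s + 1}\t{e}\t.\t+\t.\tID=exon{i + 1}\n")

    # realized summaries
    pa_hat = panels.subset_group("ref_A").allele_freq()
    pb_hat = panels.subset_group("ref_B").allele_freq()
    genome = sum(config.chrom_lengths().values())
    realized_dxy = float((pa_hat * (1 - pb_hat) + pb_hat * (1 - pa_hat)).sum() / genome)

    manifest = {
        "files": {
            "vcf": vcf_path.name,
            "groups": groups_path.name,
            "truth_bed": truth_path.name,
            "recomb_map": map_path.name,
            "gff": gff_path.name,
        },
        "config": config.to_dict(),
        "chrom_lengths": config.chrom_lengths(),
        "accessible_bases": "all",  # every base accessible; denominators = window length
        "realized": {
            "n_sites": int(full.n_sites),
            "dxy": realized_dxy,
            "admix_fraction_per_hap": {h: truth.fraction(h) for h in truth.blocks},
            "admix_fraction_mean": truth.mean_fraction(),
            "map_total_cM": {c: rmap.total_cm(c) for c in rmap.chroms},
        },
    }
    with open(out_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest
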