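"""Shared fixtures: synthetic datasets at the pipeline's default scale.

Session-scoped so the expensive 10 Mb simulations are built once and
shared between the unit and acceptance layers.
"""

import numpy as np
import pytest

from hsrscan.genomic_io import PhasedPanel
from hsrscan.hsr_scan import ScanConfig, call_hsrs, genomewide_mean_ratio, score_windows
from hsrscan.synthetic_data import (
    SimConfig,
    simulate_admixed_haplotypes,
    simulate_recombination_map,
    simulate_reference_panels,
)


@pytest.fixture(scope="session")
def default_sim():
    """Default 10 Mb admixed dataset (8 query haplotypes, 25% species-A)."""
    cfg = SimConfig(seed=1)
    panels = simulate_reference_panels(cfg)
    query, truth = simulate_admixed_haplotypes(cfg, panels)
    return cfg, panels, query, truth


@pytest.fixture(scope="session")
def default_scan(default_sim):
    cfg, panels, query, truth = default_sim
    scan_cfg = ScanConfig()
    scores = score_windows(
        query,
        panels.subset_group("ref_A"),
        panels.subset_group("ref_B"),
        scan_cfg,
        cfg.chrom_lengths(),
    )
    mean_ratio = genomewide_mean_ratio(scores)
    calls = call_hsrs(scores, mean_ratio, scan_cfg)
    return scan_cfg, scores, mean_ratio, calls


@pytest.fixture(scope="session")
def null_scan():
    """Same design with admix_prop = 0: no introgression to find."""
    cfg = SimConfig(seed=2, admix_prop=0.0)
    panels = simulate_reference_panels(cfg)
    query, truth = simulate_admixed_haplotypes(cfg, panels)
    scan_cfg = ScanConfig()
    scores = score_windows(
        query,
        panels.subset_group("ref_A"),
        panels.subset_group("ref_B"),
        scan_cfg,
        cfg.chrom_lengths(),
    )
    return cfg, scores


@pytest.fixture(scope="session")
def default_map():
    cfg = SimConfig(seed=3)
    return simulate_recombination_map(cfg)


def make_panel(haps, group="query", pos=None, chrom="chr1"):
    """Small hand-built panel for unit tests."""
    haps = np.asarray(haps, dtype=np.uint8)
    n, m = haps.shape
    pos = np.arange(m) * 100 if pos is None else np.asarray(pos)
    n_ind = (n + 1) // 2
    samples = np.repeat([f"s{i}" for i in range(n_ind)], 2)[:n]
    return PhasedPanel(
        chrom=np.full(m, chrom, dtype=object),
        pos=pos,
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "T", dtype=object),
        haplotypes=haps,
        samples=samples.astype(object),
        phases=np.tile([0, 1], n_ind)[:n],
        groups=np.full(n, group, dtype=object),
    )
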