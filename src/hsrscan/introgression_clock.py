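"""Recombination-clock dating of introgressed tracts.

Each HSR is dated by forward-simulating the decay of an initially
chromosome-length introgressed tract under the recombination map: every
generation a single crossover occurs with probability p = min(1, G),
where G is the chromosome's genetic length in Morgans, placed with
per-base probability proportional to the local cM/Mb rate.  A crossover
inside the surviving tract truncates it on the side away from the focal
point (the HSR midpoint); crossovers outside the tract cannot affect it.
The replicate's age estimate is the first generation at which the
surviving tract is shorter than the observed HSR; replicates that reach
the generation cap are censored at the cap.

Generations convert to years with a fixed generation time (default 2.4
years, appropriate for Pacific herring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomic_io import RecombMap
from .hsr_scan import HSRCall

_CHUNK = 256  # crossover events drawn per batch


@dataclass
class ClockConfig:
    n_replicates: int = 100
    max_generations: int = 500_000
    generation_time_years: float = 2.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.max_generations < 1:
            raise ValueError("n_replicates and max_generations must be positive")
        if self.generation_time_years <= 0:
            raise ValueError("generation_time_years must be positive")


@dataclass
class AgeEstimate:
    """Per-replicate first-passage generations for one HSR."""

    hsr_id: str
    generations: np.ndarray  # one entry per replicate; censored entries = cap
    censored: np.ndarray  # boolean per replicate

    @property
    def median(self) -> float:
        return float(np.median(self.generations))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.generations, [25, 75])
        return float(lo), float(hi)

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean())


def simulate_tract_decay(
    rmap: RecombMap,
    chrom: str,
    focal_bp: int,
    observed_size_bp: int,
    max_generations: int,
    rng: np.random.Generator,
) -> tuple[int, bool]:
    """One replicate: (first-passage generation, censored flag).

    Returns the first generation at which the surviving tract around
    ``focal_bp`` is shorter than ``observed_size_bp``, or
    (max_generations, True) if the cap is reached first.  A zero-rate
    chromosome never recombines and is always censored.
    """
    length = rmap.chrom_length(chrom)
    if not 0 < observed_size_bp <= length:
        raise ValueError("observed_size_bp must be in (0, chromosome length]")
    if not 0 <= focal_bp < length:
        raise ValueError("focal_bp outside chromosome")
    total_cm = rmap.total_cm(chrom)
    p = min(1.0, total_cm / 100.0)  # Morgans, capped: "up to one crossover"
    if p <= 0.0:
        return max_generations, True
    lo, hi = 0.0, float(length)
    if hi - lo < observed_size_bp:
        return 1, False
    gen = 0
    edges_cm = rmap.cum_cm(chrom)
    edges_bp = np.concatenate([rmap.starts[chrom], [length]]).astype(float)
    while True:
        waits = rng.geometric(p, size=_CHUNK)
        u = rng.random(_CHUNK) * total_cm
        xs = np.interp(u, edges_cm, edges_bp)
        for w, x in zip(waits, xs):
            gen += int(w)
            if gen > max_generations:
                return max_generations, True
            if lo < x < hi:
                if x <= focal_bp:
                    lo = x
                else:
                    hi = x
                if hi - lo < observed_size_bp:
                    return gen, False


def tract_size_after(
    rmap: RecombMap,
    chrom: str,
    focal_bp: int,
    generations: int,
    rng: np.random.Generator,
) -> int:
    """Size (bp) of the surviving tract around ``focal_bp`` after a fixed
    number of generations of the same decay dynamics.

    Because truncation always keeps the focal side, the surviving tract is
    bounded by the crossovers nearest the focal point on either side,
    independent of event order, so the whole history can be drawn at once:
    the crossover count is Binomial(generations, p) and positions are iid
    on the genetic map.
    """
    length = rmap.chrom_length(chrom)
    if not 0 <= focal_bp < length:
        raise ValueError("focal_bp outside chromosome")
    total_cm = rmap.total_cm(chrom)
    p = min(1.0, total_cm / 100.0)
    if p <= 0.0:
        return length
    n = int(rng.binomial(int(generations), p))
    if n == 0:
        return length
    edges_cm = rmap.cum_cm(chrom)
    edges_bp = np.concatenate([rmap.starts[chrom], [length]]).astype(float)
    xs = np.interp(rng.random(n) * total_cm, edges_cm, edges_bp)
    below = xs[xs <= focal_bp]
    above = xs[xs > focal_bp]
    lo = below.max() if below.size else 0.0
    hi = above.min() if above.size else float(length)
    return max(1, int(round(hi - lo)))


def estimate_age(
    hsr: HSRCall,
    rmap: RecombMap,
    config: ClockConfig,
    hsr_index: int = 0,
) -> AgeEstimate:
    """Date one HSR with ``config.n_replicates`` independent decay runs.

    The focal point is the HSR physical midpoint; the per-HSR random
    stream is derived from (config.seed, hsr_index) for reproducibility.
    """
    if hsr.chrom not in rmap.chroms:
        raise ValueError(f"HSR chromosome {hsr.chrom} not covered by the map")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7, int(hsr_index)]))
    focal = (hsr.start + hsr.end) // 2
    size = min(hsr.size_bp, rmap.chrom_length(hsr.chrom))
    gens = np.empty(config.n_replicates, dtype=np.int64)
    cens = np.empty(config.n_replicates, dtype=bool)
    for i in range(config.n_replicates):
        gens[i], cens[i] = simulate_tract_decay(
            rmap, hsr.chrom, focal, size, config.max_generations, rng
        )
    hsr_id = f"{hsr.hap_id}:{hsr.chrom}:{hsr.start}-{hsr.end}:{hsr.origin}"
    return AgeEstimate(hsr_id=hsr_id, generations=gens, censored=cens)


def summarize_ages(estimates: list[AgeEstimate], range_cap: float = 1e5) -> dict:
    """Cohort summary: median over all loci (outliers beyond the display
    cap included in the median), plus the count beyond the cap."""
    if not estimates:
        raise ValueError("no age estimates to summarize")
    medians = np.array([e.median for e in estimates])
    return {
        "n_loci": len(estimates),
        "median_generations": float(np.median(medians)),
        "n_beyond_cap": int((medians > range_cap).sum()),
        "censored_fraction": float(np.mean([e.censored_fraction for e in estimates])),
    }


def generations_to_years(generations: float, generation_time_years: float = 2.4) -> float:
    if generations < 0:
        raise ValueError("generations must be non-negative")
    return generations * generation_time_years


def years_to_kya_display(years: float) -> int:
    """Display convention: thousands of years, rounded to nearest integer."""
    return int(round(years / 1000.0))


def ages_to_frame(estimates: list[AgeEstimate], config: ClockConfig) -> pd.DataFrame:
    rows = []
    for e in estimates:
        lo, hi = e.iqr
        rows.append(
            (
                e.hsr_id,
                e.median,
                lo,
                hi,
                e.censored_fraction,
                generations_to_years(e.median, config.generation_time_years),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hsr_id",
            "median_generations",
            "iqr_low",
            "iqr_high",
            "censored_fraction",
            "median_years",
        ],
    )
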