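"""Recurrence of HSRs across query haplotypes versus a binomial null.

Observed per-base overlap counts (how many of the n query haplotypes
carry a same-origin HSR at a position) are compared with a
random-placement null: with f_i the fraction of the callable genome
inside HSRs for haplotype i, the expected number of bases carried by all
n haplotypes is prod(f_i) * S_callable, and for a common fraction F the
expected bases at overlap count k follow the binomial
C(n,k) F^k (1-F)^(n-k) * S_callable.  Over-representation is reported as
M = log2(observed / expected).  The callable genome is the total length
of windows whose between-species F_ST exceeds a threshold (default 0.15),
i.e. where ancestry can be assigned confidently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic_io import IntervalSet, intersect_length, union_intervals
from .hsr_scan import HSRCall

logger = logging.getLogger(__name__)


@dataclass
class OverlapTrack:
    """Run-length encoded per-base overlap counts, one track per origin.

    For each chromosome, ``edges`` are segment boundaries (first 0, last =
    chromosome length) and ``counts[i]`` is the number of query haplotypes
    whose same-origin HSRs cover ``[edges[i], edges[i+1])``.
    """

    origin: str
    n_haps: int
    edges: dict[str, np.ndarray]
    counts: dict[str, np.ndarray]

    def bases_at(self, k: int, at_least: bool = False) -> int:
        if k > self.n_haps:
            raise ValueError(f"k={k} exceeds the number of query haplotypes ({self.n_haps})")
        total = 0
        for chrom in self.edges:
            seg = np.diff(self.edges[chrom])
            c = self.counts[chrom]
            mask = c >= k if at_least else c == k
            total += int(seg[mask].sum())
        return total

    def count_at(self, chrom: str, pos: int) -> int:
        i = np.searchsorted(self.edges[chrom], pos, "right") - 1
        i = min(max(i, 0), self.counts[chrom].size - 1)
        return int(self.counts[chrom][i])


def overlap_track(
    calls: Sequence[HSRCall],
    n_query_haps: int,
    chrom_lengths: Mapping[str, int],
    origin: str,
) -> OverlapTrack:
    """Per-base count of query haplotypes covered by same-origin HSRs."""
    per_hap: dict[str, list] = {}
    for c in calls:
        if c.origin != origin:
            continue
        per_hap.setdefault(c.hap_id, []).append((c.chrom, c.start, c.end))
    if len(per_hap) > n_query_haps:
        raise ValueError("calls reference more haplotypes than n_query_haps")
    edges: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        events: list[tuple[int, int]] = []
        for hap, ivs in per_hap.items():
            u = union_intervals(IntervalSet.from_records([iv for iv in ivs if iv[0] == chrom]))
            for _, s, e in u.records():
                events.append((s, +1))
                events.append((min(e, length), -1))
        pts = sorted({0, length} | {p for p, _ in events})
        pts_arr = np.array(pts, dtype=np.int64)
        delta = np.zeros(pts_arr.size, dtype=np.int64)
        idx = {p: i for i, p in enumerate(pts)}
        for p, d in events:
            delta[idx[p]] += d
        cov = np.cumsum(delta)[:-1]  # count on each segment [pts[i], pts[i+1])
        edges[chrom] = pts_arr
        counts[chrom] = cov
    return OverlapTrack(origin=origin, n_haps=n_query_haps, edges=edges, counts=counts)


def recurrent_regions(track: OverlapTrack, k: int, at_least: bool = False) -> IntervalSet:
    """Maximal runs where the overlap count equals (or reaches) ``k``."""
    if k > track.n_haps:
        raise ValueError(f"k={k} exceeds the number of query haplotypes ({track.n_haps})")
    recs: list[tuple] = []
    for chrom in track.edges:
        e = track.edges[chrom]
        c = track.counts[chrom]
        mask = c >= k if at_least else c == k
        i = 0
        while i < mask.size:
            if mask[i]:
                j = i
                while j + 1 < mask.size and mask[j + 1]:
                    j += 1
                recs.append((chrom, int(e[i]), int(e[j + 1])))
                i = j + 1
            i += 1
    return IntervalSet.from_records(recs)


def haplotype_fractions(
    calls: Sequence[HSRCall],
    callable_mask: IntervalSet,
    hap_ids: Sequence[str],
    origin: str,
) -> dict[str, float]:
    """f_i: HSR bases of each haplotype inside the callable mask, over S_callable."""
    from .genomic_io import union_length

    s_callable = union_length(callable_mask)
    if s_callable <= 0:
        raise ValueError("callable genome size must be positive")
    known = set(hap_ids)
    for c in calls:
        if c.hap_id not in known:
            raise ValueError(f"call references unknown haplotype {c.hap_id!r}")
    out: dict[str, float] = {}
    for hap in hap_ids:
        ivs = IntervalSet.from_records(
            [(c.chrom, c.start, c.end) for c in calls if c.hap_id == hap and c.origin == origin]
        )
        out[hap] = intersect_length(ivs, callable_mask) / s_callable if len(ivs) else 0.0
    return out


def expected_full_overlap(fractions: Sequence[float], s_callable: float) -> float:
    """Expected bases carried by ALL haplotypes: prod(f_i) * S_callable."""
    f = np.asarray(list(fractions), dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    return float(np.prod(f) * s_callable)


def expected_overlap_binomial(F: float, s_callable: float, k: int, n_haps: int = 8) -> float:
    """Expected bases at overlap count k: C(n,k) F^k (1-F)^(n-k) * S_callable."""
    if not 0.0 <= F <= 1.0:
        raise ValueError("F must lie in [0, 1]")
    if not 0 <= k <= n_haps:
        raise ValueError(f"k must lie in [0, {n_haps}]")
    return float(math.comb(n_haps, k) * F**k * (1.0 - F) ** (n_haps - k) * s_callable)


def m_value(observed_bases: float, expected_bases: float) -> float:
    """M = log2(observed / expected); display convention is 1 decimal."""
    if observed_bases <= 0 or expected_bases <= 0:
        raise ValueError("observed and expected must be positive")
    return float(np.log2(observed_bases / expected_bases))


def per_block_chance(expected_bases: float, block_size_bp: int = 20_000) -> float:
    """Chance of finding one overlapping block of ``block_size_bp`` in the
    genome, implied by an expected number of fully-overlapping bases."""
    if expected_bases < 0 or block_size_bp <= 0:
        raise ValueError("invalid inputs")
    return expected_bases / block_size_bp


def callable_genome_size(
    fst_windows: pd.DataFrame, threshold: float = 0.15
) -> tuple[int, IntervalSet]:
    """Total bases (and mask) of windows with F_ST strictly above threshold.

    Windows with missing F_ST are non-callable; their count is logged.
    """
    required = {"chrom", "start", "end", "fst"}
    if not required <= set(fst_windows.columns):
        raise ValueError(f"fst_windows must have columns {sorted(required)}")
    n_missing = int(fst_windows["fst"].isna().sum())
    if n_missing:
        logger.info("callable_genome_size: %d windows with missing F_ST treated as non-callable", n_missing)
    keep = fst_windows[fst_windows["fst"] > threshold]
    mask = IntervalSet.from_records(
        list(zip(keep["chrom"], keep["start"].astype(int), keep["end"].astype(int)))
    )
    return int((keep["end"] - keep["start"]).sum()), mask


def overlap_table(
    track: OverlapTrack,
    fractions: Mapping[str, float],
    s_callable: float,
) -> pd.DataFrame:
    """Observed vs expected bases and M per overlap count k = 1..n.

    The binomial expectation uses F = max(f_i) (conservative); k = n
    additionally reports the exact product-form expectation.
    """
    F = max(fractions.values()) if fractions else 0.0
    rows = []
    for k in range(1, track.n_haps + 1):
        obs = track.bases_at(k, at_least=False)
        exp = expected_overlap_binomial(F, s_callable, k, track.n_haps)
        m = m_value(obs, exp) if obs > 0 and exp > 0 else float("nan")
        rows.append((k, obs, exp, m))
    df = pd.DataFrame(rows, columns=["k", "observed_bases", "expected_bases", "m_value"])
    df.attrs["expected_full_overlap_product"] = expected_full_overlap(
        list(fractions.values()), s_callable
    )
    return df
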