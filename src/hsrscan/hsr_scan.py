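"""Windowed haplotype distance-ratio scan for introgressed regions.

Each query haplotype is scored in non-overlapping 20 kb windows by the
ratio r = d_A / d_B of its minimum Hamming distances to the species-A and
species-B reference panels.  Windows where the larger of the two distances
is below ``min_max_distance`` (default 20) are filtered as uninformative.
The genome-wide mean ratio r_bar is the mean over query haplotypes of
(mean unfiltered d_A) / (mean unfiltered d_B); windows with
r <= r_bar/fold are called species-A high-similarity regions (HSRs),
windows with r >= r_bar*fold species-B HSRs, and same-origin calls on a
haplotype closer than ``merge_gap_bp`` are combined into contiguous
regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genomic_io import IntervalSet, PhasedPanel


@dataclass
class ScanConfig:
    window_size_bp: int = 20_000
    min_max_distance: int = 20
    fold_threshold: float = 8.0
    merge_gap_bp: int = 50_000

    def __post_init__(self) -> None:
        if self.window_size_bp <= 0 or self.min_max_distance <= 0 or self.merge_gap_bp <= 0:
            raise ValueError("window_size_bp, min_max_distance and merge_gap_bp must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")


class Window(NamedTuple):
    chrom: str
    start: int
    end: int
    sites: slice  # site-index slice into the shared site arrays


@dataclass
class HSRCall:
    """A contiguous called high-similarity region on one query haplotype."""

    hap_id: str
    chrom: str
    start: int
    end: int
    origin: str  # "A" or "B"
    n_windows: int

    @property
    def size_bp(self) -> int:
        return self.end - self.start


def build_windows(
    panel: PhasedPanel,
    config: ScanConfig,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[Window]:
    """Tile each chromosome into windows from position 0.

    The trailing partial window is retained.  When ``chrom_lengths`` is not
    given, each chromosome's length is taken as (last site position + 1).
    """
    windows: list[Window] = []
    w = config.window_size_bp
    for chrom in panel.chroms:
        on = np.flatnonzero(panel.chrom == chrom)
        lo, hi = int(on[0]), int(on[-1]) + 1
        pos = panel.pos[lo:hi]
        length = int(chrom_lengths[chrom]) if chrom_lengths else int(pos[-1]) + 1
        for start in range(0, length, w):
            end = min(start + w, length)
            a = lo + int(np.searchsorted(pos, start, "left"))
            b = lo + int(np.searchsorted(pos, end, "left"))
            windows.append(Window(chrom, start, end, slice(a, b)))
    return windows


def min_hamming(hap: np.ndarray, panel_haps: np.ndarray) -> int:
    """Minimum Hamming distance from ``hap`` to any row of ``panel_haps``.

    An empty site set gives distance 0 (the window will be filtered).
    """
    panel_haps = np.atleast_2d(panel_haps)
    if panel_haps.shape[0] == 0:
        raise ValueError("empty reference panel")
    if panel_haps.shape[1] != hap.shape[0]:
        raise ValueError("haplotype/panel site-dimension mismatch")
    if hap.shape[0] == 0:
        return 0
    return int((panel_haps != hap[None, :]).sum(axis=1).min())


def score_windows(
    query: PhasedPanel,
    ref_a: PhasedPanel,
    ref_b: PhasedPanel,
    config: ScanConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per (haplotype, window) distances, ratio and filter status.

    The filter is applied per haplotype: a window is flagged when that
    haplotype's max(d_A, d_B) < min_max_distance.  d_B = 0 with d_A > 0
    yields ratio +inf; d_A = d_B = 0 is always filtered (0 < 20).
    """
    config = config or ScanConfig()
    if query.n_haps == 0:
        raise ValueError("empty query panel")
    if not (query.same_sites(ref_a) and query.same_sites(ref_b)):
        raise ValueError("query and reference panels must share the site set")
    windows = build_windows(query, config, chrom_lengths)
    hap_ids = query.hap_ids
    rows = []
    for win in windows:
        q = query.haplotypes[:, win.sites]
        a = ref_a.haplotypes[:, win.sites]
        b = ref_b.haplotypes[:, win.sites]
        if q.shape[1] == 0:
            d_a = np.zeros(query.n_haps, dtype=np.int64)
            d_b = np.zeros(query.n_haps, dtype=np.int64)
        else:
            d_a = (q[:, None, :] != a[None, :, :]).sum(axis=2).min(axis=1)
            d_b = (q[:, None, :] != b[None, :, :]).sum(axis=2).min(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d_b > 0, d_a / np.maximum(d_b, 1), np.where(d_a > 0, np.inf, np.nan))
        filtered = np.maximum(d_a, d_b) < config.min_max_distance
        for h in range(query.n_haps):
            rows.append(
                (hap_ids[h], win.chrom, win.start, win.end,
                 int(d_a[h]), int(d_b[h]), float(ratio[h]), bool(filtered[h]))
            )
    return pd.DataFrame(
        rows, columns=["hap_id", "chrom", "start", "end", "d_a", "d_b", "ratio", "filtered"]
    )


def genomewide_mean_ratio(scores: pd.DataFrame) -> float:
    """Mean over haplotypes of (mean unfiltered d_A)/(mean unfiltered d_B).

    This is the mean of per-haplotype ratios of means, not the mean of
    per-window ratios.
    """
    ratios = []
    for hap, grp in scores.groupby("hap_id", sort=True):
        ok = grp[~grp["filtered"]]
        if len(ok) == 0:
            raise ValueError(f"haplotype {hap} has no unfiltered windows")
        mean_b = ok["d_b"].mean()
        if mean_b == 0:
            raise ValueError(f"haplotype {hap} has zero mean distance to panel B")
        ratios.append(ok["d_a"].mean() / mean_b)
    return float(np.mean(ratios))


def call_thresholds(mean_ratio: float, fold_threshold: float = 8.0) -> tuple[float, float]:
    """(low, high) call thresholds: r_bar/fold and r_bar*fold."""
    if mean_ratio <= 0:
        raise ValueError("mean ratio must be positive")
    return mean_ratio / fold_threshold, mean_ratio * fold_threshold


def call_hsrs(
    scores: pd.DataFrame,
    mean_ratio: float,
    config: ScanConfig | None = None,
) -> list[HSRCall]:
    """Call HSRs from window scores.

    Unfiltered windows with ratio <= r_bar/fold become origin-A calls and
    ratio >= r_bar*fold origin-B calls (equality counts as called).
    Same-origin called windows on one haplotype are combined when their gap
    is strictly below ``merge_gap_bp``, but never across a window called
    for the opposite origin, so A and B calls cannot overlap.
    """
    config = config or ScanConfig()
    low, high = call_thresholds(mean_ratio, config.fold_threshold)
    calls: list[HSRCall] = []
    for hap, grp in scores.groupby("hap_id", sort=True):
        for chrom, sub in grp.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            ok = ~sub["filtered"].to_numpy()
            r = sub["ratio"].to_numpy()
            called_a = ok & (r <= low)
            called_b = ok & np.isfinite(high) & ((r >= high) | np.isinf(r))
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            for origin, mask, other in (("A", called_a, called_b), ("B", called_b, called_a)):
                idx = np.flatnonzero(mask)
                if idx.size == 0:
                    continue
                cur_s, cur_e, n_win = starts[idx[0]], ends[idx[0]], 1
                last = idx[0]
                for i in idx[1:]:
                    gap = starts[i] - cur_e
                    crossing = other[last + 1 : i].any()  # opposite call inside the gap
                    if gap < config.merge_gap_bp and not crossing:
                        cur_e = ends[i]
                        n_win += 1
                    else:
                        calls.append(HSRCall(hap, chrom, int(cur_s), int(cur_e), origin, n_win))
                        cur_s, cur_e, n_win = starts[i], ends[i], 1
                    last = i
                calls.append(HSRCall(hap, chrom, int(cur_s), int(cur_e), origin, n_win))
    calls.sort(key=lambda c: (c.hap_id, str(c.chrom), c.start, c.origin))
    return calls


def calls_to_intervalset(calls: Sequence[HSRCall], origin: str | None = None) -> IntervalSet:
    recs = [
        (c.chrom, c.start, c.end, c.origin)
        for c in calls
        if origin is None or c.origin == origin
    ]
    return IntervalSet.from_records(recs)


def calls_to_frame(calls: Sequence[HSRCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.hap_id, c.chrom, c.start, c.end, c.origin, c.n_windows, c.size_bp) for c in calls],
        columns=["hap_id", "chrom", "start", "end", "origin", "n_windows", "size_bp"],
    )


def pairwise_hamming_matrix(
    panel: PhasedPanel, chrom: str, start: int, end: int, normalize: bool = False
) -> np.ndarray:
    """Full pairwise Hamming distance matrix over sites in an interval.

    With ``normalize=True`` distances are divided by the largest distance
    (all-zero matrices are returned unscaled).
    """
    sl = panel.site_range(chrom, start, end)
    h = panel.haplotypes[:, sl].astype(np.int16)
    if h.shape[1] == 0:
        raise ValueError(f"no sites in {chrom}:{start}-{end}")
    d = (h[:, None, :] != h[None, :, :]).sum(axis=2).astype(float)
    if normalize and d.max() > 0:
        d = d / d.max()
    return d


def evaluate_calls(
    calls: Sequence[HSRCall],
    truth: "IntervalSet | object",
    origin: str = "A",
    min_truth_bp: int = 0,
) -> dict:
    """Block-level precision/recall/F1 of calls against truth blocks.

    Truth blocks are matched per haplotype: a truth block counts as
    recovered when a same-haplotype call of the right origin overlaps it;
    a call counts as correct when it overlaps any truth block of its
    haplotype.  Truth blocks shorter than ``min_truth_bp`` are ignored on
    both sides (they are below the scan's resolution by construction).
    """
    from .synthetic_data import TruthBlocks

    if isinstance(truth, TruthBlocks):
        truth_by_hap = {h: list(ivs) for h, ivs in truth.blocks.items()}
    else:  # IntervalSet labelled by haplotype
        truth_by_hap = {}
        for chrom, s, e, hap in truth.records():
            truth_by_hap.setdefault(hap, []).append((chrom, s, e))

    def overlaps(iv, others):
        c, s, e = iv
        return any(c == c2 and s < e2 and s2 < e for c2, s2, e2 in others)

    n_truth = n_recovered = n_calls = n_correct = 0
    call_by_hap: dict[str, list] = {}
    for c in calls:
        if c.origin == origin:
            call_by_hap.setdefault(c.hap_id, []).append((c.chrom, c.start, c.end))
    haps = set(truth_by_hap) | set(call_by_hap)
    for hap in haps:
        t_all = truth_by_hap.get(hap, [])
        t_big = [iv for iv in t_all if iv[2] - iv[1] >= min_truth_bp]
        cl = call_by_hap.get(hap, [])
        n_truth += len(t_big)
        n_recovered += sum(overlaps(iv, cl) for iv in t_big)
        n_calls += len(cl)
        n_correct += sum(overlaps(iv, t_all) for iv in cl)
    precision = n_correct / n_calls if n_calls else float("nan")
    recall = n_recovered / n_truth if n_truth else float("nan")
    if n_calls and n_truth and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0 if (n_calls or n_truth) else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_truth": n_truth,
        "n_recovered": n_recovered,
        "n_calls": n_calls,
        "n_correct": n_correct,
    }
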