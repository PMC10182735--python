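"""Windowed diversity statistics and downstream contrasts.

Estimators follow the standard windowed definitions over phased
haplotypes, with denominators over accessible bases (so monomorphic
accessible sites dilute pi and d_xy as they should):

* pi: mean pairwise difference per accessible site within a group,
  sum_s 2 c_s (n - c_s) / (n (n-1)) / accessible_bases;
* d_xy: mean cross-group difference per accessible site,
  sum_s [p1 (1-p2) + p2 (1-p1)] / accessible_bases;
* F_ST: the Hudson estimator as a ratio of sums across sites,
  sum_s [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)] /
  sum_s [p1(1-p2) + p2(1-p1)],
  over sites passing a pooled minor-allele-frequency filter (default
  0.05).  Windows with an empty denominator get a missing value.

Downstream contrasts: enrichment of recurrent-HSR bins in high-F_ST
windows (binomial tail test), exon density of called regions (edge exons
clipped to the region), recombination-rate contrast between regions and
background (Welch t-test), and the mean absolute allele-frequency
distance between pooled samples.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import (
    ExonSet,
    IntervalSet,
    PhasedPanel,
    RecombMap,
    complement_intervals,
    intersect_length,
    union_intervals,
    union_length,
)
from .overlap_model import OverlapTrack, m_value


def _window_grid(chrom_lengths: Mapping[str, int], window_size: int) -> list[tuple[str, int, int]]:
    out = []
    for chrom, length in chrom_lengths.items():
        for s in range(0, length, window_size):
            out.append((chrom, s, min(s + window_size, length)))
    return out


def _pi_from_counts(counts: np.ndarray, n: int, accessible: int) -> float:
    if n < 2:
        raise ValueError("pi requires at least two haplotypes")
    if accessible <= 0:
        raise ValueError("zero accessible bases")
    diffs = 2.0 * counts * (n - counts) / (n * (n - 1))
    return float(diffs.sum() / accessible)


def windowed_pi(
    panel: PhasedPanel,
    group: str,
    window_size: int = 5_000,
    chrom_lengths: Mapping[str, int] | None = None,
    accessible_bases: Mapping[tuple, int] | None = None,
) -> pd.DataFrame:
    """Nucleotide diversity per window for one panel group.

    ``accessible_bases`` maps (chrom, start) to the accessible denominator;
    by default every base of the window is accessible.
    """
    sub = panel.subset_group(group)
    lengths = chrom_lengths or {c: int(sub.pos[sub.chrom == c].max()) + 1 for c in sub.chroms}
    rows = []
    for chrom, s, e in _window_grid(lengths, window_size):
        sl = sub.site_range(chrom, s, e)
        counts = sub.haplotypes[:, sl].sum(axis=0)
        acc = accessible_bases.get((chrom, s), e - s) if accessible_bases else e - s
        rows.append((chrom, s, e, counts.size, _pi_from_counts(counts, sub.n_haps, acc)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "pi"])


def windowed_dxy(
    panel_a: PhasedPanel,
    panel_b: PhasedPanel,
    window_size: int = 5_000,
    chrom_lengths: Mapping[str, int] | None = None,
    accessible_bases: Mapping[tuple, int] | None = None,
) -> pd.DataFrame:
    """Between-group divergence per accessible site, per window."""
    if not panel_a.same_sites(panel_b):
        raise ValueError("panels must share the site set")
    lengths = chrom_lengths or {
        c: int(panel_a.pos[panel_a.chrom == c].max()) + 1 for c in panel_a.chroms
    }
    rows = []
    for chrom, s, e in _window_grid(lengths, window_size):
        sl = panel_a.site_range(chrom, s, e)
        p1 = panel_a.allele_freq(sl)
        p2 = panel_b.allele_freq(sl)
        acc = accessible_bases.get((chrom, s), e - s) if accessible_bases else e - s
        if acc <= 0:
            raise ValueError("zero accessible bases")
        dxy = float((p1 * (1 - p2) + p2 * (1 - p1)).sum() / acc)
        rows.append((chrom, s, e, p1.size, dxy))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "dxy"])


def hudson_fst_sums(
    p1: np.ndarray, p2: np.ndarray, n1: int, n2: int
) -> tuple[float, float]:
    """Hudson estimator numerator and denominator sums over sites."""
    if n1 < 2 or n2 < 2:
        raise ValueError("Hudson F_ST requires at least two haplotypes per group")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum()), float(den.sum())


def windowed_fst(
    panel_a: PhasedPanel,
    panel_b: PhasedPanel,
    window_size: int = 5_000,
    chrom_lengths: Mapping[str, int] | None = None,
    maf: float = 0.05,
) -> pd.DataFrame:
    """Hudson F_ST (ratio of sums) per window.

    Sites are filtered on pooled minor-allele frequency (< ``maf``
    dropped).  Monomorphic/empty windows get NaN.
    """
    if not panel_a.same_sites(panel_b):
        raise ValueError("panels must share the site set")
    lengths = chrom_lengths or {
        c: int(panel_a.pos[panel_a.chrom == c].max()) + 1 for c in panel_a.chroms
    }
    n1, n2 = panel_a.n_haps, panel_b.n_haps
    rows = []
    for chrom, s, e in _window_grid(lengths, window_size):
        sl = panel_a.site_range(chrom, s, e)
        p1 = panel_a.allele_freq(sl)
        p2 = panel_b.allele_freq(sl)
        pooled = (n1 * p1 + n2 * p2) / (n1 + n2)
        keep = np.minimum(pooled, 1 - pooled) >= maf
        if keep.sum() == 0:
            rows.append((chrom, s, e, 0, float("nan")))
            continue
        num, den = hudson_fst_sums(p1[keep], p2[keep], n1, n2)
        fst = num / den if den > 0 else float("nan")
        rows.append((chrom, s, e, int(keep.sum()), fst))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sites", "fst"])


def windowed_diversity(
    panel: PhasedPanel,
    group_a: str = "ref_A",
    group_b: str = "ref_B",
    window_size: int = 5_000,
    chrom_lengths: Mapping[str, int] | None = None,
    maf: float = 0.05,
) -> pd.DataFrame:
    """Combined per-window table: pi per group, d_xy and Hudson F_ST."""
    pa = panel.subset_group(group_a)
    pb = panel.subset_group(group_b)
    pi_a = windowed_pi(panel, group_a, window_size, chrom_lengths)
    pi_b = windowed_pi(panel, group_b, window_size, chrom_lengths)
    dxy = windowed_dxy(pa, pb, window_size, chrom_lengths)
    fst = windowed_fst(pa, pb, window_size, chrom_lengths, maf)
    out = pi_a.rename(columns={"pi": f"pi_{group_a}"}).drop(columns=["n_sites"])
    out[f"pi_{group_b}"] = pi_b["pi"]
    out["dxy"] = dxy["dxy"]
    out["fst"] = fst["fst"]
    out["n_sites"] = dxy["n_sites"]
    return out


def hsr_fst_enrichment(
    track: OverlapTrack,
    fst_windows: pd.DataFrame,
    high_fst: float = 0.6,
    midp: bool = False,
) -> pd.DataFrame:
    """High-F_ST enrichment of windows binned by HSR overlap count.

    Each F_ST window is assigned the overlap count at its midpoint.  For
    bin k the binomial tail probability of observing at least the seen
    number of high-F_ST windows is computed with success probability equal
    to the genome-wide high-F_ST window fraction.  ``midp`` applies the
    mid-p continuity correction (half weight on the observed count).
    """
    df = fst_windows.dropna(subset=["fst"]).copy()
    if len(df) == 0:
        raise ValueError("no windows with defined F_ST")
    genome_frac = float((df["fst"] > high_fst).mean())
    mids = ((df["start"] + df["end"]) // 2).to_numpy()
    ks = np.array(
        [track.count_at(c, m) for c, m in zip(df["chrom"], mids)], dtype=int
    )
    df["k"] = ks
    df["high"] = df["fst"] > high_fst
    rows = []
    for k, grp in df.groupby("k", sort=True):
        n = len(grp)
        x = int(grp["high"].sum())
        frac = x / n
        if genome_frac in (0.0, 1.0):
            p = 1.0
        else:
            p = float(stats.binom.sf(x - 1, n, genome_frac))
            if midp:
                p -= 0.5 * float(stats.binom.pmf(x, n, genome_frac))
        m = (
            m_value(frac, genome_frac)
            if frac > 0 and genome_frac > 0
            else float("nan")
        )
        rows.append((int(k), n, x, frac, m, p))
    out = pd.DataFrame(
        rows, columns=["k", "n_windows", "n_high_fst", "fraction_high", "m_value", "p_binomial"]
    )
    out.attrs["genome_fraction_high"] = genome_frac
    return out


def fraction_regions_overlapping(regions: IntervalSet, mask: IntervalSet) -> float:
    """Fraction of regions that overlap the mask by at least one base.

    This is the region-level co-occurrence summary used for recurrent HSRs
    versus high-F_ST windows.
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    n_hit = sum(
        intersect_length(IntervalSet.from_records([rec[:3]]), mask) > 0
        for rec in regions.records()
    )
    return n_hit / len(regions)


def exon_density(regions: IntervalSet, exons: ExonSet) -> float:
    """Fraction of region bases covered by exons, edge exons clipped.

    Clipping exons to the region boundary is exact (no edge
    overestimation); the result is intersection bases over region bases.
    """
    if len(regions) == 0:
        raise ValueError("regions must be nonempty")
    region_bases = union_length(regions)
    return intersect_length(regions, exons.intervals) / region_bases


def rate_contrast(
    regions: IntervalSet,
    rmap: RecombMap,
    background: IntervalSet | None = None,
) -> dict:
    """Recombination-rate contrast: regions vs background.

    Reports length-weighted mean cM/Mb inside regions and background, and
    a two-sided Welch t-test on the per-map-window rates of windows
    overlapping each set.  Default background: the map complement of the
    regions.
    """
    lengths = {c: rmap.chrom_length(c) for c in rmap.chroms}
    regions_u = union_intervals(regions)
    for chrom, s, e in regions_u.records():
        if chrom not in lengths or e > lengths[chrom]:
            raise ValueError(f"region {chrom}:{s}-{e} outside map coverage")
    if background is None:
        background = complement_intervals(regions_u, lengths)
    bg_u = union_intervals(background)

    def collect(ivset: IntervalSet) -> tuple[float, np.ndarray]:
        wsum = 0.0
        lsum = 0
        window_rates = []
        by_chrom: dict[str, list] = {}
        for chrom, s, e in ivset.records():
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, ivs in by_chrom.items():
            ws, we, wr = rmap.starts[chrom], rmap.ends[chrom], rmap.rates[chrom]
            for s, e in ivs:
                ov = np.clip(np.minimum(we, e) - np.maximum(ws, s), 0, None)
                wsum += float((wr * ov).sum())
                lsum += int(ov.sum())
                window_rates.append(wr[ov > 0])
        rates = np.concatenate(window_rates) if window_rates else np.array([])
        mean = wsum / lsum if lsum else float("nan")
        return mean, rates

    mean_r, rates_r = collect(regions_u)
    mean_b, rates_b = collect(bg_u)
    if rates_r.size > 1 and rates_b.size > 1 and (np.std(rates_r) + np.std(rates_b)) > 0:
        t, p = stats.ttest_ind(rates_r, rates_b, equal_var=False)
    else:
        t, p = float("nan"), float("nan")
    return {
        "region_mean_cM_per_Mb": mean_r,
        "background_mean_cM_per_Mb": mean_b,
        "t_statistic": float(t),
        "p_value": float(p),
        "n_region_windows": int(rates_r.size),
        "n_background_windows": int(rates_b.size),
    }


def pool_frequency_distance(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mean absolute allele-frequency difference per SNP.

    ``freq_table``: rows = SNPs, columns = pools.  Missing values raise.
    """
    if freq_table.shape[1] < 2:
        raise ValueError("need at least two pools")
    if freq_table.isna().any().any():
        raise ValueError("missing allele frequencies")
    pools = list(freq_table.columns)
    arr = freq_table.to_numpy(dtype=float)
    n = len(pools)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = float(np.abs(arr[:, i] - arr[:, j]).mean())
    return pd.DataFrame(d, index=pools, columns=pools)
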