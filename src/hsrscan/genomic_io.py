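"""Readers, writers and interval utilities shared by the whole pipeline.

Coordinates are 0-based, half-open everywhere inside the package (the BED
convention); the 1-based conventions of VCF and GFF3 are converted at the
file boundary and nowhere else.

Phased haplotypes are held in a :class:`PhasedPanel`: a sites-by-haplotypes
0/1 matrix over ordered biallelic SNPs, with each haplotype labeled by
sample, phase and panel group (``query``, ``ref_A`` or ``ref_B``).  Sites
with any missing or unphased call are dropped at load time (and counted)
rather than imputed, so that Hamming distances always compare identical
site sets across haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("query", "ref_A", "ref_B")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes over an ordered site set.

    Attributes
    ----------
    chrom, pos, ref, alt : arrays over sites
        ``pos`` is 0-based.  Positions must be strictly increasing within a
        chromosome and chromosomes must form contiguous blocks.
    haplotypes : (n_haps, n_sites) uint8 array of 0/1 alleles
    samples, phases, groups : arrays over haplotypes
    """

    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    haplotypes: np.ndarray
    samples: np.ndarray
    phases: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        self.samples = np.asarray(self.samples, dtype=object)
        self.phases = np.asarray(self.phases, dtype=np.int64)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D (haps, sites) matrix")
        n_haps, n_sites = self.haplotypes.shape
        if n_sites != self.pos.size:
            raise ValueError(
                f"haplotype matrix has {n_sites} sites but {self.pos.size} positions given"
            )
        if not (n_haps == self.samples.size == self.phases.size == self.groups.size):
            raise ValueError("per-haplotype label arrays must match matrix rows")
        bad = set(np.unique(self.haplotypes)) - {0, 1}
        if bad:
            raise ValueError(f"haplotype matrix contains non-0/1 values: {sorted(bad)}")
        seen: list = []
        for c in self.chroms:
            if seen and c in seen[:-1]:
                raise ValueError(f"chromosome {c} appears in non-contiguous blocks")
            seen.append(c)
            p = self.pos[self.chrom == c]
            if p.size > 1 and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_haps(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def chroms(self) -> list:
        out: list = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    @property
    def hap_ids(self) -> list[str]:
        return [f"{s}_{p}" for s, p in zip(self.samples, self.phases)]

    def subset_group(self, group: str) -> "PhasedPanel":
        idx = np.flatnonzero(self.groups == group)
        if idx.size == 0:
            raise ValueError(f"no haplotypes in group {group!r}")
        return self.subset_haps(idx)

    def subset_haps(self, idx: Sequence[int]) -> "PhasedPanel":
        idx = np.asarray(idx, dtype=np.int64)
        return PhasedPanel(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            haplotypes=self.haplotypes[idx],
            samples=self.samples[idx],
            phases=self.phases[idx],
            groups=self.groups[idx],
        )

    def site_range(self, chrom: str, start: int, end: int) -> slice:
        """Index slice of sites with ``start <= pos < end`` on ``chrom``."""
        on = np.flatnonzero(self.chrom == chrom)
        if on.size == 0:
            return slice(0, 0)
        lo, hi = on[0], on[-1] + 1
        p = self.pos[lo:hi]
        return slice(lo + np.searchsorted(p, start, "left"), lo + np.searchsorted(p, end, "left"))

    def allele_freq(self, sites: slice | np.ndarray | None = None) -> np.ndarray:
        """Alternate-allele sample frequency per site."""
        h = self.haplotypes if sites is None else self.haplotypes[:, sites]
        return h.mean(axis=0)

    def same_sites(self, other: "PhasedPanel") -> bool:
        return (
            self.n_sites == other.n_sites
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.chrom, other.chrom)
        )


def concat_panels(panels: Iterable[PhasedPanel]) -> PhasedPanel:
    """Stack panels sharing a site set into one (haplotype-wise)."""
    panels = list(panels)
    first = panels[0]
    for p in panels[1:]:
        if not first.same_sites(p):
            raise ValueError("panels do not share the same site set")
    return PhasedPanel(
        chrom=first.chrom,
        pos=first.pos,
        ref=first.ref,
        alt=first.alt,
        haplotypes=np.vstack([p.haplotypes for p in panels]),
        samples=np.concatenate([p.samples for p in panels]),
        phases=np.concatenate([p.phases for p in panels]),
        groups=np.concatenate([p.groups for p in panels]),
    )


@dataclass
class IntervalSet:
    """Half-open genomic intervals ``[start, end)`` with an optional label."""

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if self.label is not None:
            self.label = np.asarray(self.label, dtype=object)
            if self.label.size != self.chrom.size:
                raise ValueError("label array length mismatch")
        if not (self.chrom.size == self.start.size == self.end.size):
            raise ValueError("interval arrays must have equal length")
        if np.any(self.start >= self.end):
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return self.chrom.size

    @classmethod
    def empty(cls) -> "IntervalSet":
        return cls(np.array([], dtype=object), np.array([], dtype=np.int64), np.array([], dtype=np.int64))

    @classmethod
    def from_records(cls, records: Sequence[tuple]) -> "IntervalSet":
        """Build from (chrom, start, end[, label]) tuples."""
        if not records:
            return cls.empty()
        cols = list(zip(*records))
        label = np.array(cols[3], dtype=object) if len(cols) > 3 else None
        return cls(np.array(cols[0], dtype=object), np.array(cols[1]), np.array(cols[2]), label)

    def to_frame(self) -> pd.DataFrame:
        d = {"chrom": self.chrom, "start": self.start, "end": self.end}
        if self.label is not None:
            d["label"] = self.label
        return pd.DataFrame(d)

    def records(self) -> list[tuple]:
        if self.label is None:
            return list(zip(self.chrom, self.start.tolist(), self.end.tolist()))
        return list(zip(self.chrom, self.start.tolist(), self.end.tolist(), self.label))

    def sorted(self) -> "IntervalSet":
        order = np.lexsort((self.start, np.array([str(c) for c in self.chrom])))
        return IntervalSet(
            self.chrom[order],
            self.start[order],
            self.end[order],
            None if self.label is None else self.label[order],
        )

    def total_bases(self) -> int:
        """Sum of interval lengths (overlaps counted multiply)."""
        return int((self.end - self.start).sum())


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def merge_intervals(intervals: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap is strictly less than ``max_gap``.

    Merging is restricted to intervals on the same chromosome carrying the
    same label.  A gap of exactly ``max_gap`` is NOT merged; overlapping or
    touching intervals (gap <= 0) are always merged.  Idempotent.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    if len(intervals) == 0:
        return IntervalSet.empty()
    has_label = intervals.label is not None
    labels = intervals.label if has_label else np.array([None] * len(intervals), dtype=object)
    out: list[tuple] = []
    df = pd.DataFrame(
        {"chrom": intervals.chrom, "start": intervals.start, "end": intervals.end, "label": labels}
    )
    for (chrom, label), grp in df.groupby(["chrom", "label"], dropna=False, sort=True):
        grp = grp.sort_values(["start", "end"])
        cur_s, cur_e = None, None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s - cur_e < max_gap or s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e, label))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e, label))
    merged = IntervalSet.from_records(out)
    if not has_label:
        merged.label = None
    return merged.sorted()


def union_intervals(intervals: IntervalSet) -> IntervalSet:
    """Union per chromosome, ignoring labels (overlapping/touching merged)."""
    if len(intervals) == 0:
        return IntervalSet.empty()
    flat = IntervalSet(intervals.chrom, intervals.start, intervals.end, None)
    return merge_intervals(flat, max_gap=0)


def union_length(intervals: IntervalSet) -> int:
    """Total bases covered by the intervals, counting each base once."""
    return union_intervals(intervals).total_bases()


def intersect_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intersection of the unions of two interval sets (labels dropped)."""
    ua, ub = union_intervals(a), union_intervals(b)
    out: list[tuple] = []
    fb = ub.to_frame().groupby("chrom")
    for chrom, grp in ua.to_frame().groupby("chrom"):
        if chrom not in fb.groups:
            continue
        other = fb.get_group(chrom)
        bs, be = other["start"].to_numpy(), other["end"].to_numpy()
        for s, e in zip(grp["start"], grp["end"]):
            lo = np.searchsorted(be, s, "right")
            hi = np.searchsorted(bs, e, "left")
            for j in range(lo, hi):
                out.append((chrom, max(s, bs[j]), min(e, be[j])))
    return IntervalSet.from_records(out)


def intersect_length(a: IntervalSet, b: IntervalSet) -> int:
    return intersect_intervals(a, b).total_bases()


def complement_intervals(intervals: IntervalSet, chrom_lengths: Mapping[str, int]) -> IntervalSet:
    """Bases of each chromosome not covered by the intervals."""
    u = union_intervals(intervals).to_frame()
    out: list[tuple] = []
    for chrom, length in chrom_lengths.items():
        sub = u[u["chrom"] == chrom]
        prev = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > prev:
                out.append((chrom, prev, min(s, length)))
            prev = max(prev, e)
        if prev < length:
            out.append((chrom, prev, length))
    return IntervalSet.from_records(out)


@dataclass
class ExonSet:
    """Union of exon intervals plus the total annotated genome length."""

    intervals: IntervalSet
    genome_length: int

    @property
    def exon_bases(self) -> int:
        return self.intervals.total_bases()


@dataclass
class RecombMap:
    """Per-chromosome windowed recombination rates (cM/Mb).

    Windows are contiguous, ordered, and typically 100 kb; the last window of
    a chromosome may be shorter.  The cumulative genetic position (cM) at
    window edges is derived and used for crossover placement.
    """

    starts: dict[str, np.ndarray] = field(default_factory=dict)
    ends: dict[str, np.ndarray] = field(default_factory=dict)
    rates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c in self.chroms:
            s = np.asarray(self.starts[c], dtype=np.int64)
            e = np.asarray(self.ends[c], dtype=np.int64)
            r = np.asarray(self.rates[c], dtype=float)
            if np.any(r < 0):
                raise ValueError(f"negative recombination rate on {c}")
            if np.any(e <= s) or np.any(s[1:] != e[:-1]) or (s.size and s[0] != 0):
                raise ValueError(f"windows on {c} must tile the chromosome from 0")
            self.starts[c], self.ends[c], self.rates[c] = s, e, r

    @property
    def chroms(self) -> list[str]:
        return list(self.starts)

    def chrom_length(self, chrom: str) -> int:
        return int(self.ends[chrom][-1])

    def window_cm(self, chrom: str) -> np.ndarray:
        span_mb = (self.ends[chrom] - self.starts[chrom]) / 1e6
        return self.rates[chrom] * span_mb

    def cum_cm(self, chrom: str) -> np.ndarray:
        """Cumulative cM at window edges (length = n_windows + 1)."""
        return np.concatenate([[0.0], np.cumsum(self.window_cm(chrom))])

    def total_cm(self, chrom: str) -> float:
        return float(self.window_cm(chrom).sum())

    def genetic_to_physical(self, chrom: str, cm: np.ndarray) -> np.ndarray:
        """Map genetic positions (cM) to physical bp by piecewise-linear interpolation."""
        edges_cm = self.cum_cm(chrom)
        edges_bp = np.concatenate([self.starts[chrom], [self.ends[chrom][-1]]]).astype(float)
        return np.interp(np.asarray(cm, dtype=float), edges_cm, edges_bp)

    def mean_rate(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean rate (cM/Mb) over [start, end)."""
        if end <= start:
            raise ValueError("empty interval")
        s, e = self.starts[chrom], self.ends[chrom]
        if start < 0 or end > self.chrom_length(chrom):
            raise ValueError(f"interval [{start},{end}) outside map coverage of {chrom}")
        ov = np.minimum(e, end) - np.maximum(s, start)
        ov = np.clip(ov, 0, None)
        return float((self.rates[chrom] * ov).sum() / ov.sum())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.chroms:
            for s, e, r in zip(self.starts[c], self.ends[c], self.rates[c]):
                rows.append((c, int(s), int(e), float(r)))
        return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "rate_cM_per_Mb"])


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def read_phased_vcf(path: str | Path, group_assignment: Mapping[str, str]) -> PhasedPanel:
    """Load phased biallelic SNPs for the samples in ``group_assignment``.

    Multi-allelic records, non-SNPs, and records with any missing or
    unphased call among the selected samples are skipped (counts logged).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    vcf = VCF(str(path))
    missing = set(group_assignment) - set(vcf.samples)
    if missing:
        raise ValueError(f"samples absent from VCF: {sorted(missing)}")
    for g in set(group_assignment.values()):
        if g not in GROUPS:
            raise ValueError(f"unknown panel group {g!r}; expected one of {GROUPS}")
    sample_idx = [vcf.samples.index(s) for s in group_assignment]
    samples = list(group_assignment)

    chroms: list = []
    poss: list = []
    refs: list = []
    alts: list = []
    rows: list = []
    skipped = {"multiallelic_or_indel": 0, "unphased": 0, "missing": 0}
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            skipped["multiallelic_or_indel"] += 1
            continue
        gts = var.genotypes  # [allele0, allele1, phased] per sample
        alleles = []
        ok = True
        for i in sample_idx:
            a0, a1, phased = gts[i][0], gts[i][1], gts[i][2]
            if a0 < 0 or a1 < 0:
                skipped["missing"] += 1
                ok = False
                break
            if not phased:
                skipped["unphased"] += 1
                ok = False
                break
            alleles.extend([a0, a1])
        if not ok:
            continue
        chroms.append(var.CHROM)
        poss.append(var.POS - 1)  # to 0-based
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(alleles)
    if any(skipped.values()):
        logger.info("read_phased_vcf(%s): skipped records %s", path, skipped)
    mat = np.array(rows, dtype=np.uint8).T if rows else np.zeros((2 * len(samples), 0), np.uint8)
    return PhasedPanel(
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        haplotypes=mat,
        samples=np.repeat(samples, 2),
        phases=np.tile([0, 1], len(samples)),
        groups=np.repeat([group_assignment[s] for s in samples], 2),
    )


def write_phased_vcf(panel: PhasedPanel, path: str | Path) -> None:
    """Write the panel as a minimal phased VCF v4.2 (GT only)."""
    path = Path(path)
    samples = list(dict.fromkeys(panel.samples))  # preserve order
    cols = {s: np.flatnonzero(panel.samples == s) for s in samples}
    for s, idx in cols.items():
        if idx.size != 2:
            raise ValueError(f"sample {s} does not have exactly two haplotypes")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        seen = []
        for c in panel.chroms:
            if c not in seen:
                seen.append(c)
                length = int(panel.pos[panel.chrom == c].max()) + 1
                fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for j in range(panel.n_sites):
            gt = "\t".join(
                f"{panel.haplotypes[cols[s][0], j]}|{panel.haplotypes[cols[s][1], j]}" for s in samples
            )
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j] + 1}\t.\t{panel.ref[j]}\t{panel.alt[j]}\t.\tPASS\t.\tGT\t{gt}\n"
            )


def read_recomb_map(path: str | Path) -> RecombMap:
    """Read a recombination map TSV: chrom, start_bp, end_bp, rate_cM_per_Mb.

    A header line is required; malformed lines are reported by number.
    """
    path = Path(path)
    starts: dict[str, list] = {}
    ends: dict[str, list] = {}
    rates: dict[str, list] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        expect = ["chrom", "start_bp", "end_bp", "rate_cM_per_Mb"]
        if header.rstrip("\n").split("\t") != expect:
            raise ValueError(f"{path}: line 1: expected header {expect}")
        for lineno, line in enumerate(fh, start=2):
            if not line.endswith("\n") and line.strip():
                # a text table is always newline-terminated; treat as truncation
                raise ValueError(f"{path}: line {lineno}: truncated final line")
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            try:
                c, s, e, r = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            starts.setdefault(c, []).append(s)
            ends.setdefault(c, []).append(e)
            rates.setdefault(c, []).append(r)
    return RecombMap(
        starts={c: np.array(v) for c, v in starts.items()},
        ends={c: np.array(v) for c, v in ends.items()},
        rates={c: np.array(v) for c, v in rates.items()},
    )


def write_recomb_map(rmap: RecombMap, path: str | Path) -> None:
    rmap.to_frame().to_csv(path, sep="\t", index=False)


def read_gff_exons(path: str | Path) -> ExonSet:
    """Extract exon features from GFF3; overlapping exons are unioned.

    GFF3 is 1-based, closed; converted here to 0-based, half-open.  The
    total annotated genome length is taken from ``##sequence-region``
    pragmas when present, else from the largest feature end per seqid.
    """
    path = Path(path)
    records: list[tuple] = []
    seq_lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.endswith("\n") and line.strip():
                raise ValueError(f"{path}: line {lineno}: truncated final line")
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    seq_lengths[parts[1]] = int(parts[3])
                continue
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}: line {lineno}: expected 9 columns, got {len(parts)}")
            seqid, _, ftype, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            seq_lengths[seqid] = max(seq_lengths.get(seqid, 0), end_i)
            if ftype.lower() == "exon":
                records.append((seqid, start_i - 1, end_i))  # strand ignored
    exons = union_intervals(IntervalSet.from_records(records))
    return ExonSet(intervals=exons, genome_length=sum(seq_lengths.values()))


def write_bed(intervals: IntervalSet, path: str | Path, extra: pd.DataFrame | None = None) -> None:
    """Write BED3(+label[+extra columns]); no header, tab-separated."""
    df = intervals.to_frame()
    if extra is not None:
        df = pd.concat([df.reset_index(drop=True), extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3 or BED4 (4th column becomes the label)."""
    path = Path(path)
    records: list[tuple] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.endswith("\n") and line.strip():
                raise ValueError(f"{path}: line {lineno}: truncated final line")
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                rec = (parts[0], int(parts[1]), int(parts[2]))
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if len(parts) > 3:
                rec = rec + (parts[3],)
            records.append(rec)
    return IntervalSet.from_records(records)
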