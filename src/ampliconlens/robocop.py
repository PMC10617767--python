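"""ROlling Binmeans Of COPy numbers.

Summarizes segmented total copy number over a fixed view window (default
2 Mb around the FGFR1 locus split into 10,000 bins): per-bin overlap-
weighted means per sample, per-condition per-bin means across samples,
and a centered rolling mean (window 10 for WGS data, 500 for CAGE data)
to suppress noise.  Also provides amplicon peak-centering and
half-maximum focality metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .genome_model import GeneFixture, GenomicInterval

__all__ = [
    "CNSegment",
    "BinnedProfile",
    "read_seg",
    "write_seg",
    "bin_segments",
    "group_mean_profile",
    "rolling_mean",
    "robocop_profile",
    "peak_center",
    "focal_width",
    "default_window",
    "DIPLOID_BASELINE",
    "ROLL_WINDOW",
]

DIPLOID_BASELINE = 2.0
ROLL_WINDOW = {"wgs": 10, "cage": 500}
DEFAULT_N_BINS = 10_000
DEFAULT_WINDOW_BP = 2_000_000


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment: genomic interval plus total copy number."""

    interval: GenomicInterval
    cn: float

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError(f"copy number must be >= 0, got {self.cn}")


@dataclass
class BinnedProfile:
    """Per-bin copy number over a fixed window."""

    window: GenomicInterval
    values: np.ndarray
    roll_window: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a nonempty 1-D array")

    @property
    def n_bins(self) -> int:
        return self.values.size

    @property
    def bin_width(self) -> float:
        return len(self.window) / self.n_bins

    def bin_edges(self) -> np.ndarray:
        return self.window.start + np.arange(self.n_bins + 1) * self.bin_width

    def compatible(self, other: "BinnedProfile") -> bool:
        return (
            self.window == other.window and self.n_bins == other.n_bins
        )


def default_window(fixture: GeneFixture, window_bp: int = DEFAULT_WINDOW_BP) -> GenomicInterval:
    """2 Mb (by default) window centered on the gene-body midpoint."""
    span = fixture.transcript.span
    mid = (span.start + span.end) // 2
    start = max(0, mid - window_bp // 2)
    return GenomicInterval(span.chrom, start, start + window_bp)


def _validate_non_overlapping(segments: Sequence[CNSegment]) -> None:
    by_chrom: dict[str, list[CNSegment]] = {}
    for s in segments:
        by_chrom.setdefault(s.interval.chrom, []).append(s)
    for chrom_segs in by_chrom.values():
        chrom_segs.sort(key=lambda s: s.interval.start)
        for s1, s2 in zip(chrom_segs, chrom_segs[1:]):
            if s1.interval.end > s2.interval.start:
                raise ValueError(
                    f"overlapping copy-number segments: {s1.interval} and "
                    f"{s2.interval}"
                )


def bin_segments(
    segments: Sequence[CNSegment],
    window: GenomicInterval,
    n_bins: int = DEFAULT_N_BINS,
    baseline: float = DIPLOID_BASELINE,
    midpoint_rule: bool = False,
) -> BinnedProfile:
    """Map segments onto equal-width bins of ``window``.

    Each bin takes the overlap-length-weighted mean copy number of the
    segments overlapping it; bins with no overlap take ``baseline``
    (diploid 2 by default).  With ``midpoint_rule`` a bin instead takes the
    value of the segment covering its midpoint.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    _validate_non_overlapping(segments)
    segs = [s for s in segments if s.interval.overlaps(window)]
    width = len(window) / n_bins
    edges = window.start + np.arange(n_bins + 1) * width

    if midpoint_rule:
        mids = (edges[:-1] + edges[1:]) / 2.0
        values = np.full(n_bins, baseline, dtype=float)
        for s in segs:
            mask = (mids >= s.interval.start) & (mids < s.interval.end)
            values[mask] = s.cn
        return BinnedProfile(window, values)

    weighted = np.zeros(n_bins)
    covered = np.zeros(n_bins)
    for s in segs:
        ov_start = np.clip(edges[:-1], s.interval.start, s.interval.end)
        ov_end = np.clip(edges[1:], s.interval.start, s.interval.end)
        ov = np.maximum(ov_end - ov_start, 0.0)
        weighted += ov * s.cn
        covered += ov
    with np.errstate(invalid="ignore"):
        values = np.where(covered > 0, weighted / np.maximum(covered, 1e-300), baseline)
    return BinnedProfile(window, values)


def group_mean_profile(profiles: Sequence[BinnedProfile]) -> BinnedProfile:
    """Per-bin arithmetic mean across samples."""
    if not profiles:
        raise ValueError("need at least one profile")
    first = profiles[0]
    for p in profiles[1:]:
        if not first.compatible(p):
            raise ValueError("profiles have mismatched windows or bin counts")
    values = np.mean([p.values for p in profiles], axis=0)
    return BinnedProfile(first.window, values)


def rolling_mean(profile: BinnedProfile, w: int) -> BinnedProfile:
    """Centered rolling mean with symmetric edge shrinkage.

    Interior bins average exactly ``w`` values spanning
    ``[i - (w-1)//2, i + w//2]``; where that window would overrun an edge
    the window shrinks symmetrically to ``[i - s, i + s]`` with
    ``s = min(i, n-1-i)``.  Output length equals input length.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    n = profile.n_bins
    if w > n:
        raise ValueError(f"window size {w} exceeds bin count {n}")
    v = profile.values
    if w == 1:
        return BinnedProfile(profile.window, v.copy(), roll_window=1)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    half_l = (w - 1) // 2
    half_r = w // 2
    out = np.empty(n)
    for i in range(n):
        lo, hi = i - half_l, i + half_r
        if lo < 0 or hi > n - 1:
            s = min(i, n - 1 - i)
            lo, hi = i - s, i + s
        out[i] = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return BinnedProfile(profile.window, out, roll_window=w)


def robocop_profile(
    samples: Sequence[Sequence[CNSegment]],
    labels: Sequence[str],
    data_kind: str = "wgs",
    window: Optional[GenomicInterval] = None,
    n_bins: int = DEFAULT_N_BINS,
    roll_window: Optional[int] = None,
    baseline: float = DIPLOID_BASELINE,
) -> dict[str, BinnedProfile]:
    """Full ROBOCOP composition per condition.

    bin_segments -> group_mean_profile -> rolling_mean, with the rolling
    window selected by ``data_kind`` (wgs -> 10, cage -> 500) unless
    overridden.
    """
    if len(samples) != len(labels):
        raise ValueError("samples and labels must have equal length")
    if window is None:
        raise ValueError("a view window is required (see default_window)")
    if roll_window is None:
        try:
            roll_window = ROLL_WINDOW[data_kind]
        except KeyError:
            raise ValueError(f"unknown data_kind {data_kind!r}; use wgs or cage")
    conditions: dict[str, list[BinnedProfile]] = {}
    for segs, lab in zip(samples, labels):
        conditions.setdefault(lab, []).append(
            bin_segments(segs, window, n_bins, baseline=baseline)
        )
    out = {}
    for lab, profiles in conditions.items():
        if not profiles:
            raise ValueError(f"condition {lab!r} has no samples")
        out[lab] = rolling_mean(group_mean_profile(profiles), roll_window)
    return out


@dataclass
class PeakCall:
    position: int
    bin_index: int
    gene: Optional[str]
    distinct: bool


def peak_center(
    profile: BinnedProfile,
    fixtures: Iterable[GeneFixture] = (),
) -> PeakCall:
    """Genomic midpoint of the maximal bin and the containing/nearest gene.

    Ties take the leftmost maximum; a flat profile is flagged as having no
    distinct peak.
    """
    v = profile.values
    idx = int(np.argmax(v))
    distinct = bool(np.ptp(v) > 0)
    edges = profile.bin_edges()
    pos = int((edges[idx] + edges[idx + 1]) / 2)
    best_gene = None
    best_dist = None
    for fx in fixtures:
        span = fx.transcript.span
        if span.chrom != profile.window.chrom:
            continue
        if span.contains(pos):
            dist = 0
        else:
            dist = min(abs(pos - span.start), abs(pos - (span.end - 1)))
        if best_dist is None or dist < best_dist:
            best_dist = dist
            best_gene = fx.transcript.gene
    return PeakCall(position=pos, bin_index=idx, gene=best_gene, distinct=distinct)


@dataclass
class FocalWidth:
    width_bp: float
    no_peak: bool = False


def focal_width(profile: BinnedProfile, baseline: float = DIPLOID_BASELINE) -> FocalWidth:
    """Half-maximum width of the amplicon peak.

    Length (bp) of the maximal contiguous run of bins around the peak with
    value >= baseline + (peak - baseline)/2; 0 with a flag when the
    profile never exceeds baseline.
    """
    v = profile.values
    peak = float(np.max(v))
    if peak <= baseline:
        return FocalWidth(0.0, no_peak=True)
    thresh = baseline + (peak - baseline) / 2.0
    idx = int(np.argmax(v))
    lo = idx
    while lo > 0 and v[lo - 1] >= thresh:
        lo -= 1
    hi = idx
    while hi < v.size - 1 and v[hi + 1] >= thresh:
        hi += 1
    return FocalWidth((hi - lo + 1) * profile.bin_width)


# -- SEG-like I/O -----------------------------------------------------------


def read_seg(path) -> dict[str, list[CNSegment]]:
    """Read a SEG-like TSV (sample, chrom, start, end, total_cn)."""
    out: dict[str, list[CNSegment]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample", "chrom", "start", "end", "total_cn"]
        if [h.lower() for h in header] != expected:
            raise ValueError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 5:
                raise ValueError(f"{path}: line {lineno}: expected 5 columns")
            sample, chrom, start, end, cn = f
            out.setdefault(sample, []).append(
                CNSegment(GenomicInterval(chrom, int(start), int(end)), float(cn))
            )
    return out


def write_seg(samples: dict[str, Sequence[CNSegment]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\ttotal_cn\n")
        for sample in samples:
            for s in samples[sample]:
                fh.write(
                    f"{sample}\t{s.interval.chrom}\t{s.interval.start}\t"
                    f"{s.interval.end}\t{s.cn:g}\n"
                )


def write_profile_tsv(profiles: dict[str, BinnedProfile], path) -> None:
    """Write per-condition profiles as a TSV (bin_start, bin_end, one
    column per condition)."""
    if not profiles:
        raise ValueError("nothing to write")
    conds = list(profiles)
    first = profiles[conds[0]]
    for p in profiles.values():
        if not first.compatible(p):
            raise ValueError("profiles have mismatched windows")
    edges = first.bin_edges()
    with open(path, "w") as fh:
        fh.write("bin_start\tbin_end\t" + "\t".join(conds) + "\n")
        for i in range(first.n_bins):
            vals = "\t".join(f"{profiles[c].values[i]:.6g}" for c in conds)
            fh.write(f"{int(edges[i])}\t{int(edges[i + 1])}\t{vals}\n")
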