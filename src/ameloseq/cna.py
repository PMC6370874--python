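"""Read-depth copy-number profiling for tumor-only exomes.

With no matched normals, each sample is normalized against the rest of the
cohort (panel): a bin's signal is the log2 of its within-sample relative
depth minus the panel median of that same quantity, which cancels both
library size and per-target capture efficiency. Profiles are then segmented
by recursive binary splitting on mean shifts, and a per-profile "flatness"
(fraction of bins in copy-neutral segments) summarizes whether the genome is
copy-number quiet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ameloseq.formats import TargetInterval

#: |log2 ratio| below which a segment is considered copy-neutral
FLAT_THRESHOLD = 0.3
#: minimum fraction of copy-neutral bins for a profile to be called flat
FLATNESS_CUTOFF = 0.95


@dataclass
class CoverageProfile:
    """Per-target mean read depths for one sample, in genome order."""

    sample_id: str
    bins: list  # [(TargetInterval, mean_depth)]

    def depths(self) -> np.ndarray:
        return np.asarray([d for _, d in self.bins], dtype=float)

    def intervals(self) -> list[TargetInterval]:
        return [iv for iv, _ in self.bins]


@dataclass
class Segment:
    span: TargetInterval
    log2_ratio: float
    start_bin: int  # half-open bin index range
    end_bin: int

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class SegmentedProfile:
    """Segmentation result plus the flatness summary."""

    sample_id: str
    segments: list  # of Segment, tiling all bins
    flatness: float
    is_flat: bool


@dataclass
class SegmentationParams:
    min_segment_size: int = 5
    #: minimum |mean shift| (log2 units) to accept a split
    split_delta: float = 0.1
    #: minimum t-like statistic |mean_L - mean_R| / (sigma * sqrt(1/nL + 1/nR))
    #: for a split, with sigma estimated robustly from first differences
    t_threshold: float = 5.0
    #: adjacent segments closer than this are merged back
    merge_delta: float = 0.1
    flat_threshold: float = FLAT_THRESHOLD
    flatness_cutoff: float = FLATNESS_CUTOFF


def normalize(
    profile: CoverageProfile, panel: Sequence[CoverageProfile]
) -> np.ndarray:
    """Per-bin log2 ratios of a sample against a panel of cohort samples.

    ratio_i = log2(d_i / median(d)) - median_panel(log2(p_i / median(p))).
    Bins where the panel median relative depth is zero are masked (NaN), as
    are zero-depth sample bins. With an empty panel the sample-median-only
    ratios are returned (flagged by the caller); an all-zero sample is an
    error.
    """
    depths = profile.depths()
    if depths.size == 0:
        raise ValueError(f"{profile.sample_id}: empty coverage profile")
    med = np.median(depths)
    if med == 0:
        raise ValueError(f"{profile.sample_id}: all-zero coverage profile")
    with np.errstate(divide="ignore"):
        sample_rel = np.log2(depths / med)
    sample_rel[depths == 0] = np.nan

    panel = [p for p in panel if p.sample_id != profile.sample_id]
    if not panel:
        return sample_rel

    panel_rel = []
    for p in panel:
        d = p.depths()
        if d.size != depths.size:
            raise ValueError("panel profiles must share the sample's bin grid")
        m = np.median(d)
        if m == 0:
            continue
        with np.errstate(divide="ignore"):
            r = np.log2(d / m)
        r[d == 0] = -np.inf
        panel_rel.append(r)
    if not panel_rel:
        return sample_rel
    ref = np.median(np.vstack(panel_rel), axis=0)
    ratios = sample_rel - ref
    ratios[~np.isfinite(ref)] = np.nan  # panel median relative depth was zero
    return ratios


def _noise_sigma(x: np.ndarray) -> float:
    """Robust per-bin noise estimate from the MAD of first differences.

    Insensitive to a small number of true mean shifts, which contribute only
    a handful of outlying differences.
    """
    if x.size < 3:
        return float(np.std(x)) or 1e-6
    mad = np.median(np.abs(np.diff(x)))
    # MAD of N(0, sigma*sqrt(2)) differences: mad = 0.6745 * sigma * sqrt(2)
    return float(mad / 0.9539) or 1e-6


def _best_window(x: np.ndarray, min_size: int, sigma: float):
    """Best internal window [i, j) against the rest of the block.

    Scans all windows (a window touching a block edge is a plain binary
    split) and returns (t_statistic, mean_shift, i, j) for the one with the
    largest noise-scaled mean contrast. Testing windows rather than single
    cut points keeps short internal events detectable: a single top-level
    split dilutes a short event's shift by the long flat remainder.
    O(n^2) time/memory — intended for profiles of hundreds to a few
    thousand bins.
    """
    n = x.size
    if n < 2 * min_size:
        return None
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    i_idx = np.arange(n + 1)
    S = cs[None, :] - cs[:, None]  # S[i, j] = sum(x[i:j])
    W = i_idx[None, :] - i_idx[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        m_in = S / W
        m_out = (total - S) / (n - W)
        shift = np.abs(m_in - m_out)
        t = shift / (sigma * np.sqrt(1.0 / W + 1.0 / (n - W)))
    valid = (W >= min_size) & ((n - W) >= min_size)
    # edge-anchored windows are single splits; interior windows need both
    # flanks (the recursion handles asymmetric flanks after the cut)
    t[~valid] = -np.inf
    flat = int(np.nanargmax(t))
    i, j = divmod(flat, n + 1)
    return float(t[i, j]), float(shift[i, j]), int(i), int(j)


def _segment_recursive(
    x: np.ndarray, offset: int, params: SegmentationParams, breaks: list, sigma: float
) -> None:
    found = _best_window(x, params.min_segment_size, sigma)
    if found is None:
        return
    t, shift, i, j = found
    if shift < params.split_delta or t < params.t_threshold:
        return
    cuts = [k for k in (i, j) if 0 < k < x.size]
    for k in cuts:
        breaks.append(offset + k)
    edges = [0, *cuts, x.size]
    for a, b in zip(edges, edges[1:]):
        _segment_recursive(x[a:b], offset + a, params, breaks, sigma)


def segment(
    ratios: np.ndarray,
    intervals: Sequence[TargetInterval],
    sample_id: str = "",
    params: Optional[SegmentationParams] = None,
) -> SegmentedProfile:
    """Recursive binary segmentation of a log2-ratio profile.

    NaN bins (masked during normalization) are mean-imputed for split
    search but excluded from segment means. Adjacent segments whose means
    differ by less than ``merge_delta`` are merged. Deterministic.
    """
    params = params or SegmentationParams()
    ratios = np.asarray(ratios, dtype=float)
    n = ratios.size
    if n == 0:
        raise ValueError("empty ratio vector")
    finite = np.isfinite(ratios)
    x = ratios.copy()
    if not finite.all():
        fill = ratios[finite].mean() if finite.any() else 0.0
        x[~finite] = fill

    breaks: list[int] = []
    _segment_recursive(x, 0, params, breaks, _noise_sigma(x))
    bounds = [0] + sorted(breaks) + [n]

    def seg_mean(a: int, b: int) -> float:
        vals = ratios[a:b][finite[a:b]]
        return float(vals.mean()) if vals.size else 0.0

    # merge adjacent segments with near-identical means
    merged = [(bounds[0], bounds[1])]
    for a, b in zip(bounds[1:-1], bounds[2:]):
        pa, pb = merged[-1]
        if abs(seg_mean(pa, pb) - seg_mean(a, b)) < params.merge_delta:
            merged[-1] = (pa, b)
        else:
            merged.append((a, b))

    segments = []
    for a, b in merged:
        span = TargetInterval(
            intervals[a].chrom, intervals[a].start, intervals[b - 1].end, label=f"seg{a}"
        )
        segments.append(Segment(span=span, log2_ratio=seg_mean(a, b), start_bin=a, end_bin=b))

    flat_bins = sum(s.n_bins for s in segments if abs(s.log2_ratio) < params.flat_threshold)
    flatness = flat_bins / n
    return SegmentedProfile(
        sample_id=sample_id,
        segments=segments,
        flatness=flatness,
        is_flat=flatness >= params.flatness_cutoff,
    )


def profile_cohort(
    profiles: Sequence[CoverageProfile], params: Optional[SegmentationParams] = None
) -> list[SegmentedProfile]:
    """Normalize each sample against the rest of the cohort and segment it."""
    return [
        segment(normalize(p, profiles), p.intervals(), p.sample_id, params) for p in profiles
    ]


def read_coverage_tsv(path) -> CoverageProfile:
    """Read a per-target depth TSV: chrom, start, end, label, mean_depth."""
    bins = []
    sample_id = ""
    with open(path) as fh:
        header = None
        for ln in fh:
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            if header is None:
                header = ln.split("\t")
                continue
            row = dict(zip(header, ln.split("\t")))
            sample_id = row.get("sample_id", sample_id)
            bins.append(
                (
                    TargetInterval(row["chrom"], int(row["start"]), int(row["end"]), row.get("label", "")),
                    float(row["mean_depth"]),
                )
            )
    return CoverageProfile(sample_id=sample_id, bins=bins)


def write_coverage_tsv(profile: CoverageProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tlabel\tmean_depth\n")
        for iv, d in profile.bins:
            fh.write(f"{profile.sample_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\t{d:.4f}\n")


def write_segments_tsv(profile: SegmentedProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tlog2_ratio\tn_bins\n")
        for s in profile.segments:
            fh.write(
                f"{profile.sample_id}\t{s.span.chrom}\t{s.span.start}\t{s.span.end}\t"
                f"{s.log2_ratio:.4f}\t{s.n_bins}\n"
            )
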