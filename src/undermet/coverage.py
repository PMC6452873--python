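"""Read-depth duplication (amplification) calling for bacterial genomes.

Large segmental duplications show up in whole-genome sequencing as
multi-kilobase runs of roughly doubled read depth.  The caller bins a
per-position depth table, computes the depth mean μ and standard deviation
σ per contig, and flags bins whose depth strictly exceeds 2μ − σ (a fold-2
threshold backed off by one standard deviation).  Maximal runs of flagged
bins — allowing short gaps — that reach a minimum length are emitted as
amplified regions with their mean fold change.  A mirrored strict-less-than
threshold (μ/2, off by default) flags large deletions with the same
machinery.

Coordinates are 1-based inclusive internally; BED output converts to
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd


@dataclass
class CoverageProfile:
    contig: str
    bin_size: int
    depths: np.ndarray  # mean depth per bin
    start_coordinate: int = 1  # 1-based position of the first bin's first base

    def __post_init__(self):
        self.depths = np.asarray(self.depths, dtype=float)
        if self.bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class AmplifiedRegion:
    contig: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    mean_fold: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")


@dataclass
class CallerParams:
    """Caller knobs; the threshold rule itself is depth > 2μ − σ.

    ``alt_threshold`` switches to the alternative reading 2(μ − σ);
    ``global_stats`` pools μ/σ over all contigs instead of per contig;
    ``deletions`` calls depth < μ/2 regions instead of amplifications.
    """

    min_length: int = 5000
    merge_gap: int = 1000
    alt_threshold: bool = False
    global_stats: bool = False
    deletions: bool = False

    def __post_init__(self):
        if self.min_length < 1 or self.merge_gap < 0:
            raise ValueError("min_length >= 1 and merge_gap >= 0 required")


def read_depth_table(path, bin_size: int = 100) -> list[CoverageProfile]:
    """Bin a per-position depth TSV (contig, 1-based position, depth).

    The layout matches what standard alignment depth tools print.  Positions
    must be sorted and unique within a contig; positions absent from the
    table are treated as depth 0.  The trailing partial bin is averaged over
    its actual width.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["contig", "pos", "depth"],
                     comment="#")
    profiles = []
    for contig, grp in df.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if (np.diff(pos) <= 0).any():
            raise ValueError(f"{path}: positions not sorted/unique in contig {contig}")
        profiles.append(
            profile_from_positions(str(contig), pos, grp["depth"].to_numpy(float),
                                   bin_size)
        )
    return profiles


def profile_from_positions(
    contig: str, positions: np.ndarray, depths: np.ndarray, bin_size: int
) -> CoverageProfile:
    """Mean depth per bin from (1-based position, depth) pairs; gaps count as 0."""
    length = int(positions.max())
    full = np.zeros(length)
    full[positions - 1] = depths
    return profile_from_array(contig, full, bin_size)


def profile_from_array(contig: str, per_base: np.ndarray, bin_size: int) -> CoverageProfile:
    """Bin a dense per-base depth array (index 0 = position 1)."""
    per_base = np.asarray(per_base, dtype=float)
    n_bins = -(-len(per_base) // bin_size)
    sums = np.add.reduceat(per_base, np.arange(0, len(per_base), bin_size))
    widths = np.full(n_bins, bin_size, dtype=float)
    widths[-1] = len(per_base) - bin_size * (n_bins - 1)
    return CoverageProfile(contig=contig, bin_size=bin_size, depths=sums / widths)


def _threshold(mu: float, sigma: float, params: CallerParams) -> float:
    if params.deletions:
        return mu / 2.0
    return 2.0 * (mu - sigma) if params.alt_threshold else 2.0 * mu - sigma


def call_amplifications(
    profiles: CoverageProfile | list[CoverageProfile],
    params: CallerParams | None = None,
) -> list[AmplifiedRegion]:
    """Call amplified (or, optionally, deleted) regions from binned coverage.

    Per contig (or globally with ``global_stats``), bins with depth strictly
    above 2μ − σ are flagged; flagged runs separated by gaps of at most
    ``merge_gap`` bp are merged, runs shorter than ``min_length`` bp are
    dropped, and each surviving run is reported with its mean depth divided
    by μ as ``mean_fold``.  Output is sorted by contig appearance then start.
    """
    params = params or CallerParams()
    if isinstance(profiles, CoverageProfile):
        profiles = [profiles]
    if params.global_stats:
        pooled = np.concatenate([p.depths for p in profiles])
        stats_by_contig = {p.contig: (pooled.mean(), pooled.std()) for p in profiles}
    else:
        stats_by_contig = {p.contig: (p.depths.mean(), p.depths.std()) for p in profiles}

    regions: list[AmplifiedRegion] = []
    for prof in profiles:
        mu, sigma = stats_by_contig[prof.contig]
        if mu == 0:
            warnings.warn(f"contig {prof.contig}: all-zero coverage, no calls",
                          stacklevel=2)
            continue
        if params.min_length < prof.bin_size:
            raise ValueError("min_length must be >= bin_size")
        thr = _threshold(mu, sigma, params)
        flagged = prof.depths < thr if params.deletions else prof.depths > thr
        max_gap_bins = params.merge_gap // prof.bin_size
        for lo, hi in _merged_runs(flagged, max_gap_bins):
            start = prof.start_coordinate + lo * prof.bin_size
            end = prof.start_coordinate + (hi + 1) * prof.bin_size - 1
            if end - start + 1 < params.min_length:
                continue
            regions.append(
                AmplifiedRegion(
                    contig=prof.contig,
                    start=start,
                    end=end,
                    mean_fold=float(prof.depths[lo : hi + 1].mean() / mu),
                )
            )
    return regions


def _merged_runs(flagged: np.ndarray, max_gap_bins: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging runs separated by <= max_gap_bins Falses."""
    idx = np.flatnonzero(flagged)
    if idx.size == 0:
        return []
    runs = []
    lo = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= max_gap_bins:
            prev = i
        else:
            runs.append((int(lo), int(prev)))
            lo = prev = i
    runs.append((int(lo), int(prev)))
    return runs


def write_bed(regions: list[AmplifiedRegion], path) -> None:
    """Write regions as BED (0-based half-open): contig, start-1, end, name, fold."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\tamp_{i}\t{r.mean_fold:.4f}\n")


def read_bed(path) -> list[AmplifiedRegion]:
    """Read back the BED written by :func:`write_bed` (coordinate round-trip)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start0, end, _name, fold = line.rstrip("\n").split("\t")[:5]
            out.append(
                AmplifiedRegion(
                    contig=contig, start=int(start0) + 1, end=int(end),
                    mean_fold=float(fold),
                )
            )
    return out
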