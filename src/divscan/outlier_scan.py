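"""Joint FST-quantile + reduced-Pi candidate windows, merged into regions.

A window is a candidate for a population pair when its FST is STRICTLY above
the genome-wide q-quantile of window FST and its Pi is STRICTLY below the
genome-wide r-quantile of window Pi in at least one population of the pair
(or in a single focal population when configured). Candidates on the same
chromosome whose gap is at most ``merge_max_gap`` bp are merged into regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .window_stats import WindowStats


@dataclass(frozen=True)
class ScanConfig:
    fst_top_quantile: float = 0.95
    pi_reduction_quantile: float = 0.50
    merge_max_gap: int = 0
    #: when set, "reduced Pi" is required in this population only;
    #: default None means at least one population of the pair.
    focal_pop: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.fst_top_quantile < 1.0:
            raise ValueError("fst_top_quantile must be in (0, 1)")
        if not 0.0 <= self.pi_reduction_quantile < 1.0:
            raise ValueError("pi_reduction_quantile must be in [0, 1)")
        if self.merge_max_gap < 0:
            raise ValueError("merge_max_gap must be >= 0")


@dataclass
class CandidateRegion:
    chrom: str
    start: int
    end: int
    member_windows: list[WindowStats]
    mean_fst: float

    @property
    def n_windows(self) -> int:
        return len(self.member_windows)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start <= end and self.end >= start


def _pair_key(ws: WindowStats, pair: tuple[str, str]) -> tuple[str, str]:
    if pair in ws.fst:
        return pair
    rev = (pair[1], pair[0])
    if rev in ws.fst:
        return rev
    raise KeyError(f"population pair {pair} not present in scan")


def fst_threshold(
    stats: list[WindowStats], pair: tuple[str, str], q: float
) -> float:
    """Empirical q-quantile (linear interpolation) of defined window FST."""
    key = _pair_key(stats[0], pair)
    vals = np.asarray([ws.fst[key] for ws in stats], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no windows with defined FST for pair {pair}")
    return float(np.quantile(vals, q))


def pi_threshold(stats: list[WindowStats], population: str, r: float) -> float:
    """Genome-wide r-quantile of window Pi for one population."""
    vals = np.asarray([ws.pi[population] for ws in stats], dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no windows with defined Pi for {population}")
    return float(np.quantile(vals, r))


def detect_candidate_windows(
    stats: list[WindowStats], pair: tuple[str, str], cfg: ScanConfig
) -> list[WindowStats]:
    """Windows with FST strictly above the q-quantile AND reduced Pi."""
    key = _pair_key(stats[0], pair)
    fst_thr = fst_threshold(stats, pair, cfg.fst_top_quantile)
    pi_pops = [cfg.focal_pop] if cfg.focal_pop is not None else list(key)
    pi_thr = {p: pi_threshold(stats, p, cfg.pi_reduction_quantile) for p in pi_pops}
    out = []
    for ws in stats:
        f = ws.fst[key]
        if not (math.isfinite(f) and f > fst_thr):
            continue
        if any(
            math.isfinite(ws.pi[p]) and ws.pi[p] < pi_thr[p] for p in pi_pops
        ):
            out.append(ws)
    return sorted(out, key=lambda w: (w.chrom, w.start))


def merge_candidate_windows(
    candidates: list[WindowStats],
    cfg: ScanConfig,
    pair: tuple[str, str] | None = None,
) -> list[CandidateRegion]:
    """Single linear pass per chromosome: extend the open region while the
    next window's start <= current end + 1 + merge_max_gap."""
    if not candidates:
        return []
    key = _pair_key(candidates[0], pair) if pair is not None else None

    def region_from(members: list[WindowStats]) -> CandidateRegion:
        if key is not None:
            vals = [w.fst[key] for w in members]
        else:
            # mean over all pairs when none specified
            vals = [np.nanmean(list(w.fst.values())) for w in members]
        return CandidateRegion(
            chrom=members[0].chrom,
            start=min(w.start for w in members),
            end=max(w.end for w in members),
            member_windows=members,
            mean_fst=float(np.nanmean(vals)),
        )

    cand = sorted(candidates, key=lambda w: (w.chrom, w.start))
    regions: list[CandidateRegion] = []
    open_members = [cand[0]]
    open_end = cand[0].end
    for ws in cand[1:]:
        if (
            ws.chrom == open_members[0].chrom
            and ws.start <= open_end + 1 + cfg.merge_max_gap
        ):
            open_members.append(ws)
            open_end = max(open_end, ws.end)
        else:
            regions.append(region_from(open_members))
            open_members = [ws]
            open_end = ws.end
    regions.append(region_from(open_members))
    return regions


def find_candidate_regions(
    stats: list[WindowStats], pair: tuple[str, str], cfg: ScanConfig
) -> list[CandidateRegion]:
    """detect_candidate_windows followed by merge_candidate_windows."""
    return merge_candidate_windows(
        detect_candidate_windows(stats, pair, cfg), cfg, pair=pair
    )


def write_regions_bed(regions: list[CandidateRegion], path: str) -> None:
    """BED (0-based half-open): bed_start = start - 1, bed_end = end."""
    with open(path, "w") as fh:
        for i, r in enumerate(regions, 1):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\tregion_{i}\n")


def read_regions_bed(path: str) -> list[tuple[str, int, int]]:
    """Back to 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]) + 1, int(parts[2])))
    return out


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "CHROM": r.chrom,
                "START": r.start,
                "END": r.end,
                "N_WINDOWS": r.n_windows,
                "MEAN_FST": r.mean_fst,
            }
            for r in regions
        ],
        columns=["CHROM", "START", "END", "N_WINDOWS", "MEAN_FST"],
    )
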