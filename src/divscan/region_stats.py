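"""Region-vs-background enrichment battery.

Quantifies how a candidate region's windowed FST and Pi differ from the
genome-wide window distribution: fold enrichment, percentile rank, 95th/99th
percentile exceedance fractions, a rank-sum test on FST, the Pi ratio and
reduction-of-diversity (ROD) statistic, the fraction of windows with lower
focal Pi, and a paired signed-rank test on per-window (Pi_focal, Pi_ref).

The rank tests are self-contained: exact enumeration for small samples
(midranks for ties), normal approximation with tie-corrected variance and
continuity correction otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


@dataclass
class RegionEnrichment:
    fold: float
    percentile_rank: float
    frac_exceed_p95: float
    frac_exceed_p99: float
    ranksum_p: float
    pi_ratio: float
    rod: float
    frac_lower_pi: float
    signedrank_p: float


# ---------------------------------------------------------------------------
# FST enrichment


def fold_enrichment(
    region_windows: list[float] | np.ndarray,
    genome_windows: list[float] | np.ndarray,
) -> float:
    """mean(region FST) / mean(genome FST); the genome list includes the
    region's own windows. NaN with a warning when the genome mean is <= 0."""
    region = np.asarray(region_windows, dtype=float)
    genome = np.asarray(genome_windows, dtype=float)
    region = region[np.isfinite(region)]
    genome = genome[np.isfinite(genome)]
    if region.size == 0 or genome.size == 0:
        raise ValueError("empty window list")
    gmean = genome.mean()
    if gmean <= 0:
        logger.warning("fold_enrichment: genome mean %g <= 0; undefined", gmean)
        return math.nan
    return float(region.mean() / gmean)


def percentile_rank(region_mean: float, genome_windows) -> float:
    """Fraction of genome windows with FST strictly below the region mean."""
    genome = np.asarray(genome_windows, dtype=float)
    genome = genome[np.isfinite(genome)]
    if genome.size == 0:
        raise ValueError("empty genome window list")
    return float((genome < region_mean).sum() / genome.size)


def exceedance_fractions(
    region_windows, genome_windows, percentiles=(0.95, 0.99)
) -> dict[float, float]:
    """For each percentile, the fraction of region windows strictly above the
    genome-wide empirical percentile of window FST."""
    region = np.asarray(region_windows, dtype=float)
    genome = np.asarray(genome_windows, dtype=float)
    region = region[np.isfinite(region)]
    genome = genome[np.isfinite(genome)]
    if region.size == 0 or genome.size == 0:
        raise ValueError("empty window list")
    out = {}
    for p in percentiles:
        thr = np.quantile(genome, p)
        out[p] = float((region > thr).sum() / region.size)
    return out


# ---------------------------------------------------------------------------
# rank tests

#: exact rank-sum enumeration is used when C(n, min) stays below this.
_EXACT_COMB_LIMIT = 200_000


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test with midranks for ties.

    Exact enumeration of the rank-sum distribution when min(|x|, |y|) < 8
    (and the enumeration is tractable); otherwise a normal approximation
    with tie-corrected variance and continuity correction. Returns
    (rank sum of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    nx, ny = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return w, 1.0

    small = min(nx, ny) < 8 and math.comb(nx + ny, min(nx, ny)) <= _EXACT_COMB_LIMIT
    if small:
        sums = np.fromiter(
            (sum(comb) for comb in combinations(ranks, nx)),
            dtype=float,
            count=math.comb(nx + ny, nx),
        )
        eps = 1e-9
        p_low = float((sums <= w + eps).mean())
        p_high = float((sums >= w - eps).mean())
        return w, min(1.0, 2.0 * min(p_low, p_high))

    n = nx + ny
    mu = nx * (n + 1) / 2.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return w, 1.0
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    return w, float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_signed_rank(pairs) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; midranks on |differences|. The exact null
    distribution (generating-function convolution over sign assignments) is
    used for <= 25 nonzero pairs, a tie-corrected normal approximation with
    continuity correction otherwise. Returns (W+, p).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an iterable of (a, b)")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0.0]
    k = d.size
    if k == 0:
        return 0.0, 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if k <= 25:
        # exact: W+ = sum of included ranks, each independently with prob 1/2.
        # midranks are multiples of 1/2, so double to integers and convolve.
        r2 = np.rint(2.0 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(round(2.0 * w_plus))
        p_low = float(dist[: w2 + 1].sum())
        p_high = float(dist[w2:].sum())
        return w_plus, min(1.0, 2.0 * min(p_low, p_high))

    mu = k * (k + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = k * (k + 1) * (2 * k + 1) / 24.0 - tie_term / 48.0
    if var <= 0:
        return w_plus, 1.0
    z = (
        (w_plus - mu - math.copysign(0.5, w_plus - mu)) / math.sqrt(var)
        if w_plus != mu
        else 0.0
    )
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# diversity contrast


def pi_ratio_rod(region_pi_focal, region_pi_ref) -> tuple[float, float]:
    """(pi_ratio, rod): pi_ratio = mean(ref)/mean(focal) over the region's
    windows; rod = 1 - mean(focal)/mean(ref) = 1 - 1/pi_ratio."""
    focal = np.asarray(region_pi_focal, dtype=float)
    ref = np.asarray(region_pi_ref, dtype=float)
    if focal.size != ref.size:
        raise ValueError("focal and reference lists must have equal length")
    mf, mr = focal.mean(), ref.mean()
    if mf <= 0 or mr <= 0:
        logger.warning("pi_ratio_rod: non-positive mean Pi; undefined")
        return math.nan, math.nan
    return float(mr / mf), float(1.0 - mf / mr)


def rod_from_ratio(pi_ratio: float) -> float:
    """ROD via the identity rod = 1 - 1/pi_ratio."""
    return 1.0 - 1.0 / pi_ratio


def fraction_windows_lower_pi(region_pi_focal, region_pi_ref) -> float:
    """Fraction of region windows where focal Pi is strictly below ref Pi."""
    focal = np.asarray(region_pi_focal, dtype=float)
    ref = np.asarray(region_pi_ref, dtype=float)
    if focal.size != ref.size:
        raise ValueError("focal and reference lists must have equal length")
    if focal.size == 0:
        raise ValueError("empty window lists")
    return float((focal < ref).sum() / focal.size)


# ---------------------------------------------------------------------------
# full battery


def region_enrichment(
    region_fst,
    genome_fst,
    region_pi_focal,
    region_pi_ref,
    exclude_region_from_background: bool = False,
    background_fst=None,
) -> RegionEnrichment:
    """Assemble the full RegionEnrichment bundle for one region.

    ``genome_fst`` is the full genome-wide window list (including the region
    by default); when ``exclude_region_from_background`` is set, the rank-sum
    background and fold denominator use ``background_fst`` (genome minus
    region), which must then be provided.
    """
    if exclude_region_from_background:
        if background_fst is None:
            raise ValueError("background_fst required when excluding the region")
        bg = np.asarray(background_fst, dtype=float)
    else:
        bg = np.asarray(genome_fst, dtype=float)
    bg = bg[np.isfinite(bg)]
    region = np.asarray(region_fst, dtype=float)
    region = region[np.isfinite(region)]

    fold = fold_enrichment(region, bg)
    prank = percentile_rank(float(region.mean()), bg)
    exceed = exceedance_fractions(region, bg)
    _, rs_p = wilcoxon_rank_sum(region, bg)
    ratio, rod = pi_ratio_rod(region_pi_focal, region_pi_ref)
    frac_lower = fraction_windows_lower_pi(region_pi_focal, region_pi_ref)
    _, sr_p = wilcoxon_signed_rank(
        np.column_stack([region_pi_focal, region_pi_ref])
    )
    return RegionEnrichment(
        fold=fold,
        percentile_rank=prank,
        frac_exceed_p95=exceed[0.95],
        frac_exceed_p99=exceed[0.99],
        ranksum_p=rs_p,
        pi_ratio=ratio,
        rod=rod,
        frac_lower_pi=frac_lower,
        signedrank_p=sr_p,
    )


def enrichment_to_frame(
    rows: list[tuple[str, int, int, RegionEnrichment]]
) -> pd.DataFrame:
    """One row per region; fold rounded to 2 decimals and fractions to 4 for
    the report (raw values live on the RegionEnrichment objects)."""
    recs = []
    for chrom, start, end, e in rows:
        recs.append(
            {
                "CHROM": chrom,
                "START": start,
                "END": end,
                "FOLD": round(e.fold, 2),
                "PERCENTILE_RANK": round(e.percentile_rank, 4),
                "FRAC_EXCEED_P95": round(e.frac_exceed_p95, 4),
                "FRAC_EXCEED_P99": round(e.frac_exceed_p99, 4),
                "RANKSUM_P": e.ranksum_p,
                "PI_RATIO": round(e.pi_ratio, 6),
                "ROD": round(e.rod, 6),
                "FRAC_LOWER_PI": round(e.frac_lower_pi, 4),
                "SIGNEDRANK_P": e.signedrank_p,
            }
        )
    return pd.DataFrame(recs)
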