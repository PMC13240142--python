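"""Sliding-window nucleotide diversity, Weir-Cockerham FST and Tajima's D.

Windows are 1-based inclusive intervals [start, start + size - 1], stepped by
``step`` within each chromosome; trailing windows are truncated at the
chromosome end. Per-window FST is the weighted (ratio-of-sums) estimator
sum(a) / sum(a + b + c) over usable sites. Undefined statistics are reported
as NaN, never as zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WindowSpec:
    size: int = 100_000
    step: int = 10_000

    def __post_init__(self) -> None:
        if not self.size >= self.step >= 1:
            raise ValueError(
                f"require size >= step >= 1, got size={self.size} step={self.step}"
            )


@dataclass(frozen=True)
class TajimaConstants:
    """The standard normalizing constants for Tajima's D at sample size n
    (number of sequences, i.e. 2x called diploids)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError(f"need n >= 2 sequences, got {n}")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


@dataclass
class WindowStats:
    """Per-window statistics bundle; keys of ``fst`` are (popA, popB) pairs
    in population order."""

    chrom: str
    start: int
    end: int
    n_variants: int
    n_sites: dict[str, int] = field(default_factory=dict)  # segregating, per pop
    pi: dict[str, float] = field(default_factory=dict)
    fst: dict[tuple[str, str], float] = field(default_factory=dict)
    tajima_d: dict[str, float] = field(default_factory=dict)

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def make_windows(
    chrom_lengths: dict[str, int], spec: WindowSpec
) -> list[tuple[str, int, int]]:
    """Sliding windows over each chromosome, sorted by (chrom, start)."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if length < 1:
            raise ValueError(f"chromosome {chrom} has length {length}")
        start = 1
        while start <= length:
            out.append((chrom, start, min(start + spec.size - 1, length)))
            start += spec.step
    return out


# ---------------------------------------------------------------------------
# per-site vectorized kernels


def _pop_site_arrays(gm: GenotypeMatrix, population: str):
    """(m, j, het_count, n_called) arrays over all sites for one population."""
    sub = gm.calls[gm.sample_indices(population), :]
    called = sub != MISSING
    n_called = called.sum(axis=0)
    j = np.where(called, sub, 0).sum(axis=0).astype(np.float64)
    het = ((sub == 1) & called).sum(axis=0)
    m = 2.0 * n_called
    return m, j, het.astype(np.float64), n_called.astype(np.int64)


def sitewise_pi(gm: GenotypeMatrix, population: str) -> np.ndarray:
    """Unbiased per-site heterozygosity 2 j (m - j) / (m (m - 1)) over called
    alleles; NaN where fewer than 2 alleles are called."""
    m, j, _, _ = _pop_site_arrays(gm, population)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (m - j) / (m * (m - 1.0))
    pi[m < 2] = np.nan
    return pi


def site_pi(calls_col: np.ndarray) -> float:
    """Per-site diversity for one site's dosage column (one population).

    Equals the fraction of differing pairs among the m sampled alleles.
    Returns NaN when fewer than 2 alleles are called.
    """
    col = np.asarray(calls_col)
    called = col != MISSING
    m = 2 * int(called.sum())
    if m < 2:
        return math.nan
    j = int(col[called].sum())
    return 2.0 * j * (m - j) / (m * (m - 1.0))


def site_wc_components(
    calls_col: np.ndarray, pop_a_idx: np.ndarray, pop_b_idx: np.ndarray
) -> tuple[float, float, float]:
    """Two-level Weir-Cockerham variance components (a, b, c) for one site and
    one population pair, from called genotypes only.

    Returns NaNs when either population has no called genotype or when both
    have a single one (the finite-sample corrections are then undefined).
    """
    col = np.asarray(calls_col, dtype=np.float64)
    comp = sitewise_wc_components_pair(
        col[np.asarray(pop_a_idx)][:, None], col[np.asarray(pop_b_idx)][:, None]
    )
    return float(comp[0][0]), float(comp[1][0]), float(comp[2][0])


def sitewise_wc_components_pair(
    calls_a: np.ndarray, calls_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized WC84 (a, b, c) for every site (columns) given the two
    populations' call sub-matrices. Unusable sites yield NaN components."""
    r = 2.0
    stats = []
    for sub in (calls_a, calls_b):
        called = sub != MISSING
        n = called.sum(axis=0).astype(np.float64)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(called, sub, 0).sum(axis=0) / (2.0 * n)
            h = ((sub == 1) & called).sum(axis=0) / n
        stats.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = stats
    usable = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)

        a = (n_bar / n_c) * (
            s2
            - (p_bar * (1.0 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0)
            / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1.0 - p_bar)
            - (r - 1.0) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0

    nan = np.where(usable, 0.0, np.nan)
    return a + nan, b + nan, c + nan


# ---------------------------------------------------------------------------
# single-window operations


def _window_site_index(gm: GenotypeMatrix, window: tuple[str, int, int]) -> np.ndarray:
    chrom, start, end = window
    idx = [
        i
        for i, s in enumerate(gm.sites)
        if s.chrom == chrom and start <= s.pos <= end
    ]
    return np.asarray(idx, dtype=np.intp)


def window_pi(
    gm: GenotypeMatrix, window: tuple[str, int, int], population: str
) -> float:
    """Sum of per-site diversity over the window divided by its bp span."""
    _, start, end = window
    idx = _window_site_index(gm, window)
    if idx.size == 0:
        return 0.0
    pi = sitewise_pi(gm, population)[idx]
    return float(np.nansum(pi)) / (end - start + 1)


def window_weighted_fst(
    gm: GenotypeMatrix, window: tuple[str, int, int], pops: tuple[str, str]
) -> float:
    """sum(a) / sum(a+b+c) over usable sites; NaN when no usable site or the
    denominator is zero."""
    idx = _window_site_index(gm, window)
    if idx.size == 0:
        return math.nan
    a, b, c = sitewise_wc_components_pair(
        gm.calls[gm.sample_indices(pops[0]), :][:, idx].astype(np.float64),
        gm.calls[gm.sample_indices(pops[1]), :][:, idx].astype(np.float64),
    )
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if not np.any(np.isfinite(a)) or den == 0.0:
        return math.nan
    return float(num / den)


def window_tajima_d(
    gm: GenotypeMatrix, window: tuple[str, int, int], population: str
) -> float:
    """Tajima's D over the window's segregating sites in one population.

    The sample size n is fixed at 2x the minimum number of called diploids
    across the window's segregating sites. NaN when there are no segregating
    sites or n < 4.
    """
    idx = _window_site_index(gm, window)
    if idx.size == 0:
        return math.nan
    m, j, _, n_called = _pop_site_arrays(gm, population)
    m, j, n_called = m[idx], j[idx], n_called[idx]
    seg = (m >= 2) & (j > 0) & (j < m)
    S = int(seg.sum())
    if S == 0:
        return math.nan
    n = 2 * int(n_called[seg].min())
    if n < 4:
        return math.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        pi_sum = float(
            np.sum(2.0 * j[seg] * (m[seg] - j[seg]) / (m[seg] * (m[seg] - 1.0)))
        )
    k = TajimaConstants.from_n(n)
    var = k.e1 * S + k.e2 * S * (S - 1)
    if var <= 0:
        return math.nan
    return (pi_sum - S / k.a1) / math.sqrt(var)


# ---------------------------------------------------------------------------
# genome scan


def infer_chrom_lengths(gm: GenotypeMatrix) -> dict[str, int]:
    """Chromosome lengths from the maximum site position (fallback when no
    explicit lengths are provided)."""
    lengths: dict[str, int] = {}
    for s in gm.sites:
        lengths[s.chrom] = max(lengths.get(s.chrom, 1), s.pos)
    return lengths


def genome_scan(
    gm: GenotypeMatrix,
    spec: WindowSpec,
    pops: list[str] | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[WindowStats]:
    """One WindowStats per sliding window with all per-population Pi and
    Tajima's D and all pairwise FST. Deterministic given the input."""
    if pops is None:
        pops = gm.populations
    if chrom_lengths is None:
        chrom_lengths = infer_chrom_lengths(gm)
    windows = make_windows(chrom_lengths, spec)
    if gm.n_sites == 0:
        logger.warning("genome_scan: empty genotype matrix; emitting empty stats")
    pairs = list(combinations(pops, 2))

    # per-population site arrays, computed once
    pop_arrays = {p: _pop_site_arrays(gm, p) for p in pops}
    pop_pi: dict[str, np.ndarray] = {}
    pop_seg: dict[str, np.ndarray] = {}
    for p, (m, j, _, _) in pop_arrays.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = 2.0 * j * (m - j) / (m * (m - 1.0))
        pi[m < 2] = np.nan
        pop_pi[p] = pi
        pop_seg[p] = (m >= 2) & (j > 0) & (j < m)
    pair_abc = {}
    for pa, pb in pairs:
        a, b, c = sitewise_wc_components_pair(
            gm.calls[gm.sample_indices(pa), :].astype(np.float64),
            gm.calls[gm.sample_indices(pb), :].astype(np.float64),
        )
        pair_abc[(pa, pb)] = (a, a + b + c)

    # site positions grouped by chromosome (positions are nondecreasing)
    chrom_site_idx: dict[str, np.ndarray] = {}
    chrom_pos: dict[str, np.ndarray] = {}
    all_chroms = [s.chrom for s in gm.sites]
    all_pos = np.asarray([s.pos for s in gm.sites], dtype=np.int64)
    for chrom in chrom_lengths:
        idx = np.asarray(
            [i for i, c in enumerate(all_chroms) if c == chrom], dtype=np.intp
        )
        chrom_site_idx[chrom] = idx
        chrom_pos[chrom] = all_pos[idx]

    out: list[WindowStats] = []
    for chrom, start, end in windows:
        cidx = chrom_site_idx.get(chrom, np.empty(0, dtype=np.intp))
        cpos = chrom_pos.get(chrom, np.empty(0, dtype=np.int64))
        lo = int(np.searchsorted(cpos, start, side="left"))
        hi = int(np.searchsorted(cpos, end, side="right"))
        idx = cidx[lo:hi]
        span = end - start + 1
        ws = WindowStats(chrom=chrom, start=start, end=end, n_variants=len(idx))
        for p in pops:
            pi_vals = pop_pi[p][idx]
            ws.pi[p] = float(np.nansum(pi_vals)) / span
            seg = pop_seg[p][idx]
            S = int(seg.sum())
            ws.n_sites[p] = S
            if S == 0:
                ws.tajima_d[p] = math.nan
            else:
                n_called = pop_arrays[p][3][idx]
                n = 2 * int(n_called[seg].min())
                if n < 4:
                    ws.tajima_d[p] = math.nan
                else:
                    k = TajimaConstants.from_n(n)
                    var = k.e1 * S + k.e2 * S * (S - 1)
                    pi_sum = float(np.nansum(pi_vals[seg]))
                    ws.tajima_d[p] = (
                        (pi_sum - S / k.a1) / math.sqrt(var) if var > 0 else math.nan
                    )
        for pair in pairs:
            a, abc = pair_abc[pair]
            aw, abcw = a[idx], abc[idx]
            den = np.nansum(abcw)
            if not np.any(np.isfinite(aw)) or den == 0.0:
                ws.fst[pair] = math.nan
            else:
                ws.fst[pair] = float(np.nansum(aw) / den)
        out.append(ws)
    return out


# ---------------------------------------------------------------------------
# tabular report


def scan_to_frame(stats: list[WindowStats]) -> pd.DataFrame:
    """Tabular scan report: CHROM, BIN_START, BIN_END, N_SITES, PI_<pop>,
    TAJIMA_D_<pop>, FST_<popA>_<popB> columns."""
    if not stats:
        return pd.DataFrame(columns=["CHROM", "BIN_START", "BIN_END", "N_SITES"])
    pops = list(stats[0].pi)
    pairs = list(stats[0].fst)
    rows = []
    for ws in stats:
        row: dict[str, object] = {
            "CHROM": ws.chrom,
            "BIN_START": ws.start,
            "BIN_END": ws.end,
            "N_SITES": ws.n_variants,
        }
        for p in pops:
            row[f"PI_{p}"] = ws.pi[p]
        for p in pops:
            row[f"TAJIMA_D_{p}"] = ws.tajima_d[p]
        for pa, pb in pairs:
            row[f"FST_{pa}_{pb}"] = ws.fst[(pa, pb)]
        rows.append(row)
    return pd.DataFrame(rows)


def write_scan_tsv(stats: list[WindowStats], path: str) -> None:
    scan_to_frame(stats).to_csv(path, sep="\t", index=False, na_rep="nan")


def read_scan_tsv(path: str) -> list[WindowStats]:
    """Inverse of write_scan_tsv (column layout defines pops and pairs)."""
    df = pd.read_csv(path, sep="\t")
    pops = [c[len("PI_"):] for c in df.columns if c.startswith("PI_")]
    pairs: list[tuple[str, str]] = []
    for c in df.columns:
        if not c.startswith("FST_"):
            continue
        tail = c[len("FST_"):]
        for p in pops:
            if tail.startswith(p + "_") and tail[len(p) + 1 :] in pops:
                pairs.append((p, tail[len(p) + 1 :]))
                break
        else:
            raise ValueError(f"cannot split FST column {c!r} into known pops")
    out = []
    for _, r in df.iterrows():
        ws = WindowStats(
            chrom=str(r["CHROM"]),
            start=int(r["BIN_START"]),
            end=int(r["BIN_END"]),
            n_variants=int(r["N_SITES"]),
        )
        for p in pops:
            ws.pi[p] = float(r[f"PI_{p}"])
            ws.tajima_d[p] = float(r[f"TAJIMA_D_{p}"])
        for pa, pb in pairs:
            ws.fst[(pa, pb)] = float(r[f"FST_{pa}_{pb}"])
        out.append(ws)
    return out
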