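"""Read, filter and write multi-sample VCFs as genotype dosage matrices.

Only the GT subfield of each call is consumed; phased (``|``) and unphased
(``/``) separators are equivalent. Diploid genotypes are encoded as
alt-allele dosage 0/1/2; anything containing a ``.`` allele (including
half-calls like ``./1``) is MISSING. Population labels travel in a separate
two-column text table, not in the VCF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: Sentinel dosage code for a missing diploid genotype.
MISSING: int = -1

_HARD_FILTER_DEFAULTS = {
    "QD_min": 2.0,
    "MQ_min": 40.0,
    "FS_max": 60.0,
    "SOR_max": 3.0,
    "MQRankSum_min": -12.5,
    "ReadPosRankSum_min": -8.0,
}

#: INFO keys parsed into VariantSite.info when present and numeric.
INFO_KEYS = ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum")


class VcfParseError(ValueError):
    """Raised for a structurally invalid VCF, naming the offending line."""


class PopulationTableError(ValueError):
    """Raised when a VCF sample has no population assignment."""


@dataclass(frozen=True)
class VariantSite:
    """One VCF site: coordinates, alleles, QUAL and numeric INFO annotations."""

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    info: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref:
            raise ValueError("ref allele must be non-empty")
        if not self.alts:
            raise ValueError("alts must be non-empty")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


@dataclass(frozen=True)
class FilterConfig:
    """Site-level filter thresholds.

    ``hard_filter_thresholds`` keys: QD_min, MQ_min, FS_max, SOR_max,
    MQRankSum_min, ReadPosRankSum_min. A site fails a hard filter only when
    the annotation is present and violates its threshold.
    """

    qual_min: float = 40.0
    maf_min: float = 0.05
    min_call_rate: float = 0.95
    biallelic_only: bool = True
    hard_filter_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(_HARD_FILTER_DEFAULTS)
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError(f"maf_min must be in [0, 0.5], got {self.maf_min}")
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError(
                f"min_call_rate must be in [0, 1], got {self.min_call_rate}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x sites diploid alt-dosage calls with population labels.

    ``calls`` is an int8 array of shape (n_samples, n_sites) holding
    0, 1, 2 or MISSING (-1).
    """

    samples: list[str]
    pop_of: dict[str, str]
    sites: list[VariantSite]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        legal = np.isin(self.calls, (0, 1, 2, MISSING))
        if not legal.all():
            bad = np.unique(self.calls[~legal])
            raise ValueError(f"illegal dosage codes {bad.tolist()}")
        missing_pop = [s for s in self.samples if s not in self.pop_of]
        if missing_pop:
            raise PopulationTableError(
                f"samples without population label: {missing_pop}"
            )
        prev: tuple[str, int] | None = None
        for site in self.sites:
            if prev is not None and prev[0] == site.chrom and site.pos < prev[1]:
                raise ValueError(
                    f"positions not nondecreasing on {site.chrom}: "
                    f"{prev[1]} then {site.pos}"
                )
            prev = (site.chrom, site.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance among samples."""
        seen: list[str] = []
        for s in self.samples:
            p = self.pop_of[s]
            if p not in seen:
                seen.append(p)
        return seen

    def sample_indices(self, population: str) -> np.ndarray:
        idx = [i for i, s in enumerate(self.samples) if self.pop_of[s] == population]
        if not idx:
            raise KeyError(f"no samples in population {population!r}")
        return np.asarray(idx, dtype=np.intp)

    def take_sites(self, mask_or_index: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to the selected site columns."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            samples=list(self.samples),
            pop_of=dict(self.pop_of),
            sites=[self.sites[i] for i in idx],
            calls=self.calls[:, idx].copy(),
        )


def read_pop_table(path: str) -> dict[str, str]:
    """Two whitespace/TSV columns: sample identifier, population label."""
    pop_of: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise PopulationTableError(
                    f"{path}:{lineno}: expected 'sample population', got {line!r}"
                )
            pop_of[parts[0]] = parts[1]
    return pop_of


def _parse_gt(token: str) -> int:
    # GT is the first colon-separated subfield; "." anywhere -> MISSING
    gt = token.split(":", 1)[0]
    sep = "|" if "|" in gt else "/"
    alleles = gt.split(sep)
    if len(alleles) != 2:
        if gt in (".", "./.", ".|."):
            return MISSING
        raise ValueError(f"non-diploid GT {gt!r}")
    dosage = 0
    for a in alleles:
        if a == ".":
            return MISSING
        dosage += int(a != "0")
    return dosage


def _parse_info(info_field: str) -> dict[str, float]:
    out: dict[str, float] = {}
    if info_field in (".", ""):
        return out
    for item in info_field.split(";"):
        key, _, val = item.partition("=")
        if key in INFO_KEYS and val:
            try:
                out[key] = float(val)
            except ValueError:
                continue
    return out


def read_vcf(path: str, pop_table: dict[str, str]) -> GenotypeMatrix:
    """Parse a VCFv4.2 text file into a GenotypeMatrix.

    Every VCF sample must appear in ``pop_table``. Multiallelic sites are
    retained (dosage counts alt index 1 only) and flagged for downstream
    filtering via ``VariantSite.is_biallelic``.
    """
    samples: list[str] | None = None
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if len(cols) < 9 or cols[:9] != [
                    "#CHROM", "POS", "ID", "REF", "ALT",
                    "QUAL", "FILTER", "INFO", "FORMAT",
                ]:
                    raise VcfParseError(
                        f"{path}:{lineno}: malformed #CHROM header line"
                    )
                samples = cols[9:]
                absent = [s for s in samples if s not in pop_table]
                if absent:
                    raise PopulationTableError(
                        f"VCF samples absent from population table: {absent}"
                    )
                continue
            if samples is None:
                raise VcfParseError(
                    f"{path}:{lineno}: data line before #CHROM header"
                )
            fields = line.split("\t")
            if len(fields) != 9 + len(samples):
                raise VcfParseError(
                    f"{path}:{lineno}: expected {9 + len(samples)} columns, "
                    f"got {len(fields)}"
                )
            try:
                pos = int(fields[1])
                qual = None if fields[5] == "." else float(fields[5])
                alts = tuple(fields[4].split(","))
                if fields[4] == ".":
                    raise ValueError("missing ALT")
                site = VariantSite(
                    chrom=fields[0],
                    pos=pos,
                    ref=fields[3],
                    alts=alts,
                    qual=qual,
                    info=_parse_info(fields[7]),
                )
                row = np.fromiter(
                    (_parse_gt(tok) for tok in fields[9:]),
                    dtype=np.int8,
                    count=len(samples),
                )
            except VcfParseError:
                raise
            except (ValueError, OverflowError) as exc:
                raise VcfParseError(f"{path}:{lineno}: {exc}") from exc
            sites.append(site)
            rows.append(row)
    if samples is None:
        raise VcfParseError(f"{path}: no #CHROM header line found")
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=list(samples),
        pop_of={s: pop_table[s] for s in samples},
        sites=sites,
        calls=calls,
    )


def apply_hard_filters(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Drop sites where any PRESENT annotation violates its hard threshold.

    Absent annotations never trigger removal. Inequalities are strict in
    the removal direction, e.g. FS == 60.0 is retained under FS_max = 60.
    """
    thr = cfg.hard_filter_thresholds
    keep = np.ones(gm.n_sites, dtype=bool)
    for i, site in enumerate(gm.sites):
        info = site.info

        def viol(key: str, bound_key: str, low: bool) -> bool:
            if bound_key not in thr or key not in info:
                return False
            return info[key] < thr[bound_key] if low else info[key] > thr[bound_key]

        if (
            viol("QD", "QD_min", True)
            or viol("MQ", "MQ_min", True)
            or viol("FS", "FS_max", False)
            or viol("SOR", "SOR_max", False)
            or viol("MQRankSum", "MQRankSum_min", True)
            or viol("ReadPosRankSum", "ReadPosRankSum_min", True)
        ):
            keep[i] = False
    return gm.take_sites(keep)


def site_maf(calls_col: np.ndarray) -> float:
    """MAF over called alleles only; NaN when nothing is called."""
    called = calls_col != MISSING
    m = 2 * int(called.sum())
    if m == 0:
        return math.nan
    p = float(calls_col[called].sum()) / m
    return min(p, 1.0 - p)


def apply_site_filters(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Retain sites passing biallelic / QUAL / call-rate / MAF rules.

    QUAL must be strictly greater than ``qual_min``; an absent QUAL (".")
    fails. Call rate is the fraction of non-missing genotypes; MAF is
    computed on called alleles only. A site with zero called genotypes is
    dropped by the call-rate rule, never a division error.
    """
    keep = np.ones(gm.n_sites, dtype=bool)
    n = gm.n_samples
    for i, site in enumerate(gm.sites):
        if cfg.biallelic_only and not site.is_biallelic:
            keep[i] = False
            continue
        if site.qual is None or not site.qual > cfg.qual_min:
            keep[i] = False
            continue
        col = gm.calls[:, i]
        called = int((col != MISSING).sum())
        if n == 0 or called / n < cfg.min_call_rate:
            keep[i] = False
            continue
        maf = site_maf(col)
        if math.isnan(maf) or maf < cfg.maf_min:
            keep[i] = False
    return gm.take_sites(keep)


def filter_genotypes(gm: GenotypeMatrix, cfg: FilterConfig) -> GenotypeMatrix:
    """Hard filters then site filters, as one call."""
    return apply_site_filters(apply_hard_filters(gm, cfg), cfg)


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a GT-only VCFv4.2 file; read_vcf(write_vcf(gm)) is an identity
    on calls, positions, alleles and sample order."""
    chrom_max: dict[str, int] = {}
    for site in gm.sites:
        chrom_max[site.chrom] = max(chrom_max.get(site.chrom, 0), site.pos)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=divscan\n")
        for key in INFO_KEYS:
            fh.write(
                f'##INFO=<ID={key},Number=1,Type=Float,Description="{key}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, site in enumerate(gm.sites):
            qual = "." if site.qual is None else f"{site.qual:g}"
            info = (
                ";".join(f"{k}={site.info[k]:g}" for k in INFO_KEYS if k in site.info)
                or "."
            )
            gts = "\t".join(_GT_STR[int(d)] for d in gm.calls[:, j])
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{','.join(site.alts)}"
                f"\t{qual}\tPASS\t{info}\tGT\t{gts}\n"
            )


def write_pop_table(pop_of: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for sample, pop in pop_of.items():
            fh.write(f"{sample}\t{pop}\n")


def with_filter_overrides(cfg: FilterConfig, **kwargs) -> FilterConfig:
    """Convenience for CLI: replace selected FilterConfig fields."""
    return replace(cfg, **kwargs)
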