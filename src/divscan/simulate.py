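"""Synthetic multi-population diploid SNP panels with known truth.

Per site an ancestral allele frequency p is drawn from the configured law;
each population's frequency is a Balding-Nichols draw
p_k ~ Beta(p (1-F)/F, (1-p) (1-F)/F), so E[p_k] = p and
Var(p_k) = F p (1-p), and the two-population Weir-Cockerham FST parameter has
analytic expectation (F_a + F_b) / 2 (see expected_fst). Diploid dosages are
Binomial(2, p_k).

An optional planted block substitutes F_block for the focal population's
divergence inside the block interval and shrinks its frequencies toward the
nearest boundary so that p'(1-p') = diversity_scale * p(1-p) exactly, giving
elevated differentiation with smoothly reduced diversity.

Draw order from the single seeded generator is fixed (positions per
chromosome, ancestral frequencies, per-population frequencies in pop order,
genotypes in pop order, missingness mask), so fixtures are reproducible
bit-for-bit. Site positions are uniform without linkage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    VariantSite,
    write_pop_table,
    write_vcf,
)

_F_EXACT_EPS = 1e-12  # F below this: p_k = p exactly (degenerate Beta guard)


@dataclass(frozen=True)
class BlockConfig:
    chrom: str
    start: int
    end: int
    f_block: float
    focal_pop: str
    diversity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError("invalid block interval")
        if not 0.0 <= self.f_block < 1.0:
            raise ValueError("f_block must be in [0, 1)")
        if not 0.0 < self.diversity_scale <= 1.0:
            raise ValueError("diversity_scale must be in (0, 1]")


@dataclass(frozen=True)
class SimConfig:
    """Defaults mirror a three-population design of 14 + 10 + 10 diploids."""

    pops: tuple[tuple[str, int, float], ...] = (
        ("ST", 14, 0.001),
        ("ZH", 10, 0.001),
        ("HN", 10, 0.001),
    )
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000}
    )
    # 8400 sites/Mb under the default ancestral law gives per-bp Pi ~ 3e-3
    n_sites: int = 8400
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    block: BlockConfig | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, n, f in self.pops:
            if not 0.0 <= f < 1.0:
                raise ValueError(f"population {label}: F must be in [0, 1)")
            if n < 1:
                raise ValueError(f"population {label}: need >= 1 diploid")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.block is not None:
            if self.block.chrom not in self.chrom_lengths:
                raise ValueError(f"block chrom {self.block.chrom!r} unknown")
            if self.block.end > self.chrom_lengths[self.block.chrom]:
                raise ValueError("block extends past chromosome end")
            if self.block.focal_pop not in [p[0] for p in self.pops]:
                raise ValueError(f"block focal_pop {self.block.focal_pop!r} unknown")


@dataclass
class SimTruth:
    positions: dict[str, np.ndarray]
    ancestral_freq: np.ndarray
    pop_freq: dict[str, np.ndarray]
    block: BlockConfig | None
    seed: int

    def to_json(self, path: str) -> None:
        obj = {
            "seed": self.seed,
            "positions": {c: p.tolist() for c, p in self.positions.items()},
            "ancestral_freq": self.ancestral_freq.tolist(),
            "pop_freq": {k: v.tolist() for k, v in self.pop_freq.items()},
            "block": None
            if self.block is None
            else {
                "chrom": self.block.chrom,
                "start": self.block.start,
                "end": self.block.end,
                "f_block": self.block.f_block,
                "focal_pop": self.block.focal_pop,
                "diversity_scale": self.block.diversity_scale,
            },
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)


def expected_fst(f_a: float, f_b: float) -> float:
    """Analytic two-population Weir-Cockerham FST expectation under
    Balding-Nichols draws with divergences f_a and f_b.

    With p_k ~ BN(p, F_k): the among-population variance component per site
    is E[(p_a - p_b)^2] / 2 = (F_a + F_b)/2 * p(1-p), and the total
    (a + b + c) limit is E[p_bar(1 - p_bar)] + s^2/2 = p(1-p); the p(1-p)
    factors cancel in the ratio of sums, leaving (F_a + F_b) / 2 for any
    ancestral frequency law.
    """
    if not (0.0 <= f_a < 1.0 and 0.0 <= f_b < 1.0):
        raise ValueError("F values must be in [0, 1)")
    return (f_a + f_b) / 2.0


def _draw_ancestral(rng: np.random.Generator, law: tuple, size: int) -> np.ndarray:
    kind = law[0]
    if kind == "uniform":
        lo, hi = float(law[1]), float(law[2])
        return rng.uniform(lo, hi, size=size)
    if kind == "beta":
        a, b = float(law[1]), float(law[2])
        return rng.beta(a, b, size=size)
    raise ValueError(f"unknown ancestral_freq_law {law!r}")


def _bn_draw(rng: np.random.Generator, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Vectorized Balding-Nichols draw; F ~ 0 returns p exactly."""
    out = p.copy()
    live = f > _F_EXACT_EPS
    if live.any():
        ratio = (1.0 - f[live]) / f[live]
        out[live] = rng.beta(p[live] * ratio, (1.0 - p[live]) * ratio)
    return out


def _shrink_heterozygosity(p: np.ndarray, scale: float) -> np.ndarray:
    """Move frequencies toward the nearest boundary so that the new
    heterozygosity p'(1-p') equals scale * p(1-p) exactly."""
    v = scale * p * (1.0 - p)
    disc = np.sqrt(np.maximum(1.0 - 4.0 * v, 0.0))
    low = 0.5 * (1.0 - disc)
    high = 0.5 * (1.0 + disc)
    return np.where(p <= 0.5, low, high)


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate a GenotypeMatrix plus its generating truth, reproducibly
    from cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    total_len = sum(cfg.chrom_lengths.values())

    # site positions per chromosome, proportional to length, sorted, unique
    positions: dict[str, np.ndarray] = {}
    chroms = sorted(cfg.chrom_lengths)
    remaining = cfg.n_sites
    for ci, chrom in enumerate(chroms):
        length = cfg.chrom_lengths[chrom]
        if ci == len(chroms) - 1:
            k = remaining
        else:
            k = int(round(cfg.n_sites * length / total_len))
            k = min(k, remaining)
        remaining -= k
        k = min(k, length)
        pos = rng.choice(length, size=k, replace=False) + 1
        positions[chrom] = np.sort(pos)

    n_total = sum(len(p) for p in positions.values())
    p_anc = _draw_ancestral(rng, cfg.ancestral_freq_law, n_total)

    # per-site F per population, with the planted-block override
    site_chrom = np.concatenate(
        [np.repeat(c, len(positions[c])) for c in chroms]
    )
    site_pos = np.concatenate([positions[c] for c in chroms])
    in_block = np.zeros(n_total, dtype=bool)
    if cfg.block is not None:
        in_block = (
            (site_chrom == cfg.block.chrom)
            & (site_pos >= cfg.block.start)
            & (site_pos <= cfg.block.end)
        )

    pop_freq: dict[str, np.ndarray] = {}
    for label, _, f_base in cfg.pops:
        f_site = np.full(n_total, f_base)
        if cfg.block is not None and label == cfg.block.focal_pop:
            f_site[in_block] = cfg.block.f_block
        pk = _bn_draw(rng, p_anc, f_site)
        if (
            cfg.block is not None
            and label == cfg.block.focal_pop
            and cfg.block.diversity_scale < 1.0
        ):
            pk[in_block] = _shrink_heterozygosity(
                pk[in_block], cfg.block.diversity_scale
            )
        pop_freq[label] = pk

    samples: list[str] = []
    pop_of: dict[str, str] = {}
    rows: list[np.ndarray] = []
    for label, n_dip, _ in cfg.pops:
        dosages = rng.binomial(2, pop_freq[label][None, :], size=(n_dip, n_total))
        for i in range(n_dip):
            name = f"{label}_{i + 1:02d}"
            samples.append(name)
            pop_of[name] = label
            rows.append(dosages[i].astype(np.int8))
    calls = np.stack(rows, axis=0)

    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)

    sites = [
        VariantSite(chrom=str(c), pos=int(p), ref="A", alts=("T",), qual=100.0)
        for c, p in zip(site_chrom, site_pos)
    ]
    gm = GenotypeMatrix(samples=samples, pop_of=pop_of, sites=sites, calls=calls)
    truth = SimTruth(
        positions=positions,
        ancestral_freq=p_anc,
        pop_freq=pop_freq,
        block=cfg.block,
        seed=cfg.seed,
    )
    return gm, truth


def write_fixture(cfg: SimConfig, out_prefix: str) -> dict[str, str]:
    """Write <prefix>.vcf, <prefix>.pops.tsv and <prefix>.truth.json;
    the trio is sufficient to run every CLI subcommand."""
    gm, truth = simulate_genotypes(cfg)
    paths = {
        "vcf": f"{out_prefix}.vcf",
        "pops": f"{out_prefix}.pops.tsv",
        "truth": f"{out_prefix}.truth.json",
    }
    write_vcf(gm, paths["vcf"])
    write_pop_table(gm.pop_of, paths["pops"])
    truth.to_json(paths["truth"])
    return paths


def sim_config_from_yaml(path: str) -> SimConfig:
    """Load a SimConfig from a YAML mapping (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict = {}
    if "pops" in raw:
        kwargs["pops"] = tuple(
            (str(p["label"]), int(p["n"]), float(p["f"])) for p in raw["pops"]
        )
    if "chrom_lengths" in raw:
        kwargs["chrom_lengths"] = {
            str(k): int(v) for k, v in raw["chrom_lengths"].items()
        }
    for key in ("n_sites", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "missing_rate" in raw:
        kwargs["missing_rate"] = float(raw["missing_rate"])
    if "ancestral_freq_law" in raw:
        kwargs["ancestral_freq_law"] = tuple(raw["ancestral_freq_law"])
    if raw.get("block"):
        b = raw["block"]
        kwargs["block"] = BlockConfig(
            chrom=str(b["chrom"]),
            start=int(b["start"]),
            end=int(b["end"]),
            f_block=float(b["f_block"]),
            focal_pop=str(b["focal_pop"]),
            diversity_scale=float(b.get("diversity_scale", 1.0)),
        )
    return SimConfig(**kwargs)
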