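"""Synthetic MAGIC doubled-haploid populations with known ground truth.

Emulates an eight-way funnel cross of fully inbred founders: four two-way
crosses, two four-way crosses, one eight-way cross, then derivation of a
doubled-haploid (DH) line by doubling a single gamete of the eight-way F1.
Meioses follow the Haldane (no-interference) map function, so the
recombination fraction between markers ``d`` cM apart is
``r = (1 - exp(-2 d / 100)) / 2``.

Every line's genome is a mosaic of founder segments; the founder-of-origin
labels are retained (:class:`FounderMosaic`) so that downstream QTL scans and
founder allelic-effect estimates can be checked against planted truth.
Phenotypes follow a mixed model with line (polygenic + planted QTL), fixed
treatment, random year, random line-by-treatment and residual terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "CrossingScheme",
    "FounderMosaic",
    "QTLSpec",
    "PhenotypeModel",
    "DegradeReport",
    "SimDataset",
    "haldane_r",
    "simulate_founders",
    "simulate_meiosis",
    "simulate_magic_dh",
    "simulate_phenotypes",
    "degrade_genotypes",
    "default_config",
    "simulate_dataset",
]

MINOR, MAJOR = 0, 2  # DH genotype codes: minor / major homozygote


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

class GeneticMap:
    """Ordered marker map: (marker_id, chromosome, position in cM).

    Positions must be non-decreasing within each chromosome, marker ids
    unique, and every chromosome must carry at least one marker.  Positions
    are genetic (cM), zero-based from each chromosome's first marker.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["marker_id", "chromosome", "position_cM"]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"genetic map missing columns: {missing}")
        frame = frame[required].reset_index(drop=True)
        if frame["marker_id"].duplicated().any():
            dups = frame.loc[frame["marker_id"].duplicated(), "marker_id"]
            raise ValueError(f"duplicate marker ids: {sorted(set(dups))[:5]}")
        if (frame["position_cM"] < 0).any():
            raise ValueError("map positions must be >= 0")
        for chrom, grp in frame.groupby("chromosome", sort=False):
            if not grp["position_cM"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted on chromosome {chrom}")
        self.frame = frame
        self.marker_ids = frame["marker_id"].to_numpy()
        self.chromosomes = frame["chromosome"].to_numpy()
        self.positions = frame["position_cM"].to_numpy(dtype=float)
        self._index = {m: i for i, m in enumerate(self.marker_ids)}
        # contiguous blocks per chromosome, in file order
        self.chrom_slices: dict = {}
        start = 0
        for chrom, grp in frame.groupby("chromosome", sort=False):
            self.chrom_slices[chrom] = slice(start, start + len(grp))
            start += len(grp)
        if start != len(frame):
            raise ValueError("chromosome blocks are interleaved; sort the map")

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def index_of(self, marker_id) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise KeyError(f"marker {marker_id!r} not in map") from None

    def chrom_bounds(self, chrom) -> tuple[float, float]:
        sl = self.chrom_slices[chrom]
        return float(self.positions[sl.start]), float(self.positions[sl.stop - 1])

    def nearest_marker(self, chrom, pos_cM: float) -> int:
        """Index of the marker on ``chrom`` closest to ``pos_cM``."""
        sl = self.chrom_slices[chrom]
        pos = self.positions[sl]
        return sl.start + int(np.argmin(np.abs(pos - pos_cM)))

    @classmethod
    def uniform(cls, chrom_lengths: Mapping[str, float],
                spacing_cM: float = 0.191) -> "GeneticMap":
        """Evenly spaced markers along each chromosome at ``spacing_cM``."""
        rows = []
        for chrom, length in chrom_lengths.items():
            n = max(2, int(round(length / spacing_cM)) + 1)
            pos = np.linspace(0.0, length, n)
            for j, p in enumerate(pos):
                rows.append((f"{chrom}_m{j:05d}", chrom, p))
        return cls(pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_cM"]))

    def __len__(self) -> int:
        return self.n_markers


@dataclass(frozen=True)
class CrossingScheme:
    """Balanced funnel pairing of founders: adjacent pairs are crossed, then
    the pair of pairs, and so on — a complete binary tree with the founders
    as leaves in the given order."""

    founders: tuple

    def __post_init__(self):
        n = len(self.founders)
        if n < 2 or (n & (n - 1)) != 0:
            raise ValueError(
                f"funnel requires a power-of-two founder count, got {n}; "
                "balanced 2-way/4-way/8-way crossing is undefined otherwise")
        if len(set(self.founders)) != n:
            raise ValueError("founders must be distinct")

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    @property
    def depth(self) -> int:
        return int(np.log2(self.n_founders))


@dataclass
class FounderMosaic:
    """Per-line, per-marker founder of origin.

    ``origin[i, j]`` is the index into ``founders`` of the founder whose
    haplotype line ``i`` carries at marker ``j``.  DH lines are fully
    homozygous, so a single label per marker suffices.
    """

    lines: list
    founders: tuple
    origin: np.ndarray  # (n_lines, n_markers) int
    gmap: GeneticMap

    def __post_init__(self):
        self.origin = np.asarray(self.origin)
        if self.origin.shape != (len(self.lines), self.gmap.n_markers):
            raise ValueError("origin shape does not match lines x markers")
        if self.origin.min() < 0 or self.origin.max() >= len(self.founders):
            raise ValueError("origin entries must index the founder list")

    def founder_names_at(self, marker_idx: int) -> np.ndarray:
        return np.asarray(self.founders)[self.origin[:, marker_idx]]

    def to_frame(self) -> pd.DataFrame:
        names = np.asarray(self.founders)[self.origin]
        return pd.DataFrame(names, index=pd.Index(self.lines, name="line"),
                            columns=self.gmap.marker_ids)


@dataclass
class QTLSpec:
    """Ground-truth QTL: founder effects in trait units plus an optional
    treatment-specific shift applied to carrier lines."""

    trait: str
    chromosome: str
    position_cM: float
    founder_effects: dict
    treatment_interaction: dict = field(default_factory=dict)
    carrier_founders: frozenset | None = None  # default: founders with effect > 0

    def effects_vector(self, founders: Sequence) -> np.ndarray:
        missing = [f for f in founders if f not in self.founder_effects]
        if missing:
            raise ValueError(f"founder_effects missing founders: {missing}")
        v = np.array([float(self.founder_effects[f]) for f in founders])
        if not np.all(np.isfinite(v)):
            raise ValueError("founder effects must be finite")
        return v

    def carriers(self, founders: Sequence) -> np.ndarray:
        if self.carrier_founders is None:
            chosen = {f for f, e in self.founder_effects.items() if e > 0}
        else:
            chosen = set(self.carrier_founders)
        return np.array([f in chosen for f in founders])


@dataclass
class PhenotypeModel:
    """Generative model for one trait.

    value = mean + treatment shift + polygenic(line) + QTL founder effects
            + QTL x treatment shifts for carriers + year + line x treatment
            + residual, with every random term Gaussian.
    """

    trait: str
    mean: float
    polygenic_variance: float
    year_variance: float
    line_treatment_variance: float
    residual_variance: float
    treatment_effects: dict = field(default_factory=dict)
    qtls: list = field(default_factory=list)

    def __post_init__(self):
        for name in ("polygenic_variance", "year_variance",
                     "line_treatment_variance", "residual_variance"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DegradeReport:
    """Markers removed by the MAF / missingness filter, with reasons."""

    removed: pd.DataFrame  # columns: marker_id, reason, maf, missing_frac
    n_kept: int
    n_masked: int


@dataclass
class SimDataset:
    """One simulated study: map, founder alleles, mosaic, genotypes (possibly
    degraded), long phenotype table, and the generative models (ground truth)."""

    gmap: GeneticMap
    scheme: CrossingScheme
    founder_alleles: np.ndarray
    mosaic: FounderMosaic
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    models: dict
    degrade_report: DegradeReport | None = None


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def haldane_r(d_cM) -> np.ndarray:
    """Haldane recombination fraction for a genetic distance in cM."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0))


def _switch_probs(gmap: GeneticMap) -> np.ndarray:
    """Per-marker probability that the transmitted strand switches relative
    to the previous marker; chromosome starts draw a fresh strand (p = 0.5)."""
    p = np.empty(gmap.n_markers)
    for chrom, sl in gmap.chrom_slices.items():
        p[sl.start] = 0.5
        if sl.stop - sl.start > 1:
            d = np.diff(gmap.positions[sl])
            p[sl.start + 1:sl.stop] = haldane_r(d)
    return p


def _gamete_batch(h1: np.ndarray, h2: np.ndarray, gmap: GeneticMap,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample one gamete per row from parent haplotype pairs (n, m)."""
    switches = rng.random(h1.shape) < _switch_probs(gmap)
    # parity of accumulated switches = which strand is transmitted
    state = np.cumsum(switches, axis=1) & 1
    return np.where(state == 0, h1, h2)


def simulate_meiosis(hap1: np.ndarray, hap2: np.ndarray, gmap: GeneticMap,
                     rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parent carrying ``hap1``/``hap2`` over ``gmap``.

    Crossovers are placed without interference: adjacent markers ``d`` cM
    apart recombine with probability ``(1 - exp(-2d/100)) / 2`` and each
    chromosome starts from a uniformly chosen strand.
    """
    hap1 = np.asarray(hap1)
    hap2 = np.asarray(hap2)
    if hap1.shape != (gmap.n_markers,) or hap2.shape != (gmap.n_markers,):
        raise ValueError("haplotypes must be defined on the same map "
                         f"(expected length {gmap.n_markers})")
    return _gamete_batch(hap1[None, :], hap2[None, :], gmap, rng)[0]


# ---------------------------------------------------------------------------
# founders and funnel
# ---------------------------------------------------------------------------

def simulate_founders(gmap: GeneticMap, maf_range: tuple[float, float],
                      n_founders: int, rng: np.random.Generator) -> np.ndarray:
    """Founder allele matrix (founder x marker), coded 1 for the allele that
    is minor *among the founders* and 0 for the major allele.

    Each marker's founder-level minor-allele count is drawn uniformly from
    the integers compatible with ``maf_range``; the carriers are random.
    """
    low, high = maf_range
    if not (0 < low <= high <= 0.5):
        raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
    if n_founders < 2 or (n_founders & (n_founders - 1)) != 0:
        raise ValueError(
            f"n_founders={n_founders} is not a power of 2; the balanced "
            "funnel cross is only defined for 2, 4, 8, ... founders")
    c_lo = int(np.ceil(low * n_founders - 1e-9))
    c_hi = int(np.floor(high * n_founders + 1e-9))
    c_lo = max(c_lo, 1)
    c_hi = min(c_hi, n_founders // 2)
    if c_lo > c_hi:
        raise ValueError(f"maf_range {maf_range} admits no founder minor-allele "
                         f"count with {n_founders} founders")
    m = gmap.n_markers
    counts = rng.integers(c_lo, c_hi + 1, size=m)
    alleles = np.zeros((n_founders, m), dtype=np.int8)
    # rank a uniform draw per founder; the `count` smallest carry the minor allele
    order = rng.random((n_founders, m)).argsort(axis=0)
    alleles[order < counts[None, :]] = 1
    return alleles


def simulate_magic_dh(scheme: CrossingScheme, founder_alleles: np.ndarray,
                      gmap: GeneticMap, n_lines: int,
                      rng: np.random.Generator,
                      line_prefix: str = "L") -> tuple[FounderMosaic, pd.DataFrame]:
    """Simulate ``n_lines`` DH lines through the funnel and emit genotypes.

    Each line descends through fresh gametes at every funnel generation
    (2-way F1s are fixed because founders are inbred); the DH genome is one
    gamete of the eight-way F1, doubled.  Genotypes are coded 0 (minor
    homozygote) / 2 (major homozygote) using founder-level minor alleles.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    nf = scheme.n_founders
    if founder_alleles.shape[0] != nf or founder_alleles.shape[1] != gmap.n_markers:
        raise ValueError("founder allele matrix must be (n_founders, n_markers)")
    m = gmap.n_markers

    def const(i):
        return np.full((n_lines, m), i, dtype=np.int16)

    # haplotype pairs at the current generation, as founder-origin labels
    layer = [(const(i), const(i)) for i in range(nf)]
    while len(layer) > 1:
        nxt = []
        for a, b in zip(layer[::2], layer[1::2]):
            g_a = _gamete_batch(a[0], a[1], gmap, rng)
            g_b = _gamete_batch(b[0], b[1], gmap, rng)
            nxt.append((g_a, g_b))
        layer = nxt
    final = layer[0]
    origin = _gamete_batch(final[0], final[1], gmap, rng)  # DH: double one gamete

    lines = [f"{line_prefix}{i + 1:04d}" for i in range(n_lines)]
    mosaic = FounderMosaic(lines=lines, founders=scheme.founders,
                           origin=origin, gmap=gmap)
    allele = founder_alleles[origin, np.arange(m)[None, :]]
    geno = np.where(allele == 1, MINOR, MAJOR).astype(float)
    genotypes = pd.DataFrame(geno, index=pd.Index(lines, name="line"),
                             columns=gmap.marker_ids)
    return mosaic, genotypes


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def simulate_phenotypes(mosaic: FounderMosaic,
                        models: PhenotypeModel | Sequence[PhenotypeModel],
                        treatments: Sequence[str], years: Sequence,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Long phenotype table (line, trait, treatment, year, value).

    Line-level random effects (polygenic, line x treatment) are drawn once
    per trait and reused across years; year effects are shared across lines.
    QTL positions are snapped to the nearest mapped marker on their
    chromosome.
    """
    if isinstance(models, PhenotypeModel):
        models = [models]
    traits = [mdl.trait for mdl in models]
    if len(set(traits)) != len(traits):
        raise ValueError("duplicate trait models")
    n = len(mosaic.lines)
    founders = mosaic.founders
    frames = []
    for mdl in models:
        for q in mdl.qtls:
            if q.trait != mdl.trait:
                raise ValueError(
                    f"QTL for trait {q.trait!r} attached to model {mdl.trait!r}; "
                    f"requested traits are {traits}")
        poly = rng.normal(0.0, np.sqrt(mdl.polygenic_variance), size=n)
        year_eff = {yr: rng.normal(0.0, np.sqrt(mdl.year_variance)) for yr in years}
        lt_eff = {t: rng.normal(0.0, np.sqrt(mdl.line_treatment_variance), size=n)
                  for t in treatments}
        # planted QTL contributions, per line
        qtl_main = np.zeros(n)
        qtl_inter = {t: np.zeros(n) for t in treatments}
        for q in mdl.qtls:
            j = mosaic.gmap.nearest_marker(q.chromosome, q.position_cM)
            origin_j = mosaic.origin[:, j]
            qtl_main += q.effects_vector(founders)[origin_j]
            carrier = q.carriers(founders)[origin_j].astype(float)
            for t, shift in q.treatment_interaction.items():
                if t in qtl_inter:
                    qtl_inter[t] += shift * carrier
        sd_e = np.sqrt(mdl.residual_variance)
        for t in treatments:
            shift = float(mdl.treatment_effects.get(t, 0.0))
            base = (mdl.mean + shift + poly + qtl_main + qtl_inter[t] + lt_eff[t])
            for yr in years:
                vals = base + year_eff[yr] + rng.normal(0.0, sd_e, size=n)
                frames.append(pd.DataFrame({
                    "line": mosaic.lines, "trait": mdl.trait,
                    "treatment": t, "year": yr, "value": vals}))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# genotype degradation (missingness + MAF / missing-rate filter)
# ---------------------------------------------------------------------------

def degrade_genotypes(genotypes: pd.DataFrame, missing_rate: float,
                      maf_floor: float, rng: np.random.Generator,
                      max_missing: float = 0.10
                      ) -> tuple[pd.DataFrame, DegradeReport]:
    """Mask calls at ``missing_rate`` and drop markers failing the filters.

    A marker is removed when its population minor-allele frequency (over
    non-missing calls) falls below ``maf_floor`` or its missing fraction
    reaches ``max_missing``.
    """
    if not (0 <= missing_rate < 1):
        raise ValueError("missing_rate must be in [0, 1)")
    vals = genotypes.to_numpy(dtype=float, copy=True)
    n_masked = 0
    if missing_rate > 0:
        mask = rng.random(vals.shape) < missing_rate
        vals[mask] = np.nan
        n_masked = int(mask.sum())
    n_obs = np.sum(~np.isnan(vals), axis=0)
    missing_frac = 1.0 - n_obs / vals.shape[0]
    with np.errstate(invalid="ignore"):
        f_minor = np.nansum(vals == MINOR, axis=0) / np.maximum(n_obs, 1)
    maf = np.minimum(f_minor, 1.0 - f_minor)
    maf[n_obs == 0] = 0.0
    bad_maf = maf < maf_floor
    bad_miss = missing_frac >= max_missing
    drop = bad_maf | bad_miss
    reasons = np.where(bad_maf & bad_miss, "maf+missing",
                       np.where(bad_maf, "maf", "missing"))
    removed = pd.DataFrame({
        "marker_id": genotypes.columns[drop],
        "reason": reasons[drop],
        "maf": maf[drop],
        "missing_frac": missing_frac[drop],
    })
    kept = ~drop
    if not kept.any():
        raise ValueError("all markers removed by MAF/missingness filter")
    out = pd.DataFrame(vals[:, kept], index=genotypes.index,
                       columns=genotypes.columns[kept])
    return out, DegradeReport(removed=removed, n_kept=int(kept.sum()),
                              n_masked=n_masked)


# ---------------------------------------------------------------------------
# study-scale default configuration
# ---------------------------------------------------------------------------

#: Founders of the spring barley MAGIC population: seven German landraces and
#: the elite cultivar Barke.
DEFAULT_FOUNDERS = (
    "Ack. Bavaria", "Ack. Danubia", "Criewener", "Heils Franken",
    "Heines Hanna", "Pflugs Intensiv", "Ragusa", "Barke",
)

#: Trait models at the study's scale: per-trait mean, treatment shift for
#: late-terminal drought (TD), variance components, and planted QTL.  Means,
#: dispersions and broad-sense heritabilities echo the published descriptive
#: statistics; variance components were derived once from (SD, H2) with
#: year and line-by-treatment terms each at 5% of the phenotypic variance
#: and H2 = VG / (VG + VE / 2) for two unreplicated years.
def _trait_cfg(mean, td_shift, sd, h2, qtls):
    v = sd ** 2
    vg = 0.9 * v * h2 / (2.0 - h2)
    ve = 2.0 * vg * (1.0 - h2) / h2
    return {"mean": mean, "treatment_effects": {"WW": 0.0, "TD": td_shift},
            "polygenic_variance": round(vg, 3), "year_variance": round(0.05 * v, 3),
            "line_treatment_variance": round(0.05 * v, 3),
            "residual_variance": round(ve, 3), "qtls": qtls}


def _qtl(chrom, pos, effects, interaction=None, carriers=None):
    return {"chromosome": chrom, "position_cM": pos, "founder_effects": effects,
            "treatment_interaction": interaction or {},
            "carrier_founders": carriers}


def default_config() -> dict:
    """Study-scale simulation settings: 534 DH lines, 7 chromosomes at one
    marker per 0.191 cM (~5200 SNPs), 7 traits x 2 treatments x 2 years,
    planted QTL at loci reported for this population."""
    return {
        "n_lines": 534,
        "chrom_lengths": {"1H": 130.0, "2H": 160.0, "3H": 160.0, "4H": 120.0,
                          "5H": 170.0, "6H": 130.0, "7H": 130.0},
        "marker_spacing_cM": 0.191,  # ~1 SNP per 0.191 cM, ~5200 markers
        "founders": list(DEFAULT_FOUNDERS),
        "clone_founder": None,  # e.g. ["Criewener", "Pflugs Intensiv"]
        "maf_range": [0.125, 0.5],
        "missing_rate": 0.02,
        "maf_floor": 0.01,
        "treatments": ["WW", "TD"],
        "years": [2011, 2012],
        "traits": {
            "DHE": _trait_cfg(56.87, -0.07, 5.00, 0.73, [
                _qtl("7H", 32.79, {"Ragusa": 3.0}),
                _qtl("2H", 19.90, {"Barke": -2.0}),
            ]),
            "GFP": _trait_cfg(38.50, -0.74, 3.38, 0.23, [
                _qtl("2H", 19.90, {"Ragusa": 1.5}, {"TD": -1.0}),
            ]),
            "PLH": _trait_cfg(92.16, -12.63, 15.75, 0.54, [
                _qtl("3H", 109.21, {"Heines Hanna": 8.0}),
                _qtl("3H", 51.20, {"Barke": -6.0}, {"TD": -3.0},
                     carriers=["Barke"]),
            ]),
            "AGB": _trait_cfg(12.00, -5.26, 3.00, 0.28, [
                _qtl("4H", 97.17, {"Heils Franken": 1.5}),
                _qtl("7H", 32.79, {"Ragusa": 1.0}, {"TD": 0.8}),
            ]),
            "NE": _trait_cfg(5.31, -1.88, 1.59, 0.33, [
                _qtl("5H", 122.43, {"Ack. Bavaria": 0.8}),
                _qtl("5H", 0.14, {"Ragusa": 0.6}),
            ]),
            "NK": _trait_cfg(21.06, -4.10, 6.40, 0.70, [
                _qtl("2H", 76.66, {"Ragusa": 2.5, "Barke": -0.5}, {"TD": 1.2}),
                _qtl("5H", 0.14, {"Ragusa": 0.65}),
            ]),
            "TKW": _trait_cfg(49.65, -2.84, 6.38, 0.69, [
                _qtl("2H", 19.90, {"Ragusa": 6.23, "Criewener": -0.8,
                                   "Pflugs Intensiv": -0.8}, {"TD": 1.5}),
                _qtl("2H", 76.66, {"Barke": 2.0}),
            ]),
        },
    }


def _build_models(cfg: dict) -> dict:
    founders = list(cfg["founders"])
    models = {}
    for trait, tc in cfg["traits"].items():
        qtls = []
        for q in tc.get("qtls", []):
            effects = {f: 0.0 for f in founders}
            effects.update(q["founder_effects"])
            carriers = q.get("carrier_founders")
            qtls.append(QTLSpec(trait=trait, chromosome=q["chromosome"],
                                position_cM=q["position_cM"],
                                founder_effects=effects,
                                treatment_interaction=dict(q.get("treatment_interaction", {})),
                                carrier_founders=frozenset(carriers) if carriers else None))
        models[trait] = PhenotypeModel(
            trait=trait, mean=tc["mean"],
            polygenic_variance=tc["polygenic_variance"],
            year_variance=tc["year_variance"],
            line_treatment_variance=tc["line_treatment_variance"],
            residual_variance=tc["residual_variance"],
            treatment_effects=dict(tc.get("treatment_effects", {})),
            qtls=qtls)
    return models


def simulate_dataset(config: dict | None = None, seed: int = 0) -> SimDataset:
    """Run the full generator: map -> founders -> funnel DH lines ->
    genotype degradation -> phenotypes, with one sub-stream of the seeded
    generator per stage so stages are individually reproducible."""
    cfg = default_config()
    if config:
        cfg.update(config)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]

    gmap = GeneticMap.uniform(cfg["chrom_lengths"], cfg["marker_spacing_cM"])
    scheme = CrossingScheme(tuple(cfg["founders"]))
    alleles = simulate_founders(gmap, tuple(cfg["maf_range"]),
                                scheme.n_founders, rngs[0])
    clone = cfg.get("clone_founder")
    if clone:
        src, dst = clone
        alleles[cfg["founders"].index(dst)] = alleles[cfg["founders"].index(src)]
    mosaic, genotypes = simulate_magic_dh(scheme, alleles, gmap,
                                          cfg["n_lines"], rngs[1])
    report = None
    if cfg.get("missing_rate", 0) or cfg.get("maf_floor", 0):
        genotypes, report = degrade_genotypes(genotypes, cfg["missing_rate"],
                                              cfg["maf_floor"], rngs[2])
    models = _build_models(cfg)
    phenotypes = simulate_phenotypes(mosaic, list(models.values()),
                                     cfg["treatments"], cfg["years"], rngs[3])
    return SimDataset(gmap=gmap, scheme=scheme, founder_alleles=alleles,
                      mosaic=mosaic, genotypes=genotypes, phenotypes=phenotypes,
                      models=models, degrade_report=report)
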