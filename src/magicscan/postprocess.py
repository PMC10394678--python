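"""From scan hits to QTL records: confidence intervals, colocalization, and
founder allelic effects.

A QTL interval is centred on the most significant marker of a region and
extends 3.5 cM to each side (the population's linkage-disequilibrium-based
choice), clipped to the chromosome's mapped extent.  Regions are formed by
single-linkage clustering of significant first-iteration markers within the
comparison window.  Peaks from different traits or treatment contexts are
declared colocalized when they chain within a 7 cM window (single linkage;
chaining is a documented consequence of pairwise position comparison).

Founder allelic effects at a peak are group-mean deviations: the mean
response of the lines carrying a founder's haplotype minus the population
mean, so the carrier-count-weighted effects sum to zero identically.
Founders sharing a haplotype (indistinguishable) are reported as one merged
class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import FounderMosaic, GeneticMap

__all__ = [
    "QTLRecord",
    "ColocCluster",
    "define_intervals",
    "colocalize",
    "founder_allelic_effects",
    "annotate_against_known_loci",
]

CI_HALF_WIDTH_CM = 3.5
COLOC_WINDOW_CM = 7.0


@dataclass
class QTLRecord:
    trait: str
    context: str  # WW, TD, MxT or ST
    peak_marker: object
    chromosome: object
    position_cM: float
    ci: tuple[float, float]
    P: float
    R2M: float | None = None
    founder_effects: dict = field(default_factory=dict)
    member_markers: list = field(default_factory=list)
    known_loci: list = field(default_factory=list)


@dataclass
class ColocCluster:
    members: list
    chromosome: object
    span: tuple[float, float]
    n_traits: int
    contexts: tuple


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def _clip_ci(pos: float, gmap: GeneticMap | None, chrom,
             half: float = CI_HALF_WIDTH_CM) -> tuple[float, float]:
    lo, hi = pos - half, pos + half
    if gmap is not None and chrom in gmap.chrom_slices:
        cmin, cmax = gmap.chrom_bounds(chrom)
        lo, hi = max(lo, cmin), min(hi, cmax)
    else:
        lo = max(lo, 0.0)
    return lo, hi


def define_intervals(significant: pd.DataFrame, gmap: GeneticMap | None = None,
                     trait: str = "", context: str = "",
                     gap_cM: float = COLOC_WINDOW_CM,
                     half_width_cM: float = CI_HALF_WIDTH_CM) -> list[QTLRecord]:
    """Cluster significant markers of one scan into per-region QTL records.

    ``significant`` needs columns marker_id, chromosome, position_cM, P (and
    optionally R2M).  Markers on one chromosome belong to one region while
    consecutive gaps stay within ``gap_cM``; the region's peak is its most
    significant marker and the confidence interval is peak +/- 3.5 cM
    clipped to the chromosome's mapped bounds.
    """
    records: list[QTLRecord] = []
    for chrom, grp in significant.groupby("chromosome", sort=False):
        grp = grp.sort_values("position_cM").reset_index(drop=True)
        gaps = grp["position_cM"].diff().fillna(0.0)
        region_id = (gaps > gap_cM).cumsum()
        for _, region in grp.groupby(region_id):
            peak = region.loc[region["P"].idxmin()]
            pos = float(peak["position_cM"])
            records.append(QTLRecord(
                trait=trait, context=context, peak_marker=peak["marker_id"],
                chromosome=chrom, position_cM=pos,
                ci=_clip_ci(pos, gmap, chrom, half_width_cM),
                P=float(peak["P"]),
                R2M=float(peak["R2M"]) if "R2M" in region.columns else None,
                member_markers=list(region["marker_id"])))
    return records


# ---------------------------------------------------------------------------
# colocalization
# ---------------------------------------------------------------------------

def colocalize(records: list[QTLRecord],
               window_cM: float = COLOC_WINDOW_CM) -> list[ColocCluster]:
    """Single-linkage clusters of QTL peaks within ``window_cM`` per
    chromosome; order-invariant."""
    clusters: list[ColocCluster] = []
    by_chrom: dict = {}
    for rec in records:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom in by_chrom:
        recs = sorted(by_chrom[chrom], key=lambda r: (r.position_cM, str(r.peak_marker)))
        current = [recs[0]]
        for rec in recs[1:]:
            if rec.position_cM - current[-1].position_cM <= window_cM:
                current.append(rec)
            else:
                clusters.append(_make_cluster(chrom, current))
                current = [rec]
        clusters.append(_make_cluster(chrom, current))
    return clusters


def _make_cluster(chrom, members: list[QTLRecord]) -> ColocCluster:
    pos = [r.position_cM for r in members]
    return ColocCluster(members=list(members), chromosome=chrom,
                        span=(min(pos), max(pos)),
                        n_traits=len({r.trait for r in members}),
                        contexts=tuple(sorted({r.context for r in members})))


# ---------------------------------------------------------------------------
# founder allelic effects
# ---------------------------------------------------------------------------

def _merged_classes(mosaic: FounderMosaic, founder_alleles: np.ndarray | None
                    ) -> list[tuple]:
    """Founder classes, merging founders with identical allele vectors
    (indistinguishable haplotypes) when founder alleles are supplied."""
    founders = list(mosaic.founders)
    if founder_alleles is None:
        return [(f,) for f in founders]
    groups: dict[bytes, list] = {}
    for i, f in enumerate(founders):
        groups.setdefault(founder_alleles[i].tobytes(), []).append(f)
    return [tuple(v) for v in groups.values()]


def founder_allelic_effects(mosaic: FounderMosaic, y, peak_marker,
                            founder_alleles: np.ndarray | None = None,
                            min_carriers: int = 3) -> pd.DataFrame:
    """Founder haplotype effects at a peak marker, as deviations from the
    population mean of the included lines.

    Returns one row per (possibly merged) founder class with the effect, the
    carrier count, the standard error of the group mean, and a
    ``low_confidence`` flag for classes with fewer than ``min_carriers``
    carriers.  The carrier-weighted sum of effects is identically zero.
    """
    y = pd.Series(y).dropna()
    j = mosaic.gmap.index_of(peak_marker)
    origin_names = pd.Series(mosaic.founder_names_at(j), index=mosaic.lines)
    common = y.index.intersection(origin_names.index)
    n_excluded = len(y) - len(common)
    if len(common) == 0:
        raise ValueError("no line has both a response and a founder label at the peak")
    yv = y.loc[common]
    labels = origin_names.loc[common]
    grand = float(yv.mean())
    rows = []
    for cls in _merged_classes(mosaic, founder_alleles):
        sel = labels.isin(cls)
        ncar = int(sel.sum())
        vals = yv[sel]
        effect = float(vals.mean()) - grand if ncar else np.nan
        se = float(vals.std(ddof=1) / np.sqrt(ncar)) if ncar > 1 else np.nan
        rows.append({"founder_class": "/".join(str(c) for c in cls),
                     "effect": effect, "n_carriers": ncar, "se": se,
                     "low_confidence": ncar < min_carriers})
    out = pd.DataFrame(rows)
    out.attrs["peak_marker"] = peak_marker
    out.attrs["population_mean"] = grand
    out.attrs["n_lines_excluded"] = n_excluded
    return out


def founder_effects_regression(mosaic: FounderMosaic, y, peak_marker,
                               founder_alleles: np.ndarray | None = None
                               ) -> pd.DataFrame:
    """Alternative estimator: joint OLS on founder-class indicators (no
    intercept), effects re-centred to carrier-weighted zero.  With a single
    locus and no other covariates this coincides with group-mean deviations;
    provided for extension to adjusted models."""
    base = founder_allelic_effects(mosaic, y, peak_marker, founder_alleles,
                                   min_carriers=0)
    y = pd.Series(y).dropna()
    j = mosaic.gmap.index_of(peak_marker)
    origin_names = pd.Series(mosaic.founder_names_at(j), index=mosaic.lines)
    common = y.index.intersection(origin_names.index)
    labels = origin_names.loc[common]
    classes = base["founder_class"].tolist()
    members = [set(c.split("/")) for c in classes]
    X = np.column_stack([[l in mem for l in labels] for mem in members]).astype(float)
    beta, *_ = np.linalg.lstsq(X, y.loc[common].to_numpy(dtype=float), rcond=None)
    w = X.sum(axis=0)
    beta = beta - np.average(beta, weights=np.maximum(w, 1e-9))
    out = base.copy()
    out["effect"] = np.where(w > 0, beta, np.nan)
    return out


# ---------------------------------------------------------------------------
# known-locus annotation
# ---------------------------------------------------------------------------

def annotate_against_known_loci(records: list[QTLRecord],
                                known: pd.DataFrame,
                                window_cM: float = COLOC_WINDOW_CM
                                ) -> list[QTLRecord]:
    """Attach user-supplied known loci (columns name, chromosome, position_cM)
    lying within ``window_cM`` of each record's peak, nearest first."""
    for rec in records:
        near = known[known["chromosome"] == rec.chromosome].copy()
        near["distance_cM"] = (near["position_cM"] - rec.position_cM).abs()
        near = near[near["distance_cM"] <= window_cM].sort_values(
            ["distance_cM", "name"])
        rec.known_loci = [(row["name"], float(row["distance_cM"]))
                          for _, row in near.iterrows()]
    return records


def records_to_frame(records: list[QTLRecord]) -> pd.DataFrame:
    """Flatten QTL records into the supplementary-table shape."""
    rows = []
    for r in records:
        row = {"trait": r.trait, "context": r.context, "chromosome": r.chromosome,
               "position_cM": r.position_cM, "peak_marker": r.peak_marker,
               "P": r.P, "R2M": r.R2M, "ci_low": r.ci[0], "ci_high": r.ci[1],
               "known_loci": ";".join(f"{n}@{d:.2f}" for n, d in r.known_loci)}
        for cls, eff in r.founder_effects.items():
            row[f"effect[{cls}]"] = eff
        rows.append(row)
    return pd.DataFrame(rows)
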