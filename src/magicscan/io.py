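"""TSV readers/writers, run configuration, and the full pipeline driver.

All artifacts are plain TSV.  Files written here start with ``#``-prefixed
header lines carrying the tool version, the seed and a hash of the
configuration, so every output is traceable and re-runs are reproducible;
readers skip those lines.

Schemas
-------
map         : marker_id, chromosome, position_cM
genotypes   : lines as rows (first column ``line``), markers as columns,
              calls in {0, 2, NA}
mosaic      : same shape as genotypes, values are founder identifiers
phenotypes  : long table line, trait, treatment, year, value
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (FounderMosaic, GeneticMap, SimDataset, simulate_dataset)
from .phenostats import (blup_matrix, lsmeans_and_correlations, sti_response,
                         sti_table, summary_table, blup_line_effects)
from .scan import ScanConfig, forward_multilocus_scan, mxt_scan
from .postprocess import (annotate_against_known_loci, colocalize,
                          define_intervals, founder_allelic_effects,
                          records_to_frame)

__all__ = [
    "RunConfig",
    "read_map", "read_genotypes", "read_phenotypes", "read_mosaic",
    "write_map", "write_genotypes", "write_phenotypes", "write_mosaic",
    "write_tsv", "validate_dataset", "load_run_config",
    "run_full_pipeline", "run_pipeline",
]

log = logging.getLogger("magicscan")

PIPELINE_FILES = [
    "summary_stats.tsv", "blups.tsv", "sti.tsv", "correlations.tsv",
    "scan_WW.tsv", "scan_TD.tsv", "scan_MxT.tsv", "scan_ST.tsv",
    "qtl_records.tsv", "colocalization.tsv",
]


# ---------------------------------------------------------------------------
# generic TSV with provenance header
# ---------------------------------------------------------------------------

def _config_hash(obj) -> str:
    payload = yaml.safe_dump(obj, sort_keys=True, default_flow_style=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]


def write_tsv(frame: pd.DataFrame, path, seed=None, config_hash=None,
              index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# magicscan v{__version__}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        if config_hash is not None:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep="NA")


def _read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=["NA"], **kw)


# ---------------------------------------------------------------------------
# schema readers / writers
# ---------------------------------------------------------------------------

def read_map(path) -> GeneticMap:
    return GeneticMap(_read_tsv(path))


def write_map(gmap: GeneticMap, path, **meta) -> None:
    write_tsv(gmap.frame, path, **meta)


def read_genotypes(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    if frame.columns[0] != "line":
        raise ValueError("genotype file must have 'line' as its first column")
    frame = frame.set_index("line")
    if frame.index.duplicated().any():
        dups = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"duplicate line ids: {dups[:5]}")
    if frame.columns.duplicated().any():
        dups = sorted(set(frame.columns[frame.columns.duplicated()]))
        raise ValueError(f"duplicate marker ids: {dups[:5]}")
    vals = frame.to_numpy(dtype=float)
    bad = ~(np.isnan(vals) | (vals == 0) | (vals == 2))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype call {vals[i, j]!r} at line {frame.index[i]!r}, "
            f"marker {frame.columns[j]!r}; calls must be 0, 2 or NA")
    miss = float(np.isnan(vals).mean())
    log.info("genotypes: %d lines x %d markers, %.2f%% missing",
             frame.shape[0], frame.shape[1], 100 * miss)
    return frame


def write_genotypes(genotypes: pd.DataFrame, path, **meta) -> None:
    out = genotypes.reset_index()
    out.columns = ["line"] + list(genotypes.columns)
    write_tsv(out, path, **meta)


def read_phenotypes(path) -> pd.DataFrame:
    frame = _read_tsv(path)
    required = ["line", "trait", "treatment", "year", "value"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    dup = frame.duplicated(subset=["line", "trait", "treatment", "year"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (line, trait, treatment, "
                         "year) records")
    return frame[required]


def write_phenotypes(phenotypes: pd.DataFrame, path, **meta) -> None:
    write_tsv(phenotypes, path, **meta)


def read_mosaic(path, gmap: GeneticMap) -> FounderMosaic:
    frame = _read_tsv(path)
    if frame.columns[0] != "line":
        raise ValueError("mosaic file must have 'line' as its first column")
    frame = frame.set_index("line")
    missing = [m for m in frame.columns if m not in set(gmap.marker_ids)]
    if missing:
        raise ValueError(f"mosaic markers absent from map: {missing[:5]}")
    frame = frame[list(gmap.marker_ids)]
    founders = tuple(sorted(pd.unique(frame.to_numpy().ravel())))
    lookup = {f: i for i, f in enumerate(founders)}
    origin = np.vectorize(lookup.get)(frame.to_numpy())
    return FounderMosaic(lines=list(frame.index), founders=founders,
                         origin=origin, gmap=gmap)


def write_mosaic(mosaic: FounderMosaic, path, **meta) -> None:
    out = mosaic.to_frame().reset_index()
    write_tsv(out, path, **meta)


def validate_dataset(gmap: GeneticMap, genotypes: pd.DataFrame,
                     phenotypes: pd.DataFrame | None = None,
                     mosaic: FounderMosaic | None = None) -> dict:
    """Cross-check the loaded files; raises on inconsistencies, returns a
    summary of line-set overlaps."""
    mapped = set(gmap.marker_ids)
    offenders = [m for m in genotypes.columns if m not in mapped]
    if offenders:
        raise ValueError(f"{len(offenders)} genotyped markers absent from map, "
                         f"e.g. {offenders[:5]}")
    report = {"n_markers": genotypes.shape[1], "n_lines": genotypes.shape[0]}
    if phenotypes is not None:
        geno_lines = set(genotypes.index)
        pheno_lines = set(phenotypes["line"])
        report["lines_genotyped_and_phenotyped"] = len(geno_lines & pheno_lines)
        report["lines_phenotype_only"] = len(pheno_lines - geno_lines)
        log.info("line overlap: %d shared, %d phenotype-only",
                 report["lines_genotyped_and_phenotyped"],
                 report["lines_phenotype_only"])
    if mosaic is not None and list(mosaic.lines) != list(genotypes.index):
        report["mosaic_lines_match"] = False
    return report


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Paths plus scan settings for a full pipeline run."""

    out_dir: str
    genotype_path: str | None = None
    map_path: str | None = None
    phenotype_path: str | None = None
    mosaic_path: str | None = None
    traits: list | None = None
    treatments: tuple = ("WW", "TD")
    scan: ScanConfig = field(default_factory=ScanConfig)
    seed: int = 0
    log_level: str = "INFO"
    known_loci_path: str | None = None

    def validate(self) -> None:
        for name in ("genotype_path", "map_path", "phenotype_path"):
            p = getattr(self, name)
            if p is None:
                raise ValueError(f"{name} is required")
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    scan_kw = raw.pop("scan", {})
    cfg = RunConfig(scan=ScanConfig(**scan_kw), **raw)
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _scan_seed(base: int, k: int) -> int:
    return int((base * 1000003 + k) % (2 ** 31 - 1))


def run_pipeline(gmap: GeneticMap, genotypes: pd.DataFrame,
                 phenotypes: pd.DataFrame, out_dir,
                 mosaic: FounderMosaic | None = None,
                 scan_config: ScanConfig | None = None,
                 traits: list | None = None,
                 treatments: tuple = ("WW", "TD"),
                 seed: int = 0,
                 known_loci: pd.DataFrame | None = None,
                 founder_alleles: np.ndarray | None = None) -> dict:
    """Run every stage in order — summary statistics, BLUPs, STI, the four
    scans (WW, TD, M x T, ST), intervals, colocalization and founder
    effects — writing one TSV per stage into ``out_dir``.

    Returns a dict with the in-memory results keyed by stage.  Any stage
    failure raises with the stage name; files already written persist.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan_config = scan_config or ScanConfig()
    chash = _config_hash({"scan": vars(scan_config), "seed": seed,
                          "treatments": list(treatments)})
    meta = {"seed": seed, "config_hash": chash}
    traits = traits or sorted(phenotypes["trait"].unique())
    results: dict = {}
    stage = "validate"
    try:
        validate_dataset(gmap, genotypes, phenotypes, mosaic)

        stage = "summary_stats"
        stats = summary_table(phenotypes[phenotypes["trait"].isin(traits)])
        write_tsv(stats, out_dir / "summary_stats.tsv", **meta)
        results["summary_stats"] = stats

        stage = "blups"
        blup_rows = []
        responses: dict = {}
        for trait in traits:
            for trt in treatments:
                years = sorted(phenotypes.loc[
                    (phenotypes["trait"] == trait)
                    & (phenotypes["treatment"] == trt), "year"].unique())
                for yr in years:
                    res = blup_line_effects(phenotypes, trait, trt, yr)
                    blup_rows.append(pd.DataFrame({
                        "line": res.effects.index, "trait": trait,
                        "treatment": trt, "year": yr,
                        "blup": res.effects.to_numpy()}))
                responses[(trait, trt)] = blup_matrix(phenotypes, trait, trt)
        blups = pd.concat(blup_rows, ignore_index=True)
        write_tsv(blups, out_dir / "blups.tsv", **meta)
        results["blups"] = blups

        stage = "sti"
        sti = sti_table(phenotypes[phenotypes["trait"].isin(traits)])
        write_tsv(sti, out_dir / "sti.tsv", **meta)
        results["sti"] = sti

        stage = "correlations"
        corr_frames = []
        for trt in treatments:
            _, r, n = lsmeans_and_correlations(
                phenotypes[phenotypes["trait"].isin(traits)], trt)
            r = r.reset_index(names="trait")
            r.insert(0, "treatment", trt)
            corr_frames.append(r)
        corr = pd.concat(corr_frames, ignore_index=True)
        write_tsv(corr, out_dir / "correlations.tsv", **meta)
        results["correlations"] = corr

        records = []
        scan_results: dict = {}
        for ctx_idx, ctx in enumerate(["WW", "TD", "MxT", "ST"]):
            stage = f"scan_{ctx}"
            tabs = []
            for t_idx, trait in enumerate(traits):
                cfg_t = ScanConfig(**{**vars(scan_config),
                                      "seed": _scan_seed(seed, 100 * ctx_idx + t_idx)})
                if ctx == "MxT":
                    res = mxt_scan(responses[(trait, treatments[0])],
                                   responses[(trait, treatments[1])],
                                   genotypes, cfg_t, gmap)
                    resp = responses[(trait, treatments[0])]
                elif ctx == "ST":
                    try:
                        resp = sti_response(phenotypes, trait)
                    except ValueError:
                        continue
                    res = forward_multilocus_scan(resp, genotypes, cfg_t, gmap)
                else:
                    resp = responses[(trait, ctx)]
                    res = forward_multilocus_scan(resp, genotypes, cfg_t, gmap)
                scan_results[(ctx, trait)] = res
                if res.iterations:
                    full = pd.concat(res.iterations, ignore_index=True)
                    full.insert(0, "trait", trait)
                    full["selected"] = full["marker_id"].isin(res.selected["marker_id"])
                    tabs.append(full)
                log.info("scan %s/%s: %d QTL, total R2=%.3f", ctx, trait,
                         len(res.selected), res.total_r2)
                records.extend(_records_from_scan(res, gmap, trait, ctx,
                                                  resp, mosaic, founder_alleles))
            scan_tab = (pd.concat(tabs, ignore_index=True) if tabs
                        else pd.DataFrame(columns=["trait", "marker_id", "F", "P"]))
            write_tsv(scan_tab, out_dir / f"scan_{ctx}.tsv", **meta)
            results[f"scan_{ctx}"] = scan_results

        stage = "qtl_records"
        if known_loci is not None:
            records = annotate_against_known_loci(records, known_loci)
        rec_frame = records_to_frame(records)
        write_tsv(rec_frame, out_dir / "qtl_records.tsv", **meta)
        results["qtl_records"] = records

        stage = "colocalization"
        clusters = colocalize(records) if records else []
        coloc = pd.DataFrame([{
            "cluster_id": i, "chromosome": c.chromosome,
            "span_low": c.span[0], "span_high": c.span[1],
            "n_traits": c.n_traits,
            "traits": ";".join(sorted({m.trait for m in c.members})),
            "contexts": ";".join(c.contexts),
        } for i, c in enumerate(clusters)])
        write_tsv(coloc, out_dir / "colocalization.tsv", **meta)
        results["colocalization"] = clusters
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def _records_from_scan(res, gmap, trait, ctx, response, mosaic, founder_alleles):
    """QTL records from one scan: intervals from the gated first-iteration
    markers, founder effects at each peak when a mosaic is available."""
    if res.selected.empty or not res.iterations:
        return []
    it1 = res.iterations[0]
    cfg = res.config
    gate = (it1["tested"] & (it1["P"] <= cfg.alpha)
            & (it1["P_adj"] <= cfg.fdr_q))
    if res.perm_threshold is not None:
        gate &= it1["P"] <= res.perm_threshold
    sig = it1[gate].copy()
    # always include the selected peaks themselves
    sel = res.selected
    sig = pd.concat([sig, it1[it1["marker_id"].isin(sel["marker_id"])]],
                    ignore_index=True).drop_duplicates("marker_id")
    r2 = dict(zip(sel["marker_id"], sel["R2M"]))
    sig["R2M"] = sig["marker_id"].map(r2)
    records = define_intervals(sig, gmap, trait=trait, context=ctx)
    if mosaic is not None:
        for rec in records:
            try:
                eff = founder_allelic_effects(mosaic, response, rec.peak_marker,
                                              founder_alleles)
                rec.founder_effects = dict(zip(eff["founder_class"],
                                               eff["effect"]))
            except (KeyError, ValueError):
                pass
    return records


def run_full_pipeline(config: RunConfig) -> dict:
    """File-based entry point: load and cross-check the four input TSVs,
    then run every stage (see :func:`run_pipeline`)."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    config.validate()
    gmap = read_map(config.map_path)
    genotypes = read_genotypes(config.genotype_path)
    phenotypes = read_phenotypes(config.phenotype_path)
    mosaic = read_mosaic(config.mosaic_path, gmap) if config.mosaic_path else None
    known = (_read_tsv(config.known_loci_path)
             if config.known_loci_path else None)
    return run_pipeline(gmap, genotypes, phenotypes, config.out_dir,
                        mosaic=mosaic, scan_config=config.scan,
                        traits=config.traits, treatments=tuple(config.treatments),
                        seed=config.seed, known_loci=known)


def write_simulated_dataset(ds: SimDataset, out_dir, seed: int = 0) -> dict:
    """Write a simulated dataset's four input files (map, genotypes, mosaic,
    phenotypes) into ``out_dir``."""
    out_dir = Path(out_dir)
    meta = {"seed": seed}
    write_map(ds.gmap, out_dir / "map.tsv", **meta)
    write_genotypes(ds.genotypes, out_dir / "genotypes.tsv", **meta)
    write_mosaic(ds.mosaic, out_dir / "mosaic.tsv", **meta)
    write_phenotypes(ds.phenotypes, out_dir / "phenotypes.tsv", **meta)
    return {k: str(out_dir / f"{k}.tsv")
            for k in ["map", "genotypes", "mosaic", "phenotypes"]}
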