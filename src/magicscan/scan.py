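"""Multilocus forward-selection QTL scan with permutation and FDR control.

Single-marker model:  value = mu + marker (+ previously selected markers as
cofactors), tested by a sequential (Type-I) F-test of the marker entered
last.  The multilocus procedure iterates: test every unselected marker with
the current cofactor set, and admit the most informative one (smallest P)
provided it passes all three gates — nominal P <= alpha, Benjamini-Hochberg
FDR-adjusted P <= q, and the genome-wide permutation threshold — until no
marker qualifies.

The permutation threshold is experiment-wise: the response is shuffled
across lines, the genome-wide minimum P recorded per permutation, and the
alpha-quantile of that null distribution used as the cut.  By default the
null is computed once at the first iteration (cofactor-free) and reused, a
documented runtime choice; set ``perm_each_iteration`` to recompute.

The marker-by-treatment scan stacks the two treatments' responses and tests
the marker x treatment interaction entered after the marker main effect in

    value = mu + M + T + M x T + error.

Explained variance follows sequential sums of squares in selection order:
R2_M = SQ_M / SQ_g with SQ_g the total (line) sum of squares of the
response.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import GeneticMap

__all__ = [
    "ScanConfig",
    "MarkerTest",
    "ScanResult",
    "fdr_adjust",
    "single_marker_test",
    "permutation_threshold",
    "forward_multilocus_scan",
    "cross_validate_qtl",
    "mxt_scan",
    "variance_explained",
]

_EPS = 1e-10


@dataclass
class ScanConfig:
    """Thresholds and sampling settings for the multilocus scan.

    Defaults follow the study protocol: nominal P <= 0.001, 1000
    permutations, FDR <= 0.05, 20 rounds of leave-20%-out cross-validation.
    """

    alpha: float = 0.001
    n_perm: int = 1000
    fdr_q: float = 0.05
    cv_rounds: int = 20
    cv_holdout: float = 0.20
    max_iterations: int = 30
    seed: int = 0
    perm_each_iteration: bool = False
    cv_retention_alpha: float | None = None  # default: alpha

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 <= self.cv_holdout < 1):
            raise ValueError("cv_holdout must be in [0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @property
    def retention_alpha(self) -> float:
        return self.alpha if self.cv_retention_alpha is None else self.cv_retention_alpha


@dataclass
class MarkerTest:
    marker_id: object
    F: float
    P: float
    P_adj: float | None = None
    R2M: float | None = None
    skipped: str | None = None  # reason when the test could not be run


@dataclass
class ScanResult:
    """Outcome of a forward scan: the ordered selected markers with their
    statistics, the full per-iteration test tables (audit trail), the
    permutation threshold(s) used, and the total explained variance."""

    selected: pd.DataFrame
    iterations: list
    perm_threshold: float | None
    perm_min_p: np.ndarray | None
    total_r2: float
    config: ScanConfig


# ---------------------------------------------------------------------------
# linear-algebra core
# ---------------------------------------------------------------------------

def _impute_mean(G: np.ndarray) -> np.ndarray:
    """Column-mean imputation of missing genotype calls."""
    G = np.array(G, dtype=float, copy=True)
    if np.isnan(G).any():
        mu = np.nanmean(G, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(G))
        G[idx] = mu[idx[1]]
    return G


def _basis(n: int, cols: np.ndarray | None = None) -> np.ndarray:
    """Orthonormal basis of the column space of [1 | cols]."""
    X = np.ones((n, 1))
    if cols is not None and cols.size:
        X = np.hstack([X, cols])
    Q, R = np.linalg.qr(X)
    keep = np.abs(np.diag(R)) > _EPS * max(1.0, np.abs(R[0, 0]))
    return Q[:, keep]


def _residualize(M: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return M - Q @ (Q.T @ M)


def _seq_f(y_t: np.ndarray, G_t: np.ndarray, df: int):
    """Sequential F and P for each column of residualized ``G_t`` added last
    to a model whose fitted space was already projected out of both inputs.

    Returns (F, P, tested) where ``tested`` is False for columns that are
    (numerically) constant or collinear with the cofactors.
    """
    ss_y = float(y_t @ y_t)
    g2 = np.einsum("ij,ij->j", G_t, G_t)
    scale = max(np.max(g2), 1.0)
    tested = g2 > _EPS * scale
    proj = y_t @ G_t
    ss_m = np.zeros_like(g2)
    np.divide(proj ** 2, g2, out=ss_m, where=tested)
    rss = np.maximum(ss_y - ss_m, 0.0)
    F = np.full_like(g2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        F[tested] = ss_m[tested] / np.maximum(rss[tested] / df, _EPS * max(ss_y, 1.0) / df)
    P = np.full_like(g2, np.nan)
    P[tested] = stats.f.sf(F[tested], 1, df)
    return F, P, tested


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (order preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# single-marker test
# ---------------------------------------------------------------------------

def _align(y, G: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    y = pd.Series(y).dropna()
    common = y.index.intersection(G.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 lines shared between response and genotypes")
    return (y.loc[common].to_numpy(dtype=float),
            _impute_mean(G.loc[common].to_numpy(dtype=float)), common)


def single_marker_test(y, g, cofactors: np.ndarray | None = None,
                       marker_id="marker") -> MarkerTest:
    """F-test of one marker entered after the cofactors (Type-I order)."""
    y = np.asarray(y, dtype=float)
    g = _impute_mean(np.asarray(g, dtype=float).reshape(-1, 1))
    cof = None
    if cofactors is not None:
        cof = _impute_mean(np.asarray(cofactors, dtype=float))
        if cof.ndim == 1:
            cof = cof.reshape(-1, 1)
    Q = _basis(len(y), cof)
    df = len(y) - Q.shape[1] - 1
    if df < 1:
        return MarkerTest(marker_id, np.nan, np.nan, skipped="insufficient df")
    F, P, tested = _seq_f(_residualize(y, Q), _residualize(g, Q), df)
    if not tested[0]:
        return MarkerTest(marker_id, np.nan, np.nan,
                          skipped="constant or collinear with cofactors")
    return MarkerTest(marker_id, float(F[0]), float(P[0]))


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def permutation_threshold(y, G, cofactors: np.ndarray | None, config: ScanConfig,
                          rng: np.random.Generator | None = None
                          ) -> tuple[float, np.ndarray]:
    """Experiment-wise threshold from the min-P null distribution.

    The response is permuted across lines ``n_perm`` times (cofactors kept
    attached to the genotypes); each permutation's genome-wide minimum P is
    recorded and the empirical ``alpha``-quantile returned.
    """
    if isinstance(G, pd.DataFrame):
        yv, Gv, _ = _align(y, G)
    else:
        yv = np.asarray(y, dtype=float)
        Gv = _impute_mean(np.asarray(G, dtype=float))
    n = len(yv)
    if n < 4:
        raise ValueError("too few lines to permute distinctly")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cof = None
    if cofactors is not None and np.size(cofactors):
        cof = _impute_mean(np.asarray(cofactors, dtype=float))
        if cof.ndim == 1:
            cof = cof.reshape(-1, 1)
    Q = _basis(n, cof)
    df = n - Q.shape[1] - 1
    G_t = _residualize(Gv, Q)
    g2 = np.einsum("ij,ij->j", G_t, G_t)
    tested = g2 > _EPS * max(float(np.max(g2)), 1.0)
    if not tested.any():
        raise ValueError("no testable markers")
    G_t = G_t[:, tested]
    g2 = g2[tested]
    perms = np.stack([rng.permutation(n) for _ in range(config.n_perm)])
    Yp = yv[perms]                               # (n_perm, n)
    Yp_t = Yp - (Yp @ Q) @ Q.T
    ss_y = np.einsum("ij,ij->i", Yp_t, Yp_t)
    proj = Yp_t @ G_t                            # (n_perm, m)
    ss_m = proj ** 2 / g2
    with np.errstate(divide="ignore", invalid="ignore"):
        Fmat = ss_m / np.maximum((ss_y[:, None] - ss_m) / df, _EPS)
    max_f = Fmat.max(axis=1)
    min_p = stats.f.sf(max_f, 1, df)
    return float(np.quantile(min_p, config.alpha)), min_p


# ---------------------------------------------------------------------------
# forward multilocus scan
# ---------------------------------------------------------------------------

def _marker_meta(marker_ids, gmap: GeneticMap | None):
    if gmap is None:
        chrom = np.array([""] * len(marker_ids), dtype=object)
        pos = np.arange(len(marker_ids), dtype=float)
        order = np.arange(len(marker_ids))
    else:
        idx = np.array([gmap.index_of(m) for m in marker_ids])
        chrom = gmap.chromosomes[idx]
        pos = gmap.positions[idx]
        order = idx
    return chrom, pos, order


def _pick_best(cand: np.ndarray, P, F, order, pos, marker_ids) -> int:
    """Most informative candidate: smallest P, then largest F, then lowest
    (chromosome, cM) by map order, then marker id."""
    idx = np.flatnonzero(cand)
    keys = sorted(idx, key=lambda j: (P[j], -F[j], order[j], pos[j], str(marker_ids[j])))
    return int(keys[0])


def forward_multilocus_scan(y, G: pd.DataFrame, config: ScanConfig | None = None,
                            gmap: GeneticMap | None = None) -> ScanResult:
    """Iterative forward selection over all markers with permutation + FDR
    gates; returns the selected markers in order with a full audit trail."""
    config = config or ScanConfig()
    yv, Gv, lines = _align(y, G)
    marker_ids = np.asarray(G.columns)
    chrom, pos, order = _marker_meta(marker_ids, gmap)
    n, m = Gv.shape
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    selected_idx: list[int] = []
    iterations: list[pd.DataFrame] = []
    thr: float | None = None
    min_p_null: np.ndarray | None = None

    if float(np.var(yv)) <= _EPS:
        empty = _selected_frame([], [], [], [], chrom, pos, marker_ids)
        return ScanResult(selected=empty, iterations=[], perm_threshold=None,
                          perm_min_p=None, total_r2=0.0, config=config)

    sel_F: list[float] = []
    sel_P: list[float] = []
    sel_Padj: list[float] = []
    for it in range(1, config.max_iterations + 1):
        cof = Gv[:, selected_idx] if selected_idx else None
        if thr is None or config.perm_each_iteration:
            thr, min_p_null = permutation_threshold(yv, Gv, cof, config, rng)
        Q = _basis(n, cof)
        df = n - Q.shape[1] - 1
        if df < 1:
            break
        remaining = np.setdiff1d(np.arange(m), selected_idx)
        F, P, tested = _seq_f(_residualize(yv, Q), _residualize(Gv[:, remaining], Q), df)
        P_adj = np.full_like(P, np.nan)
        P_adj[tested] = fdr_adjust(P[tested])
        tab = pd.DataFrame({
            "marker_id": marker_ids[remaining], "chromosome": chrom[remaining],
            "position_cM": pos[remaining], "iteration": it, "F": F, "P": P,
            "P_adj": P_adj, "tested": tested,
        })
        iterations.append(tab)
        cand = tested & (P <= config.alpha) & (P_adj <= config.fdr_q) & (P <= thr)
        if not cand.any():
            break
        j_local = _pick_best(cand, P, F, order[remaining], pos[remaining],
                             marker_ids[remaining])
        j = int(remaining[j_local])
        selected_idx.append(j)
        sel_F.append(float(F[j_local]))
        sel_P.append(float(P[j_local]))
        sel_Padj.append(float(P_adj[j_local]))

    selected = _selected_frame(selected_idx, sel_F, sel_P, sel_Padj,
                               chrom, pos, marker_ids)
    total_r2 = 0.0
    if selected_idx:
        r2, total_r2 = _variance_explained_arrays(yv, Gv[:, selected_idx])
        selected["R2M"] = r2
        cv = _cross_validate_arrays(yv, Gv[:, selected_idx], config, rng)
        selected["cv_mean_P"] = cv["cv_mean_P"].to_numpy()
        selected["cv_retained"] = cv["cv_retained"].to_numpy()
    return ScanResult(selected=selected, iterations=iterations,
                      perm_threshold=thr, perm_min_p=min_p_null,
                      total_r2=total_r2, config=config)


def _selected_frame(idx, F, P, P_adj, chrom, pos, marker_ids) -> pd.DataFrame:
    idx = list(idx)
    return pd.DataFrame({
        "marker_id": marker_ids[idx] if idx else np.array([], dtype=object),
        "chromosome": chrom[idx] if idx else np.array([], dtype=object),
        "position_cM": pos[idx] if idx else np.array([], dtype=float),
        "iteration": np.arange(1, len(idx) + 1),
        "F": np.asarray(F, dtype=float), "P": np.asarray(P, dtype=float),
        "P_adj": np.asarray(P_adj, dtype=float),
        "R2M": np.full(len(idx), np.nan),
        "cv_mean_P": np.full(len(idx), np.nan),
        "cv_retained": np.zeros(len(idx), dtype=bool),
    })


# ---------------------------------------------------------------------------
# explained variance and cross-validation
# ---------------------------------------------------------------------------

def _variance_explained_arrays(yv: np.ndarray, S: np.ndarray):
    yc = yv - yv.mean()
    sq_g = float(yc @ yc)
    if sq_g <= _EPS:
        raise ValueError("total line sum of squares is zero")
    n = len(yv)
    r2 = []
    for k in range(S.shape[1]):
        Q = _basis(n, S[:, :k])  # intercept + markers selected before this one
        g_t = _residualize(S[:, [k]], Q)
        y_t = _residualize(yv, Q)
        g2 = float(g_t[:, 0] @ g_t[:, 0])
        ss = 0.0 if g2 <= _EPS else float((y_t @ g_t[:, 0]) ** 2 / g2)
        r2.append(ss / sq_g)
    return np.array(r2), float(np.sum(r2))


def variance_explained(y, selected_markers: Sequence, G: pd.DataFrame
                       ) -> tuple[pd.Series, float]:
    """Per-marker R2_M = SQ_M / SQ_g (sequential, in selection order) and the
    total explained variance."""
    yv, Gv, _ = _align(y, G)
    cols = [G.columns.get_loc(mk) for mk in selected_markers]
    r2, total = _variance_explained_arrays(yv, Gv[:, cols])
    return pd.Series(r2, index=list(selected_markers), name="R2M"), total


def _cross_validate_arrays(yv: np.ndarray, S: np.ndarray, config: ScanConfig,
                           rng: np.random.Generator) -> pd.DataFrame:
    n, k = S.shape
    keep = max(int(round(n * (1 - config.cv_holdout))), k + 2)
    sums = np.zeros(k)
    counts = np.zeros(k)
    for _ in range(max(config.cv_rounds, 1)):
        sub = rng.choice(n, size=min(keep, n), replace=False)
        y_f, S_f = yv[sub], S[sub]
        Q = _basis(len(sub))
        for j in range(k):
            df = len(sub) - Q.shape[1] - 1
            if df < 1:
                break
            F, P, tested = _seq_f(_residualize(y_f, Q), _residualize(S_f[:, [j]], Q), df)
            if tested[0]:
                sums[j] += P[0]
                counts[j] += 1
            Q = _basis(len(sub), S_f[:, :j + 1])
    mean_p = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame({"cv_mean_P": mean_p,
                         "cv_retained": mean_p <= config.retention_alpha,
                         "cv_folds": counts.astype(int)})


def cross_validate_qtl(y, G: pd.DataFrame, selected_markers: Sequence,
                       config: ScanConfig | None = None,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Leave-``cv_holdout``-out validation of an already selected marker set.

    Each round refits the multilocus model on a random subset and records
    every selected marker's sequential P (selection order fixed from the
    full-data scan); markers are retained when the mean P stays at or below
    the retention level.
    """
    if not len(selected_markers):
        raise ValueError("selected marker set is empty")
    config = config or ScanConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    yv, Gv, _ = _align(y, G)
    cols = [G.columns.get_loc(mk) for mk in selected_markers]
    out = _cross_validate_arrays(yv, Gv[:, cols], config, rng)
    out.insert(0, "marker_id", list(selected_markers))
    return out


# ---------------------------------------------------------------------------
# marker x treatment interaction scan
# ---------------------------------------------------------------------------

def _mxt_f(ys_t, G_t, H_t, df):
    """Interaction F for each marker: sequential SS of g*T entered after g,
    all inputs already residualized against the shared design."""
    g2 = np.einsum("ij,ij->j", G_t, G_t)
    scale = max(float(np.max(g2)), 1.0)
    tested = g2 > _EPS * scale
    gy = ys_t @ G_t
    gh = np.einsum("ij,ij->j", G_t, H_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        H_perp = H_t - G_t * np.where(tested, gh / np.where(tested, g2, 1.0), 0.0)
    h2 = np.einsum("ij,ij->j", H_perp, H_perp)
    tested &= h2 > _EPS * max(float(np.max(h2, initial=1.0)), 1.0)
    hy = ys_t @ H_perp
    ss_y = float(ys_t @ ys_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_main = np.where(tested, gy ** 2 / np.where(g2 > 0, g2, 1.0), 0.0)
        ss_int = np.where(tested, hy ** 2 / np.where(h2 > 0, h2, 1.0), 0.0)
    rss = np.maximum(ss_y - ss_main - ss_int, 0.0)
    F = np.full_like(g2, np.nan)
    P = np.full_like(g2, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        F[tested] = ss_int[tested] / np.maximum(rss[tested] / df, _EPS)
    P[tested] = stats.f.sf(F[tested], 1, df)
    return F, P, tested, H_perp


def mxt_scan(y_ww, y_td, G: pd.DataFrame, config: ScanConfig | None = None,
             gmap: GeneticMap | None = None) -> ScanResult:
    """Forward scan of the marker x treatment interaction term.

    Responses from the two treatments are stacked with a treatment
    indicator; per marker the model mu + M + T + M x T is fitted and the
    interaction F (entered last) reported.  Selected markers contribute both
    their main and interaction columns as cofactors in later iterations.
    The permutation null shuffles line labels, keeping each line's WW/TD
    response pair together so the treatment main effect is preserved.
    """
    config = config or ScanConfig()
    y_ww = pd.Series(y_ww).dropna()
    y_td = pd.Series(y_td).dropna()
    if y_ww.empty or y_td.empty:
        raise ValueError("a treatment stratum is empty")
    common = y_ww.index.intersection(y_td.index).intersection(G.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 lines shared across treatments and genotypes")
    Gv = _impute_mean(G.loc[common].to_numpy(dtype=float))
    n, m = Gv.shape
    marker_ids = np.asarray(G.columns)
    chrom, pos, order = _marker_meta(marker_ids, gmap)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    yw = y_ww.loc[common].to_numpy(dtype=float)
    yt = y_td.loc[common].to_numpy(dtype=float)
    ys = np.concatenate([yw, yt])
    T = np.concatenate([np.zeros(n), np.ones(n)])
    Gs = np.vstack([Gv, Gv])
    GT = Gs * T[:, None]
    N = 2 * n

    selected_idx: list[int] = []
    sel_F: list[float] = []
    sel_P: list[float] = []
    sel_Padj: list[float] = []
    iterations: list[pd.DataFrame] = []
    thr: float | None = None
    min_p_null: np.ndarray | None = None

    for it in range(1, config.max_iterations + 1):
        cof_cols = [np.ones((N, 1)), T[:, None]]
        for j in selected_idx:
            cof_cols += [Gs[:, [j]], GT[:, [j]]]
        Q = _basis(N, np.hstack(cof_cols[1:]))
        df = N - Q.shape[1] - 2  # marker main + interaction enter the model
        if df < 1:
            break
        remaining = np.setdiff1d(np.arange(m), selected_idx)
        ys_t = _residualize(ys, Q)
        G_t = _residualize(Gs[:, remaining], Q)
        H_t = _residualize(GT[:, remaining], Q)
        F, P, tested, H_perp = _mxt_f(ys_t, G_t, H_t, df)
        if thr is None or config.perm_each_iteration:
            thr, min_p_null = _mxt_perm_threshold(yw, yt, Q, G_t, H_perp, tested,
                                                  df, config, rng)
        P_adj = np.full_like(P, np.nan)
        P_adj[tested] = fdr_adjust(P[tested])
        iterations.append(pd.DataFrame({
            "marker_id": marker_ids[remaining], "chromosome": chrom[remaining],
            "position_cM": pos[remaining], "iteration": it, "F": F, "P": P,
            "P_adj": P_adj, "tested": tested}))
        cand = tested & (P <= config.alpha) & (P_adj <= config.fdr_q) & (P <= thr)
        if not cand.any():
            break
        j_local = _pick_best(cand, P, F, order[remaining], pos[remaining],
                             marker_ids[remaining])
        selected_idx.append(int(remaining[j_local]))
        sel_F.append(float(F[j_local]))
        sel_P.append(float(P[j_local]))
        sel_Padj.append(float(P_adj[j_local]))

    selected = _selected_frame(selected_idx, sel_F, sel_P, sel_Padj,
                               chrom, pos, marker_ids)
    # R2M for the interaction scan: sequential interaction SS over the total
    # stacked response SS, in selection order.
    total_r2 = 0.0
    if selected_idx:
        yc = ys - ys.mean()
        sq_g = float(yc @ yc)
        r2 = []
        cof_cols = [T[:, None]]
        for j in selected_idx:
            Q = _basis(N, np.hstack(cof_cols + [Gs[:, [j]]]))
            ss_int = float((_residualize(ys, Q) @ _residualize(GT[:, [j]], Q)[:, 0]) ** 2
                           / max(float(np.sum(_residualize(GT[:, [j]], Q) ** 2)), _EPS))
            r2.append(ss_int / sq_g)
            cof_cols += [Gs[:, [j]], GT[:, [j]]]
        selected["R2M"] = r2
        total_r2 = float(np.sum(r2))
    return ScanResult(selected=selected, iterations=iterations,
                      perm_threshold=thr, perm_min_p=min_p_null,
                      total_r2=total_r2, config=config)


def _mxt_perm_threshold(yw, yt, Q, G_t, H_perp, tested, df, config, rng):
    """Min-P null for the interaction scan: permute line labels jointly for
    the WW/TD response pair."""
    n = len(yw)
    perms = np.stack([rng.permutation(n) for _ in range(config.n_perm)])
    Yp = np.concatenate([yw[perms], yt[perms]], axis=1)      # (n_perm, 2n)
    Yp_t = Yp - (Yp @ Q) @ Q.T
    G_use, H_use = G_t[:, tested], H_perp[:, tested]
    g2 = np.einsum("ij,ij->j", G_use, G_use)
    h2 = np.einsum("ij,ij->j", H_use, H_use)
    ss_y = np.einsum("ij,ij->i", Yp_t, Yp_t)
    pm = Yp_t @ G_use
    pi = Yp_t @ H_use
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_main = pm ** 2 / g2
        ss_int = pi ** 2 / h2
        Fmat = ss_int / np.maximum((ss_y[:, None] - ss_main - ss_int) / df, _EPS)
    min_p = stats.f.sf(Fmat.max(axis=1), 1, df)
    return float(np.quantile(min_p, config.alpha)), min_p
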