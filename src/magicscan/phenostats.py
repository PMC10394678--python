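"""Phenotype statistics for unreplicated multi-year trials.

Descriptive statistics, variance components and broad-sense heritability per
treatment, per-treatment-year line BLUPs, trait LSmeans and Pearson
correlations, and the stress-tolerance index

    STI = (yp * ys) / ybar_p^2

with ``yp`` the line's value under the well-watered control, ``ys`` its
value under stress, and ``ybar_p`` the control population mean.

Variance components come from the model

    value = mu + line + year + line:year + error        (random line, year)

For balanced data the ANOVA (expected-mean-squares) estimators are used;
they coincide with REML whenever the estimates are interior, and negative
solutions are truncated at zero.  Unbalanced layouts fall back to an
EM-REML iteration on the mixed-model equations.  With one observation per
line-year cell — the situation in an unreplicated trial — the line:year and
error variances are confounded; the fit then reports their sum as VE with
VGY = 0 and a ``confounded`` flag, which is exactly what the heritability
denominator VG + VGY/y + VE/y needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptiveStats",
    "VarianceComponents",
    "BlupResult",
    "descriptive_stats",
    "fit_variance_components",
    "heritability",
    "blup_line_effects",
    "stress_tolerance_index",
    "sti_table",
    "lsmeans_and_correlations",
    "treatment_effect_test",
    "summary_table",
]


# ---------------------------------------------------------------------------
# descriptive statistics
# ---------------------------------------------------------------------------

@dataclass
class DescriptiveStats:
    n: int
    mean: float
    min: float
    max: float
    se: float
    sd: float
    cv: float | None  # percent; None when the mean is zero


def descriptive_stats(values) -> DescriptiveStats:
    """Mean, range, SE, sample SD and CV (percent) over non-missing values."""
    v = pd.Series(values, dtype=float).dropna().to_numpy()
    if v.size < 2:
        raise ValueError("need at least two non-missing values")
    sd = float(np.std(v, ddof=1))
    mean = float(np.mean(v))
    cv = 100.0 * sd / mean if mean != 0 else None
    return DescriptiveStats(n=v.size, mean=mean, min=float(v.min()),
                            max=float(v.max()), se=sd / math.sqrt(v.size),
                            sd=sd, cv=cv)


# ---------------------------------------------------------------------------
# variance components and heritability
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    VG: float
    VGY: float
    VE: float
    y: int
    converged: bool = True
    confounded: bool = False  # True when line:year and error cannot be separated
    method: str = "anova-ems"
    n_iter: int = 0


def _stratum(table: pd.DataFrame, trait: str, treatment: str) -> pd.DataFrame:
    sub = table[(table["trait"] == trait) & (table["treatment"] == treatment)]
    sub = sub.dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no records for trait={trait!r} treatment={treatment!r}")
    return sub


def _em_reml(y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray],
             max_iter: int = 2000, tol: float = 1e-6):
    """EM-REML for y = X b + sum_k Z_k u_k + e with u_k ~ N(0, s2_k I).

    Returns (s2 list, s2e, n_iter, converged).  Classical Henderson updates on
    the mixed-model equations; suitable for the moderate problem sizes here.
    """
    n, p = X.shape
    qs = [Z.shape[1] for Z in Zs]
    W = np.hstack([X] + Zs)
    WtW = W.T @ W
    Wty = W.T @ y
    var_y = float(np.var(y, ddof=1)) or 1.0
    s2 = [var_y / (len(Zs) + 1)] * len(Zs)
    s2e = var_y / (len(Zs) + 1)
    it = 0
    converged = False
    for it in range(1, max_iter + 1):
        M = WtW.copy().astype(float)
        off = p
        for k, q in enumerate(qs):
            lam = s2e / max(s2[k], 1e-12)
            M[off:off + q, off:off + q] += lam * np.eye(q)
            off += q
        C = np.linalg.pinv(M)
        sol = C @ Wty
        b, us = sol[:p], []
        off = p
        for q in qs:
            us.append(sol[off:off + q])
            off += q
        new_s2 = []
        off = p
        for k, q in enumerate(qs):
            Ckk = C[off:off + q, off:off + q]
            new_s2.append(float((us[k] @ us[k] + s2e * np.trace(Ckk)) / q))
            off += q
        resid = y - W @ sol
        new_s2e = float((y @ resid) / (n - np.linalg.matrix_rank(X)))
        new_s2e = max(new_s2e, 1e-12)
        # components hitting the boundary converge only sublinearly; pin them
        new_s2 = [0.0 if v < 1e-8 * var_y else v for v in new_s2]
        delta = abs(new_s2e - s2e) + sum(abs(a - b_) for a, b_ in zip(new_s2, s2))
        s2, s2e = new_s2, new_s2e
        if delta < tol * var_y:
            converged = True
            break
    return s2, s2e, it, converged


def fit_variance_components(table: pd.DataFrame, trait: str,
                            treatment: str) -> VarianceComponents:
    """REML/ANOVA variance components for one treatment's records.

    Requires at least two years and two lines.  Balanced layouts use the
    closed-form expected-mean-squares solution (equal to REML when interior);
    unbalanced layouts use EM-REML.
    """
    sub = _stratum(table, trait, treatment)
    lines = sub["line"].unique()
    years = sub["year"].unique()
    n_l, n_y = len(lines), len(years)
    if n_y < 2:
        raise ValueError("need >= 2 years: genotype-by-year and error variance "
                         "are unidentifiable from a single year")
    if n_l < 2:
        raise ValueError("need >= 2 lines")
    counts = sub.groupby(["line", "year"], observed=True)["value"].count()
    r = int(counts.max())
    balanced = (len(counts) == n_l * n_y) and counts.nunique() == 1
    confounded = r == 1

    if balanced:
        cell = sub.groupby(["line", "year"], observed=True)["value"].mean().unstack()
        grand = float(sub["value"].mean())
        line_means = cell.mean(axis=1)
        year_means = cell.mean(axis=0)
        ss_l = r * n_y * float(((line_means - grand) ** 2).sum())
        ss_ly = r * float(((cell.sub(line_means, axis=0).sub(year_means, axis=1)
                            + grand) ** 2).to_numpy().sum())
        ms_l = ss_l / (n_l - 1)
        ms_ly = ss_ly / ((n_l - 1) * (n_y - 1))
        if r > 1:
            cell_long = sub.set_index(["line", "year"])["value"]
            ss_e = float(((cell_long - cell.stack().reindex(cell_long.index)) ** 2).sum())
            ms_e = ss_e / (n_l * n_y * (r - 1))
            ve = ms_e
            vgy = max((ms_ly - ms_e) / r, 0.0)
        else:
            ve = ms_ly  # line:year + error, inseparable at r = 1
            vgy = 0.0
        vg = max((ms_l - ms_ly) / (r * n_y), 0.0)
        return VarianceComponents(VG=vg, VGY=vgy, VE=max(ve, 0.0), y=n_y,
                                  confounded=confounded, method="anova-ems")

    # unbalanced: EM-REML on mixed-model equations
    yv = sub["value"].to_numpy(dtype=float)
    X = np.ones((len(yv), 1))
    Zl = pd.get_dummies(sub["line"]).to_numpy(dtype=float)
    Zy = pd.get_dummies(sub["year"]).to_numpy(dtype=float)
    Zs = [Zl, Zy]
    if not confounded:
        Zly = pd.get_dummies(sub["line"].astype(str) + "/" +
                             sub["year"].astype(str)).to_numpy(dtype=float)
        Zs.append(Zly)
    s2, s2e, it, ok = _em_reml(yv, X, Zs)
    if not ok:
        raise RuntimeError(f"EM-REML did not converge in {it} iterations "
                           f"(last estimates {s2 + [s2e]})")
    vgy = 0.0 if confounded else max(s2[2], 0.0)
    return VarianceComponents(VG=max(s2[0], 0.0), VGY=vgy, VE=max(s2e, 0.0),
                              y=n_y, confounded=confounded, method="em-reml",
                              n_iter=it)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability H2 = VG / (VG + VGY/y + VE/y).

    Returns NaN (undefined) when every component is zero.
    """
    denom = vc.VG + vc.VGY / vc.y + vc.VE / vc.y
    if denom == 0:
        return float("nan")
    return vc.VG / denom


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------

@dataclass
class BlupResult:
    """Predicted line effects (deviations from the stratum mean) for one
    treatment-year stratum, with the variance components behind the
    shrinkage.  ``identified`` is False when every line has a single record,
    in which case only sigma2_g + sigma2_e is estimable and the boundary
    convention sigma2_e = 0 (no shrinkage) is adopted."""

    effects: pd.Series
    mu: float
    sigma2_g: float
    sigma2_e: float
    identified: bool = True


def blup_line_effects(table: pd.DataFrame, trait: str, treatment: str,
                      year) -> BlupResult:
    """Random-intercept BLUPs of line effects within one treatment-year.

    Model: value = mu + line + error, line random, fitted by REML (closed
    form in the balanced case).  Shrinkage: with n records per line,
    BLUP_i = (s2g / (s2g + s2e/n)) * (ybar_i - mu).
    """
    sub = table[(table["trait"] == trait) & (table["treatment"] == treatment)
                & (table["year"] == year)].dropna(subset=["value"])
    if sub["line"].nunique() < 2:
        raise ValueError("need >= 2 lines for BLUP estimation")
    grp = sub.groupby("line", observed=True)["value"]
    means, counts = grp.mean(), grp.count()
    mu = float(sub["value"].mean())
    if counts.max() == 1:
        # one record per line: only s2g + s2e identified; boundary s2e = 0
        s2g = float(np.var(means.to_numpy(), ddof=1))
        return BlupResult(effects=means - mu, mu=mu, sigma2_g=s2g,
                          sigma2_e=0.0, identified=False)
    if counts.nunique() == 1:
        # balanced one-way random model: ANOVA = REML estimators
        n = int(counts.iloc[0])
        l = len(means)
        msb = n * float(((means - mu) ** 2).sum()) / (l - 1)
        msw = float(((sub.set_index("line")["value"] - means.reindex(
            sub["line"]).to_numpy()) ** 2).sum()) / (len(sub) - l)
        s2e = msw
        s2g = max((msb - msw) / n, 0.0)
    else:
        yv = sub["value"].to_numpy(dtype=float)
        X = np.ones((len(yv), 1))
        Zl = pd.get_dummies(sub["line"]).to_numpy(dtype=float)
        (s2g,), s2e, _, ok = _em_reml(yv, X, [Zl])
        s2g = max(s2g, 0.0)
        if not ok:
            raise RuntimeError("EM-REML for BLUPs did not converge")
    shrink = s2g / (s2g + s2e / counts) if (s2g + s2e) > 0 else counts * 0.0
    return BlupResult(effects=shrink * (means - mu), mu=mu, sigma2_g=s2g,
                      sigma2_e=s2e, identified=True)


def blup_matrix(table: pd.DataFrame, trait: str, treatment: str) -> pd.Series:
    """Per-treatment-year BLUPs averaged across years: the scan response."""
    years = sorted(table.loc[table["treatment"] == treatment, "year"].unique())
    per_year = [blup_line_effects(table, trait, treatment, yr).effects
                for yr in years]
    return pd.concat(per_year, axis=1).mean(axis=1)


# ---------------------------------------------------------------------------
# stress tolerance index
# ---------------------------------------------------------------------------

def stress_tolerance_index(yp, ys, yp_mean: float):
    """STI = (yp * ys) / yp_mean**2; dimensionless, 1 for an average line
    unaffected by stress."""
    if yp_mean == 0:
        raise ValueError("control mean is zero; STI undefined")
    return (np.asarray(yp, dtype=float) * np.asarray(ys, dtype=float)) / yp_mean ** 2


def sti_table(table: pd.DataFrame, control: str = "WW",
              stress: str = "TD") -> pd.DataFrame:
    """Per-line, per-year STI for every trait with records in both treatments.

    The control mean is taken per trait and year, matching a per-year index.
    """
    rows = []
    for (trait, year), grp in table.groupby(["trait", "year"], observed=True):
        wide = grp.pivot_table(index="line", columns="treatment", values="value")
        if control not in wide.columns or stress not in wide.columns:
            continue
        both = wide[[control, stress]].dropna()
        yp_mean = float(both[control].mean())
        sti = stress_tolerance_index(both[control], both[stress], yp_mean)
        rows.append(pd.DataFrame({"line": both.index, "trait": trait,
                                  "year": year, "sti": sti}))
    if not rows:
        return pd.DataFrame(columns=["line", "trait", "year", "sti"])
    return pd.concat(rows, ignore_index=True)


def sti_response(table: pd.DataFrame, trait: str) -> pd.Series:
    """Scan response for stress tolerance: per-line STI averaged over years."""
    sti = sti_table(table)
    sti = sti[sti["trait"] == trait]
    if sti.empty:
        raise ValueError(f"no STI values for trait {trait!r}")
    return sti.groupby("line", observed=True)["sti"].mean()


# ---------------------------------------------------------------------------
# LSmeans, correlations, treatment test
# ---------------------------------------------------------------------------

def lsmeans_and_correlations(table: pd.DataFrame, treatment: str
                             ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Line LSmeans per trait (marginal over years) within one treatment and
    the pairwise Pearson correlation matrix among traits.

    Returns ``(lsmeans, r, n)`` with ``n`` the pairwise-complete sample
    sizes.  Pairs with fewer than three complete lines or a zero-variance
    trait are NaN.
    """
    sub = table[table["treatment"] == treatment].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no records for treatment {treatment!r}")
    ls = sub.pivot_table(index="line", columns="trait", values="value",
                         aggfunc="mean")
    r = ls.corr(method="pearson", min_periods=3)
    present = ls.notna().astype(int)
    n = pd.DataFrame(present.T.to_numpy() @ present.to_numpy(),
                     index=ls.columns, columns=ls.columns)
    return ls, r, n


def treatment_effect_test(table: pd.DataFrame, trait: str,
                          treatments: tuple[str, str] = ("WW", "TD")
                          ) -> dict:
    """F-test of the fixed treatment term with line as the blocking factor:
    a paired comparison of line means between the two treatments."""
    from scipy import stats

    wide = (table[table["trait"] == trait]
            .pivot_table(index="line", columns="treatment", values="value"))
    both = wide[list(treatments)].dropna()
    if len(both) < 3:
        raise ValueError("need >= 3 lines observed in both treatments")
    diff = both[treatments[0]] - both[treatments[1]]
    t = float(diff.mean() / (diff.std(ddof=1) / math.sqrt(len(diff))))
    df = len(diff) - 1
    f = t * t
    p = float(stats.f.sf(f, 1, df))
    return {"F": f, "df": (1, df), "P": p, "mean_difference": float(diff.mean()),
            "n_lines": len(diff)}


def summary_table(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics plus H2 for every trait x treatment, in the
    shape of a published summary table (mean, min, max, SE, SD, CV, H2)."""
    rows = []
    for (trait, trt), grp in table.groupby(["trait", "treatment"], observed=True):
        d = descriptive_stats(grp["value"])
        try:
            h2 = heritability(fit_variance_components(table, trait, trt))
        except ValueError:
            h2 = float("nan")
        rows.append({"trait": trait, "treatment": trt, "n": d.n, "mean": d.mean,
                     "min": d.min, "max": d.max, "SE": d.se, "SD": d.sd,
                     "CV": d.cv, "H2": h2})
    return pd.DataFrame(rows)
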