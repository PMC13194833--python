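"""Reliability screening and group inference.

ICC(3,k) — two-way mixed, consistency, average-measures — quantifies the
test-retest reliability of an index over the 40 repeated epochs: with epochs
as raters (rows) and subjects as targets (columns),

    ICC(3,k) = (BMS - EMS) / BMS

from the two-way ANOVA mean squares (BMS between targets, EMS residual).
Cells are classified as poor (< 0.40), fair (0.40-0.60), good (0.60-0.75)
or excellent (>= 0.75); only cells reaching ICC >= 0.60 enter group testing.

Group differences are estimated per state/band/index by the random-intercept
linear mixed-effects model ``Value ~ Group + (1 | Subject)`` fitted by REML
(statsmodels MixedLM), with Wald 95% CI and p-value for the group effect,
Benjamini-Hochberg FDR correction pooled across all tests, and Cohen's f²
computed from the marginal R² (fixed-effect variance over total variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

ICC_BINS = ((0.40, "poor"), (0.60, "fair"), (0.75, "good"))


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------

def icc_3k(M: np.ndarray) -> float:
    """ICC(3,k) of a raters x targets grid (epochs x subjects).

    Undefined (NaN) when the between-target variance vanishes.  Negative
    values are reported as computed, not truncated.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("need a grid with >= 2 raters and >= 2 targets")
    k, n = M.shape
    grand = M.mean()
    col_means = M.mean(axis=0)
    row_means = M.mean(axis=1)
    ss_total = ((M - grand) ** 2).sum()
    ss_targets = k * ((col_means - grand) ** 2).sum()
    ss_raters = n * ((row_means - grand) ** 2).sum()
    ss_resid = ss_total - ss_targets - ss_raters
    bms = ss_targets / (n - 1)
    ems = ss_resid / ((n - 1) * (k - 1))
    if bms <= 0:
        return float("nan")
    return float((bms - ems) / bms)


def classify_icc(icc: float) -> str:
    """Bin an ICC value: poor < 0.40 <= fair < 0.60 <= good < 0.75 <= excellent.

    Negative values (reported as computed) fall in "poor"; NaN maps to
    "undefined".
    """
    if np.isnan(icc):
        return "undefined"
    for upper, label in ICC_BINS:
        if icc < upper:
            return label
    return "excellent"


def reliability_grid(long_table: pd.DataFrame,
                     value_col: str = "value") -> pd.DataFrame:
    """ICC(3,k) per (group, state, cleaning, measure, band, index) cell.

    ``long_table`` must carry one row per (subject, epoch) observation with
    the grouping columns present.  Epochs act as raters, subjects as targets.
    """
    keys = [c for c in ("group", "state", "cleaning", "measure", "band", "index_name")
            if c in long_table.columns]
    rows = []
    for key_vals, sub in long_table.groupby(keys, sort=True):
        grid = sub.pivot_table(index="epoch", columns="subject_id",
                               values=value_col)
        icc = icc_3k(grid.to_numpy())
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update({"icc": icc, "label": classify_icc(icc),
                    "negative": bool(icc < 0) if np.isfinite(icc) else False})
        rows.append(row)
    return pd.DataFrame(rows)


def screen_reliability(grid: pd.DataFrame, threshold: float = 0.60) -> pd.DataFrame:
    """Keep cells whose ICC reaches the threshold in every group."""
    keys = [c for c in ("state", "cleaning", "measure", "band", "index_name")
            if c in grid.columns]
    ok = (grid.assign(pass_=grid["icc"] >= threshold)
              .groupby(keys)["pass_"].all())
    return ok[ok].reset_index()[keys]


# ---------------------------------------------------------------------------
# LME
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    beta0: float
    beta1: float
    ci_low: float
    ci_high: float
    p_value: float
    sigma_u2: float
    sigma2: float
    f2: float
    singular: bool
    p_fdr: float | None = None


def fit_lme(table: pd.DataFrame, value_col: str = "value",
            df_method: str = "wald_z") -> LMEResult:
    """Random-intercept model ``Value ~ Group + (1 | Subject)`` via REML.

    ``Group`` is coded with Control as reference, so beta1 is the
    Miners - Control mean difference; the 95% CI and p-value refer to beta1.
    ``df_method="wald_z"`` (default) uses the Wald z reference;
    ``df_method="subjects_t"`` uses a t reference with n_subjects - 2
    degrees of freedom (a conservative between-subject approximation).  A
    singular fit (vanishing random-intercept variance) is retained and
    flagged.
    """
    df = table.rename(columns={value_col: "Value"}).copy()
    counts = df.groupby("group")["subject_id"].nunique()
    if len(counts) != 2 or counts.min() < 2:
        raise ValueError("need two groups with >= 2 subjects each")
    df["g"] = (df["group"] != "Control").astype(float)
    y = df["Value"].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), df["g"].to_numpy()])
    beta0 = beta1 = se = np.nan
    sigma_u2 = sigma2 = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = MixedLM(y, X, groups=df["subject_id"].to_numpy()).fit(reml=True)
        beta0, beta1 = res.fe_params
        se = float(res.bse_fe[1])
        sigma_u2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
    except np.linalg.LinAlgError:
        pass
    if not (np.isfinite(se) and se > 0):
        # boundary fit (sigma_u^2 -> 0): the model reduces to pooled OLS
        beta_hat, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        beta0, beta1 = beta_hat
        resid = y - X @ beta_hat
        sigma2 = float(resid @ resid / (len(y) - 2))
        sigma_u2 = 0.0
        gram_inv = np.linalg.inv(X.T @ X)
        se = float(np.sqrt(sigma2 * gram_inv[1, 1]))
    if df_method == "wald_z":
        z = spstats.norm.ppf(0.975)
        p = 2 * spstats.norm.sf(abs(beta1) / se) if se > 0 else 1.0
    elif df_method == "subjects_t":
        dof = df["subject_id"].nunique() - 2
        z = spstats.t.ppf(0.975, dof)
        p = 2 * spstats.t.sf(abs(beta1) / se, dof) if se > 0 else 1.0
    else:
        raise ValueError("df_method must be 'wald_z' or 'subjects_t'")
    singular = sigma_u2 <= 1e-10 * max(sigma2, 1e-300)
    out = LMEResult(float(beta0), float(beta1), float(beta1 - z * se),
                    float(beta1 + z * se), float(p), sigma_u2, sigma2,
                    f2=float("nan"), singular=singular)
    out.f2 = cohens_f2(out, df)
    return out


def cohens_f2(r: LMEResult, table: pd.DataFrame) -> float:
    """f² = R²_marginal / (1 - R²_marginal) with marginal R² from the fixed part."""
    g = (table["group"] != "Control").astype(float).to_numpy()
    fixed = r.beta0 + r.beta1 * g
    var_fixed = float(np.var(fixed))
    total = var_fixed + r.sigma_u2 + r.sigma2
    if total <= 0:
        return float("nan")
    r2m = var_fixed / total
    return r2m / (1.0 - r2m) if r2m < 1 else float("inf")


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def lme_table(long_table: pd.DataFrame, screened: pd.DataFrame | None = None,
              value_col: str = "value") -> pd.DataFrame:
    """Fit one LME per (state, cleaning, measure, band, index) cell.

    When ``screened`` is given only those cells are tested; FDR correction is
    pooled across all fitted tests.
    """
    keys = [c for c in ("state", "cleaning", "measure", "band", "index_name")
            if c in long_table.columns]
    if screened is not None:
        long_table = long_table.merge(screened, on=list(screened.columns))
    rows = []
    for key_vals, sub in long_table.groupby(keys, sort=True):
        res = fit_lme(sub, value_col=value_col)
        row = dict(zip(keys, key_vals if isinstance(key_vals, tuple) else (key_vals,)))
        row.update({"beta1": res.beta1, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p": res.p_value,
                    "sigma_u2": res.sigma_u2, "sigma2": res.sigma2,
                    "f2": res.f2, "singular": res.singular})
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# correlations and summary t-tests
# ---------------------------------------------------------------------------

def correlate_with_psychometrics(index_means: pd.DataFrame,
                                 scores: pd.DataFrame,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Pearson r of per-subject epoch-mean indices against psychometric columns.

    Both frames must be indexed by subject.  Returns the full table with
    two-tailed p and BH-FDR adjusted p pooled over all tested pairs, plus a
    ``significant`` flag at the given FDR level.  Zero-variance pairs are
    flagged as missing.
    """
    common = index_means.index.intersection(scores.index)
    if len(common) < 4:
        raise ValueError("need >= 4 complete subjects")
    rows = []
    for icol in index_means.columns:
        x = index_means.loc[common, icol].to_numpy(dtype=float)
        for scol in scores.columns:
            y = scores.loc[common, scol].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                rows.append({"index_name": icol, "score": scol,
                             "r": np.nan, "p": np.nan})
                continue
            r, p = spstats.pearsonr(x, y)
            rows.append({"index_name": icol, "score": scol, "r": r, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["p_fdr"] = np.nan
    if valid.any():
        out.loc[valid, "p_fdr"] = bh_fdr(out.loc[valid, "p"].to_numpy())
    out["significant"] = out["p_fdr"] <= alpha
    return out


def t_from_summary(m1: float, sd1: float, n1: int,
                   m2: float, sd2: float, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sample t-test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    if se == 0:
        if m1 == m2:
            return 0.0, 1.0
        return float("inf") * np.sign(m1 - m2), 0.0
    t = (m1 - m2) / se
    p = 2 * spstats.t.sf(abs(t), df)
    return float(t), float(p)
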