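"""Association battery: EA–CA correlations per tissue, EAA–covariate
Spearman correlations, and pairwise Welch tests between tissue types.

All results are returned as a tidy frame with one row per (test, clock,
group) carrying the statistic, two-sided p-value, effect estimate and its
95% confidence interval.  Raw p-values are reported (with a star bin per the
conventional figure annotation); a Benjamini–Hochberg column is emitted
alongside for convenience but never gates anything.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import ConfigError, EaakitError, TISSUES

RESULT_COLUMNS = [
    "test", "clock", "group", "n", "n2", "estimate",
    "statistic", "df", "p", "ci_low", "ci_high", "stars",
]

COVARIATE_CODES: Dict[str, Dict[str, float]] = {
    "sex": {"female": 0.0, "male": 1.0},
    "side": {"left": 0.0, "right": 1.0},
}


def p_stars(p: float) -> str:
    """Star bins: ns (p>0.05), * (≤0.05), ** (<1e-3), *** (<1e-4)."""
    if not np.isfinite(p):
        return "na"
    if p < 1e-4:
        return "***"
    if p < 1e-3:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def _pearson_ci(r: float, n: int, level: float = 0.95) -> Tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4 or abs(r) >= 1:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    q = stats.norm.ppf(0.5 + level / 2)
    return (float(np.tanh(z - q * se)), float(np.tanh(z + q * se)))


def ea_ca_correlation(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    tissues: Sequence[str] = TISSUES,
) -> pd.DataFrame:
    """Pearson correlation of epigenetic vs chronological age, per clock and
    tissue stratum.  Strata with fewer than 3 samples are reported as absent
    (no row); zero-variance EA gives an undefined r (NaN row)."""
    rows = []
    common = [s for s in scores.index if s in sheet.index]
    scores = scores.loc[common]
    sheet = sheet.loc[common]
    for tissue in tissues:
        ids = sheet.index[sheet["tissue"] == tissue]
        if len(ids) < 3:
            continue
        ca = sheet.loc[ids, "age_years"].astype(float).to_numpy()
        for clock in scores.columns:
            ea = scores.loc[ids, clock].to_numpy(dtype=float)
            ok = np.isfinite(ea) & np.isfinite(ca)
            if ok.sum() < 3:
                continue
            if np.std(ea[ok]) == 0 or np.std(ca[ok]) == 0:
                rows.append(_row("pearson_ea_ca", clock, tissue, int(ok.sum())))
                continue
            r, p = stats.pearsonr(ca[ok], ea[ok])
            lo, hi = _pearson_ci(r, int(ok.sum()))
            rows.append(
                _row("pearson_ea_ca", clock, tissue, int(ok.sum()),
                     estimate=r, statistic=r, p=p, ci=(lo, hi))
            )
    return _finish(rows)


def eaa_covariate_correlation(
    eaa: pd.DataFrame,
    sheet: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "side"),
    by_tissue: bool = False,
) -> pd.DataFrame:
    """Spearman rank correlation of each clock's EAA with each covariate.

    Binary covariates are rank-coded 0/1 (female/male, left/right); samples
    with unknown side are excluded from the side correlations.  Constant
    covariates give an undefined ρ (NaN row).  The absolute values of the
    estimates are what a correlation heatmap displays.
    """
    rows = []
    common = [s for s in eaa.index if s in sheet.index]
    eaa = eaa.loc[common]
    sheet = sheet.loc[common]
    strata = (
        [(t, sheet.index[sheet["tissue"] == t]) for t in sheet["tissue"].unique()]
        if by_tissue
        else [("all", sheet.index)]
    )
    for stratum, ids in strata:
        for cov in covariates:
            x = _covariate_values(sheet.loc[ids], cov)
            for clock in eaa.columns:
                y = eaa.loc[ids, clock].to_numpy(dtype=float)
                ok = np.isfinite(x) & np.isfinite(y)
                label = f"{stratum}:{cov}" if by_tissue else cov
                if ok.sum() < 3:
                    continue
                if np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
                    rows.append(_row("spearman_eaa", clock, label, int(ok.sum())))
                    continue
                rho, p = stats.spearmanr(x[ok], y[ok])
                rows.append(
                    _row("spearman_eaa", clock, label, int(ok.sum()),
                         estimate=rho, statistic=rho, p=p)
                )
    return _finish(rows)


def _covariate_values(sheet: pd.DataFrame, cov: str) -> np.ndarray:
    if cov == "age":
        return sheet["age_years"].astype(float).to_numpy()
    if cov in COVARIATE_CODES:
        if cov not in sheet.columns:
            return np.full(len(sheet), np.nan)
        return sheet[cov].map(COVARIATE_CODES[cov]).astype(float).to_numpy()
    raise ConfigError(f"unknown covariate {cov!r}; allowed: age, sex, side")


def welch_test(x: np.ndarray, y: np.ndarray, level: float = 0.95):
    """Welch two-sample t-test with Welch–Satterthwaite df and a CI for the
    mean difference.  Returns (t, df, p, mean_diff, ci_low, ci_high)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise EaakitError("Welch test needs >= 2 samples per group")
    v1, v2 = np.var(x, ddof=1), np.var(y, ddof=1)
    if v1 == 0 and v2 == 0:
        if np.mean(x) == np.mean(y):
            return 0.0, float(n1 + n2 - 2), 1.0, 0.0, 0.0, 0.0
        raise EaakitError("degenerate groups: zero variance in both groups")
    se2 = v1 / n1 + v2 / n2
    t = (np.mean(x) - np.mean(y)) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * stats.t.sf(abs(t), df)
    q = stats.t.ppf(0.5 + level / 2, df)
    diff = float(np.mean(x) - np.mean(y))
    half = q * np.sqrt(se2)
    return float(t), float(df), float(p), diff, diff - half, diff + half


def tissue_welch_tests(
    eaa: pd.DataFrame,
    sheet: pd.DataFrame,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
) -> pd.DataFrame:
    """Welch two-sample t-tests of EAA between tissue types, per clock.

    ``pairs`` defaults to every unordered pair of tissues present.  The
    estimate is mean(EAA first) − mean(EAA second) with its 95% CI.  Groups
    with < 2 samples or zero variance (in both groups, unequal means) raise.
    """
    common = [s for s in eaa.index if s in sheet.index]
    eaa = eaa.loc[common]
    sheet = sheet.loc[common]
    present = [t for t in TISSUES if (sheet["tissue"] == t).sum() >= 2]
    if pairs is None:
        pairs = list(combinations(present, 2))
    rows = []
    for t1, t2 in pairs:
        ids1 = sheet.index[sheet["tissue"] == t1]
        ids2 = sheet.index[sheet["tissue"] == t2]
        for g, t in ((ids1, t1), (ids2, t2)):
            if len(g) < 2:
                raise EaakitError(f"group {t!r} has fewer than 2 samples")
        for clock in eaa.columns:
            x = eaa.loc[ids1, clock].dropna().to_numpy(dtype=float)
            y = eaa.loc[ids2, clock].dropna().to_numpy(dtype=float)
            t, df, p, diff, lo, hi = welch_test(x, y)
            rows.append(
                _row("welch_eaa", clock, f"{t1}_vs_{t2}", len(x), n2=len(y),
                     estimate=diff, statistic=t, df=df, p=p, ci=(lo, hi))
            )
    return _finish(rows)


def _row(test, clock, group, n, n2=np.nan, estimate=np.nan, statistic=np.nan,
         df=np.nan, p=np.nan, ci=(np.nan, np.nan)):
    return {
        "test": test, "clock": clock, "group": group, "n": n, "n2": n2,
        "estimate": estimate, "statistic": statistic, "df": df, "p": p,
        "ci_low": ci[0], "ci_high": ci[1], "stars": p_stars(p),
    }


def _finish(rows) -> pd.DataFrame:
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    ok = out["p"].notna()
    out["p_bh"] = np.nan
    if ok.any():
        out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out
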