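"""Control-anchored epigenetic age acceleration (EAA).

EAA is computed in three steps, per clock:

1. an *anchor* ordinary-least-squares regression of epigenetic age (EA) onto
   chronological age (and optionally sex and/or platform), fitted only on a
   reference tissue class (healthy colon by default).  Anchoring on controls
   gives every clock — including mitotic scores whose units are divisions,
   not years — an EAA on a common residual scale;
2. raw EAA for *all* samples as EA minus the anchor model's prediction;
3. an optional random-intercept adjustment ``EAA ~ (1|dataset) + (1|patient)``
   removing dataset batch offsets and within-patient correlation; the
   adjusted EAA is the model's conditional residual (observed minus fixed
   intercept minus the predicted dataset and patient intercepts).

A simple-difference screen (EAAd = EA − CA, defined for non-mitotic clocks
only) flags outlier samples lying outside mean ± k·SD in at least
``min_clocks`` clocks before any anchor is fitted.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .types import ConfigError, EaakitError

SEX_CODE = {"female": 0.0, "male": 1.0}
PLATFORM_CODE = {"450k": 0.0, "EPIC": 1.0}
ANCHOR_COVARIATES = ("age", "sex", "platform")


@dataclass
class AnchorModel:
    """OLS anchor fit for one clock: EA ~ CA (+ sex) (+ platform)."""

    clock: str
    anchor_class: str
    covariates: Tuple[str, ...]
    coef: Dict[str, float]  # intercept + one entry per covariate
    n_anchor: int
    anchor_sample_ids: List[str] = field(default_factory=list)

    def design(self, sheet: pd.DataFrame) -> pd.DataFrame:
        cols = {"intercept": np.ones(len(sheet))}
        if "age" in self.covariates:
            cols["age"] = sheet["age_years"].to_numpy(dtype=float)
        if "sex" in self.covariates:
            cols["sex"] = sheet["sex"].map(SEX_CODE).to_numpy(dtype=float)
        if "platform" in self.covariates:
            cols["platform"] = sheet["platform"].map(PLATFORM_CODE).to_numpy(dtype=float)
        return pd.DataFrame(cols, index=sheet.index)

    def predict(self, sheet: pd.DataFrame) -> pd.Series:
        X = self.design(sheet)
        b = np.array([self.coef[c] for c in X.columns])
        return pd.Series(X.to_numpy() @ b, index=sheet.index, name=self.clock)

    def to_dict(self) -> dict:
        return {
            "clock": self.clock,
            "anchor_class": self.anchor_class,
            "covariates": list(self.covariates),
            "coef": dict(self.coef),
            "n_anchor": self.n_anchor,
            "anchor_sample_ids": list(self.anchor_sample_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorModel":
        return cls(
            clock=d["clock"],
            anchor_class=d["anchor_class"],
            covariates=tuple(d["covariates"]),
            coef={k: float(v) for k, v in d["coef"].items()},
            n_anchor=int(d["n_anchor"]),
            anchor_sample_ids=list(d.get("anchor_sample_ids", [])),
        )


def fit_anchor(
    scores: pd.Series,
    sheet: pd.DataFrame,
    anchor_class: str = "healthy",
    covariates: Sequence[str] = ("age", "sex"),
) -> AnchorModel:
    """OLS of EA onto the covariates, on anchor-class samples only.

    ``covariates`` must include ``age``; sex is coded 0 = female, 1 = male
    and platform 0 = 450k, 1 = EPIC.  Fewer than 3 anchor samples or a
    collinear design (e.g. a single-sex anchor set with the sex covariate)
    is an error naming the offending covariate.
    """
    covariates = tuple(covariates)
    unknown = set(covariates) - set(ANCHOR_COVARIATES)
    if unknown:
        raise ConfigError(f"unknown anchor covariates {sorted(unknown)}")
    if "age" not in covariates:
        raise ConfigError("anchor covariates must include 'age'")
    ids = [
        s
        for s in scores.index
        if s in sheet.index
        and sheet.loc[s, "tissue"] == anchor_class
        and np.isfinite(scores[s])
    ]
    if len(ids) < 3:
        raise EaakitError(
            f"clock {scores.name!r}: only {len(ids)} {anchor_class!r} anchor "
            "samples; need >= 3"
        )
    shell = AnchorModel(
        clock=str(scores.name),
        anchor_class=anchor_class,
        covariates=covariates,
        coef={},
        n_anchor=len(ids),
        anchor_sample_ids=ids,
    )
    X = shell.design(sheet.loc[ids])
    Xa = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        for col in X.columns[1:]:
            if X[col].nunique() < 2:
                raise EaakitError(
                    f"clock {scores.name!r}: covariate {col!r} is constant on the "
                    f"{anchor_class!r} anchor set"
                )
        raise EaakitError(f"clock {scores.name!r}: collinear anchor design matrix")
    res = sm.OLS(scores.loc[ids].to_numpy(dtype=float), Xa).fit()
    shell.coef = {c: float(b) for c, b in zip(X.columns, res.params)}
    return shell


def compute_raw_eaa(
    scores: pd.Series,
    sheet: pd.DataFrame,
    model: AnchorModel,
) -> pd.Series:
    """EAA_s = EA_s − anchor prediction, for every sample (anchor class or
    not).  Samples with a missing covariate get NaN."""
    common = [s for s in scores.index if s in sheet.index]
    pred = model.predict(sheet.loc[common])
    eaa = scores.loc[common].astype(float) - pred
    eaa.name = model.clock
    return eaa


def flag_eaad_outliers(
    eaad: pd.DataFrame,
    k_sd: float = 3.0,
    min_clocks: int = 2,
) -> List[str]:
    """Samples whose EAAd lies outside mean ± k·SD in ≥ ``min_clocks`` clocks.

    Per clock, the mean and (sample, ddof=1) SD are computed over the whole
    table, outlier candidates included.  ``min_clocks=2`` is the association
    default; classifier mode uses 1 ("outlier in even one clock").
    """
    if k_sd <= 0:
        raise ConfigError("k_sd must be > 0")
    if min_clocks < 1:
        raise ConfigError("min_clocks must be >= 1")
    if len(eaad) < 2:
        raise EaakitError("EAAd outlier rule needs >= 2 samples (SD undefined)")
    mean = eaad.mean(axis=0)
    sd = eaad.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore"):
        flags = (eaad - mean).abs() > k_sd * sd
    n_flagged = flags.sum(axis=1)
    return sorted(eaad.index[n_flagged >= min_clocks].tolist())


def _fallback_center(df: pd.DataFrame) -> pd.Series:
    """Method-of-moments fallback: remove grand mean, then dataset-mean and
    patient-mean deviations (no shrinkage)."""
    y = df["y"] - df["y"].mean()
    y = y - y.groupby(df["dataset_id"]).transform("mean")
    rep = df["patient_id"].map(df["patient_id"].value_counts()) > 1
    if rep.any():
        pat_dev = y.groupby(df["patient_id"]).transform("mean")
        y = y.where(~rep, y - pat_dev)
    return y


def adjust_mixed(raw_eaa: pd.Series, sheet: pd.DataFrame) -> pd.Series:
    """Random-intercept adjustment ``EAA ~ (1|dataset) + (1|patient)``.

    Fits a REML linear mixed model with independent dataset and patient
    random intercepts (patients are nested in datasets by the sample-sheet
    invariant) and returns the conditional residual: raw EAA minus the fixed
    intercept minus the BLUPs of both intercepts.  Terms whose grouping is
    degenerate are dropped: the patient intercept when no patient has two
    samples, the dataset intercept when there is a single dataset.  With
    neither grouping the adjustment reduces to grand-mean centering.  If REML
    fails, falls back to group-mean centering with a warning.
    """
    common = [s for s in raw_eaa.index if s in sheet.index and np.isfinite(raw_eaa[s])]
    df = pd.DataFrame(
        {
            "y": raw_eaa.loc[common].astype(float),
            "dataset_id": sheet.loc[common, "dataset_id"].astype(str),
            "patient_id": sheet.loc[common, "patient_id"].astype(str),
        }
    )
    out = pd.Series(np.nan, index=raw_eaa.index, name=raw_eaa.name)
    multi_dataset = df["dataset_id"].nunique() >= 2
    has_repeat = (df["patient_id"].value_counts() > 1).any()
    mode = ("both" if multi_dataset and has_repeat
            else "ds" if multi_dataset
            else "pat" if has_repeat
            else "none")
    try:
        adjusted = _mixed_resid(df, mode)
    except Exception as exc:  # pragma: no cover - exercised only on failure
        _warnings.warn(
            f"REML adjustment failed ({exc!r}); falling back to group-mean centering"
        )
        adjusted = _fallback_center(df)
    out.loc[common] = adjusted
    return out


def _mixed_resid(df: pd.DataFrame, mode: str) -> pd.Series:
    """REML fit + conditional residuals, dropping variance components whose
    REML estimate collapses to ~0 (their BLUPs are 0 and statsmodels cannot
    predict from a singular covariance).  The response is standardised before
    fitting (clock scores span units from years to beta fractions) and the
    residuals mapped back."""
    if mode == "none":
        return df["y"] - df["y"].mean()
    scale = float(df["y"].std(ddof=0))
    if scale > 0 and not np.isclose(scale, 1.0):
        scaled = df.copy()
        scaled["y"] = (df["y"] - df["y"].mean()) / scale
        return _mixed_resid(scaled, mode) * scale
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        if mode == "both":
            md = smf.mixedlm(
                "y ~ 1", df, groups="dataset_id", re_formula="1",
                vc_formula={"patient": "0 + C(patient_id)"},
            )
        elif mode == "ds":
            md = smf.mixedlm("y ~ 1", df, groups="dataset_id", re_formula="1")
        else:  # pat
            md = smf.mixedlm("y ~ 1", df, groups="patient_id", re_formula="1")
        res = None
        last_exc: Exception | None = None
        # l-bfgs occasionally steps through a singular RE covariance during
        # its line search; bfgs/powell take different paths to the optimum
        for method in ("lbfgs", "bfgs", "powell"):
            try:
                res = md.fit(reml=True, method=method, maxiter=200)
                break
            except np.linalg.LinAlgError as exc:
                last_exc = exc
        if res is None:
            raise last_exc
    tol = 1e-8 * max(float(res.scale), 1e-12)
    grp_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    vc_var = float(res.vcomp[0]) if len(res.vcomp) else 0.0
    if mode == "both":
        if grp_var <= tol and vc_var <= tol:
            return _mixed_resid(df, "none")
        if grp_var <= tol:
            return _mixed_resid(df, "pat")
        if vc_var <= tol:
            return _mixed_resid(df, "ds")
    elif grp_var <= tol:
        return _mixed_resid(df, "none")
    # statsmodels fittedvalues include the predicted random effects, so
    # resid is exactly the conditional residual y - fixed - BLUPs
    return pd.Series(np.asarray(res.resid), index=df.index)


@dataclass
class EAAResult:
    """Per-sample × clock epigenetic ages, EAAs and screening table."""

    ea: pd.DataFrame  # sample × clock epigenetic ages / scores
    eaad: pd.DataFrame  # EA − CA, non-mitotic clocks only
    eaa_raw: pd.DataFrame  # EA − anchor prediction
    eaa_adj: Optional[pd.DataFrame]  # conditional residuals of the mixed model
    anchors: Dict[str, AnchorModel]
    outliers: List[str]
    sheet: pd.DataFrame  # retained samples

    @property
    def eaa(self) -> pd.DataFrame:
        """Adjusted EAA when the adjustment ran, else raw."""
        return self.eaa_adj if self.eaa_adj is not None else self.eaa_raw


def compute_eaad(scores: pd.DataFrame, sheet: pd.DataFrame, nonmitotic: Sequence[str]) -> pd.DataFrame:
    """EAAd = EA − CA for the given (non-mitotic) clocks."""
    common = [s for s in scores.index if s in sheet.index]
    ca = sheet.loc[common, "age_years"].astype(float)
    return scores.loc[common, list(nonmitotic)].sub(ca, axis=0)


def compute_eaa_table(
    scoreset,
    sheet: pd.DataFrame,
    anchor_class: str = "healthy",
    covariates: Sequence[str] = ("age", "sex"),
    adjust: bool = True,
    remove_outliers: bool = True,
    k_sd: float = 3.0,
    min_clocks: int = 2,
    outlier_order: str = "before",
) -> EAAResult:
    """Run the full anchored-EAA procedure for every clock in a score set.

    ``outlier_order='before'`` (default) removes EAAd outliers before anchors
    are fitted; ``'after'`` fits anchors on the full data and only drops the
    outliers from the output tables.
    """
    if outlier_order not in ("before", "after"):
        raise ConfigError("outlier_order must be 'before' or 'after'")
    scores = scoreset.scores
    common = [s for s in scores.index if s in sheet.index]
    scores = scores.loc[common]
    sub_sheet = sheet.loc[common]

    nonmito = scoreset.nonmitotic_clocks()
    eaad = compute_eaad(scores, sub_sheet, nonmito) if nonmito else pd.DataFrame(index=scores.index)
    outliers: List[str] = []
    if remove_outliers and len(nonmito) > 0 and len(eaad) >= 2:
        outliers = flag_eaad_outliers(eaad, k_sd=k_sd, min_clocks=min_clocks)
    retained = [s for s in scores.index if s not in set(outliers)]
    anchor_pool = retained if outlier_order == "before" else list(scores.index)

    anchors: Dict[str, AnchorModel] = {}
    raw_cols, adj_cols = [], []
    for clock in scores.columns:
        model = fit_anchor(
            scores.loc[anchor_pool, clock], sub_sheet.loc[anchor_pool],
            anchor_class=anchor_class, covariates=covariates,
        )
        anchors[clock] = model
        raw = compute_raw_eaa(scores.loc[retained, clock], sub_sheet.loc[retained], model)
        raw_cols.append(raw)
        if adjust:
            adj_cols.append(adjust_mixed(raw, sub_sheet.loc[retained]))
    return EAAResult(
        ea=scores.loc[retained],
        eaad=eaad.loc[retained] if len(eaad.columns) else eaad,
        eaa_raw=pd.concat(raw_cols, axis=1),
        eaa_adj=pd.concat(adj_cols, axis=1) if adjust else None,
        anchors=anchors,
        outliers=outliers,
        sheet=sub_sheet.loc[retained],
    )
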