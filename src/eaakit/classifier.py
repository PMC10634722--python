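"""Leak-safe CRC-status classifier on sex + per-clock EAA features.

The classifier distinguishes histologically normal colon tissue adjacent to
a tumour ("normal", the positive class) from normal colon tissue of
individuals without CRC ("healthy").  Leakage is controlled at every stage:

* anchors (EA ~ CA, optionally + platform) are fitted only on *training*
  healthy samples — inside cross-validation, only on the fold-train healthy;
* feature standardisation uses training means/SDs, never the test set's own;
* cross-validation folds are dataset pairs: two whole datasets form the fold
  test set and the remaining datasets the fold train set, so samples from
  one dataset (one batch) never appear on both sides;
* the final train/test split is at dataset granularity, asserted at
  evaluation time.

Model selection is a grid search over the elastic-net mixing α and penalty λ
maximising mean ROC-AUC across folds (ties broken toward the sparser model:
larger λ, then larger α).  ROC-AUC is computed as the Mann–Whitney
U-statistic with ties counted ½ and its confidence interval by DeLong's
method; the PR curve is summarised by average precision with the class
prevalence as the no-skill baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .eaa import AnchorModel, compute_eaad, compute_raw_eaa, fit_anchor, flag_eaad_outliers
from .enet import fit_elastic_net
from .types import ConfigError, EaakitError

POSITIVE_TISSUE = "normal"  # tissue adjacent to tumour = positive class
NEGATIVE_TISSUE = "healthy"
SEX_CODE = {"female": 0.0, "male": 1.0}

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))  # 21 values
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.01), 2))  # 101 values


# ---------------------------------------------------------------------------
# metrics

def roc_auc(y: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC as the Mann–Whitney statistic U/(n₁·n₀) with ties counted ½."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise EaakitError("ROC-AUC needs both classes present")
    ranks = rankdata(s)
    u = np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _midrank_stats(pos: np.ndarray, neg: np.ndarray):
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    t_all = rankdata(allv)
    t_pos = rankdata(pos)
    t_neg = rankdata(neg)
    v10 = (t_all[:m] - t_pos) / n
    v01 = 1.0 - (t_all[m:] - t_neg) / m
    theta = (np.sum(t_all[:m]) - m * (m + 1) / 2.0) / (m * n)
    return theta, v10, v01


def delong_ci(y: np.ndarray, scores: np.ndarray, level: float = 0.95
              ) -> Tuple[float, float, float]:
    """DeLong variance-based CI for the ROC-AUC; returns (auc, lo, hi)."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise EaakitError("DeLong CI needs >= 2 samples per class")
    theta, v10, v01 = _midrank_stats(pos, neg)
    var = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    q = norm.ppf(0.5 + level / 2.0)
    half = q * np.sqrt(max(var, 0.0))
    return float(theta), float(max(theta - half, 0.0)), float(min(theta + half, 1.0))


# ---------------------------------------------------------------------------
# features

@dataclass
class Scaler:
    """Standard-normal feature scaling frozen from a training set."""

    mean: pd.Series
    sd: pd.Series
    fit_sample_ids: List[str] = field(default_factory=list)

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "Scaler":
        sd = X.std(axis=0, ddof=0)
        zero = sd.index[sd == 0]
        if len(zero):
            raise EaakitError(f"feature {zero[0]!r} has zero training SD")
        return cls(X.mean(axis=0), sd, list(X.index))

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.mean.index] - self.mean) / self.sd


def fit_anchors(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    platform_adjust: bool = False,
) -> Dict[str, AnchorModel]:
    """Per-clock anchor EA ~ CA (+ platform) on the healthy samples of the
    given (training) sheet only."""
    covariates = ("age", "platform") if platform_adjust else ("age",)
    return {
        clock: fit_anchor(scores[clock], sheet, anchor_class=NEGATIVE_TISSUE,
                          covariates=covariates)
        for clock in scores.columns
    }


def build_features(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    anchors: Dict[str, AnchorModel],
    scaler: Optional[Scaler] = None,
) -> Tuple[pd.DataFrame, pd.Series, Scaler]:
    """Sex + one EAA column per clock, standard-normal scaled.

    When ``scaler`` is None it is fitted on these (training) features and
    returned; otherwise the given training scaler is applied unchanged (test
    data must never be scaled with its own statistics).  Labels are
    normal = 1, healthy = 0; other tissues are excluded.
    """
    keep = sheet.index[sheet["tissue"].isin([POSITIVE_TISSUE, NEGATIVE_TISSUE])]
    keep = [s for s in keep if s in scores.index]
    sub = sheet.loc[keep]
    cols = {"sex": sub["sex"].map(SEX_CODE).astype(float)}
    for clock in scores.columns:
        cols[f"eaa_{clock}"] = compute_raw_eaa(scores.loc[keep, clock], sub, anchors[clock])
    X = pd.DataFrame(cols, index=pd.Index(keep, name="sample_id"))
    y = (sub["tissue"] == POSITIVE_TISSUE).astype(float)
    if scaler is None:
        scaler = Scaler.fit(X)
    return scaler.transform(X), y, scaler


# ---------------------------------------------------------------------------
# folds

@dataclass
class FoldPlan:
    """Dataset-pair cross-validation folds over the training datasets."""

    folds: List[Tuple[Tuple[str, str], Tuple[str, ...]]]  # (test pair, train rest)
    invalid: List[Tuple[Tuple[str, str], str]] = field(default_factory=list)


def make_folds(sheet: pd.DataFrame, require_platform_variation: bool = False) -> FoldPlan:
    """Enumerate unordered dataset pairs; a pair is a valid fold when both
    the two test datasets combined and the remaining training datasets
    combined contain at least one healthy and one normal sample.  Datasets
    are ordered by sorted ID, so the plan is deterministic.

    ``require_platform_variation`` additionally demands that the fold-train
    healthy samples span both array platforms — necessary for the
    platform-adjusted anchor to be estimable, and the reason the
    platform-adjusted variant runs on fewer folds."""
    datasets = sorted(sheet["dataset_id"].unique())
    if len(datasets) < 3:
        raise EaakitError(
            f"dataset-pair folds need >= 3 training datasets, got {len(datasets)}"
        )
    by_ds = {
        d: set(sheet.loc[sheet["dataset_id"] == d, "tissue"].unique()) for d in datasets
    }
    healthy_platforms = {
        d: set(
            sheet.loc[
                (sheet["dataset_id"] == d) & (sheet["tissue"] == NEGATIVE_TISSUE),
                "platform",
            ].unique()
        )
        for d in datasets
    }
    folds, invalid = [], []
    for pair in combinations(datasets, 2):
        rest = tuple(d for d in datasets if d not in pair)
        test_classes = by_ds[pair[0]] | by_ds[pair[1]]
        train_classes = set().union(*(by_ds[d] for d in rest))
        missing = []
        for cls in (NEGATIVE_TISSUE, POSITIVE_TISSUE):
            if cls not in test_classes:
                missing.append(f"test side lacks {cls!r}")
            if cls not in train_classes:
                missing.append(f"train side lacks {cls!r}")
        if require_platform_variation:
            train_platforms = set().union(*(healthy_platforms[d] for d in rest))
            if len(train_platforms) < 2:
                missing.append("train-side healthy samples span a single platform")
        if missing:
            invalid.append((pair, "; ".join(missing)))
        else:
            folds.append((pair, rest))
    if not folds:
        raise EaakitError(
            "no valid dataset-pair fold: " +
            "; ".join(f"{p}: {r}" for p, r in invalid)
        )
    return FoldPlan(folds, invalid)


# ---------------------------------------------------------------------------
# grid search

@dataclass
class GridResult:
    """Per-(α, λ, fold) metrics plus the across-fold summary."""

    per_fold: pd.DataFrame  # columns alpha, lam, fold, roc_auc, pr_auc
    summary: pd.DataFrame  # columns alpha, lam, mean_roc_auc, sd_roc_auc, mean_pr_auc
    best_alpha: float
    best_lambda: float


def grid_search(
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    folds: FoldPlan,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    platform_adjust: bool = False,
) -> GridResult:
    """Cross-validated grid search maximising mean ROC-AUC over folds.

    EAA anchors and feature scalers are refitted inside every fold on the
    fold-train healthy samples only, so no information from a fold's test
    datasets leaks into its features.  Ties on mean ROC-AUC are broken toward
    larger λ, then larger α (the sparser model).
    """
    rows = []
    for k, (test_pair, train_rest) in enumerate(folds.folds):
        tr_sheet = sheet[sheet["dataset_id"].isin(train_rest)]
        te_sheet = sheet[sheet["dataset_id"].isin(test_pair)]
        anchors = fit_anchors(scores.loc[scores.index.intersection(tr_sheet.index)],
                              tr_sheet, platform_adjust)
        Xtr, ytr, scaler = build_features(scores, tr_sheet, anchors)
        Xte, yte, _ = build_features(scores, te_sheet, anchors, scaler)
        Xtr_a, ytr_a = Xtr.to_numpy(), ytr.to_numpy()
        Xte_a, yte_a = Xte.to_numpy(), yte.to_numpy()
        for lam in lambda_grid:
            for alpha in alpha_grid:
                fit = fit_elastic_net(Xtr_a, ytr_a, alpha, lam, strict=False)
                s = fit.decision(Xte_a)
                rows.append(
                    {
                        "alpha": float(alpha), "lam": float(lam), "fold": k,
                        "roc_auc": roc_auc(yte_a, s),
                        "pr_auc": float(average_precision_score(yte_a, s)),
                    }
                )
    per_fold = pd.DataFrame(rows)
    summary = (
        per_fold.groupby(["alpha", "lam"])
        .agg(mean_roc_auc=("roc_auc", "mean"), sd_roc_auc=("roc_auc", "std"),
             mean_pr_auc=("pr_auc", "mean"))
        .reset_index()
    )
    best = summary.sort_values(
        ["mean_roc_auc", "lam", "alpha"], ascending=[False, False, False]
    ).iloc[0]
    return GridResult(per_fold, summary, float(best["alpha"]), float(best["lam"]))


# ---------------------------------------------------------------------------
# bundle / pipeline

@dataclass
class ClassifierBundle:
    """Everything needed to score a new sample: per-clock anchors, training
    scaling statistics, elastic-net coefficients and the chosen (α, λ)."""

    anchors: Dict[str, AnchorModel]
    scaler: Scaler
    feature_names: List[str]
    coef: Dict[str, float]
    intercept: float
    alpha: float
    lam: float
    platform_adjust: bool
    train_datasets: List[str]
    train_sample_ids: List[str]
    label_convention: str = "normal=1,healthy=0"
    schema_version: int = 1

    def predict_scores(self, scores: pd.DataFrame, sheet: pd.DataFrame
                       ) -> Tuple[pd.Series, pd.Series]:
        """Decision scores (linear predictor) and labels for eligible samples."""
        X, y, _ = build_features(scores, sheet, self.anchors, self.scaler)
        X = X[self.feature_names]
        b = np.array([self.coef[c] for c in self.feature_names])
        return pd.Series(self.intercept + X.to_numpy() @ b, index=X.index), y

    def to_json(self) -> str:
        d = {
            "schema_version": self.schema_version,
            "label_convention": self.label_convention,
            "anchors": {k: v.to_dict() for k, v in self.anchors.items()},
            "scaler": {
                "mean": self.scaler.mean.to_dict(),
                "sd": self.scaler.sd.to_dict(),
                "fit_sample_ids": self.scaler.fit_sample_ids,
            },
            "feature_names": self.feature_names,
            "coef": self.coef,
            "intercept": self.intercept,
            "alpha": self.alpha,
            "lambda": self.lam,
            "platform_adjust": self.platform_adjust,
            "train_datasets": self.train_datasets,
            "train_sample_ids": self.train_sample_ids,
        }
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ClassifierBundle":
        d = json.loads(text)
        names = d["feature_names"]
        return cls(
            anchors={k: AnchorModel.from_dict(v) for k, v in d["anchors"].items()},
            scaler=Scaler(
                pd.Series(d["scaler"]["mean"]).loc[names],
                pd.Series(d["scaler"]["sd"]).loc[names],
                list(d["scaler"]["fit_sample_ids"]),
            ),
            feature_names=list(names),
            coef={k: float(v) for k, v in d["coef"].items()},
            intercept=float(d["intercept"]),
            alpha=float(d["alpha"]),
            lam=float(d["lambda"]),
            platform_adjust=bool(d["platform_adjust"]),
            train_datasets=list(d["train_datasets"]),
            train_sample_ids=list(d["train_sample_ids"]),
            label_convention=d.get("label_convention", "normal=1,healthy=0"),
            schema_version=int(d.get("schema_version", 1)),
        )


@dataclass
class TrainConfig:
    """Configuration of :func:`train_pipeline`."""

    train_datasets: Sequence[str]
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID
    lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID
    platform_adjust: bool = False
    outlier_k_sd: float = 3.0
    outlier_min_clocks: int = 1  # classifier mode: outlier in even one clock


def train_pipeline(scoreset, sheet: pd.DataFrame, config: TrainConfig
                   ) -> Tuple[ClassifierBundle, GridResult]:
    """End-to-end training: EAAd outlier filter (classifier mode, one clock
    suffices) → dataset-pair folds → (α, λ) grid search → final anchor,
    scaler and elastic-net fit on the full training data.  Deterministic:
    identical inputs give identical bundles."""
    train_datasets = sorted(config.train_datasets)
    sheet_tr = sheet[
        sheet["dataset_id"].isin(train_datasets)
        & sheet["tissue"].isin([POSITIVE_TISSUE, NEGATIVE_TISSUE])
    ]
    if sheet_tr.empty:
        raise EaakitError("no training samples in the requested datasets")
    scores = scoreset.scores.loc[scoreset.scores.index.intersection(sheet_tr.index)]
    sheet_tr = sheet_tr.loc[scores.index]

    nonmito = scoreset.nonmitotic_clocks()
    if nonmito and len(scores) >= 2:
        eaad = compute_eaad(scores, sheet_tr, nonmito)
        outliers = set(flag_eaad_outliers(
            eaad, k_sd=config.outlier_k_sd, min_clocks=config.outlier_min_clocks
        ))
        keep = [s for s in scores.index if s not in outliers]
        scores, sheet_tr = scores.loc[keep], sheet_tr.loc[keep]

    folds = make_folds(sheet_tr, require_platform_variation=config.platform_adjust)
    grid = grid_search(
        scores, sheet_tr, folds,
        alpha_grid=config.alpha_grid, lambda_grid=config.lambda_grid,
        platform_adjust=config.platform_adjust,
    )
    anchors = fit_anchors(scores, sheet_tr, config.platform_adjust)
    X, y, scaler = build_features(scores, sheet_tr, anchors)
    fit = fit_elastic_net(
        X.to_numpy(), y.to_numpy(), grid.best_alpha, grid.best_lambda, strict=False
    )
    bundle = ClassifierBundle(
        anchors=anchors,
        scaler=scaler,
        feature_names=list(X.columns),
        coef={c: float(b) for c, b in zip(X.columns, fit.coef)},
        intercept=fit.intercept,
        alpha=grid.best_alpha,
        lam=grid.best_lambda,
        platform_adjust=config.platform_adjust,
        train_datasets=train_datasets,
        train_sample_ids=list(X.index),
    )
    return bundle, grid


@dataclass
class EvalResult:
    roc: pd.DataFrame  # fpr, tpr, threshold
    pr: pd.DataFrame  # recall, precision, threshold
    roc_auc: float
    roc_auc_ci: Tuple[float, float]
    pr_auc: float
    prevalence: float  # PR no-skill baseline (minimum precision line)
    scores: pd.Series
    labels: pd.Series


def evaluate(
    bundle: ClassifierBundle,
    scores: pd.DataFrame,
    sheet: pd.DataFrame,
    filter_outliers: bool = False,
    scoreset=None,
) -> EvalResult:
    """Score held-out samples and compute ROC/PR curves and AUCs.

    The evaluation sheet must be disjoint — at dataset granularity — from the
    bundle's training datasets.  ``filter_outliers`` applies the EAAd screen
    (classifier mode) to the evaluation samples first, which requires the
    ``scoreset`` for clock categories.
    """
    eval_ds = set(sheet["dataset_id"].unique())
    overlap = eval_ds & set(bundle.train_datasets)
    if overlap:
        raise EaakitError(
            f"evaluation datasets overlap training datasets: {sorted(overlap)}"
        )
    if filter_outliers:
        if scoreset is None:
            raise ConfigError("filter_outliers=True needs the scoreset")
        sub = scores.loc[scores.index.intersection(sheet.index)]
        eaad = compute_eaad(sub, sheet.loc[sub.index], scoreset.nonmitotic_clocks())
        out = set(flag_eaad_outliers(eaad, min_clocks=1))
        sheet = sheet.loc[[s for s in sheet.index if s not in out]]
    s, y = bundle.predict_scores(scores, sheet)
    if y.nunique() < 2:
        raise EaakitError("evaluation set contains a single class")
    auc, lo, hi = delong_ci(y.to_numpy(), s.to_numpy())
    fpr, tpr, thr = roc_curve(y, s)
    prec, rec, pthr = precision_recall_curve(y, s)
    return EvalResult(
        roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
        pr=pd.DataFrame(
            {"recall": rec, "precision": prec,
             "threshold": np.append(pthr, np.nan)}
        ),
        roc_auc=auc,
        roc_auc_ci=(lo, hi),
        pr_auc=float(average_precision_score(y, s)),
        prevalence=float(y.mean()),
        scores=s,
        labels=y,
    )
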