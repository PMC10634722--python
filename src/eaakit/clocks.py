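"""Score epigenetic clocks against a beta matrix.

Three clock families are supported, mirroring the common taxonomy of
first-generation, second-generation and mitotic clocks:

* linear clocks (weighted sums of CpG betas with an optional Horvath-style
  inverse transform),
* mean-methylation clocks (plain mean beta over a CpG panel, as used by
  EpiTOC-style hyper- and solo-WCGW hypo-methylation scores),
* mitotic-fit clocks (per-sample cell-division count estimated by least
  squares under the saturating model β_i = a_i + b_i·c_i^n, MiAge-style).

Missing clock CpGs (absent rows or NaN calls) are handled per the
``missing_policy``; per-sample coverage (fraction of clock CpGs observed) is
always reported alongside the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .types import (
    BetaMatrix,
    ClockDefinition,
    ConfigError,
    EaakitError,
    horvath_inverse,
)

MISSING_POLICIES = ("error", "observed-only", "impute-cohort-mean")

#: Coverage below this fraction triggers a recorded warning (not an error).
DEFAULT_COVERAGE_FLOOR = 0.5


@dataclass
class ClockScores:
    """Per-sample scores for one clock, with coverage and any warnings."""

    name: str
    scores: pd.Series  # index sample_id
    coverage: pd.Series  # fraction of the clock's CpGs observed, in [0, 1]
    units: str = "years"
    warnings: List[str] = field(default_factory=list)


@dataclass
class ClockScoreSet:
    """Scores for a battery of clocks: sample × clock frames plus metadata."""

    scores: pd.DataFrame  # sample × clock
    coverage: pd.DataFrame  # sample × clock
    categories: Dict[str, str]  # clock name -> first_gen/second_gen/mitotic
    units: Dict[str, str]
    warnings: Dict[str, List[str]] = field(default_factory=dict)

    def nonmitotic_clocks(self) -> List[str]:
        return [c for c, cat in self.categories.items() if cat != "mitotic"]


def _clock_betas(
    beta: BetaMatrix, clock: ClockDefinition, missing_policy: str
) -> Tuple[np.ndarray, np.ndarray, pd.Series, List[str]]:
    """Align clock CpGs with the matrix.

    Returns (values p×n with NaN for missing, boolean keep-vector over the
    clock's CpG list marking rows present in the matrix, coverage per sample,
    warnings).
    """
    if missing_policy not in MISSING_POLICIES:
        raise ConfigError(
            f"unknown missing_policy {missing_policy!r}; allowed: {list(MISSING_POLICIES)}"
        )
    present = [c for c in clock.cpg_ids if c in beta.values.index]
    if not present:
        raise EaakitError(f"clock {clock.name!r}: none of its CpGs are in the matrix")
    vals = beta.values.loc[present].to_numpy(dtype=float)
    observed = ~np.isnan(vals)
    coverage = pd.Series(
        observed.sum(axis=0) / len(clock.cpg_ids), index=beta.sample_ids, name=clock.name
    )
    warnings: List[str] = []
    if missing_policy == "error":
        if len(present) < len(clock.cpg_ids) or not observed.all():
            raise EaakitError(
                f"clock {clock.name!r}: missing CpG calls under missing_policy='error'"
            )
    if (coverage < DEFAULT_COVERAGE_FLOOR).any():
        n_low = int((coverage < DEFAULT_COVERAGE_FLOOR).sum())
        warnings.append(
            f"{n_low} sample(s) below coverage floor {DEFAULT_COVERAGE_FLOOR}"
        )
    if missing_policy == "impute-cohort-mean" and not observed.all():
        row_mean = np.nanmean(vals, axis=1, keepdims=True)
        vals = np.where(np.isnan(vals), row_mean, vals)
    keep = np.array([c in beta.values.index for c in clock.cpg_ids])
    return vals, keep, coverage, warnings


def score_linear(
    beta: BetaMatrix,
    clock: ClockDefinition,
    missing_policy: str = "observed-only",
) -> ClockScores:
    """raw = intercept + Σ w_i·β_i over observed clock CpGs, then the inverse
    transform.  Under ``observed-only`` missing terms are simply dropped (no
    renormalisation); ``impute-cohort-mean`` fills them with the CpG's mean
    over observed samples."""
    assert clock.kind == "linear"
    vals, keep, coverage, warns = _clock_betas(beta, clock, missing_policy)
    w = clock.weights[keep]
    raw = clock.intercept + np.nansum(w[:, None] * vals, axis=0)
    if clock.transform == "horvath_log":
        score = horvath_inverse(raw, clock.adult_age)
    else:
        score = raw
    return ClockScores(
        clock.name,
        pd.Series(score, index=beta.sample_ids, name=clock.name),
        coverage,
        clock.output_units,
        warns,
    )


def score_mean_beta(
    beta: BetaMatrix,
    clock: ClockDefinition,
    missing_policy: str = "observed-only",
) -> ClockScores:
    """Plain mean beta over the clock's observed CpGs.  The orientation
    (hyper: higher = more divisions; hypo: lower = more divisions) is metadata
    for interpretation only — the score itself is the unmodified mean."""
    assert clock.kind == "mean_beta"
    vals, _, coverage, warns = _clock_betas(beta, clock, missing_policy)
    score = np.nanmean(vals, axis=0)
    return ClockScores(
        clock.name,
        pd.Series(score, index=beta.sample_ids, name=clock.name),
        coverage,
        clock.output_units,
        warns,
    )


def _mitotic_objective(vals: np.ndarray, a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Vectorised SSE objective over candidate division counts.

    ``vals`` is (p,) for one sample with NaN for missing; returns a function
    of an array of n values."""
    ok = ~np.isnan(vals)
    v, aa, bb, cc = vals[ok], a[ok], b[ok], c[ok]

    def f(n: np.ndarray) -> np.ndarray:
        n = np.atleast_1d(np.asarray(n, dtype=float))
        model = aa[None, :] + bb[None, :] * np.power(cc[None, :], n[:, None])
        return np.sum((v[None, :] - model) ** 2, axis=1)

    return f, int(ok.sum())


def estimate_mitotic_age(
    beta: BetaMatrix,
    clock: ClockDefinition,
    n_bounds: Tuple[float, float] = (1.0, 1e4),
    missing_policy: str = "observed-only",
) -> ClockScores:
    """Per-sample division count minimising Σ_i (β_i − (a_i + b_i·c_i^n))².

    A coarse geometric grid brackets the optimum, then bounded 1-D
    minimisation refines it to 1e-6 on n.  A flat model (all b_i = 0) makes
    the objective constant; such samples get the lower bound and a recorded
    non-identifiability warning.
    """
    assert clock.kind == "mitotic_fit"
    lo, hi = n_bounds
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ConfigError(f"invalid n_bounds {n_bounds!r}: need min < max, finite")
    vals, keep, coverage, warns = _clock_betas(beta, clock, missing_policy)
    sp = clock.site_params.loc[[c for c, k in zip(clock.cpg_ids, keep) if k]]
    a = sp["a"].to_numpy(dtype=float)
    b = sp["b"].to_numpy(dtype=float)
    c = sp["c"].to_numpy(dtype=float)

    grid = np.geomspace(lo, hi, 96)
    out = np.empty(beta.n_samples)
    flat_flag = False
    for j in range(beta.n_samples):
        f, n_obs = _mitotic_objective(vals[:, j], a, b, c)
        if n_obs == 0:
            out[j] = np.nan
            continue
        ok = ~np.isnan(vals[:, j])
        if np.all(b[ok] == 0):
            out[j] = lo
            flat_flag = True
            continue
        losses = f(grid)
        k = int(np.argmin(losses))
        blo = grid[max(k - 1, 0)]
        bhi = grid[min(k + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda n: float(f(n)[0]),
            bounds=(blo, bhi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        out[j] = float(np.clip(res.x, lo, hi))
    if flat_flag:
        warns.append("non-identifiable (flat model, all b=0) for some samples; "
                     "lower bound returned")
    return ClockScores(
        clock.name,
        pd.Series(out, index=beta.sample_ids, name=clock.name),
        coverage,
        clock.output_units,
        warns,
    )


_DISPATCH = {
    "linear": score_linear,
    "mean_beta": score_mean_beta,
    "mitotic_fit": estimate_mitotic_age,
}


def score_clock(beta: BetaMatrix, clock: ClockDefinition, **kw) -> ClockScores:
    """Dispatch on clock kind."""
    return _DISPATCH[clock.kind](beta, clock, **kw)


def score_all(
    beta: BetaMatrix,
    clocks: Sequence[ClockDefinition],
    missing_policy: str = "observed-only",
) -> ClockScoreSet:
    """Score every clock; returns a sample × clock frame plus coverage and
    per-clock metadata.  Duplicate clock names are an error."""
    if len(clocks) == 0:
        raise ConfigError("score_all needs at least one clock")
    names = [c.name for c in clocks]
    if len(set(names)) != len(names):
        dup = next(n for n in names if names.count(n) > 1)
        raise ConfigError(f"duplicate clock name {dup!r}")
    scored = [score_clock(beta, c, missing_policy=missing_policy) for c in clocks]
    return ClockScoreSet(
        scores=pd.concat([s.scores for s in scored], axis=1),
        coverage=pd.concat([s.coverage for s in scored], axis=1),
        categories={c.name: c.category for c in clocks},
        units={c.name: c.output_units for c in clocks},
        warnings={s.name: s.warnings for s in scored if s.warnings},
    )
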