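"""Synthetic multi-dataset methylation cohorts with known planted structure.

The generator emulates the shape of a multi-study colon-methylome meta-cohort:
several datasets with their own batch offsets, two array platforms, four
tissue types (healthy, tumour-adjacent normal, tumour, adenoma), paired
tumour/adjacent-normal samples sharing a patient, age-correlated methylation
at a block of "clock" CpGs, and a planted per-tissue epigenetic-age-
acceleration (EAA) shift.  Every planted quantity is recorded in a
:class:`GroundTruth` object so downstream stages can be tested against known
answers.

Methylation model (logit-normal, keeps betas in [0, 1]):

``logit(β_is) = b0_i + m·(CA_s + Δ_s) + m·batch_d + platform + ε_is``

for age-informative CpG *i* in sample *s*, where ``m`` is the methylation
drift per year (logit units), ``Δ_s`` is the sample's true EAA offset in
years (tissue group shift + per-sample jitter), ``batch_d`` is the sample's
dataset random intercept *in years* (applied through the slope so its effect
on any clock is directly interpretable in years) and ``platform`` is an
additive logit offset for EPIC-labelled datasets.  Background CpGs carry the
batch/platform terms but no age signal; a designated sex-probe block has a
mean separation between the sexes; a "mitotic" CpG block follows the
saturating-exponential division model ``β_i = a_i + b_i·c_i^n`` with the
per-sample division count ``n`` tied to the planted EAA offset (not to
chronological age, so mitotic scores are uncorrelated with CA and carry zero
class signal when all group shifts are zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .types import (
    BetaMatrix,
    ClockDefinition,
    ConfigError,
    TISSUES,
    horvath_forward,
)

DEFAULT_TISSUE_PROPORTIONS: Mapping[str, float] = {
    "healthy": 0.40,
    "normal": 0.30,
    "tumour": 0.25,
    "adenoma": 0.05,
}
DEFAULT_GROUP_SHIFT: Mapping[str, float] = {
    "healthy": 0.0,
    "normal": -5.0,
    "tumour": 10.0,
    "adenoma": 5.0,
}

# Per-sample jitter (years) of the true EAA offset around its tissue shift.
EAA_JITTER_SD = 1.0
# Division-count model: n = base + per_year·Δ + jitter, floored at 1.
DIVISION_BASE = 500.0
DIVISIONS_PER_EAA_YEAR = 20.0
DIVISION_JITTER_SD = 25.0
# Sex-probe block: logit(0.7) for females, logit(0.3) for males.
SEX_PROBE_LOGIT = float(logit(0.7))
N_SEX_PROBES = 8
N_MITOTIC_CPGS = 24  # split evenly into a hyper- and a hypo-methylating block


@dataclass(frozen=True)
class SimConfig:
    """Configuration for :func:`simulate_cohort`.

    Defaults give a mid-sized multi-study cohort: 4 datasets of 80 samples,
    ages 30–88, 300 CpGs of which 10% carry age signal at 0.02 logit/year,
    a −5-year EAA shift planted in tumour-adjacent normal tissue, 1.5-year
    dataset batch SD and a small EPIC platform offset.
    """

    n_datasets: int = 4
    samples_per_dataset: int = 80
    tissue_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_PROPORTIONS)
    )
    age_range_years: Tuple[float, float] = (30.0, 88.0)
    n_cpgs: int = 300
    clock_cpg_fraction: float = 0.10
    age_slope_per_year: float = 0.02
    group_shift: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SHIFT)
    )
    batch_sd: float = 1.5
    platform_effect: float = 0.05
    noise_sd: float = 0.05
    paired_fraction: float = 0.5
    missing_rate: float = 0.0
    mask_bad_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_datasets < 1:
            raise ConfigError("n_datasets must be >= 1")
        if self.samples_per_dataset < 1:
            raise ConfigError("samples_per_dataset must be >= 1")
        if self.n_cpgs < 1:
            raise ConfigError("n_cpgs must be >= 1")
        props = dict(self.tissue_proportions)
        unknown = set(props) - set(TISSUES)
        if unknown:
            raise ConfigError(f"tissue_proportions has unknown tissues {sorted(unknown)}")
        vals = list(props.values())
        if any(p < 0 or p > 1 for p in vals):
            raise ConfigError("tissue_proportions entries must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigError(f"tissue_proportions must sum to 1, got {sum(vals)!r}")
        lo, hi = self.age_range_years
        if not (0 < lo < hi):
            raise ConfigError("age_range_years must satisfy 0 < min < max")
        for name in ("batch_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("clock_cpg_fraction", "paired_fraction", "missing_rate", "mask_bad_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        n_clock = max(1, round(self.clock_cpg_fraction * self.n_cpgs))
        if self.n_cpgs < n_clock + N_MITOTIC_CPGS + N_SEX_PROBES:
            raise ConfigError(
                f"n_cpgs too small: need at least {n_clock + N_MITOTIC_CPGS + N_SEX_PROBES} "
                f"CpGs for clock ({n_clock}), mitotic ({N_MITOTIC_CPGS}) and sex "
                f"({N_SEX_PROBES}) blocks"
            )


@dataclass
class GroundTruth:
    """Planted parameters of a simulated cohort (one row per emitted sample)."""

    samples: pd.DataFrame  # index sample_id: true_eaa, divisions, batch_years, ...
    dataset_effects: pd.DataFrame  # index dataset_id: batch_years, platform
    clock_cpg_ids: list
    cpg_params: pd.DataFrame  # index clock CpG: b0, slope_per_year
    mitotic_params: pd.DataFrame  # index mitotic CpG: a, b, c, block
    sex_probe_ids: list
    pairing: pd.DataFrame  # columns tumour_sample_id, normal_sample_id
    age_range: Tuple[float, float]


def _tissue_counts(props: Mapping[str, float], n: int) -> Dict[str, int]:
    """Deterministic largest-remainder apportionment of n samples."""
    raw = {t: props.get(t, 0.0) * n for t in TISSUES}
    counts = {t: math.floor(v) for t, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(TISSUES, key=lambda t: (-(raw[t] - counts[t]), TISSUES.index(t)))
    for t in order[:short]:
        counts[t] += 1
    return counts


def simulate_cohort(config: SimConfig) -> Tuple[BetaMatrix, pd.DataFrame, GroundTruth]:
    """Generate one cohort; identical config + seed gives identical output.

    Returns ``(beta, sheet, ground_truth)`` where ``sheet`` is a validated
    sample sheet indexed by sample_id.  One root pseudo-random stream is
    seeded from ``config.seed``; per-dataset sub-streams are spawned
    deterministically so a dataset's content does not depend on how many
    other datasets are generated after it.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_datasets + 1)
    rng0 = np.random.default_rng(children[0])

    lo, hi = config.age_range_years
    mid_age = 0.5 * (lo + hi)
    m = config.age_slope_per_year

    n_clock = max(1, round(config.clock_cpg_fraction * config.n_cpgs))
    n_bg = config.n_cpgs - n_clock - N_MITOTIC_CPGS - N_SEX_PROBES

    clock_ids = [f"cg{i:07d}" for i in range(n_clock)]
    mito_ids = [f"cg{i:07d}" for i in range(n_clock, n_clock + N_MITOTIC_CPGS)]
    bg_ids = [
        f"cg{i:07d}"
        for i in range(n_clock + N_MITOTIC_CPGS, n_clock + N_MITOTIC_CPGS + n_bg)
    ]
    sex_ids = [f"sexp{i:03d}" for i in range(N_SEX_PROBES)]
    all_ids = clock_ids + mito_ids + bg_ids + sex_ids

    # shared CpG parameters (drawn once, before any dataset sub-stream)
    b0_clock = -m * mid_age + rng0.normal(0.0, 0.3, size=n_clock)
    b0_bg = rng0.normal(0.0, 1.2, size=n_bg)
    half = N_MITOTIC_CPGS // 2
    a_hyper = rng0.uniform(0.75, 0.90, size=half)
    b_hyper = rng0.uniform(0.02, 0.08, size=half) - a_hyper  # rises with n
    a_hypo = rng0.uniform(0.05, 0.15, size=N_MITOTIC_CPGS - half)
    b_hypo = rng0.uniform(0.80, 0.95, size=N_MITOTIC_CPGS - half) - a_hypo  # falls
    c_mito = rng0.uniform(0.9955, 0.9985, size=N_MITOTIC_CPGS)
    mito_a = np.concatenate([a_hyper, a_hypo])
    mito_b = np.concatenate([b_hyper, b_hypo])
    mito_block = ["hyper"] * half + ["hypo"] * (N_MITOTIC_CPGS - half)

    counts = _tissue_counts(config.tissue_proportions, config.samples_per_dataset)

    beta_cols, sheet_rows, gt_rows, pairs = [], [], [], []
    mask_cols = [] if config.mask_bad_rate > 0 else None
    ds_effects = []

    for d in range(config.n_datasets):
        rng = np.random.default_rng(children[d + 1])
        ds = f"DS{d:02d}"
        platform = "450k" if d % 2 == 0 else "EPIC"
        batch_years = rng.normal(0.0, config.batch_sd) if config.batch_sd > 0 else 0.0
        ds_effects.append((ds, batch_years, platform))

        tissues = [t for t in TISSUES for _ in range(counts[t])]
        n_s = len(tissues)
        ages = rng.uniform(lo, hi, size=n_s)
        sexes = np.where(rng.random(n_s) < 0.5, "female", "male")
        sample_ids = [f"{ds}_s{i:04d}" for i in range(n_s)]
        patient_ids = [f"{ds}_p{i:04d}" for i in range(n_s)]

        # pair a fraction of tumours with an adjacent normal from same patient
        t_idx = [i for i, t in enumerate(tissues) if t == "tumour"]
        n_idx = [i for i, t in enumerate(tissues) if t == "normal"]
        n_pair = min(int(round(config.paired_fraction * len(t_idx))), len(n_idx))
        for k in range(n_pair):
            it, im = t_idx[k], n_idx[k]
            patient_ids[im] = patient_ids[it]
            ages[im] = ages[it]
            sexes[im] = sexes[it]
            pairs.append((sample_ids[it], sample_ids[im]))

        shifts = np.array([config.group_shift.get(t, 0.0) for t in tissues])
        # biological dispersion is part of the stochastic regime: a noise-free
        # configuration is exactly deterministic given age and tissue
        jit = EAA_JITTER_SD if config.noise_sd > 0 else 0.0
        div_jit = DIVISION_JITTER_SD if config.noise_sd > 0 else 0.0
        offsets = shifts + rng.normal(0.0, jit, size=n_s)
        divisions = np.maximum(
            DIVISION_BASE
            + DIVISIONS_PER_EAA_YEAR * offsets
            + rng.normal(0.0, div_jit, size=n_s),
            1.0,
        )

        logits = np.empty((config.n_cpgs, n_s))
        eff_age = ages + offsets  # years, per sample
        logits[:n_clock] = b0_clock[:, None] + m * eff_age[None, :]
        mito_beta = np.clip(
            mito_a[:, None] + mito_b[:, None] * np.power(c_mito[:, None], divisions[None, :]),
            1e-6,
            1 - 1e-6,
        )
        logits[n_clock : n_clock + N_MITOTIC_CPGS] = logit(mito_beta)
        logits[n_clock + N_MITOTIC_CPGS : n_clock + N_MITOTIC_CPGS + n_bg] = b0_bg[:, None]
        sex_sign = np.where(sexes == "female", 1.0, -1.0)
        logits[-N_SEX_PROBES:] = SEX_PROBE_LOGIT * sex_sign[None, :]

        logits += m * batch_years  # dataset batch, uniform across CpGs
        if platform == "EPIC":
            logits += config.platform_effect
        if config.noise_sd > 0:
            logits += rng.normal(0.0, config.noise_sd, size=logits.shape)
        betas = expit(logits)

        if config.missing_rate > 0:
            betas = np.where(rng.random(betas.shape) < config.missing_rate, np.nan, betas)
        if mask_cols is not None:
            mask_cols.append(rng.random(betas.shape) < config.mask_bad_rate)

        beta_cols.append(betas)
        for i in range(n_s):
            sheet_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "patient_id": patient_ids[i],
                    "dataset_id": ds,
                    "age_years": ages[i],
                    "sex": sexes[i],
                    "tissue": tissues[i],
                    "platform": platform,
                }
            )
            gt_rows.append(
                {
                    "sample_id": sample_ids[i],
                    "true_eaa": offsets[i],
                    "divisions": divisions[i],
                    "batch_years": batch_years,
                    "dataset_id": ds,
                    "tissue": tissues[i],
                }
            )

    sheet = pd.DataFrame(sheet_rows).set_index("sample_id")
    values = pd.DataFrame(
        np.concatenate(beta_cols, axis=1), index=all_ids, columns=sheet.index
    )
    mask = None
    if mask_cols is not None:
        mask = pd.DataFrame(
            np.concatenate(mask_cols, axis=1), index=all_ids, columns=sheet.index
        )
    beta = BetaMatrix(values, mask)

    gt = GroundTruth(
        samples=pd.DataFrame(gt_rows).set_index("sample_id"),
        dataset_effects=pd.DataFrame(
            ds_effects, columns=["dataset_id", "batch_years", "platform"]
        ).set_index("dataset_id"),
        clock_cpg_ids=clock_ids,
        cpg_params=pd.DataFrame(
            {"b0": b0_clock, "slope_per_year": np.full(n_clock, m)}, index=clock_ids
        ),
        mitotic_params=pd.DataFrame(
            {"a": mito_a, "b": mito_b, "c": c_mito, "block": mito_block}, index=mito_ids
        ),
        sex_probe_ids=sex_ids,
        pairing=pd.DataFrame(pairs, columns=["tumour_sample_id", "normal_sample_id"]),
        age_range=(lo, hi),
    )
    return beta, sheet, gt


def _linear_subset(ids: Sequence[str], i: int) -> list:
    """Deterministic distinct CpG subsets for successive linear clocks."""
    patterns = [
        slice(None),
        slice(0, None, 2),
        slice(1, None, 2),
        slice(0, None, 3),
        slice(1, None, 3),
        slice(2, None, 3),
    ]
    sub = list(ids)[patterns[i % len(patterns)]]
    return sub if sub else list(ids)


def make_fixture_clocks(
    cpg_ids: Sequence[str],
    ground_truth: GroundTruth,
    kinds: Optional[Sequence[str]] = None,
) -> list:
    """Build clock definitions that invert the generator's planted signals.

    ``kinds`` is a list of clock kinds (entries may repeat); each entry yields
    one clock.  Linear clocks invert the linearised logit-normal age model
    around the mid-age operating point (weights ``1/(p·m·β₀(1−β₀))``), so on
    noise-free healthy data EA tracks CA to within sigmoid-curvature error
    (< ~1.5 y at the range ends).  Every second linear clock targets the
    Horvath-transformed age scale to exercise the piecewise-log transform.
    Mean-beta clocks average the hyper-/hypo-methylating mitotic blocks, and
    mitotic-fit clocks reuse the planted (a, b, c) site parameters exactly.
    """
    if kinds is None:
        kinds = ["linear", "linear", "linear", "mean_beta", "mean_beta", "mitotic_fit"]
    unknown = set(kinds) - {"linear", "mean_beta", "mitotic_fit"}
    if unknown:
        raise ConfigError(
            f"unknown clock kind(s) {sorted(unknown)}; supported: "
            "['linear', 'mean_beta', 'mitotic_fit']"
        )
    gt = ground_truth
    known = set(gt.cpg_params.index) | set(gt.mitotic_params.index) | set(gt.sex_probe_ids)
    stray = [c for c in cpg_ids if c not in known]
    if stray:
        raise ConfigError(f"cpg_ids not present in the simulation: {stray[:3]}")
    lin_pool = [c for c in cpg_ids if c in gt.cpg_params.index]
    if not lin_pool:
        lin_pool = list(gt.cpg_params.index)

    lo, hi = gt.age_range
    mid = 0.5 * (lo + hi)
    hyper = gt.mitotic_params[gt.mitotic_params["block"] == "hyper"]
    hypo = gt.mitotic_params[gt.mitotic_params["block"] == "hypo"]

    clocks = []
    n_lin = n_mean = n_mito = 0
    for kind in kinds:
        if kind == "linear":
            sub = _linear_subset(lin_pool, n_lin)
            p = len(sub)
            b0 = gt.cpg_params.loc[sub, "b0"].to_numpy()
            m = gt.cpg_params.loc[sub, "slope_per_year"].to_numpy()
            beta_mid = expit(b0 + m * mid)
            g = m * beta_mid * (1.0 - beta_mid)  # dβ/dage at mid-age
            use_horvath = n_lin % 2 == 1
            if use_horvath:
                # target the transformed scale; ages > adult_age so the
                # forward map is affine and inverts exactly
                adult_age = 20.0
                scale = 1.0 / (adult_age + 1.0)
                w = scale / (p * g)
                intercept = float(
                    horvath_forward(np.array([mid]), adult_age)[0] - np.sum(w * beta_mid)
                )
                clocks.append(
                    ClockDefinition(
                        name=f"sim_lin{n_lin:02d}_horvath",
                        category="second_gen" if n_lin % 2 else "first_gen",
                        kind="linear",
                        cpg_ids=list(sub),
                        weights=w,
                        intercept=intercept,
                        transform="horvath_log",
                        adult_age=adult_age,
                        output_units="years",
                    )
                )
            else:
                w = 1.0 / (p * g)
                intercept = float(mid - np.sum(w * beta_mid))
                clocks.append(
                    ClockDefinition(
                        name=f"sim_lin{n_lin:02d}",
                        category="first_gen" if n_lin == 0 else "second_gen",
                        kind="linear",
                        cpg_ids=list(sub),
                        weights=w,
                        intercept=intercept,
                        transform="identity",
                        output_units="years",
                    )
                )
            n_lin += 1
        elif kind == "mean_beta":
            block = hyper if n_mean % 2 == 0 else hypo
            orientation = "hyper" if n_mean % 2 == 0 else "hypo"
            clocks.append(
                ClockDefinition(
                    name=f"sim_mean_{orientation}{n_mean:02d}",
                    category="mitotic",
                    kind="mean_beta",
                    cpg_ids=list(block.index),
                    orientation=orientation,
                    output_units="score",
                )
            )
            n_mean += 1
        else:  # mitotic_fit
            block = hyper if n_mito % 2 == 0 else hypo
            clocks.append(
                ClockDefinition(
                    name=f"sim_mitotic{n_mito:02d}",
                    category="mitotic",
                    kind="mitotic_fit",
                    cpg_ids=list(block.index),
                    site_params=block[["a", "b", "c"]].copy(),
                    output_units="divisions",
                )
            )
            n_mito += 1
    return clocks
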