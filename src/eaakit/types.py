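"""Core domain types shared across the pipeline.

The central containers are:

* a *sample sheet* — per-sample phenotypes (chronological age, sex, tissue
  type, dataset/patient/platform IDs, optional colon location), the join key
  for every downstream stage;
* a :class:`BetaMatrix` — CpG × sample methylation fractions in [0, 1] with
  an optional boolean low-quality-call mask;
* a :class:`ClockDefinition` — one epigenetic clock's scoring recipe.

Sample sheets are plain :class:`pandas.DataFrame` objects indexed by
``sample_id`` and validated by :func:`validate_sample_sheet`; the beta matrix
carries no phenotype information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

TISSUES = ("healthy", "normal", "tumour", "adenoma")
SEXES = ("female", "male")
PLATFORMS = ("450k", "EPIC")
SIDES = ("left", "right", "unknown")
CLOCK_CATEGORIES = ("first_gen", "second_gen", "mitotic")
CLOCK_KINDS = ("linear", "mean_beta", "mitotic_fit")
TRANSFORMS = ("identity", "horvath_log")
ORIENTATIONS = ("hyper", "hypo")

#: Columns a sample sheet must provide (``sample_id`` is the index).
SHEET_REQUIRED = ("patient_id", "dataset_id", "age_years", "sex", "tissue", "platform")
SHEET_OPTIONAL = ("location", "side")


class EaakitError(Exception):
    """Base class for all package errors."""


class ConfigError(EaakitError):
    """Invalid configuration value; message names the offending field."""


class ParseError(EaakitError):
    """Malformed on-disk artifact; message points at the row/column."""


class SchemaError(EaakitError):
    """Structurally invalid clock definition or model bundle."""


class ConvergenceError(EaakitError):
    """An iterative fit failed to converge within its iteration budget."""


def validate_sample_sheet(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a sample sheet.

    Accepts a frame either indexed by ``sample_id`` or carrying a
    ``sample_id`` column, and returns a copy indexed by ``sample_id`` with
    vocabulary columns checked against the closed vocabularies.  A patient
    must never span two datasets (dataset-level train/test splits rely on
    this), ages must be positive and sample IDs unique.
    """
    df = df.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"duplicate sample_id {dup!r} in sample sheet")
    missing = [c for c in SHEET_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"sample sheet lacks required columns: {missing}")

    df["age_years"] = pd.to_numeric(df["age_years"], errors="raise")
    if (df["age_years"] <= 0).any():
        bad = df.index[df["age_years"] <= 0][0]
        raise ParseError(f"non-positive age_years for sample {bad!r}")

    for col, vocab in (("sex", SEXES), ("tissue", TISSUES), ("platform", PLATFORMS)):
        bad = set(df[col].dropna().unique()) - set(vocab)
        if bad:
            raise ParseError(
                f"unknown {col} label(s) {sorted(bad)}; allowed: {list(vocab)}"
            )

    # a patient never spans two datasets
    span = df.groupby("patient_id")["dataset_id"].nunique()
    if (span > 1).any():
        pid = span.index[span > 1][0]
        raise ParseError(f"patient {pid!r} spans more than one dataset")

    if "side" in df.columns:
        bad = set(df["side"].dropna().unique()) - set(SIDES)
        if bad:
            raise ParseError(f"unknown side label(s) {sorted(bad)}; allowed: {list(SIDES)}")
    return df


@dataclass
class BetaMatrix:
    """CpG × sample matrix of methylation beta values.

    ``values`` is indexed by CpG ID with sample IDs as columns; entries are
    methylation fractions in [0, 1], ``NaN`` marking missing calls.  ``mask``
    (same shape, boolean) marks low-quality calls — the stand-in for
    detection-p / bead-count flags that cannot be recomputed from betas.
    """

    values: pd.DataFrame
    mask: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            raise ParseError(f"duplicate CpG id {v.index[v.index.duplicated()][0]!r}")
        if v.columns.duplicated().any():
            raise ParseError(
                f"duplicate sample id {v.columns[v.columns.duplicated()][0]!r}"
            )
        arr = v.to_numpy(dtype=float)
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ParseError(
                f"beta value {arr[i, j]!r} outside [0,1] at CpG {v.index[i]!r}, "
                f"sample {v.columns[j]!r}"
            )
        if self.mask is not None:
            m = self.mask
            if not (m.index.equals(v.index) and m.columns.equals(v.columns)):
                raise ParseError("quality mask dimensions do not match beta matrix")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        ids = list(sample_ids)
        return BetaMatrix(
            self.values[ids],
            None if self.mask is None else self.mask[ids],
        )

    def select_cpgs(self, cpg_ids: Sequence[str]) -> "BetaMatrix":
        ids = list(cpg_ids)
        return BetaMatrix(
            self.values.loc[ids],
            None if self.mask is None else self.mask.loc[ids],
        )


@dataclass
class ClockDefinition:
    """One clock's scoring recipe.

    ``kind`` selects the scoring rule:

    * ``linear`` — ``raw = intercept + Σ w_i·β_i`` followed by the inverse
      ``transform`` (``identity`` or the Horvath-style piecewise log with its
      ``adult_age`` knot);
    * ``mean_beta`` — the plain mean beta over ``cpg_ids``; ``orientation``
      records whether higher (``hyper``) or lower (``hypo``) methylation
      means more accumulated cell divisions;
    * ``mitotic_fit`` — per-sample division count ``n`` minimising
      ``Σ_i (β_i − (a_i + b_i·c_i^n))²`` given per-CpG ``site_params``.
    """

    name: str
    category: str
    kind: str
    cpg_ids: list = field(default_factory=list)
    weights: Optional[np.ndarray] = None
    intercept: float = 0.0
    transform: str = "identity"
    adult_age: float = 20.0
    orientation: Optional[str] = None
    site_params: Optional[pd.DataFrame] = None  # columns a, b, c indexed by CpG
    output_units: str = "years"

    def __post_init__(self) -> None:
        if self.category not in CLOCK_CATEGORIES:
            raise SchemaError(
                f"clock {self.name!r}: unknown category {self.category!r}; "
                f"allowed: {list(CLOCK_CATEGORIES)}"
            )
        if self.kind not in CLOCK_KINDS:
            raise SchemaError(
                f"clock {self.name!r}: unknown kind {self.kind!r}; "
                f"allowed: {list(CLOCK_KINDS)}"
            )
        if len(self.cpg_ids) == 0 and self.kind != "mitotic_fit":
            raise SchemaError(f"clock {self.name!r}: empty CpG list")
        if self.kind == "linear":
            if self.weights is None:
                raise SchemaError(f"clock {self.name!r}: linear clock lacks weights")
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.cpg_ids):
                raise SchemaError(
                    f"clock {self.name!r}: {len(self.weights)} weights for "
                    f"{len(self.cpg_ids)} CpGs"
                )
            if self.transform not in TRANSFORMS:
                raise SchemaError(
                    f"clock {self.name!r}: unknown transform {self.transform!r}"
                )
        elif self.kind == "mean_beta":
            if self.orientation not in ORIENTATIONS:
                raise SchemaError(
                    f"clock {self.name!r}: mean_beta clock needs orientation in "
                    f"{list(ORIENTATIONS)}, got {self.orientation!r}"
                )
        elif self.kind == "mitotic_fit":
            sp = self.site_params
            if sp is None or not {"a", "b", "c"}.issubset(sp.columns):
                raise SchemaError(
                    f"clock {self.name!r}: mitotic_fit clock needs site_params "
                    "with columns a, b, c"
                )
            c = sp["c"].to_numpy(dtype=float)
            if np.any(~np.isfinite(sp.to_numpy(dtype=float))):
                bad = sp.index[~np.isfinite(sp.to_numpy(dtype=float)).any(axis=1)][0]
                raise SchemaError(f"clock {self.name!r}: non-finite parameter at CpG {bad!r}")
            if np.any(c <= 0) or np.any(np.abs(c - 1.0) < 1e-6):
                bad = sp.index[(c <= 0) | (np.abs(c - 1.0) < 1e-6)][0]
                raise SchemaError(
                    f"clock {self.name!r}: decay base c must be positive and "
                    f"bounded away from 1 (CpG {bad!r})"
                )
            if not self.cpg_ids:
                self.cpg_ids = list(sp.index)


def horvath_forward(age: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Map age to the Horvath-transformed scale (log below the adult knot)."""
    age = np.asarray(age, dtype=float)
    lo = np.log((age + 1.0) / (adult_age + 1.0))
    hi = (age - adult_age) / (adult_age + 1.0)
    return np.where(age <= adult_age, lo, hi)


def horvath_inverse(raw: np.ndarray, adult_age: float = 20.0) -> np.ndarray:
    """Inverse of :func:`horvath_forward`: raw ≤ 0 → (1+A)·exp(raw) − 1,
    raw > 0 → (1+A)·raw + A."""
    raw = np.asarray(raw, dtype=float)
    lo = (1.0 + adult_age) * np.exp(raw) - 1.0
    hi = (1.0 + adult_age) * raw + adult_age
    return np.where(raw <= 0, lo, hi)
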