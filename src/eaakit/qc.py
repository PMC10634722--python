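"""Sample/probe quality filtering, sex-consistency checks and colon-side mapping.

Detection p-values and bead counts are not recoverable from beta values, so
the filters operate on a boolean low-quality-call mask carried by the
:class:`~eaakit.types.BetaMatrix` (missing calls count too — the union of
missing and masked entries is what the 1% rules see).  Both thresholds use a
strict ``>`` comparison: a sample or probe sitting exactly at the 1% boundary
is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import BetaMatrix, EaakitError

EXCLUSION_REASONS = ("low_quality_fraction", "sex_mismatch", "missing_probe_fraction")

# splenic flexure drains left; hepatic flexure right — per the standard
# anatomical split used in colon methylation studies
LEFT_SITES = frozenset(
    {"descending colon", "rectosigmoid junction", "rectum", "sigmoid", "splenic flexure"}
)
RIGHT_SITES = frozenset(
    {"ascending colon", "caecum", "hepatic flexure", "transverse colon"}
)


@dataclass
class QCReport:
    """Which samples/probes were excluded, why, and with what thresholds."""

    excluded_samples: List[Tuple[str, str]] = field(default_factory=list)
    excluded_probes: List[Tuple[str, str]] = field(default_factory=list)
    thresholds: Dict[str, float] = field(default_factory=dict)
    details: Dict[str, float] = field(default_factory=dict)  # id -> offending fraction
    ambiguous_sex: List[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", s, r, self.details.get(s, np.nan)) for s, r in self.excluded_samples]
        rows += [("probe", p, r, self.details.get(p, np.nan)) for p, r in self.excluded_probes]
        return pd.DataFrame(rows, columns=["kind", "id", "reason", "fraction"])


def _bad_matrix(beta: BetaMatrix) -> np.ndarray:
    """Union of missing and masked (low-quality) calls."""
    bad = np.isnan(beta.values.to_numpy(dtype=float))
    if beta.mask is not None:
        bad |= beta.mask.to_numpy(dtype=bool)
    return bad


def filter_samples(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    max_bad_probe_fraction: float = 0.01,
) -> Tuple[BetaMatrix, QCReport]:
    """Drop samples whose fraction of low-quality/missing probe calls strictly
    exceeds the threshold (default 1%).  Requires a quality mask — without
    one the rule has no inputs; pass a mask or skip this step explicitly."""
    if beta.mask is None:
        raise EaakitError(
            "filter_samples needs a quality mask; supply BetaMatrix.mask or "
            "skip sample filtering explicitly"
        )
    bad = _bad_matrix(beta)
    frac = bad.mean(axis=0)
    report = QCReport(thresholds={"max_bad_probe_fraction": max_bad_probe_fraction})
    keep = []
    for j, sid in enumerate(beta.sample_ids):
        if frac[j] > max_bad_probe_fraction:
            report.excluded_samples.append((sid, "low_quality_fraction"))
            report.details[sid] = float(frac[j])
        else:
            keep.append(sid)
    return beta.select_samples(keep), report


def filter_probes(
    beta: BetaMatrix,
    max_bad_sample_fraction: float = 0.01,
) -> Tuple[BetaMatrix, QCReport]:
    """Drop probes missing or masked in strictly more than the threshold
    fraction of samples (default 1%)."""
    bad = _bad_matrix(beta)
    frac = bad.mean(axis=1)
    report = QCReport(thresholds={"max_bad_sample_fraction": max_bad_sample_fraction})
    keep = []
    for i, cpg in enumerate(beta.cpg_ids):
        if frac[i] > max_bad_sample_fraction:
            report.excluded_probes.append((cpg, "missing_probe_fraction"))
            report.details[cpg] = float(frac[i])
        else:
            keep.append(cpg)
    return beta.select_cpgs(keep), report


def infer_sex(
    beta: BetaMatrix,
    sex_probe_ids: Sequence[str],
    threshold: float = 0.5,
) -> Tuple[Dict[str, str], List[str]]:
    """Classify each sample by its mean beta over designated sex probes.

    Mean > threshold → female, < threshold → male; a mean exactly at the
    threshold is assigned female and flagged ambiguous.  Returns
    ``(inferred, ambiguous_sample_ids)``.
    """
    present = [p for p in sex_probe_ids if p in beta.values.index]
    if not present:
        raise EaakitError("none of the designated sex probes are in the matrix")
    means = beta.values.loc[present].mean(axis=0, skipna=True)
    inferred, ambiguous = {}, []
    for sid, mval in means.items():
        if mval >= threshold:
            inferred[sid] = "female"
            if mval == threshold:
                ambiguous.append(sid)
        else:
            inferred[sid] = "male"
    return inferred, ambiguous


def check_sex_consistency(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    sex_probe_ids: Sequence[str],
    threshold: float = 0.5,
) -> Tuple[BetaMatrix, QCReport]:
    """Drop samples whose reported sex disagrees with the probe-inferred sex."""
    inferred, ambiguous = infer_sex(beta, sex_probe_ids, threshold)
    report = QCReport(thresholds={"sex_threshold": threshold}, ambiguous_sex=ambiguous)
    keep = []
    for sid in beta.sample_ids:
        reported = sheet.loc[sid, "sex"] if sid in sheet.index else None
        if reported is not None and inferred.get(sid) != reported:
            report.excluded_samples.append((sid, "sex_mismatch"))
        else:
            keep.append(sid)
    return beta.select_samples(keep), report


def map_colon_side(location: Optional[str]) -> str:
    """Map a free-text colon location to left/right/unknown by
    case-insensitive exact match against the standard anatomical lists."""
    if location is None or (isinstance(location, float) and np.isnan(location)):
        return "unknown"
    loc = str(location).strip().lower()
    if loc in LEFT_SITES:
        return "left"
    if loc in RIGHT_SITES:
        return "right"
    return "unknown"


def run_qc(
    beta: BetaMatrix,
    sheet: pd.DataFrame,
    max_bad_probe_fraction: float = 0.01,
    max_bad_sample_fraction: float = 0.01,
    sex_probe_ids: Optional[Sequence[str]] = None,
    sex_threshold: float = 0.5,
) -> Tuple[BetaMatrix, pd.DataFrame, QCReport]:
    """Full QC pass: sample filter, optional sex check, then probe filter
    (samples first, then probes).  Returns the filtered matrix, the sheet
    restricted to retained samples, and a merged report."""
    merged = QCReport(
        thresholds={
            "max_bad_probe_fraction": max_bad_probe_fraction,
            "max_bad_sample_fraction": max_bad_sample_fraction,
        }
    )
    if beta.mask is not None:
        beta, rep = filter_samples(beta, sheet, max_bad_probe_fraction)
        merged.excluded_samples += rep.excluded_samples
        merged.details.update(rep.details)
    if sex_probe_ids is not None:
        beta, rep = check_sex_consistency(beta, sheet, sex_probe_ids, sex_threshold)
        merged.excluded_samples += rep.excluded_samples
        merged.ambiguous_sex = rep.ambiguous_sex
    beta, rep = filter_probes(beta, max_bad_sample_fraction)
    merged.excluded_probes += rep.excluded_probes
    merged.details.update(rep.details)
    sheet = sheet.loc[[s for s in sheet.index if s in set(beta.sample_ids)]]
    return beta, sheet, merged
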