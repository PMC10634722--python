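"""Readers and writers for all on-disk artifacts.

Formats are deliberately plain text and diff-friendly:

* beta matrix — TSV, CpG rows × sample columns, header row of sample IDs,
  missing cells encoded ``NA`` (transparently gzipped when the path ends in
  ``.gz``);
* sample sheet — CSV with a ``sample_id`` column;
* clock definitions — one CSV per clock: ``#key=value`` metadata header
  lines followed by the CpG table (columns depending on the clock kind);
* score sets, EAA tables, ground truth — CSV;
* run log — JSON lines, one record per pipeline invocation (config hash,
  seed, input checksums, sample/probe counts in and out) for exact re-runs.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import qc as _qc
from .clocks import ClockScoreSet
from .types import BetaMatrix, ClockDefinition, ParseError, SchemaError, validate_sample_sheet

PathLike = Union[str, Path]
_FLOAT_FMT = "%.12g"  # >= 10 significant digits for lossless round-trips


def _open_text(path: PathLike, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


# ---------------------------------------------------------------------------
# beta matrix

def write_beta_matrix(beta: BetaMatrix, path: PathLike,
                      mask_path: Optional[PathLike] = None) -> None:
    with _open_text(path, "w") as fh:
        beta.values.to_csv(fh, sep="\t", na_rep="NA", index_label="cpg_id",
                           float_format=_FLOAT_FMT)
    if mask_path is not None and beta.mask is not None:
        with _open_text(mask_path, "w") as fh:
            beta.mask.astype(int).to_csv(fh, sep="\t", index_label="cpg_id")


def read_beta_matrix(path: PathLike, mask_path: Optional[PathLike] = None) -> BetaMatrix:
    with _open_text(path, "r") as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = next(v for v in df[col] if not _is_number(v))
            row = df.index[[not _is_number(v) for v in df[col]]][0]
            raise ParseError(
                f"non-numeric beta value {bad!r} at CpG {row!r}, sample {col!r}"
            )
    arr = df.to_numpy(dtype=float)
    out = (arr < 0) | (arr > 1)
    out &= ~np.isnan(arr)
    if out.any():
        i, j = np.argwhere(out)[0]
        raise ParseError(
            f"beta value {arr[i, j]!r} outside [0,1] at CpG {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    mask = None
    if mask_path is not None:
        with _open_text(mask_path, "r") as fh:
            mask = pd.read_csv(fh, sep="\t", index_col=0).astype(bool)
        mask.index = mask.index.astype(str)
        mask.columns = mask.columns.astype(str)
    return BetaMatrix(df, mask)


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# sample sheet

def write_sample_sheet(sheet: pd.DataFrame, path: PathLike) -> None:
    sheet.to_csv(path, index_label="sample_id", float_format=_FLOAT_FMT)


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError("sample sheet lacks a sample_id column")
    df = validate_sample_sheet(df)
    # derive side from location when absent
    if "side" not in df.columns:
        if "location" in df.columns:
            df["side"] = df["location"].map(_qc.map_colon_side)
        else:
            df["side"] = pd.NA
    else:
        fill = df["side"].isna()
        if "location" in df.columns and fill.any():
            df.loc[fill, "side"] = df.loc[fill, "location"].map(_qc.map_colon_side)
    return df


# ---------------------------------------------------------------------------
# clock definitions

def write_clock_definition(clock: ClockDefinition, path: PathLike) -> None:
    meta = {
        "name": clock.name,
        "category": clock.category,
        "kind": clock.kind,
        "output_units": clock.output_units,
    }
    if clock.kind == "linear":
        meta["intercept"] = repr(float(clock.intercept))
        meta["transform"] = clock.transform
        meta["adult_age"] = repr(float(clock.adult_age))
        table = pd.DataFrame({"cpg_id": clock.cpg_ids, "weight": clock.weights})
    elif clock.kind == "mean_beta":
        meta["orientation"] = clock.orientation
        table = pd.DataFrame({"cpg_id": clock.cpg_ids})
    else:
        table = clock.site_params.reset_index().rename(columns={"index": "cpg_id"})
        table.columns = ["cpg_id", "a", "b", "c"]
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"#{k}={v}\n")
        table.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_clock_definition(path: PathLike) -> ClockDefinition:
    meta: Dict[str, str] = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "=" not in line:
                    raise ParseError(f"{path}: malformed metadata line {line.strip()!r}")
                k, v = line[1:].strip().split("=", 1)
                meta[k] = v
            else:
                lines.append(line)
    for req in ("name", "kind", "category"):
        if req not in meta:
            raise SchemaError(f"{path}: clock file lacks {req!r} metadata")
    from io import StringIO

    table = pd.read_csv(StringIO("".join(lines)))
    if "cpg_id" not in table.columns:
        raise SchemaError(f"{path}: clock table lacks cpg_id column")
    kind = meta["kind"]
    kw = dict(
        name=meta["name"],
        category=meta["category"],
        kind=kind,
        cpg_ids=[str(c) for c in table["cpg_id"]],
        output_units=meta.get("output_units", "years"),
    )
    if kind == "linear":
        if "weight" not in table.columns:
            raise SchemaError(f"{path}: linear clock lacks a weight column")
        kw.update(
            weights=table["weight"].to_numpy(dtype=float),
            intercept=float(meta.get("intercept", 0.0)),
            transform=meta.get("transform", "identity"),
            adult_age=float(meta.get("adult_age", 20.0)),
        )
    elif kind == "mean_beta":
        kw.update(orientation=meta.get("orientation"))
    elif kind == "mitotic_fit":
        missing = {"a", "b", "c"} - set(table.columns)
        if missing:
            raise SchemaError(
                f"{path}: mitotic_fit clock lacks column(s) {sorted(missing)}"
            )
        kw.update(
            site_params=table.set_index("cpg_id")[["a", "b", "c"]].astype(float)
        )
    return ClockDefinition(**kw)


def read_clock_definitions(path: PathLike) -> List[ClockDefinition]:
    """Read one clock CSV, or every ``*.csv`` in a directory (sorted)."""
    path = Path(path)
    if path.is_dir():
        return [read_clock_definition(p) for p in sorted(path.glob("*.csv"))]
    return [read_clock_definition(path)]


def write_clock_definitions(clocks: Sequence[ClockDefinition], out_dir: PathLike) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for clock in clocks:
        write_clock_definition(clock, out_dir / f"{clock.name}.csv")


# ---------------------------------------------------------------------------
# score sets

def write_scoreset(scoreset: ClockScoreSet, out_dir: PathLike) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scoreset.scores.to_csv(out_dir / "scores.csv", index_label="sample_id",
                           float_format=_FLOAT_FMT)
    scoreset.coverage.to_csv(out_dir / "coverage.csv", index_label="sample_id",
                             float_format=_FLOAT_FMT)
    meta = pd.DataFrame(
        {
            "clock": list(scoreset.categories),
            "category": [scoreset.categories[c] for c in scoreset.categories],
            "units": [scoreset.units.get(c, "") for c in scoreset.categories],
        }
    )
    meta.to_csv(out_dir / "clock_meta.csv", index=False)


def read_scoreset(out_dir: PathLike) -> ClockScoreSet:
    out_dir = Path(out_dir)
    scores = pd.read_csv(out_dir / "scores.csv", index_col=0)
    coverage = pd.read_csv(out_dir / "coverage.csv", index_col=0)
    meta = pd.read_csv(out_dir / "clock_meta.csv")
    return ClockScoreSet(
        scores=scores,
        coverage=coverage,
        categories=dict(zip(meta["clock"], meta["category"])),
        units=dict(zip(meta["clock"], meta["units"])),
    )


# ---------------------------------------------------------------------------
# run log

def file_checksum(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def append_run_log(
    out_dir: PathLike,
    command: str,
    config: dict,
    seed: Optional[int] = None,
    inputs: Optional[Sequence[PathLike]] = None,
    counts: Optional[Dict[str, int]] = None,
) -> None:
    """Append one JSON-lines record to ``<out_dir>/run_log.jsonl``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(config, sort_keys=True, default=str)
    record = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "command": command,
        "config": config,
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "inputs": {
            str(p): file_checksum(p) for p in (inputs or []) if Path(p).exists()
        },
        "counts": counts or {},
    }
    with open(out_dir / "run_log.jsonl", "a") as fh:
        fh.write(json.dumps(record, default=str) + "\n")
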