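"""Reading and writing the plain-text interchange formats.

Parcellated BOLD runs are TSV (volumes x networks, header row of network
labels); motion traces are TSV (volumes x 6, columns tx,ty,tz,rx,ry,rz);
phenotypes are CSV with one row per subject.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .motion import MotionTrace
from .simulate import ParcellatedRun

MOTION_COLUMNS = ("tx", "ty", "tz", "rx", "ry", "rz")
_RUN_RE = re.compile(r"sub-(?P<sub>[^_]+)_run-(?P<run>[^_]+)_(?P<kind>bold|motion)\.tsv$")


def _read_numeric_tsv(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) != len(set(header)) or any(not h.strip() for h in header):
        raise ValueError(f"{path}: duplicate or missing column labels")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((converted.isna()).idxmax())
            raise ValueError(
                f"{path}: non-numeric or missing value at row {row}, column {col!r}"
            )
        out[col] = converted.to_numpy(dtype=float)
    return pd.DataFrame(out)


def read_parcellated_run(path, subject_id: str = "", run_id: str = "",
                         tr_seconds: float = float("nan"),
                         motion: MotionTrace | None = None) -> ParcellatedRun:
    """Load one volumes x networks BOLD TSV (header = network labels)."""
    path = Path(path)
    df = _read_numeric_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 network columns")
    if not subject_id or not run_id:
        m = _RUN_RE.search(path.name)
        if m:
            subject_id = subject_id or f"sub-{m.group('sub')}"
            run_id = run_id or f"run-{m.group('run')}"
    return ParcellatedRun(
        subject_id=subject_id or path.stem,
        run_id=run_id or "run-1",
        data=df.to_numpy(),
        motion=motion,
        tr_seconds=tr_seconds,
        labels=tuple(df.columns),
    )


def write_parcellated_run(run: ParcellatedRun, path) -> None:
    pd.DataFrame(run.data, columns=list(run.labels)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_motion_trace(path, subject_id: str = "", run_id: str = "") -> MotionTrace:
    """Load one volumes x 6 motion TSV (tx,ty,tz in mm; rx,ry,rz in rad)."""
    path = Path(path)
    df = _read_numeric_tsv(path)
    if tuple(df.columns) != MOTION_COLUMNS:
        raise ValueError(
            f"{path}: motion columns must be {','.join(MOTION_COLUMNS)}"
        )
    if not subject_id or not run_id:
        m = _RUN_RE.search(path.name)
        if m:
            subject_id = subject_id or f"sub-{m.group('sub')}"
            run_id = run_id or f"run-{m.group('run')}"
    return MotionTrace(
        subject_id=subject_id or path.stem, run_id=run_id or "run-1",
        params=df.to_numpy(),
    )


def write_motion_trace(trace: MotionTrace, path) -> None:
    pd.DataFrame(trace.params, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_cohort(runs: dict, phenotypes: pd.DataFrame, truth: pd.DataFrame,
                 out_dir) -> None:
    """Write a simulated cohort in the on-disk layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, subj_runs in runs.items():
        for run in subj_runs:
            stem = f"{sid}_{run.run_id}"
            write_parcellated_run(run, out / f"{stem}_bold.tsv")
            write_motion_trace(run.motion, out / f"{stem}_motion.tsv")
    phenotypes.to_csv(out / "phenotypes.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)


def discover_runs(bold_dir, motion_dir=None) -> dict:
    """Map subject id -> sorted list of (bold path, motion path or None)."""
    bold_dir = Path(bold_dir)
    motion_dir = Path(motion_dir) if motion_dir is not None else bold_dir
    found = {}
    for p in sorted(bold_dir.glob("sub-*_run-*_bold.tsv")):
        m = _RUN_RE.search(p.name)
        if not m:
            continue
        sid = f"sub-{m.group('sub')}"
        motion = motion_dir / p.name.replace("_bold.tsv", "_motion.tsv")
        found.setdefault(sid, []).append((p, motion if motion.exists() else None))
    if not found:
        raise FileNotFoundError(f"no sub-*_run-*_bold.tsv files under {bold_dir}")
    return found
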