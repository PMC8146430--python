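"""Delimited-text containers for cohorts, matrices and reports.

The native on-disk format is deliberately plain: one whitespace-delimited
numeric matrix per subject (ROIs x samples) or per connectivity matrix,
plus a JSON manifest carrying subject ids, group labels, sampling rate and
trial indices.  The same container is both the generator's output and the
pipeline's file-mode input.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .containers import RoiTimeSeries, SubjectRecord, ValidationError

MANIFEST_NAME = "manifest.json"


def write_cohort(records: Iterable[SubjectRecord], out_dir: str | Path) -> Path:
    """Write one matrix file per subject plus a cohort manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in records:
        fname = f"{rec.subject_id}.txt"
        np.savetxt(out / fname, rec.timeseries.data, fmt="%.8g")
        entries.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "fs": rec.timeseries.fs,
            "trial_index": rec.timeseries.trial_index,
            "file": fname,
        })
    manifest = out / MANIFEST_NAME
    manifest.write_text(json.dumps({"subjects": entries}, indent=1))
    return manifest


def read_cohort(in_dir: str | Path) -> Iterator[SubjectRecord]:
    """Stream subjects back from a directory written by :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = root / MANIFEST_NAME
    if not manifest.exists():
        raise ValidationError(f"no {MANIFEST_NAME} in {root}")
    meta = json.loads(manifest.read_text())
    for entry in meta["subjects"]:
        data = np.loadtxt(root / entry["file"], ndmin=2)
        ts = RoiTimeSeries(data=data, fs=float(entry["fs"]),
                           subject_id=entry["subject_id"],
                           trial_index=entry.get("trial_index"))
        yield SubjectRecord(subject_id=entry["subject_id"],
                            group=entry["group"], timeseries=ts)


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.8g")


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=2)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")
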