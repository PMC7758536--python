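"""Plain-text file formats for every pipeline artifact.

ROI time series travel as TSV (header row of ROI labels, one row per
frame) with a JSON sidecar carrying TR and subject id; motion as 6-column
whitespace files in the realignment-parameter dialect (3 translations in
mm, 3 rotations in radians); connectivity matrices as labeled square TSV;
edge statistics as long-format TSV (roi_i, roi_j, value columns); subject
tables as CSV.  Every writer can stamp a provenance record (config hash,
seed) into the sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, EdgeStatMap, RoiTimeSeries, SubjectRecord, edge_index_pairs

__all__ = [
    "read_roi_timeseries",
    "write_roi_timeseries",
    "read_motion",
    "write_motion",
    "read_subject_table",
    "write_subject_table",
    "read_connectivity",
    "write_connectivity",
    "write_edge_stats",
    "read_edge_stats",
    "config_hash",
]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_roi_timeseries(ts: RoiTimeSeries, path, provenance: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(ts.data, columns=ts.roi_labels).to_csv(path, sep="\t", index=False, float_format="%.6g")
    meta = {"tr_seconds": ts.tr_seconds, "subject_id": ts.subject_id}
    meta.update(provenance or {})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_roi_timeseries(path, tr_seconds: float | None = None) -> RoiTimeSeries:
    """Read a frames x ROIs TSV; TR from the sidecar unless given."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        labels = header.split("\t")
        if not labels or any(_is_number(c) for c in labels):
            raise ValueError(f"{path}:1: expected a header row of ROI labels")
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}:1: duplicate ROI labels")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            cells = line.rstrip("\n").split("\t")
            if len(cells) != len(labels):
                raise ValueError(f"{path}:{lineno}: {len(cells)} cells, expected {len(labels)}")
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(c for c in cells if not _is_number(c))
                raise ValueError(f"{path}:{lineno}: non-numeric cell {bad!r}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    tr = tr_seconds if tr_seconds is not None else meta.get("tr_seconds")
    if tr is None:
        raise ValueError(f"{path}: TR not given and no sidecar {sidecar.name}")
    return RoiTimeSeries(np.asarray(rows), float(tr), labels, meta.get("subject_id", path.stem))


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_motion(motion: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(motion, dtype=float), fmt="%.8g")


def read_motion(path) -> np.ndarray:
    m = np.loadtxt(path, ndmin=2)
    if m.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 motion columns, found {m.shape[1]}")
    return m


_SUBJECT_COLS = [
    "subject_id", "group", "age", "sex", "yoe", "race", "pss", "psy",
    "rms_motion_mm", "n_fights", "years_fighting", "knockouts", "motion_file",
]


def write_subject_table(subjects: list[SubjectRecord], path) -> None:
    rows = [{c: getattr(s, c) for c in _SUBJECT_COLS} for s in subjects]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subject_table(path) -> list[SubjectRecord]:
    df = pd.read_csv(path)
    missing = {"subject_id", "group", "age", "sex", "yoe", "race", "pss"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _SUBJECT_COLS if c in df.columns and pd.notna(row.get(c))}
        kwargs["subject_id"] = str(kwargs["subject_id"])
        kwargs["sex"] = int(kwargs["sex"])
        kwargs["race"] = int(kwargs["race"])
        out.append(SubjectRecord(**kwargs))
    return out


def write_connectivity(cm: ConnectivityMatrix, path, provenance: dict | None = None) -> None:
    path = Path(path)
    pd.DataFrame(cm.values, index=cm.roi_labels, columns=cm.roi_labels).to_csv(
        path, sep="\t", float_format="%.8g"
    )
    meta = {"kind": cm.kind, "subject_id": cm.subject_id}
    meta.update(cm.meta)
    meta.update(provenance or {})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_connectivity(path, kind: str | None = None) -> ConnectivityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    k = kind or meta.get("kind")
    if k is None:
        raise ValueError(f"{path}: connectivity kind not given and no sidecar")
    extra = {key: v for key, v in meta.items() if key not in ("kind", "subject_id")}
    return ConnectivityMatrix(df.values, k, list(df.columns), meta.get("subject_id", path.stem), meta=extra)


def write_edge_stats(stat: EdgeStatMap, roi_labels: list[str], path) -> None:
    iu, ju = edge_index_pairs(stat.n_roi)
    pd.DataFrame(
        {
            "roi_i": [roi_labels[i] for i in iu],
            "roi_j": [roi_labels[j] for j in ju],
            "t": stat.t,
            "p_unc": stat.p_unc,
            "d": stat.d,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_edge_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"roi_i", "roi_j", "t", "p_unc", "d"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return df
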