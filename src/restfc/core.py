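"""Core in-memory containers shared across the pipeline.

The connectome is treated as an undirected graph on ``n_roi`` nodes; every
edge-valued quantity (connectivity, t statistic, effect size) is stored as a
flat vector over the unique edges in upper-triangular row-major order, i.e.
the order produced by ``numpy.triu_indices(n_roi, 1)``. All modules share
this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RoiTimeSeries",
    "SubjectRecord",
    "ConnectivityMatrix",
    "EdgeStatMap",
    "edge_index_pairs",
    "n_edges",
]

GROUPS = ("nc", "non_impaired", "impaired")


def n_edges(n_roi: int) -> int:
    """Number of unique (unordered, off-diagonal) ROI pairs."""
    return n_roi * (n_roi - 1) // 2


def edge_index_pairs(n_roi: int) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) node indices of the unique edges, i < j, row-major."""
    return np.triu_indices(n_roi, 1)


@dataclass
class RoiTimeSeries:
    """One subject's parcellated BOLD signal: frames x ROIs plus timing.

    ``data[t, r]`` is the (arbitrary-unit) signal of ROI ``r`` at frame
    ``t``; frame timestamps are ``t * tr_seconds`` starting at zero.
    """

    data: np.ndarray
    tr_seconds: float
    roi_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-series data must be 2-D (frames x ROIs)")
        if self.data.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_labels)} ROI labels"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_roi(self) -> int:
        return self.data.shape[1]


@dataclass
class SubjectRecord:
    """Group membership, demographics and scores for one subject.

    ``group`` is one of ``nc`` (normal control), ``non_impaired`` or
    ``impaired`` (fighters split by processing-speed impairment).  ``race``
    is an integer category code; ``sex`` is 0 = man, 1 = woman.  ``pss`` and
    ``psy`` are the processing-speed and psychomotor-speed scores consumed
    as plain numbers.  ``rms_motion_mm`` is the subject's RMS head motion.
    """

    subject_id: str
    group: str
    age: float
    sex: int
    yoe: float
    race: int
    pss: float
    psy: float = float("nan")
    rms_motion_mm: float = float("nan")
    n_fights: float = float("nan")
    years_fighting: float = float("nan")
    knockouts: float = float("nan")
    motion_file: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI edge values for one subject.

    ``kind`` is ``sfc_z`` (Fisher-z static connectivity) or ``dfc_sd``
    (windowed-correlation standard deviation).  The diagonal is undefined
    and stored as NaN.
    """

    values: np.ndarray
    kind: str
    roi_labels: list[str]
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("connectivity values must be square")
        if len(self.roi_labels) != n:
            raise ValueError("roi_labels length does not match matrix size")
        if self.kind not in ("sfc_z", "dfc_sd"):
            raise ValueError(f"unknown connectivity kind {self.kind!r}")
        off = self.values[~np.eye(n, dtype=bool)]
        asym = np.nanmax(np.abs(self.values - self.values.T), initial=0.0)
        if asym > 1e-12:
            raise ValueError(f"connectivity matrix asymmetric (max |A-A'| = {asym:g})")
        if self.kind == "dfc_sd" and off.size and np.nanmin(off) < 0:
            raise ValueError("dfc_sd values must be nonnegative")
        np.fill_diagonal(self.values, np.nan)

    @property
    def n_roi(self) -> int:
        return self.values.shape[0]

    def edge_vector(self) -> np.ndarray:
        """Unique edges in the shared i<j row-major order."""
        iu, ju = edge_index_pairs(self.n_roi)
        return self.values[iu, ju]


@dataclass
class EdgeStatMap:
    """Edge-wise inference results for one contrast or association.

    ``t``/``p_unc``/``d`` are flat vectors over the unique edges (shared
    ordering).  ``p_unc`` is the one-sided upper-tail p-value in the
    contrast's direction.  Degenerate edges (zero residual variance) carry
    NaN and are excluded from supra-threshold sets downstream.
    """

    t: np.ndarray
    p_unc: np.ndarray
    d: np.ndarray
    df: int
    contrast: np.ndarray
    n_roi: int
    name: str = ""

    def __post_init__(self) -> None:
        m = n_edges(self.n_roi)
        for attr in ("t", "p_unc", "d"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (m,):
                raise ValueError(f"{attr} must have one value per unique edge ({m})")
            setattr(self, attr, v)
        ok = np.isfinite(self.t) & np.isfinite(self.d)
        if np.any(np.sign(self.t[ok]) * np.sign(self.d[ok]) < 0):
            raise ValueError("t and Cohen's d disagree in sign")
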