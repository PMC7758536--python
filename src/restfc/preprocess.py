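"""Formula-level fMRI preprocessing for parcellated time series.

Implements the nuisance pipeline applied before connectivity estimation:
initial-frame dropping, discrete-cosine high-pass filtering (0.008 Hz
cutoff by default), anatomical-CompCor component extraction from eroded
white-matter / CSF voxel sets, joint nuisance regression, per-column
variance normalization, and RMS head-motion summarization with rotations
projected onto a 50 mm sphere.

Fixed operation order: drop frames -> build nuisance set -> regress ->
variance normalize.  The cosine basis is included in a single joint
regression with the other nuisance blocks, which is equivalent to
sequential residualization on the combined column space and avoids
reintroducing drift.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import RoiTimeSeries

__all__ = [
    "NuisanceSet",
    "MotionSummary",
    "drop_initial_frames",
    "cosine_highpass_basis",
    "erode_mask",
    "compcor_components",
    "regress_nuisance",
    "variance_normalize",
    "rms_head_motion",
    "preprocess_subject",
]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF_HZ = 0.008
DEFAULT_N_DROP = 4
DEFAULT_N_COMPCOR = 5
SPHERE_RADIUS_MM = 50.0


@dataclass
class NuisanceSet:
    """Column blocks regressed out of every ROI signal.

    All blocks must share the frame count; empty blocks are allowed.
    Component columns are unit variance and cosine columns mutually
    orthogonal by construction.
    """

    motion_regressors: np.ndarray | None = None
    wm_components: np.ndarray | None = None
    csf_components: np.ndarray | None = None
    highpass_basis: np.ndarray | None = None

    def blocks(self) -> list[np.ndarray]:
        out = []
        for b in (self.highpass_basis, self.motion_regressors, self.wm_components, self.csf_components):
            if b is not None and np.size(b):
                out.append(np.atleast_2d(np.asarray(b, dtype=float)))
        return out

    def n_frames(self) -> int | None:
        frames = {b.shape[0] for b in self.blocks()}
        if len(frames) > 1:
            raise ValueError(f"nuisance blocks disagree on frame count: {sorted(frames)}")
        return frames.pop() if frames else None


@dataclass
class MotionSummary:
    """RMS head motion (mm) and the per-frame displacement trace."""

    rms_motion_mm: float
    framewise_displacements: np.ndarray = field(repr=False)


def drop_initial_frames(ts: RoiTimeSeries, n_drop: int = DEFAULT_N_DROP) -> RoiTimeSeries:
    """Remove the first ``n_drop`` frames (T1-equilibration period)."""
    if n_drop < 0:
        raise ValueError("n_drop must be nonnegative")
    if n_drop >= ts.n_frames:
        raise ValueError(f"cannot drop {n_drop} of {ts.n_frames} frames (empty output)")
    return RoiTimeSeries(ts.data[n_drop:].copy(), ts.tr_seconds, list(ts.roi_labels), ts.subject_id)


def cosine_highpass_basis(n_frames: int, tr: float, cutoff_hz: float = DEFAULT_CUTOFF_HZ) -> np.ndarray:
    """Discrete-cosine drift regressors below ``cutoff_hz``.

    Column ``k`` (1-based) is ``cos(pi * k * (2t + 1) / (2 * n_frames))``
    with frequency ``k / (2 * n_frames * tr)``; the basis holds
    ``K = floor(2 * n_frames * tr * cutoff_hz)`` columns.  High-pass
    filtering means residualizing on this basis plus a constant.
    """
    if n_frames < 2 or tr <= 0:
        raise ValueError("need n_frames >= 2 and tr > 0")
    if cutoff_hz >= 0.5 / tr:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist {0.5 / tr:.4f} Hz")
    K = int(np.floor(2 * n_frames * tr * cutoff_hz))
    if K == 0:
        warnings.warn("high-pass cutoff below the fundamental frequency: empty basis, no drift removal")
        return np.empty((n_frames, 0))
    t = np.arange(n_frames)
    basis = np.cos(np.pi * np.outer(2 * t + 1, np.arange(1, K + 1)) / (2 * n_frames))
    return basis


_STRUCT_6CONN = ndimage.generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, iterations: int = 2, compartment: str = "mask") -> np.ndarray:
    """Binary-erode a 3-D mask with a 6-connected element, ``iterations`` times."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    if iterations < 0:
        raise ValueError("iterations must be nonnegative")
    if iterations == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=_STRUCT_6CONN, iterations=iterations)
    if not out.any():
        raise ValueError(f"erosion ({iterations} iterations) emptied the {compartment} mask")
    return out


def compcor_components(voxel_ts: np.ndarray, n_components: int = DEFAULT_N_COMPCOR) -> np.ndarray:
    """Top principal-component time courses of a compartment voxel set.

    Columns of the demeaned frames x voxels matrix are decomposed by SVD;
    the leading ``n_components`` left singular vectors, ordered by
    decreasing explained variance and scaled to unit sample variance, are
    returned.  Sign convention: the first nonzero voxel loading of each
    component is positive.
    """
    X = np.asarray(voxel_ts, dtype=float)
    if X.ndim != 2:
        raise ValueError("voxel_ts must be frames x voxels")
    n_frames, n_vox = X.shape
    if n_vox < n_components:
        raise ValueError(f"{n_vox} voxels cannot yield {n_components} components")
    if n_frames <= n_components:
        raise ValueError(f"{n_frames} frames cannot support {n_components} components")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = S[0] * max(X.shape) * np.finfo(float).eps if S.size else 0.0
    rank = int(np.sum(S > tol))
    if rank == 0:
        raise ValueError("compartment signal has zero variance; no components")
    if rank < n_components:
        warnings.warn(f"compartment rank {rank} < requested {n_components}; returning {rank}")
        n_components = rank
    comps = U[:, :n_components]
    for k in range(n_components):
        load = Vt[k]
        nz = np.nonzero(np.abs(load) > tol)[0]
        if nz.size and load[nz[0]] < 0:
            comps[:, k] = -comps[:, k]
    comps = comps / comps.std(axis=0, ddof=1)
    return comps


def _design_with_constant(nuisance: NuisanceSet, n_frames: int) -> np.ndarray:
    cols = [np.ones((n_frames, 1))] + nuisance.blocks()
    X = np.hstack(cols)
    # prune linearly dependent columns (constant always kept)
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    keep = diag > max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    if not keep.all():
        log.warning("dropping %d linearly dependent nuisance column(s)", int((~keep).sum()))
        X = X[:, keep]
    return X


def regress_nuisance(ts: RoiTimeSeries, nuisance: NuisanceSet) -> RoiTimeSeries:
    """Replace each ROI signal by its least-squares residual on the
    constant plus all nuisance blocks."""
    nf = nuisance.n_frames()
    if nf is not None and nf != ts.n_frames:
        raise ValueError(f"nuisance frames ({nf}) != time-series frames ({ts.n_frames})")
    X = _design_with_constant(nuisance, ts.n_frames)
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return RoiTimeSeries(resid, ts.tr_seconds, list(ts.roi_labels), ts.subject_id)


def variance_normalize(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Center and scale every ROI signal to sample variance one."""
    sd = ts.data.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        names = ", ".join(ts.roi_labels[k] for k in bad[:5])
        raise ValueError(f"zero-variance ROI column(s): {names}")
    out = (ts.data - ts.data.mean(axis=0)) / sd
    return RoiTimeSeries(out, ts.tr_seconds, list(ts.roi_labels), ts.subject_id)


def rms_head_motion(motion: np.ndarray, sphere_radius_mm: float = SPHERE_RADIUS_MM) -> MotionSummary:
    """RMS head motion from six realignment parameters.

    ``motion`` is frames x 6: three translations (mm) then three rotations
    (radians).  Rotations are converted to arc displacements on a sphere of
    ``sphere_radius_mm``; the framewise displacement at frame ``t`` is the
    Euclidean norm of the backward difference of the 6-vector, and the
    summary is the RMS of those displacements over frames 2..T.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a frames x 6 matrix")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute displacement")
    mm = motion.copy()
    mm[:, 3:] *= sphere_radius_mm
    fd = np.linalg.norm(np.diff(mm, axis=0), axis=1)
    rms = float(np.sqrt(np.mean(fd**2)))
    return MotionSummary(rms, fd)


def preprocess_subject(
    ts: RoiTimeSeries,
    motion: np.ndarray | None = None,
    wm_voxels: np.ndarray | None = None,
    csf_voxels: np.ndarray | None = None,
    n_drop: int = DEFAULT_N_DROP,
    cutoff_hz: float = DEFAULT_CUTOFF_HZ,
    n_compcor: int = DEFAULT_N_COMPCOR,
) -> RoiTimeSeries:
    """Full per-subject pipeline in the fixed order.

    Frames are dropped from the ROI series, motion and compartment inputs
    alike before the nuisance set is assembled, so every regressor is
    aligned with the retained frames.
    """
    ts = drop_initial_frames(ts, n_drop)
    nuis = NuisanceSet(highpass_basis=cosine_highpass_basis(ts.n_frames, ts.tr_seconds, cutoff_hz))
    if motion is not None:
        nuis.motion_regressors = np.asarray(motion, dtype=float)[n_drop:]
    if wm_voxels is not None:
        nuis.wm_components = compcor_components(np.asarray(wm_voxels)[n_drop:], n_compcor)
    if csf_voxels is not None:
        nuis.csf_components = compcor_components(np.asarray(csf_voxels)[n_drop:], n_compcor)
    return variance_normalize(regress_nuisance(ts, nuis))
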