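"""Synthetic resting-state cohort generator with known ground truth.

Emulates a three-group study (normal controls plus fighters split into
non-impaired and impaired by processing-speed performance): parcellated
BOLD time series with a lobe-blocked correlation structure, white-matter /
CSF compartment voxels sharing latent noise components that leak into the
ROI signals, six-parameter rigid-motion traces, and demographic covariates.
Group effects are injected on chosen edges, either as a static correlation
shift or as a sinusoidally time-varying coupling, and recorded in a
:class:`GroundTruth` object so downstream inference can be validated by
parameter recovery.

The time-series model is a Gaussian linear factor construction: a draw from
the target ROI correlation matrix (via its Cholesky factor), to which
low-frequency drift and scaled compartment components are added.  Dynamic
edges are rebuilt from their partner ROI with a time-varying mixing
coefficient, which makes the target windowed-correlation trajectory exact
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GROUPS, RoiTimeSeries, SubjectRecord, edge_index_pairs

__all__ = [
    "CohortConfig",
    "CovariateSpec",
    "NoiseSpec",
    "GroundTruth",
    "default_lobe_assignment",
    "default_roi_labels",
    "block_correlation",
    "correlation_shift_for_d",
    "star_cluster_edges",
    "synthesize_timeseries",
    "generate_motion_and_compartments",
    "generate_cohort",
]

# Desikan-Killiany-like lobe composition for one hemisphere (34 cortical
# parcels) plus 12 subcortical structures -> 80 nodes total.
_HEMI_LOBE_COUNTS = {
    "Frontal": 11,
    "Temporal": 8,
    "Parietal": 5,
    "Occipital": 4,
    "CingulateCortex": 4,
    "Limbic": 1,
    "Insula": 1,
}
_N_SUBCORT = 12


def default_roi_labels(n_roi: int = 80) -> list[str]:
    """Generic ROI labels ``{hemi}_{lobe}_{k}`` in a fixed order."""
    labels: list[str] = []
    for hemi in ("L", "R"):
        for lobe, count in _HEMI_LOBE_COUNTS.items():
            labels.extend(f"{hemi}_{lobe}_{k + 1}" for k in range(count))
    labels.extend(f"Subcortical_{k + 1}" for k in range(_N_SUBCORT))
    if n_roi <= len(labels):
        return labels[:n_roi]
    return labels + [f"Extra_{k + 1}" for k in range(n_roi - len(labels))]


def default_lobe_assignment(n_roi: int = 80) -> dict[str, str]:
    """ROI label -> lobe tag, derived from the label itself."""
    out = {}
    for lab in default_roi_labels(n_roi):
        parts = lab.split("_")
        out[lab] = parts[1] if parts[0] in ("L", "R") else "Sub-cortical"
    return out


@dataclass
class CovariateSpec:
    """Per-group distribution parameters for demographics and scores.

    Defaults reproduce the published cohort's summary statistics (means,
    SDs, category frequencies) for the three groups in the order
    (NC, non-impaired, impaired).  ``pss_edge_r2`` is the share of
    within-group PSS variance explained by the designated effect edges when
    PSS is tied to connectivity.
    """

    age_mean: tuple = (28.80, 28.78, 29.78)
    age_sd: tuple = (8.52, 5.27, 6.20)
    women_frac: tuple = (4 / 35, 7 / 65, 3 / 68)
    yoe_mean: tuple = (14.37, 13.28, 13.03)
    yoe_sd: tuple = (2.57, 1.63, 2.12)
    race_probs: tuple = (
        (2 / 35, 2 / 35, 0.0, 5 / 35, 3 / 35, 23 / 35),
        (8 / 65, 5 / 65, 1 / 65, 0.0, 26 / 65, 25 / 65),
        (11 / 68, 2 / 68, 2 / 68, 1 / 68, 20 / 68, 32 / 68),
    )
    pss_mean: tuple = (63.63, 58.28, 40.85)
    pss_sd: tuple = (18.18, 7.30, 8.34)
    psy_mean: tuple = (193.94, 183.12, 153.16)
    psy_sd: tuple = (25.61, 15.95, 16.11)
    n_fights_mean: tuple = (float("nan"), 14.45, 14.47)
    n_fights_sd: tuple = (float("nan"), 12.97, 12.68)
    years_fighting_mean: tuple = (float("nan"), 5.03, 5.85)
    years_fighting_sd: tuple = (float("nan"), 4.02, 4.45)
    knockouts_mean: tuple = (float("nan"), 0.78, 1.07)
    knockouts_sd: tuple = (float("nan"), 1.14, 1.83)
    pss_edge_r2: float = 0.7


@dataclass
class NoiseSpec:
    """Structured-noise settings: compartments, drift and motion.

    ``n_components`` latent series are shared by the WM and CSF voxel sets;
    ``leak_fraction`` scales how strongly they contaminate ROI signals
    (0 = clean).  Motion traces are bounded Gaussian random walks;
    ``motion_step_mm`` is the per-frame step SD in mm (rotation steps are
    the equivalent arc on a 50 mm sphere), chosen so default RMS motion is
    about 0.25 mm, matching the published cohort.
    """

    n_components: int = 5
    n_wm_voxels: int = 60
    n_csf_voxels: int = 60
    leak_fraction: float = 0.2
    voxel_noise_sd: float = 0.5
    drift_amplitude: float = 0.5
    motion_step_mm: float = 0.10
    motion_bound_mm: float = 1.5
    sphere_radius_mm: float = 50.0


@dataclass
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults mirror the emulated study: groups of (35, 65, 68) subjects,
    80 ROIs, 137 frames at TR 2.8 s.  ``effect_edges`` receive a static
    population-correlation shift of ``static_effect_delta`` in the groups
    listed in ``static_effect_groups``, and a sinusoidal coupling
    modulation of amplitude ``dynamic_effect_amp`` (at
    ``dynamic_effect_freq_hz``) in ``dynamic_effect_groups``.

    ``subject_sigma_z`` adds individual coupling variability: every
    designated edge (effect or PSS) of every subject is perturbed by a
    draw from N(0, subject_sigma_z) on the Fisher-z scale (clipped at two
    SDs to preserve positive definiteness), emulating stable
    between-subject differences in connectivity strength beyond sampling
    noise.
    """

    n_per_group: tuple = (35, 65, 68)
    n_roi: int = 80
    n_frames: int = 137
    tr_seconds: float = 2.8
    lobe_assignment: dict | None = None
    effect_edges: tuple = ()
    static_effect_delta: float = 0.0
    static_effect_groups: tuple = ("nc",)
    dynamic_effect_amp: float = 0.9
    dynamic_effect_freq_hz: float = 0.01
    dynamic_effect_groups: tuple = ("impaired",)
    dynamic_effect_edges: tuple | None = None  # defaults to effect_edges
    pss_edges: tuple = ()
    subject_sigma_z: float = 0.15
    within_lobe_r: float = 0.35
    between_lobe_r: float = 0.10
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3:
            raise ValueError("n_per_group must give sizes for the 3 groups")
        if any(n < 0 for n in self.n_per_group) or sum(n > 0 for n in self.n_per_group) < 2:
            raise ValueError("need at least two non-empty groups")
        if any(0 < n < 2 for n in self.n_per_group):
            raise ValueError("non-empty groups need at least 2 subjects")
        if self.n_roi < 2 or self.n_frames < 3:
            raise ValueError("n_roi >= 2 and n_frames >= 3 required")
        if self.dynamic_effect_edges is None:
            self.dynamic_effect_edges = self.effect_edges
        for (i, j) in (list(self.effect_edges) + list(self.pss_edges)
                       + list(self.dynamic_effect_edges)):
            if not (0 <= i < j < self.n_roi):
                raise ValueError(f"edge ({i}, {j}) invalid for n_roi={self.n_roi} (need i<j)")
        for g in list(self.static_effect_groups) + list(self.dynamic_effect_groups):
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
        if self.lobe_assignment is None:
            self.lobe_assignment = default_lobe_assignment(self.n_roi)

    @property
    def roi_labels(self) -> list[str]:
        return list(self.lobe_assignment)

    def group_labels(self) -> list[str]:
        out: list[str] = []
        for g, n in zip(GROUPS, self.n_per_group):
            out.extend([g] * n)
        return out


@dataclass
class GroundTruth:
    """What was injected, kept next to every generated cohort."""

    effect_edges: list
    static_deltas: dict  # group -> per-edge correlation shift
    dynamic_amps: dict  # group -> modulation amplitude on effect edges
    pss_edges: list
    pss_coefficients: list  # PSS units per unit Fisher z
    baseline_correlation: np.ndarray
    noise_components: dict  # subject_id -> frames x k latent series
    subject_sigma_z: float = 0.0


def block_correlation(
    lobe_assignment: dict[str, str], within_r: float = 0.35, between_r: float = 0.10
) -> np.ndarray:
    """Lobe-blocked ROI correlation matrix (unit diagonal)."""
    lobes = np.array(list(lobe_assignment.values()))
    same = lobes[:, None] == lobes[None, :]
    corr = np.where(same, within_r, between_r)
    np.fill_diagonal(corr, 1.0)
    _cholesky_or_raise(corr)
    return corr


def correlation_shift_for_d(
    d: float, r_base: float, n_frames: int, subject_sd: float = 0.0
) -> float:
    """Correlation shift producing a between-subject Cohen's d on Fisher z.

    The between-subject SD of a sample Fisher z combines sampling noise at
    series length ``T`` (approximately ``1/sqrt(T - 3)``) with any
    subject-level coupling variability ``subject_sd`` on the z scale, so a
    z-shift of ``d * sqrt(subject_sd**2 + 1/(T - 3))`` yields effect size
    ``d``.  Returned on the correlation scale at baseline ``r_base``.
    """
    if n_frames <= 4:
        raise ValueError("n_frames too small to set an effect size")
    dz = d * np.sqrt(subject_sd**2 + 1.0 / (n_frames - 3))
    r_new = np.tanh(np.arctanh(r_base) + dz)
    return float(r_new - r_base)


def star_cluster_edges(hub: int, leaves: list[int]) -> tuple:
    """Edges of a hub-and-spoke cluster; stays connected under edge loss."""
    if hub in leaves:
        raise ValueError("hub cannot be its own leaf")
    return tuple((min(hub, v), max(hub, v)) for v in leaves)


def _ensure_spd_correlation(corr: np.ndarray, floor: float = 1e-4) -> np.ndarray:
    """Project a perturbed correlation matrix back to SPD if needed.

    Eigenvalues are clipped at ``floor`` and the diagonal renormalized to
    one; a no-op for matrices that are already positive definite.
    """
    try:
        np.linalg.cholesky(corr)
        return corr
    except np.linalg.LinAlgError:
        lam, vec = np.linalg.eigh(corr)
        fixed = (vec * np.maximum(lam, floor)) @ vec.T
        scale = np.sqrt(np.diag(fixed))
        return fixed / np.outer(scale, scale)


def _cholesky_or_raise(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("cov_target must be symmetric")
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        lam = np.linalg.eigvalsh(cov)
        raise ValueError(
            f"cov_target is not positive definite: smallest eigenvalue {lam[0]:.3e}"
        ) from None


def synthesize_timeseries(
    cov_target: np.ndarray,
    modulation: tuple = (),
    n_frames: int = 137,
    tr: float = 2.8,
    seed: int | np.random.Generator = 0,
    roi_labels: list[str] | None = None,
    subject_id: str = "",
) -> RoiTimeSeries:
    """Draw a Gaussian ROI time series with target covariance and optional
    time-varying coupling.

    ``modulation`` is a sequence of ``(i, j, amp, freq_hz)`` tuples (or
    ``(i, j, amp, freq_hz, phase)``); for each, ROI ``j`` is rebuilt from
    ROI ``i`` with mixing coefficient
    ``rho(t) = r_ij + amp * sin(2*pi*freq_hz*t + phase)`` so that edge's
    instantaneous correlation follows ``rho(t)`` exactly.  Modulated target
    ROIs must be distinct and the trajectory must stay inside (-1, 1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cov_target = np.asarray(cov_target, dtype=float)
    n_roi = cov_target.shape[0]
    scale = np.sqrt(np.diag(cov_target))
    if np.any(scale <= 0):
        raise ValueError("cov_target needs positive diagonal")
    corr = cov_target / np.outer(scale, scale)
    chol = _cholesky_or_raise(corr)
    x = rng.standard_normal((n_frames, n_roi)) @ chol.T

    targets = [m[1] for m in modulation]
    if len(set(targets)) != len(targets):
        raise ValueError("each modulated edge needs a distinct target ROI")
    t_sec = np.arange(n_frames) * tr
    for m in modulation:
        i, j, amp, freq = m[:4]
        phase = m[4] if len(m) > 4 else rng.uniform(0.0, 2 * np.pi)
        rho = corr[i, j] + amp * np.sin(2 * np.pi * freq * t_sec + phase)
        if np.max(np.abs(rho)) >= 1.0:
            raise ValueError(
                f"modulated correlation on edge ({i}, {j}) leaves (-1, 1): "
                f"max |rho| = {np.max(np.abs(rho)):.3f}"
            )
        x[:, j] = rho * x[:, i] + np.sqrt(1.0 - rho**2) * rng.standard_normal(n_frames)

    labels = roi_labels if roi_labels is not None else [f"ROI_{k}" for k in range(n_roi)]
    return RoiTimeSeries(x * scale, tr, list(labels), subject_id)


def _bounded_walk(rng: np.random.Generator, n: int, step: float, bound: float) -> np.ndarray:
    if step == 0:
        return np.zeros(n)
    steps = rng.normal(0.0, step, n)
    steps[0] = 0.0
    path = np.cumsum(steps)
    # reflect at the bounds to keep drift realistic but finite
    path = np.abs((path + bound) % (4 * bound) - 2 * bound) - bound
    return path


def generate_motion_and_compartments(config: CohortConfig, seed: int | None = None):
    """Motion traces and WM/CSF voxel sets for every subject.

    Returns ``(motion, wm, csf, latents)``: per-subject frames x 6 motion
    matrices (3 translations mm, 3 rotations radians), frames x voxels WM
    and CSF matrices built from ``noise_spec.n_components`` shared latent
    series plus voxel noise, and the latent series themselves.  The same
    latents, scaled by ``leak_fraction``, are what
    :func:`generate_cohort` adds to the ROI signals.
    """
    ns = config.noise_spec
    n_sub = sum(config.n_per_group)
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    _, noise_ss, _ = root.spawn(3)
    subject_streams = noise_ss.spawn(n_sub)

    motion, wm, csf, latents = [], [], [], []
    for ss in subject_streams:
        rng = np.random.default_rng(ss)
        lat = rng.standard_normal((config.n_frames, ns.n_components))
        wm_load = rng.standard_normal((ns.n_components, ns.n_wm_voxels))
        csf_load = rng.standard_normal((ns.n_components, ns.n_csf_voxels))
        wm.append(lat @ wm_load + ns.voxel_noise_sd * rng.standard_normal((config.n_frames, ns.n_wm_voxels)))
        csf.append(lat @ csf_load + ns.voxel_noise_sd * rng.standard_normal((config.n_frames, ns.n_csf_voxels)))
        cols = []
        for axis in range(6):
            step = ns.motion_step_mm if axis < 3 else ns.motion_step_mm / ns.sphere_radius_mm
            bound = ns.motion_bound_mm if axis < 3 else ns.motion_bound_mm / ns.sphere_radius_mm
            cols.append(_bounded_walk(rng, config.n_frames, step, bound))
        motion.append(np.column_stack(cols))
        latents.append(lat)
    return motion, wm, csf, latents


def _group_correlations(config: CohortConfig) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    base = block_correlation(config.lobe_assignment, config.within_lobe_r, config.between_lobe_r)
    per_group: dict[str, np.ndarray] = {}
    for g in GROUPS:
        corr = base.copy()
        if g in config.static_effect_groups and config.static_effect_delta != 0.0:
            for (i, j) in config.effect_edges:
                r_new = corr[i, j] + config.static_effect_delta
                if not -1.0 < r_new < 1.0:
                    raise ValueError(
                        f"static effect pushes correlation of edge ({i}, {j}) to "
                        f"{r_new:.3f}, outside (-1, 1)"
                    )
                corr[i, j] = corr[j, i] = r_new
            _cholesky_or_raise(corr)
        per_group[g] = corr
    return base, per_group


def generate_cohort(config: CohortConfig):
    """Generate a full synthetic cohort.

    Returns ``(subjects, timeseries, truth)``.  Deterministic in
    ``config.seed``; motion and compartment noise are drawn from a
    dedicated substream so :func:`generate_motion_and_compartments` called
    with the same config reproduces exactly the noise embedded here.
    """
    base_corr, group_corr = _group_correlations(config)
    cs = config.covariate_spec
    ns = config.noise_spec
    labels = config.roi_labels
    groups = config.group_labels()
    n_sub = len(groups)

    root = np.random.SeedSequence(config.seed)
    signal_ss, _, cov_ss = root.spawn(3)
    signal_streams = signal_ss.spawn(n_sub)
    cov_rng = np.random.default_rng(cov_ss)
    motion, _wm, _csf, latents = generate_motion_and_compartments(config)

    from .preprocess import rms_head_motion  # local import avoids a cycle at import time

    pss_edges = list(config.pss_edges)
    iu, ju = edge_index_pairs(config.n_roi)

    subjects: list[SubjectRecord] = []
    series: list[RoiTimeSeries] = []
    pss_signal = np.zeros(n_sub)
    t_sec = np.arange(config.n_frames) * config.tr_seconds
    noise_components: dict[str, np.ndarray] = {}

    for s, g in enumerate(groups):
        sid = f"sub-{s + 1:03d}"
        rng = np.random.default_rng(signal_streams[s])
        gi = GROUPS.index(g)
        mod = ()
        if g in config.dynamic_effect_groups and config.dynamic_effect_amp > 0:
            mod = tuple(
                (i, j, config.dynamic_effect_amp, config.dynamic_effect_freq_hz)
                for (i, j) in config.dynamic_effect_edges
            )
        subject_corr = group_corr[g]
        varied = sorted(set(config.effect_edges) | set(config.pss_edges))
        if varied and config.subject_sigma_z > 0:
            subject_corr = subject_corr.copy()
            sig = config.subject_sigma_z
            u = np.clip(rng.normal(0.0, sig, len(varied)), -2 * sig, 2 * sig)
            for (i, j), du in zip(varied, u):
                r_s = np.tanh(np.arctanh(subject_corr[i, j]) + du)
                subject_corr[i, j] = subject_corr[j, i] = r_s
            subject_corr = _ensure_spd_correlation(subject_corr)
        ts = synthesize_timeseries(
            subject_corr, mod, config.n_frames, config.tr_seconds, rng, labels, sid
        )
        base_signal = ts.data.copy()

        # low-frequency scanner drift (periods >= ~200 s, below the high-pass band)
        if ns.drift_amplitude > 0:
            n_drift = 2
            freqs = rng.uniform(1 / 600.0, 1 / 200.0, n_drift)
            phases = rng.uniform(0, 2 * np.pi, n_drift)
            drift = np.sum(
                [np.cos(2 * np.pi * f * t_sec + p) for f, p in zip(freqs, phases)], axis=0
            )
            ts.data += ns.drift_amplitude * np.outer(drift, rng.standard_normal(config.n_roi))
        if ns.leak_fraction > 0:
            load = rng.standard_normal((ns.n_components, config.n_roi))
            ts.data += ns.leak_fraction * latents[s] @ load
        noise_components[sid] = latents[s]

        if pss_edges:
            r_obs = np.corrcoef(base_signal.T)
            np.fill_diagonal(r_obs, 0.0)
            z = np.arctanh(r_obs)
            z_true = np.arctanh(np.array([group_corr[g][i, j] for (i, j) in pss_edges]))
            z_obs = np.array([z[i, j] for (i, j) in pss_edges])
            sd_z = np.sqrt(len(pss_edges)) * np.sqrt(
                config.subject_sigma_z**2 + 1.0 / (config.n_frames - 3)
            )
            pss_signal[s] = float(np.sum(z_obs - z_true) / sd_z)

        rms = rms_head_motion(motion[s], ns.sphere_radius_mm).rms_motion_mm
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=g,
                age=cov_rng.normal(cs.age_mean[gi], cs.age_sd[gi]),
                sex=int(cov_rng.random() < cs.women_frac[gi]),
                yoe=cov_rng.normal(cs.yoe_mean[gi], cs.yoe_sd[gi]),
                race=int(cov_rng.choice(len(cs.race_probs[gi]), p=cs.race_probs[gi])),
                pss=np.nan,  # filled below once the edge signal is standardized
                psy=cov_rng.normal(cs.psy_mean[gi], cs.psy_sd[gi]),
                rms_motion_mm=rms,
                n_fights=cov_rng.normal(cs.n_fights_mean[gi], cs.n_fights_sd[gi]) if gi else np.nan,
                years_fighting=(
                    cov_rng.normal(cs.years_fighting_mean[gi], cs.years_fighting_sd[gi]) if gi else np.nan
                ),
                knockouts=cov_rng.normal(cs.knockouts_mean[gi], cs.knockouts_sd[gi]) if gi else np.nan,
            )
        )
        series.append(ts)

    r2 = cs.pss_edge_r2 if pss_edges else 0.0
    pss_coeffs = []
    for s, (sub, g) in enumerate(zip(subjects, groups)):
        gi = GROUPS.index(g)
        eps = cov_rng.standard_normal()
        sub.pss = cs.pss_mean[gi] + cs.pss_sd[gi] * (
            np.sqrt(r2) * pss_signal[s] + np.sqrt(1 - r2) * eps
        )
    if pss_edges:
        # PSS units per unit Fisher z, averaged over the fighter groups
        sd_z = np.sqrt(len(pss_edges)) * np.sqrt(
            config.subject_sigma_z**2 + 1.0 / (config.n_frames - 3)
        )
        mean_sd = float(np.mean([cs.pss_sd[1], cs.pss_sd[2]]))
        pss_coeffs = [mean_sd * np.sqrt(r2) / sd_z] * len(pss_edges)

    truth = GroundTruth(
        effect_edges=list(config.effect_edges),
        static_deltas={
            g: (
                [config.static_effect_delta] * len(config.effect_edges)
                if g in config.static_effect_groups
                else [0.0] * len(config.effect_edges)
            )
            for g in GROUPS
        },
        dynamic_amps={
            g: config.dynamic_effect_amp if g in config.dynamic_effect_groups else 0.0
            for g in GROUPS
        },
        pss_edges=pss_edges,
        pss_coefficients=pss_coeffs,
        baseline_correlation=base_corr,
        noise_components=noise_components,
        subject_sigma_z=config.subject_sigma_z if (config.effect_edges or pss_edges) else 0.0,
    )
    return subjects, series, truth
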