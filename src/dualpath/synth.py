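"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the analysis chain assumes: two
diagnostic groups, a stable group-specific spatial offset ("trait" signal),
event-locked transient group differences at known windows, a stimulus
component shared across subjects (inter-subject correlation), AR(1) scanner
noise, site/sex/age confound structure, and behavioral scores linearly
loaded on per-subject event-response amplitudes.  Ground truth is returned
alongside the cohort so every downstream stage can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .cohort import Cohort, RoiTimeSeries, SubjectRecord


@dataclass(frozen=True)
class EventSpec:
    """A planted transient group difference.

    Subjects of both groups receive an event response on ``rois`` during
    [start_tr, end_tr); its amplitude is ``effect`` in controls and
    ``effect * group_gain`` in cases, plus per-subject jitter.
    """

    start_tr: int
    end_tr: int
    rois: tuple[int, ...]
    effect: float = 1.0
    group_gain: float = 2.0


@dataclass
class BehaviorModel:
    """Scores = intercept + scale * (loadings . event amplitudes) + noise.

    All scores share one loading vector over events, so the brain-behavior
    cross-covariance is rank one by construction.  ``noise_sd_ratio`` scales
    the noise sd relative to the sd of the signal part.
    """

    loadings: tuple[float, ...] = (1.0, 0.4, 0.8)
    scores: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "SRS_total": (65.0, 10.0),
        "RBS_total": (20.0, 6.0),
        "CBCL_total": (55.0, 9.0),
    })
    noise_sd_ratio: float = 0.5


@dataclass
class SyntheticSpec:
    """Desk-scale defaults: 60/group, 246 ROIs, 250 TRs at 0.8 s."""

    n_per_group: int = 60
    n_regions: int = 246
    n_timepoints: int = 250
    tr_seconds: float = 0.8
    seed: int = 0
    ar1_coefficient: float = 0.3
    noise_sd: float = 1.0
    shared_stimulus_sd: float = 0.5
    # a compact set of regions carrying the stable group offset, mirroring
    # the handful of trait-level regions such analyses typically report
    trait_rois: tuple[int, ...] = (0, 1, 2)
    trait_effect: float = 0.5
    trait_jitter_sd: float = 0.5
    events: tuple[EventSpec, ...] = (
        EventSpec(50, 80, tuple(range(30, 42)), effect=1.5),
        EventSpec(120, 150, tuple(range(60, 72)), effect=1.5),
        EventSpec(190, 220, tuple(range(90, 102)), effect=1.5),
    )
    amplitude_jitter_sd: float = 0.4
    hrf: bool = True
    # transient responses fluctuate around baseline: the event regressor is
    # demeaned over the run, so events carry no net time-averaged activation
    # and the stable (trait) and transient (event) signals are separable by
    # the two pathways
    demean_response: bool = True
    behavior: BehaviorModel = field(default_factory=BehaviorModel)
    site_levels: tuple[str, ...] = ("siteA", "siteB", "siteC")
    site_offsets: tuple[float, ...] = (-0.2, 0.0, 0.2)
    # sex imbalance by group: cases skew heavily male, controls moderately
    p_male: tuple[float, float] = (0.61, 0.85)
    age_mean: float = 11.0
    age_sd: float = 1.5
    fd_mean: float = 0.13
    fd_sd: float = 0.05

    def __post_init__(self) -> None:
        for ev in self.events:
            if not (0 <= ev.start_tr < ev.end_tr <= self.n_timepoints):
                raise ValueError(f"event window {ev.start_tr}-{ev.end_tr} outside [0, T)")
            if any(r < 0 or r >= self.n_regions for r in ev.rois):
                raise ValueError("event rois outside region range")
        if any(r < 0 or r >= self.n_regions for r in self.trait_rois):
            raise ValueError("trait rois outside region range")
        if not 0 <= self.ar1_coefficient < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")

    def null(self) -> "SyntheticSpec":
        """A copy with every planted effect removed (exchangeable groups)."""
        return replace(
            self,
            trait_effect=0.0,
            events=tuple(replace(ev, effect=0.0, group_gain=1.0) for ev in self.events),
            p_male=(self.p_male[0], self.p_male[0]),
            site_offsets=tuple(0.0 for _ in self.site_offsets),
        )


@dataclass
class GroundTruth:
    """Everything needed to score downstream recovery."""

    trait_rois: tuple[int, ...]
    event_windows: list[tuple[int, int]]
    #: where the hemodynamic response actually lives (regressor >= half max);
    #: equals event_windows in pure-boxcar mode, lagged/smeared under the HRF
    response_windows: list[tuple[int, int]]
    event_rois: list[tuple[int, ...]]
    amplitudes: pd.DataFrame          # subject x event, per-subject responses
    behavior_loadings: np.ndarray     # loading vector over events
    labels: pd.Series                 # subject_id -> diagnosis


def double_gamma_hrf(tr_seconds: float, duration: float = 30.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at the TR.

    Peak at ~6 s, undershoot at ~16 s with 1:6 amplitude ratio; normalized
    to unit peak.
    """
    t = np.arange(0, duration, tr_seconds)
    from scipy.stats import gamma
    peak = gamma.pdf(t, 6) - gamma.pdf(t, 16) / 6.0
    return peak / peak.max()


def _event_regressor(spec: SyntheticSpec, ev: EventSpec) -> np.ndarray:
    box = np.zeros(spec.n_timepoints)
    box[ev.start_tr:ev.end_tr] = 1.0
    if spec.hrf:
        h = double_gamma_hrf(spec.tr_seconds)
        reg = np.convolve(box, h)[: spec.n_timepoints]
        m = reg.max()
        reg = reg / m if m > 0 else reg
    else:
        reg = box
    if spec.demean_response:
        reg = reg - reg.mean()
    return reg


def _ar1_noise(rng: np.random.Generator, n: int, R: int, T: int,
               rho: float, sd: float) -> np.ndarray:
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    e = rng.normal(0.0, innov_sd, size=(n, R, T))
    return sps.lfilter([1.0], [1.0, -rho], e, axis=-1)


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Simulate the cohort; a fixed seed yields bit-identical output."""
    rng = np.random.default_rng(spec.seed)
    n = 2 * spec.n_per_group
    R, T = spec.n_regions, spec.n_timepoints
    labels = np.array([0] * spec.n_per_group + [1] * spec.n_per_group)
    region_ids = [f"ROI{i + 1:03d}" for i in range(R)]
    subject_ids = [f"sub-{i + 1:04d}" for i in range(n)]

    # demographics / confounds
    sites = rng.choice(len(spec.site_levels), size=n)
    sexes = np.where(rng.random(n) < np.asarray(spec.p_male)[labels], "M", "F")
    ages = rng.normal(spec.age_mean, spec.age_sd, size=n)
    while (ages <= 5).any():
        ages[ages <= 5] = rng.normal(spec.age_mean, spec.age_sd, size=int((ages <= 5).sum()))
    fds = np.abs(rng.normal(spec.fd_mean, spec.fd_sd, size=n))
    repaired = np.clip(np.abs(rng.normal(0.02, 0.02, size=n)), 0, 1)

    # shared stimulus component: one smooth R x T field added to everyone
    shared = rng.normal(0.0, 1.0, size=(R, T))
    if T >= 9:
        kernel = np.hanning(9)
        kernel /= kernel.sum()
        shared = sps.fftconvolve(shared, kernel[None, :], mode="same")
        shared /= max(shared.std(), 1e-12)
    shared *= spec.shared_stimulus_sd

    # per-subject event amplitudes: group baseline x gain + jitter
    E = len(spec.events)
    amps = np.empty((n, E))
    for e, ev in enumerate(spec.events):
        base = np.where(labels == 1, ev.effect * ev.group_gain, ev.effect)
        amps[:, e] = base + rng.normal(0.0, spec.amplitude_jitter_sd, size=n)
    regressors = np.stack([_event_regressor(spec, ev) for ev in spec.events])

    data = _ar1_noise(rng, n, R, T, spec.ar1_coefficient, spec.noise_sd)
    data += shared[None, :, :]
    data += np.asarray(spec.site_offsets)[sites][:, None, None]
    trait = np.zeros(R)
    trait[list(spec.trait_rois)] = spec.trait_effect
    # subject-level heterogeneity in trait expression (individual differences)
    trait_amp = 1.0 + rng.normal(0.0, spec.trait_jitter_sd, size=n)
    data += (labels == 1)[:, None, None] * trait_amp[:, None, None] * trait[None, :, None]
    for e, ev in enumerate(spec.events):
        roi_mask = np.zeros(R)
        roi_mask[list(ev.rois)] = 1.0
        data += amps[:, e, None, None] * roi_mask[None, :, None] * regressors[e][None, None, :]

    # behavior loaded on event amplitudes (rank-1 cross-covariance)
    w = np.asarray(spec.behavior.loadings[:E], dtype=float)
    latent = amps @ w
    latent_c = latent - latent.mean()
    sd_latent = latent_c.std() if latent_c.std() > 0 else 1.0
    behavior_cols = {}
    for name, (intercept, scale) in spec.behavior.scores.items():
        sig = scale * latent_c / sd_latent
        noise = rng.normal(0.0, spec.behavior.noise_sd_ratio * scale, size=n)
        behavior_cols[name] = intercept + sig + noise

    subjects = []
    for i, sid in enumerate(subject_ids):
        ts = RoiTimeSeries(sid, data[i], spec.tr_seconds, region_ids, "synthetic")
        rec = SubjectRecord(
            subject_id=sid,
            diagnosis=int(labels[i]),
            age_years=float(ages[i]),
            sex=str(sexes[i]),
            site=spec.site_levels[sites[i]],
            mean_fd_mm=float(fds[i]),
            pct_volumes_repaired=float(repaired[i]),
            behavior={k: float(v[i]) for k, v in behavior_cols.items()},
        )
        subjects.append((ts, rec))

    resp_windows = []
    for reg in regressors:
        above = np.flatnonzero(reg >= 0.5 * reg.max())
        resp_windows.append((int(above[0]), int(above[-1]) + 1))

    truth = GroundTruth(
        trait_rois=tuple(spec.trait_rois),
        event_windows=[(ev.start_tr, ev.end_tr) for ev in spec.events],
        response_windows=resp_windows,
        event_rois=[tuple(ev.rois) for ev in spec.events],
        amplitudes=pd.DataFrame(amps, index=subject_ids,
                                columns=[f"E{e + 1}" for e in range(E)]),
        behavior_loadings=w,
        labels=pd.Series(labels, index=subject_ids, name="diagnosis"),
    )
    return Cohort(subjects), truth


def null_permutation(cohort: Cohort, seed: int) -> Cohort:
    """Randomly permute diagnosis labels across subjects; all else untouched."""
    rng = np.random.default_rng(seed)
    labels = cohort.labels
    perm = rng.permutation(len(labels))
    subjects = []
    for (ts, rec), new_label in zip(cohort.subjects, labels[perm]):
        new_rec = SubjectRecord(rec.subject_id, int(new_label), rec.age_years,
                                rec.sex, rec.site, rec.mean_fd_mm,
                                rec.pct_volumes_repaired, dict(rec.behavior))
        subjects.append((ts, new_rec))
    return Cohort(subjects, cohort.roi_network_map)
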