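"""Simulated event-related BOLD data with configurable condition tuning.

Voxel timeseries for abstract ROIs (plain voxel sets) or small 3-D
lattices are generated as

    baseline * (1 + signal%/100 + drift%/100) + noise,

where the signal is a sum over stimulus events of amplitude x per-voxel
pattern x a peak-normalised double-gamma HRF shifted to the event onset.
Condition amplitudes follow a tuning profile over caricature level
(flat, linear ramp, saturating ramp, or V-shaped), the competing coding
hypotheses for distance-from-average tuning.  Per-voxel condition
patterns are fixed across scans of a subject so pattern consistency
(MVPA) is controllable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .design import RunSchedule, caricature_condition_set, event_related_schedule


@dataclass
class Hrf:
    """Sampled double-gamma haemodynamic response, peak-normalised."""

    kernel: np.ndarray
    tr: float
    params: dict

    @property
    def n_taps(self) -> int:
        return self.kernel.size

    def msd_index(self) -> float:
        """MSD amplitude index of the unit-peak kernel itself (lags 1-4 minus lag 0)."""
        return float(self.kernel[1:5].mean() - self.kernel[0])


def double_gamma(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Difference of two gamma densities evaluated at times ``t`` (s).

    Each lobe is parameterised by its mode: shape = delay/dispersion + 1,
    scale = dispersion, so the positive lobe peaks at ``peak_delay``.
    Not normalised.
    """
    if min(peak_delay, undershoot_delay, peak_disp, undershoot_disp, ratio) <= 0:
        raise ValueError("HRF parameters must be positive")
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, peak_delay / peak_disp + 1, scale=peak_disp)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_disp + 1, scale=undershoot_disp)
    return peak - under / ratio


def double_gamma_hrf(tr: float = 2.0, length: float = 32.0, **params) -> Hrf:
    """Double-gamma HRF sampled at TR resolution, peak normalised to 1."""
    if tr <= 0:
        raise ValueError("tr must be positive")
    if length < 20:
        raise ValueError("kernel length must be >= 20 s")
    t = np.arange(0.0, length + tr / 2, tr)
    dense = np.arange(0.0, length, 0.01)
    scale = double_gamma(dense, **params).max()
    kernel = double_gamma(t, **params) / scale
    return Hrf(kernel=kernel, tr=tr, params={"length": length, **params})


@dataclass
class TuningProfile:
    """Amplitude (% signal) as a function of caricature level offset."""

    kind: str = "flat"  # flat | ramp | saturating | v_shaped
    baseline: float = 0.5
    slope: float = 0.0  # % signal per level-SD
    saturation: float | None = None  # offset at which a saturating ramp clips
    vertex: float = 0.0  # offset of the V minimum
    inversion_multiplier: float = 1.0

    def amplitude(self, offset: float) -> float:
        if self.kind == "flat":
            return self.baseline
        if self.kind == "ramp":
            return self.baseline + self.slope * offset
        if self.kind == "saturating":
            sat = self.saturation if self.saturation is not None else 3.0
            return self.baseline + self.slope * min(offset, sat)
        if self.kind == "v_shaped":
            return self.baseline + self.slope * abs(offset - self.vertex)
        raise ValueError(f"unknown tuning profile kind {self.kind!r}")


def condition_amplitudes(profile: TuningProfile, condition_set: pd.DataFrame) -> dict[str, float]:
    """Map each condition label to its tuned amplitude (% signal units)."""
    out = {}
    for row in condition_set.itertuples():
        amp = profile.amplitude(float(row.level_offset))
        if row.orientation == "inverted":
            amp *= profile.inversion_multiplier
        out[row.trial_type] = amp
    return out


def make_patterns(
    n_voxels: int,
    conditions: list[str],
    strength: float = 0.0,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Fixed per-voxel condition pattern, mean 1 per condition.

    ``strength`` scales voxelwise standard-normal deviations around 1;
    strength 0 gives a uniform pattern (pure univariate signal).  With
    ``groups`` (condition -> group key), conditions in the same group
    share one pattern — e.g. all components at one caricature level, so
    the level-pooled analysis sees exactly that pattern.
    """
    rng = np.random.default_rng(seed)
    if groups is None:
        pat = 1.0 + strength * rng.standard_normal((n_voxels, len(conditions)))
        return pd.DataFrame(pat, columns=conditions)
    keys = list(dict.fromkeys(groups[c] for c in conditions))
    base = {k: 1.0 + strength * rng.standard_normal(n_voxels) for k in keys}
    return pd.DataFrame({c: base[groups[c]] for c in conditions})


@dataclass
class DriftSpec:
    """Linear plus slow-cosine drift, in % signal over one run."""

    linear_pct: float = 0.0  # total linear excursion across the run
    cosine_pct: float = 0.0
    cosine_period_s: float = 128.0

    def series(self, n_trs: int, tr: float) -> np.ndarray:
        t = np.arange(n_trs) * tr
        out = np.zeros(n_trs)
        if self.linear_pct:
            out += self.linear_pct * (t / max(t[-1], 1e-9) - 0.5)
        if self.cosine_pct:
            out += self.cosine_pct * np.cos(2 * np.pi * t / self.cosine_period_s)
        return out


@dataclass
class BoldRun:
    """Raw-intensity voxels x TRs array with its generating schedule."""

    data: np.ndarray  # (n_voxels, n_trs), raw intensity
    tr: float
    schedule: RunSchedule
    scan_id: int = 0
    subject_id: int = 0
    roi: str = "roi"

    def __post_init__(self) -> None:
        if self.data.shape[1] != self.schedule.n_volumes:
            raise ValueError("TR count does not match schedule duration / tr")


def condition_regressors(
    schedule: RunSchedule, hrf: Hrf, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Per-condition event sticks at the TR grid convolved with the HRF kernel.

    Onsets are snapped to the nearest TR; the canonical designs land on
    the grid exactly.  Peak response to an isolated event equals 1.
    """
    n = schedule.n_volumes
    conditions = conditions or schedule.conditions
    onset_map = {
        c: g.to_numpy() for c, g in schedule.events.groupby("trial_type")["onset"]
    }
    cols = {}
    for cond in conditions:
        sticks = np.zeros(n)
        idx = np.round(onset_map.get(cond, np.array([])) / schedule.tr).astype(int)
        np.add.at(sticks, idx[idx < n], 1.0)
        cols[cond] = np.convolve(sticks, hrf.kernel)[:n]
    return pd.DataFrame(cols)


def boxcar_regressors(
    schedule: RunSchedule,
    hrf_params: dict | None = None,
    conditions: list[str] | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Boxcar (onset, duration) indicators convolved with the HRF at fine
    resolution, sampled at the TR grid and peak-normalised per condition.

    This is the explanatory-variable shape of a blocked localiser design;
    a voxel responding with amplitude ``a`` (% signal) has peak response
    ``a`` on the regressor's scale.
    """
    hrf_params = hrf_params or {}
    total = schedule.total_duration
    fine_t = np.arange(0.0, total, dt)
    kernel_t = np.arange(0.0, 32.0, dt)
    kernel = double_gamma(kernel_t, **hrf_params) * dt
    n = schedule.n_volumes
    tr_idx = (np.arange(n) * schedule.tr / dt).round().astype(int)
    cols = {}
    conditions = conditions or schedule.conditions
    for cond in conditions:
        ev = schedule.events[schedule.events["trial_type"] == cond]
        box = np.zeros(fine_t.size)
        for row in ev.itertuples():
            i0 = int(round(row.onset / dt))
            i1 = int(round((row.onset + row.duration) / dt))
            box[i0:i1] = 1.0
        conv = np.convolve(box, kernel)[: fine_t.size]
        peak = conv.max()
        if peak <= 0:
            raise ValueError(f"condition {cond!r} has no events")
        cols[cond] = conv[tr_idx] / peak
    return pd.DataFrame(cols)


def simulate_run(
    schedule: RunSchedule,
    n_voxels: int,
    amplitudes: dict[str, float],
    patterns: pd.DataFrame | None = None,
    noise_sd: float = 0.5,
    drift: DriftSpec | None = None,
    baseline: float = 100.0,
    hrf: Hrf | None = None,
    seed: int = 0,
    subject_id: int = 0,
    scan_id: int = 0,
    roi: str = "roi",
) -> BoldRun:
    """One ROI run: tuned, patterned event responses + drift + white noise.

    ``noise_sd`` is in % signal (converted to raw units via the
    baseline).  ``patterns`` (voxels x conditions, mean ~1) must be
    shared across a subject's scans for pattern consistency to be
    meaningful.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    hrf = hrf or double_gamma_hrf(tr=schedule.tr)
    conds = list(amplitudes)
    regs = condition_regressors(schedule, hrf, conds).to_numpy()  # (n_trs, n_conds)
    amps = np.array([amplitudes[c] for c in conds])
    if patterns is None:
        pat = np.ones((n_voxels, len(conds)))
    else:
        pat = patterns[conds].to_numpy()
        if pat.shape[0] != n_voxels:
            raise ValueError("patterns voxel count mismatch")
    signal_pct = pat * amps @ regs.T  # (n_voxels, n_trs)
    n_trs = regs.shape[0]
    drift_pct = (drift or DriftSpec()).series(n_trs, schedule.tr)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * baseline / 100.0, size=(n_voxels, n_trs))
    data = baseline * (1.0 + signal_pct / 100.0 + drift_pct[None, :] / 100.0) + noise
    return BoldRun(
        data=data,
        tr=schedule.tr,
        schedule=schedule,
        scan_id=scan_id,
        subject_id=subject_id,
        roi=roi,
    )


@dataclass
class StudyBundle:
    """Simulated multi-subject study plus its generative ground truth."""

    runs: dict  # (subject, roi) -> list[BoldRun]
    condition_set: pd.DataFrame
    ground_truth: dict

    def subject_runs(self, subject: int, roi: str) -> list["BoldRun"]:
        return self.runs[(subject, roi)]

    def save_ground_truth(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True))

    @staticmethod
    def load_ground_truth(path: str | Path) -> dict:
        return json.loads(Path(path).read_text())


def simulate_study(
    profiles: dict[str, TuningProfile] | None = None,
    n_subjects: int = 9,
    scans_per_subject: int = 3,
    condition_set: pd.DataFrame | None = None,
    n_voxels: int = 24,
    pattern_strength: float = 0.0,
    pattern_by: str = "level",
    noise_sd: float = 0.5,
    drift: DriftSpec | None = None,
    subject_gain_sd: float = 0.1,
    seed: int = 0,
) -> StudyBundle:
    """Simulate subjects x scans x ROIs of event-related caricature runs.

    Schedules are re-randomised per scan; per-voxel condition patterns
    and the subject's multiplicative response gain are fixed within
    subject.  ``pattern_by='level'`` shares one pattern across the
    components of a caricature level (the level-pooled analyses are then
    exactly specified); ``'condition'`` draws an independent pattern per
    stimulus type.  Per-subject/scan seeds are spawned deterministically
    from the master seed and recorded in the ground truth.
    """
    profiles = profiles or {"ffa": TuningProfile("ramp", baseline=0.5, slope=0.1)}
    if condition_set is None:
        condition_set = caricature_condition_set(4.0, 1.0, components=3)
    root = np.random.SeedSequence(seed)
    subj_seqs = root.spawn(n_subjects)
    hrf = double_gamma_hrf()
    runs: dict = {}
    truth = {
        "seed": seed,
        "n_subjects": n_subjects,
        "scans_per_subject": scans_per_subject,
        "noise_sd": noise_sd,
        "pattern_strength": pattern_strength,
        "subjects": {},
    }
    for s, sseq in enumerate(subj_seqs):
        state = sseq.generate_state(4) % (2**31)
        gain_rng = np.random.default_rng(int(state[0]))
        gain = float(max(0.2, 1.0 + subject_gain_sd * gain_rng.standard_normal()))
        subj_truth = {"gain": gain, "seeds": [int(x) for x in state], "rois": {}}
        for roi, profile in profiles.items():
            amps = condition_amplitudes(profile, condition_set)
            amps = {k: v * gain for k, v in amps.items()}
            if pattern_by == "level" and "level_label" in condition_set.columns:
                groups = dict(
                    zip(condition_set["trial_type"], condition_set["level_label"])
                )
            else:
                groups = None
            pats = make_patterns(
                n_voxels,
                list(amps),
                strength=pattern_strength,
                seed=int(state[1]),
                groups=groups,
            )
            roi_runs = []
            for scan in range(scans_per_subject):
                sched_seed = int((state[2] + 997 * scan) % (2**31))
                noise_seed = int((state[3] + 131 * scan) % (2**31))
                sched = event_related_schedule(condition_set, seed=sched_seed)
                roi_runs.append(
                    simulate_run(
                        sched,
                        n_voxels,
                        amps,
                        patterns=pats,
                        noise_sd=noise_sd,
                        drift=drift,
                        hrf=hrf,
                        seed=noise_seed,
                        subject_id=s,
                        scan_id=scan,
                        roi=roi,
                    )
                )
            runs[(s, roi)] = roi_runs
            subj_truth["rois"][roi] = {
                "profile": asdict(profile),
                "amplitudes": amps,
            }
        truth["subjects"][str(s)] = subj_truth
    return StudyBundle(runs=runs, condition_set=condition_set, ground_truth=truth)


def simulate_localiser_lattice(
    lattice_shape: tuple[int, int, int],
    category_masks: dict[str, np.ndarray],
    schedule: RunSchedule,
    effect_pct: float = 1.0,
    noise_sd: float = 1.0,
    baseline: float = 100.0,
    hrf_params: dict | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Localiser run on a 3-D voxel lattice with planted selective clusters.

    Voxels inside ``category_masks[cat]`` respond with ``effect_pct`` to
    that category's blocks only.  Returns (n_voxels, n_trs) data in
    C-order flattening of the lattice.
    """
    n_vox = int(np.prod(lattice_shape))
    regs = boxcar_regressors(schedule, hrf_params=hrf_params).to_numpy()
    conds = schedule.conditions
    amp = np.zeros((n_vox, len(conds)))
    for ci, cat in enumerate(conds):
        if cat in category_masks:
            mask = category_masks[cat].reshape(-1)
            amp[mask, ci] = effect_pct
    signal_pct = amp @ regs.T
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * baseline / 100.0, size=signal_pct.shape)
    return baseline * (1.0 + signal_pct / 100.0) + noise
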