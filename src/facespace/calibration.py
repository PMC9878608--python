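"""Recovery and calibration suites run on simulated studies.

These routines exercise the full analysis chain on seeded synthetic
studies: power and type-I calibration of the group linear trend on the
amplitude index, null and monotonicity behaviour of the correlation
MVPA, ROI-recovery accuracy on planted lattices, and the noiseless
deconvolution oracle.  They are the package's own evidence that the
pipeline recovers what the generator injected.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import boldsim, design, glm, mvpa, preprocess, univariate
from .boldsim import TuningProfile
from .stats import linear_trend

UPRIGHT_ORDER = ["-1sd", "+0sd", "+1sd", "+3sd", "+6sd"]


def _study_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed).spawn(n)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss]


def trend_detection_rate(
    profile_kind: str = "ramp",
    n_studies: int = 100,
    slope: float = 0.1,
    baseline: float = 0.5,
    noise_sd: float = 0.5,
    n_subjects: int = 9,
    scans_per_subject: int = 3,
    n_voxels: int = 16,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulated studies whose group linear trend rejects.

    Each study is the canonical design (9 subjects x 3 scans of 63
    trials); the trend is the one-sided one-sample t on the per-subject
    (-2,-1,0,1,2) contrast over the 5 upright amplitude indices.  With
    ramp tuning this measures power; with flat tuning, type-I rate.
    """
    cset = design.caricature_condition_set(4.0, 1.0, components=3)
    profile = TuningProfile(profile_kind, baseline=baseline, slope=slope)
    hits = 0
    for s in _study_seeds(seed, n_studies):
        study = boldsim.simulate_study(
            profiles={"roi": profile},
            n_subjects=n_subjects,
            scans_per_subject=scans_per_subject,
            condition_set=cset,
            n_voxels=n_voxels,
            noise_sd=noise_sd,
            seed=s,
        )
        amp = univariate.study_amplitude_table(study)
        wide = amp.pivot_table(index="subject", columns="condition", values="index")
        res = linear_trend(wide[UPRIGHT_ORDER].to_numpy(), sidedness="greater")
        hits += res.p < alpha
    return hits / n_studies


def fir_recovery_oracle(
    seed: int = 0, n_lags: int = 17
) -> dict[str, float]:
    """Noiseless canonical-run deconvolution: profile and amplitude errors.

    Returns the max absolute FIR-profile error against the injected
    amp x kernel responses (percent data about the true baseline) and
    the worst relative amplitude error after the scan-mean percent
    signal change conversion (index rescaled by the unit-kernel MSD).
    """
    cset = design.caricature_condition_set(4.0, 1.0, components=3)
    hrf = boldsim.double_gamma_hrf()
    seeds = _study_seeds(seed, 3)
    scheds = [
        design.pool_by_level(design.event_related_schedule(cset, seed=s)) for s in seeds
    ]
    amps = {
        row.level_label: TuningProfile("ramp", baseline=0.3, slope=0.1).amplitude(
            row.level_offset
        )
        for row in cset.itertuples()
    }
    runs = [
        boldsim.simulate_run(sch, 4, amps, noise_sd=0.0, hrf=hrf, seed=i)
        for i, sch in enumerate(scheds)
    ]
    conds = list(amps)
    X = univariate.build_fir_design(scheds, n_lags=n_lags, conditions=conds)

    exact = np.concatenate([r.data - 100.0 for r in runs], axis=1)
    fir = univariate.deconvolve_roi(exact, X, conds, n_lags)
    profile_err = max(
        float(np.abs(fir.profiles[c] - a * hrf.kernel).max()) for c, a in amps.items()
    )

    pre = [preprocess.percent_signal_change(r) for r in runs]
    data, _ = preprocess.concatenate(pre)
    fir_pct = univariate.deconvolve_roi(data, X, conds, n_lags)
    unit = hrf.msd_index()
    amp_err = max(
        abs(univariate.amplitude_index(fir_pct.profiles[c]) / unit - a) / a
        for c, a in amps.items()
    )
    return {"max_profile_error": profile_err, "max_amplitude_rel_error": amp_err}


def mvpa_null_mean_z(n_reps: int = 200, n_voxels: int = 40, n_scans: int = 3, seed: int = 0) -> float:
    """Mean diagonal Fisher Z for independent random beta patterns."""
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_reps):
        pats = mvpa.BetaPatternSet(
            {
                s: {c: rng.standard_normal(n_voxels) for c in UPRIGHT_ORDER}
                for s in range(n_scans)
            },
            UPRIGHT_ORDER,
        )
        vals.append(np.diag(mvpa.cross_scan_correlation(pats).z).mean())
    return float(np.mean(vals))


def mvpa_slope_positive_rate(
    n_studies: int = 100,
    slope: float = 0.1,
    baseline: float = 0.5,
    pattern_strength: float = 0.5,
    noise_sd: float = 0.5,
    n_subjects: int = 9,
    scans_per_subject: int = 3,
    n_voxels: int = 24,
    seed: int = 0,
) -> float:
    """Fraction of studies with a positive fitted slope of group diagonal Z.

    Pattern signal grows with caricature level (ramp amplitudes times a
    fixed per-level pattern), so between-scan pattern consistency should
    increase along the diagonal of the level-pair matrix.
    """
    cset = design.caricature_condition_set(4.0, 1.0, components=3)
    profile = TuningProfile("ramp", baseline=baseline, slope=slope)
    hits = 0
    for s in _study_seeds(seed, n_studies):
        study = boldsim.simulate_study(
            profiles={"roi": profile},
            n_subjects=n_subjects,
            scans_per_subject=scans_per_subject,
            condition_set=cset,
            n_voxels=n_voxels,
            pattern_strength=pattern_strength,
            noise_sd=noise_sd,
            seed=s,
        )
        summs = mvpa.study_correlations(study)
        diag = np.mean([np.diag(x.z) for x in summs.values()], axis=0)
        fit = np.polyfit(np.arange(5), diag, 1)
        hits += fit[0] > 0
    return hits / n_studies


def roi_recovery_accuracy(
    lattice_shape: tuple[int, int, int] = (10, 10, 4),
    effect_pct: float = 5.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> float:
    """Voxel label accuracy for planted category-selective clusters."""
    rng_seeds = _study_seeds(seed, 4)
    anat = np.zeros(lattice_shape, bool)
    anat[1:-1, 1:-1, :] = True
    masks = {}
    for cat, (cx, cy) in {"faces": (2, 2), "objects": (6, 6), "scenes": (2, 6)}.items():
        m = np.zeros(lattice_shape, bool)
        m[cx : cx + 3, cy : cy + 3, 1:3] = True
        masks[cat] = m & anat
    scheds = [design.localiser_schedule(seed=s) for s in rng_seeds[:2]]
    segs = []
    for i, sch in enumerate(scheds):
        Y = boldsim.simulate_localiser_lattice(
            lattice_shape, masks, sch, effect_pct, noise_sd, seed=rng_seeds[2 + i]
        )
        mu = Y.mean(1, keepdims=True)
        segs.append(100.0 * (Y - mu) / mu)
    Yp = np.concatenate(segs, axis=1)
    rois, _ = glm.localiser_roi_pipeline(
        Yp, scheds, anatomical_mask=anat, lattice_shape=lattice_shape
    )
    truth = np.full(Yp.shape[0], "none", dtype=object)
    rename = {"faces": "face", "objects": "object", "scenes": "scene"}
    for cat, m in masks.items():
        truth[m.reshape(-1)] = rename[cat]
    return float((rois.labels == truth.astype(str)).mean())


def facespace_roundtrip(n_faces: int = 50, seed: int = 0) -> dict[str, float]:
    """Round-trip and caricature-linearity errors for a synthetic space.

    Builds a PCA space from ``n_faces`` rendered 100x120 faces, then
    measures the worst relative L2 reconstruction error over the
    training set (all components kept) and the worst relative deviation
    of caricature distance from |s| x loading SD.
    """
    from . import faces as faces_mod
    from . import space as space_mod

    pop = faces_mod.sample_population(n_faces, seed=seed)
    imgs, lsets = [], []
    for p in pop:
        img, lm = faces_mod.render_face(p)
        imgs.append(img)
        lsets.append(lm)
    vectors, _ = space_mod.vectorize_faces(imgs, lsets)
    model = space_mod.build_face_space(vectors)
    worst = 0.0
    for v in vectors:
        rec = space_mod.synthesize(space_mod.project(v, model), model)
        err = np.linalg.norm(rec.to_vector() - v.to_vector()) / np.linalg.norm(
            v.to_vector()
        )
        worst = max(worst, float(err))
    lin = 0.0
    for i in (0, 1, 2):
        for s in (1.0, 3.0, 6.0):
            c = np.zeros(model.k)
            c[i] = s
            d = np.linalg.norm(space_mod.synthesize(c, model).to_vector() - model.mean)
            lin = max(lin, abs(d - s * model.loading_sd[i]) / (s * model.loading_sd[i]))
    return {
        "max_roundtrip_rel_error": worst,
        "max_caricature_linearity_rel_error": float(lin),
        "n_components": model.k,
    }


def stats_null_rejection_rates(n_sim: int = 2000, n_subjects: int = 9, seed: int = 0) -> dict:
    """Rejection rates at alpha=.05 under the i.i.d. Gaussian null.

    Vectorised one-sample t (two-sided) and the one-sided linear-trend
    contrast over 5 levels.
    """
    from scipy.stats import t as t_dist

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_sim, n_subjects))
    t = x.mean(1) / (x.std(1, ddof=1) / np.sqrt(n_subjects))
    rate_t = float((2 * t_dist.sf(np.abs(t), n_subjects - 1) < 0.05).mean())
    data = rng.standard_normal((n_sim, n_subjects, 5))
    w = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    scores = data @ w
    t2 = scores.mean(1) / (scores.std(1, ddof=1) / np.sqrt(n_subjects))
    rate_trend = float((t_dist.sf(t2, n_subjects - 1) < 0.05).mean())
    return {"one_sample_t": rate_t, "linear_trend": rate_trend}
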