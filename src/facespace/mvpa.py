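"""Correlation-based MVPA across caricature levels.

Beta patterns for the 5 upright caricature levels are estimated per scan
with a canonical double-gamma GLM (the 2 inverted conditions enter as
nuisance regressors).  Pattern similarity is the Pearson correlation of
beta maps between scans (within-scan comparisons are avoided), converted
to Fisher Z = atanh(r) and averaged over scan pairs, giving a symmetric
5x5 level-pair matrix per subject per ROI.  Group inference: one-sided
one-sample t-tests per cell (Bonferroni over the 15 unique cells) and a
linear-trend contrast on the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boldsim import Hrf, condition_regressors, double_gamma_hrf
from .design import RunSchedule
from .glm import DesignMatrix, fit_glm, scan_intercepts
from .stats import bonferroni_alpha, linear_trend, t_tests

R_CLAMP = 1.0 - 1e-7


@dataclass
class BetaPatternSet:
    """scan id -> {condition -> per-voxel beta pattern} for one subject/ROI."""

    patterns: dict[int, dict[str, np.ndarray]]
    conditions: list[str]
    roi: str = "roi"

    def __post_init__(self) -> None:
        sizes = {
            p[c].size for p in self.patterns.values() for c in self.conditions
        }
        if len(sizes) > 1:
            raise ValueError("voxel count must be constant across scans")


@dataclass
class CorrelationSummary:
    """Scan-pair-averaged level-pair similarity for one subject/ROI."""

    z: np.ndarray  # (5, 5) mean Fisher Z
    r: np.ndarray  # (5, 5) mean Pearson r
    conditions: list[str]
    n_pairs: int = 0
    flags: list[str] = field(default_factory=list)

    def to_frame(self, subject: int = 0, roi: str = "roi") -> pd.DataFrame:
        rows = []
        for i, ci in enumerate(self.conditions):
            for j, cj in enumerate(self.conditions):
                rows.append(
                    {
                        "subject": subject,
                        "roi": roi,
                        "level_i": ci,
                        "level_j": cj,
                        "mean_r": self.r[i, j],
                        "mean_z": self.z[i, j],
                        "n_pairs": self.n_pairs,
                    }
                )
        return pd.DataFrame(rows)


def per_scan_betas(
    data_pct: np.ndarray,
    schedule: RunSchedule,
    hrf: Hrf | None = None,
    upright_conditions: list[str] | None = None,
    nuisance_conditions: list[str] | None = None,
    filter_matrix: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Canonical-HRF GLM on one scan; returns only the upright beta maps.

    ``data_pct`` is (n_voxels, n_trs) in percent signal.  Upright levels
    are the explanatory variables of interest; inverted conditions are
    modelled but discarded.
    """
    hrf = hrf or double_gamma_hrf(tr=schedule.tr)
    ev = schedule.events
    if upright_conditions is None:
        upright_conditions = list(
            pd.unique(ev.loc[ev["orientation"] == "upright", "trial_type"])
        )
    if nuisance_conditions is None:
        nuisance_conditions = [
            c for c in schedule.conditions if c not in upright_conditions
        ]
    missing = [c for c in upright_conditions if c not in set(ev["trial_type"])]
    if missing:
        raise ValueError(f"schedule is missing conditions {missing}")
    conds = list(upright_conditions) + list(nuisance_conditions)
    X_ev = condition_regressors(schedule, hrf, conds).to_numpy()
    if filter_matrix is not None:
        X_ev = filter_matrix @ X_ev
    X = np.column_stack([X_ev, np.ones(X_ev.shape[0])])
    labels = conds + ["intercept"]
    fit = fit_glm(data_pct.T, DesignMatrix(X, labels))
    return {c: fit.beta[i].copy() for i, c in enumerate(upright_conditions)}


def subject_beta_patterns(
    runs_pct: list[np.ndarray],
    schedules: list[RunSchedule],
    hrf: Hrf | None = None,
    upright_conditions: list[str] | None = None,
    filter_matrix: np.ndarray | None = None,
    roi: str = "roi",
) -> BetaPatternSet:
    patterns = {
        scan: per_scan_betas(
            d, s, hrf=hrf, upright_conditions=upright_conditions, filter_matrix=filter_matrix
        )
        for scan, (d, s) in enumerate(zip(runs_pct, schedules))
    }
    conds = upright_conditions or list(patterns[0])
    return BetaPatternSet(patterns=patterns, conditions=conds, roi=roi)


def _fisher_z(r: float) -> float:
    return float(np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP)))


def cross_scan_correlation(patterns: BetaPatternSet) -> CorrelationSummary:
    """Between-scan Pearson r per level pair, Fisher-Z averaged over scan pairs.

    For each unordered scan pair (s, s') and level pair (i, j) both
    ordered values r(b_i^s, b_j^s') and r(b_j^s, b_i^s') contribute;
    within-scan comparisons never do.  Constant (zero-variance) patterns
    are skipped and flagged.
    """
    scans = sorted(patterns.patterns)
    if len(scans) < 2:
        raise ValueError("need at least 2 scans for between-scan correlations")
    conds = patterns.conditions
    k = len(conds)
    z_sum = np.zeros((k, k))
    r_sum = np.zeros((k, k))
    counts = np.zeros((k, k))
    flags: list[str] = []
    for a_i, s in enumerate(scans):
        for sp in scans[a_i + 1 :]:
            for i in range(k):
                for j in range(i, k):
                    pairs = [(i, j, s, sp)]
                    if i != j:
                        pairs.append((j, i, s, sp))
                    for ii, jj, sa, sb in pairs:
                        x = patterns.patterns[sa][conds[ii]]
                        y = patterns.patterns[sb][conds[jj]]
                        if x.std() == 0 or y.std() == 0:
                            flags.append(f"constant_pattern_scan{sa}_{conds[ii]}")
                            continue
                        r = float(np.corrcoef(x, y)[0, 1])
                        z_sum[i, j] += _fisher_z(r)
                        r_sum[i, j] += r
                        counts[i, j] += 1
    with np.errstate(invalid="ignore"):
        z = np.where(counts > 0, z_sum / np.maximum(counts, 1), np.nan)
        r = np.where(counts > 0, r_sum / np.maximum(counts, 1), np.nan)
    # symmetrise (upper triangle was filled)
    z = np.triu(z) + np.triu(z, 1).T
    r = np.triu(r) + np.triu(r, 1).T
    n_scan_pairs = len(scans) * (len(scans) - 1) // 2
    return CorrelationSummary(z=z, r=r, conditions=conds, n_pairs=n_scan_pairs, flags=flags)


def study_correlations(
    study, highpass_hz: float | None = 0.01, roi: str | None = None
) -> dict[tuple[int, str], CorrelationSummary]:
    """Per-subject correlation summaries for a simulated study bundle.

    Standard chain: percent signal change, optional DCT high-pass with
    matched design filtering, level-pooled per-scan canonical GLMs,
    between-scan correlations.
    """
    from . import preprocess
    from .design import pool_by_level

    cs = study.condition_set
    up = cs[cs["orientation"] == "upright"].sort_values("level_offset")
    upright = list(dict.fromkeys(up["level_label"]))
    out = {}
    for (subj, r), runs in study.runs.items():
        if roi is not None and r != roi:
            continue
        scheds = [pool_by_level(x.schedule) for x in runs]
        if highpass_hz:
            filt = preprocess.highpass_matrix(
                scheds[0].n_volumes, runs[0].tr, highpass_hz
            )
            pre = [
                preprocess.highpass(preprocess.percent_signal_change(x), highpass_hz)
                for x in runs
            ]
        else:
            filt = None
            pre = [preprocess.percent_signal_change(x) for x in runs]
        pats = subject_beta_patterns(
            [p.data for p in pre], scheds,
            upright_conditions=upright, filter_matrix=filt, roi=r,
        )
        out[(subj, r)] = cross_scan_correlation(pats)
    return out


def mvpa_group_tests(
    summaries: list[CorrelationSummary],
    family_alpha: float = 0.05,
    trend_weights: tuple[float, ...] = (-2, -1, 0, 1, 2),
) -> dict:
    """Group tests on subjects' Z matrices.

    Per-cell one-sided one-sample t vs 0 over the 15 unique cells with
    Bonferroni-corrected alpha, plus the within-subject linear trend on
    the 5 diagonal (same-level) cells.
    """
    if len(summaries) < 3:
        raise ValueError("need at least 3 subjects")
    conds = summaries[0].conditions
    k = len(conds)
    stack = np.stack([s.z for s in summaries])  # (n_subjects, k, k)
    n_cells = k * (k + 1) // 2
    alpha = bonferroni_alpha(family_alpha, n_cells)
    cells = []
    for i in range(k):
        for j in range(i, k):
            vals = stack[:, i, j]
            res = t_tests(vals, mode="one_sample", sidedness="greater")
            cells.append(
                {
                    "level_i": conds[i],
                    "level_j": conds[j],
                    "mean_z": float(vals.mean()),
                    "t": res.statistic,
                    "dof": res.dof,
                    "p": res.p,
                    "significant": res.p < alpha,
                    **({"flag": res.flag} if res.flag else {}),
                }
            )
    diag = np.stack([np.diag(s.z) for s in summaries])
    trend = linear_trend(diag, weights=trend_weights, sidedness="greater")
    return {
        "cells": pd.DataFrame(cells),
        "bonferroni_alpha": alpha,
        "n_cells": n_cells,
        "diagonal_trend": trend,
    }
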