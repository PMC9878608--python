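"""Group statistics: within-subject ANOVA, trend contrasts, t-tests, alphas.

The repeated-measures ANOVA uses the orthonormal-contrast formulation:
for each effect the factor levels are projected onto normalised Helmert
contrasts (in-effect factors) and equal-weight means (out-of-effect
factors); with per-subject contrast scores D (subjects x df_effect),

    F = [n * sum(mean(D)^2) / df_effect] / [SS_resid / (df_effect (n-1))]

which reproduces the classical sums of squares exactly for balanced,
fully-crossed designs.  Greenhouse-Geisser epsilon comes from the
covariance S of the contrast scores, eps = tr(S)^2 / (df * tr(S @ S)),
and partial eta squared is SS_effect / (SS_effect + SS_error).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist, norm, t as t_dist


@dataclass
class TestResult:
    statistic: float
    dof: float
    p: float
    sidedness: str = "two-sided"
    mode: str = "one_sample"
    flag: str = ""


@dataclass
class AnovaEffect:
    effect: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    gg_epsilon: float | None = None
    p_gg: float | None = None


@dataclass
class AnovaResult:
    effects: list[AnovaEffect]

    def __getitem__(self, effect: str) -> AnovaEffect:
        for e in self.effects:
            if e.effect == effect:
                return e
        raise KeyError(effect)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {k: (np.nan if v is None else v) for k, v in vars(e).items()}
            for e in self.effects
        ]
        return pd.DataFrame(rows)


def _helmert(k: int) -> np.ndarray:
    """(k-1, k) orthonormal contrast rows (each sums to zero)."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def rm_anova(
    data: pd.DataFrame,
    dv: str = "value",
    within: list[str] | None = None,
    subject: str = "subject",
    gg_min_levels: int = 3,
) -> AnovaResult:
    """Fully-crossed within-subjects ANOVA for 1-3 within factors.

    ``data`` is long format.  Requires a complete balanced design with
    one observation per subject x cell (replicates are averaged) and at
    least 3 subjects.  GG-corrected p is reported for effects whose
    contrast dimension exceeds 1 and which involve a factor with >=
    ``gg_min_levels`` levels; for 2-level effects epsilon is exactly 1.
    """
    within = within or [c for c in data.columns if c not in (dv, subject)]
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1-3 within factors")
    levels = [sorted(data[f].unique()) for f in within]
    shape = [len(l) for l in levels]
    subjects = sorted(data[subject].unique())
    n = len(subjects)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    cell = data.groupby([subject] + within)[dv].mean()
    expected = n * int(np.prod(shape))
    if len(cell) != expected:
        raise ValueError("design has missing cells (must be complete and balanced)")
    # subjects x factor-level tensor
    Y = np.empty([n] + shape)
    for si, s in enumerate(subjects):
        for combo in itertools.product(*[range(k) for k in shape]):
            key = (s,) + tuple(levels[f][i] for f, i in enumerate(combo))
            Y[(si,) + combo] = cell[key]

    effects = []
    for r in range(1, len(within) + 1):
        for subset in itertools.combinations(range(len(within)), r):
            mats = []
            for f, k in enumerate(shape):
                if f in subset:
                    mats.append(_helmert(k))
                else:
                    mats.append(np.full((1, k), 1.0 / k))
            C = mats[0]
            for m in mats[1:]:
                C = np.kron(C, m)
            flat = Y.reshape(n, -1)
            D = flat @ C.T  # (n, df_effect)
            df1 = D.shape[1]
            mean_d = D.mean(axis=0)
            ss_eff = n * float(mean_d @ mean_d)
            resid = D - mean_d
            ss_err = float((resid**2).sum())
            df2 = df1 * (n - 1)
            # degenerate-scale guard: contrast scores that are pure floating
            # fuzz of the input count as exactly zero
            tol = 1e-24 * max(1.0, float((flat**2).sum()))
            ss_eff = 0.0 if ss_eff < tol else ss_eff
            ss_err = 0.0 if ss_err < tol else ss_err
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else (0.0 if ss_eff == 0 else np.inf)
            p = float(f_dist.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
            eps = p_gg = None
            if df1 > 1:
                S = np.cov(D, rowvar=False, ddof=1)
                tr = np.trace(S)
                tr2 = np.trace(S @ S)
                eps = float(tr**2 / (df1 * tr2)) if tr2 > 0 else 1.0
                eps = min(max(eps, 1.0 / df1), 1.0)
                if max(shape[f] for f in subset) >= gg_min_levels:
                    p_gg = float(f_dist.sf(F, df1 * eps, df2 * eps)) if np.isfinite(F) else 0.0
            elif df1 == 1:
                eps = 1.0
            effects.append(
                AnovaEffect(
                    effect="*".join(within[f] for f in subset),
                    F=F,
                    df1=df1,
                    df2=df2,
                    p=p,
                    partial_eta_sq=eta,
                    gg_epsilon=eps,
                    p_gg=p_gg,
                )
            )
    return AnovaResult(effects=effects)


def linear_trend(
    data: np.ndarray,
    weights: tuple[float, ...] = (-2, -1, 0, 1, 2),
    sidedness: str = "greater",
) -> TestResult:
    """One-sample t on per-subject linear contrast scores over ordered levels.

    Equivalent to the ANOVA linear contrast.  ``data`` is subjects x k.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 3:
        raise ValueError("data must be subjects x k with k >= 3")
    w = np.asarray(weights, dtype=float)
    assert abs(w.sum()) < 1e-12, "trend weights must sum to zero"
    if w.size != data.shape[1]:
        raise ValueError("weight length must equal number of levels")
    scores = data @ w
    res = t_tests(scores, mode="one_sample", sidedness=sidedness)
    res.mode = "linear_trend"
    return res


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 1) -> float:
    """Family alpha divided by the comparison count, reported at 3 dp."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(family_alpha / m, 3)


def normal_quantile_z(one_sided_p: float) -> float:
    """Upper-tail standard-normal quantile (Z > 1.64 at p = .05)."""
    if not 0 < one_sided_p < 1:
        raise ValueError("p must lie strictly between 0 and 1")
    return float(norm.isf(one_sided_p))


def t_tests(
    samples: np.ndarray,
    other: np.ndarray | None = None,
    mode: str = "one_sample",
    sidedness: str = "two-sided",
    popmean: float = 0.0,
) -> TestResult:
    """One-sample or paired t-test with explicit sidedness.

    Paired mode tests the difference scores against zero.
    """
    x = np.asarray(samples, dtype=float)
    if mode == "paired":
        if other is None:
            raise ValueError("paired mode requires a second sample")
        y = np.asarray(other, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
        popmean = 0.0
    elif mode != "one_sample":
        raise ValueError("mode must be 'one_sample' or 'paired'")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    flag = ""
    if sd == 0:
        flag = "zero_variance"
        stat = 0.0 if x.mean() == popmean else np.inf * np.sign(x.mean() - popmean)
    else:
        stat = (x.mean() - popmean) / (sd / np.sqrt(n))
    dof = n - 1
    if sidedness == "two-sided":
        p = 2 * float(t_dist.sf(abs(stat), dof))
    elif sidedness == "greater":
        p = float(t_dist.sf(stat, dof))
    elif sidedness == "less":
        p = float(t_dist.cdf(stat, dof))
    else:
        raise ValueError("sidedness must be 'two-sided', 'greater' or 'less'")
    return TestResult(
        statistic=float(stat), dof=dof, p=p, sidedness=sidedness, mode=mode, flag=flag
    )


def caricature_anovas(
    amplitudes: pd.DataFrame,
    dv: str = "index",
    extremes: tuple[int, int] = (-1, 6),
) -> dict[str, AnovaResult]:
    """The two canonical univariate analyses on a tidy amplitude table.

    ``amplitudes`` needs columns subject, hemisphere, orientation,
    level_offset and the dv.  Returns the 2(hemisphere) x 2(orientation)
    x 2(extreme level) ANOVA and the 2(hemisphere) x 5(upright level)
    ANOVA; with an extra ``roi`` column, 3-ROI variants including ROI as
    a factor are returned as well.
    """
    out = {}
    ext = amplitudes[amplitudes["level_offset"].isin(extremes)]
    up = amplitudes[amplitudes["orientation"] == "upright"]
    base = ["hemisphere", "orientation", "level_offset"]
    has_roi = "roi" in amplitudes.columns and amplitudes["roi"].nunique() > 1

    def run(df, factors, name):
        out[name] = rm_anova(
            df.groupby(["subject"] + factors, as_index=False)[dv].mean(),
            dv=dv,
            within=factors,
        )

    run(ext, base, "2x2x2")
    run(up, ["hemisphere", "level_offset"], "2x5")
    if has_roi:
        # ROI variants keep at most 3 factors: hemisphere is collapsed when
        # ROI enters the design, matching the reporting pattern
        run(ext, ["roi", "orientation", "level_offset"], "roi_x_orientation_x_level")
        run(up, ["roi", "level_offset"], "roi_x_level")
    return out
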