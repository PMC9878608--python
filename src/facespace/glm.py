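"""Localiser GLM, contrast Z-maps, FWE thresholding and exclusive ROI labels.

The localiser design has one boxcar-convolved explanatory variable per
stimulus category plus per-scan intercepts.  Category selectivity is a
sum-zero contrast (e.g. faces > objects + scenes with weights
[1, -0.5, -0.5]); t statistics are converted to Z by tail-probability
matching.  Voxels significant for more than one contrast are removed so
each label set is exclusive, and the FFA is the largest contiguous
face-selective cluster (6-connectivity) inside an anatomical mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import ndtri_exp
from scipy.stats import norm, t as t_dist

from .boldsim import boxcar_regressors
from .design import RunSchedule

Z_CAP = 38.0


@dataclass
class DesignMatrix:
    matrix: np.ndarray  # (n_trs, n_regressors)
    labels: list[str]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class GlmFit:
    beta: np.ndarray  # (n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_voxels,)
    dof: int
    xtx_inv: np.ndarray
    labels: list[str] = field(default_factory=list)


def scan_intercepts(n_total: int, transitions: list[int]) -> np.ndarray:
    """Block-diagonal per-scan intercept columns for concatenated data."""
    bounds = list(transitions) + [n_total]
    cols = np.zeros((n_total, len(transitions)))
    for i in range(len(transitions)):
        cols[bounds[i] : bounds[i + 1], i] = 1.0
    return cols


def build_block_design(
    schedules: RunSchedule | list[RunSchedule],
    hrf_params: dict | None = None,
    transitions: list[int] | None = None,
    filter_matrix: np.ndarray | None = None,
) -> DesignMatrix:
    """Category boxcar EVs convolved with the double-gamma HRF + scan intercepts.

    For multiple (concatenated) scans the EV columns are stacked and one
    intercept per scan is appended.  ``filter_matrix`` (per-scan residual
    former from preprocessing) is applied to the EV columns so filtered
    data and design match.
    """
    if isinstance(schedules, RunSchedule):
        schedules = [schedules]
    conds = schedules[0].conditions
    for s in schedules:
        if set(s.conditions) != set(conds):
            raise ValueError("schedules must share condition sets")
    blocks = []
    for s in schedules:
        evs = boxcar_regressors(s, hrf_params=hrf_params, conditions=conds).to_numpy()
        if filter_matrix is not None:
            evs = filter_matrix @ evs
        blocks.append(evs)
    X_ev = np.concatenate(blocks, axis=0)
    n_total = X_ev.shape[0]
    trans = transitions if transitions is not None else list(
        np.cumsum([0] + [s.n_volumes for s in schedules[:-1]])
    )
    X = np.column_stack([X_ev, scan_intercepts(n_total, trans)])
    labels = conds + [f"intercept_{i}" for i in range(len(trans))]
    return DesignMatrix(matrix=X, labels=labels)


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GlmFit:
    """Ordinary least squares per voxel; rejects rank-deficient designs."""
    labels = X.labels if isinstance(X, DesignMatrix) else [f"x{i}" for i in range(X.shape[1])]
    Xm = X.matrix if isinstance(X, DesignMatrix) else np.asarray(X)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != Xm.shape[0]:
        Y = Y.T
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError("Y rows must match design rows")
    rank = np.linalg.matrix_rank(Xm)
    if rank < Xm.shape[1]:
        # report offending columns via QR pivoting heuristic
        _, R = np.linalg.qr(Xm)
        diag = np.abs(np.diag(R))
        bad = [labels[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"rank-deficient design (suspect columns: {bad})")
    beta, _, _, _ = np.linalg.lstsq(Xm, Y, rcond=None)
    resid = Y - Xm @ beta
    dof = Xm.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(Xm.T @ Xm)
    return GlmFit(beta=beta, sigma2=sigma2, dof=dof, xtx_inv=xtx_inv, labels=labels)


def t_to_z(t_vals: np.ndarray, dof: int) -> np.ndarray:
    """Convert t to Z by matching one-sided tail probability, capped at +-38."""
    t_vals = np.asarray(t_vals, dtype=float)
    # work on the negative tail of |t| for numerical stability
    logp = t_dist.logsf(np.abs(t_vals), dof)
    z = -ndtri_exp(logp)  # normal quantile straight from log-p, no underflow
    # degenerate (zero-residual) voxels produce effectively infinite t; give
    # them the cap rather than the tail-matching asymptote
    degenerate = ~np.isfinite(t_vals) | (np.abs(t_vals) > 1e8) | ~np.isfinite(z)
    z = np.where(degenerate, Z_CAP, z)
    z = np.clip(z, -Z_CAP, Z_CAP)
    return np.sign(t_vals) * z


def contrast_zmap(fit: GlmFit, weights: np.ndarray | dict[str, float]) -> np.ndarray:
    """Per-voxel Z statistic for a contrast of the fitted betas."""
    if isinstance(weights, dict):
        c = np.zeros(len(fit.labels))
        for name, w in weights.items():
            c[fit.labels.index(name)] = w
    else:
        c = np.asarray(weights, dtype=float)
        if c.size != fit.beta.shape[0]:
            raise ValueError("contrast length must equal number of regressors")
    eff = c @ fit.beta
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_vals = np.where(var > 0, eff / np.sqrt(var), np.sign(eff) * np.inf)
    return t_to_z(t_vals, fit.dof)


def category_contrast(labels: list[str], target: str, others: list[str]) -> np.ndarray:
    """Sum-zero selectivity contrast: target > mean(others)."""
    c = np.zeros(len(labels))
    c[labels.index(target)] = 1.0
    for o in others:
        c[labels.index(o)] = -1.0 / len(others)
    return c


def fwe_threshold(
    zmap: np.ndarray, alpha: float = 0.05, n_tests: int | None = None, method: str = "bonferroni"
) -> np.ndarray:
    """One-sided threshold mask: Bonferroni over n_tests, or uncorrected.

    With n_tests=1 (or method='uncorrected') the threshold is the plain
    upper-tail quantile, Z = 1.64 at alpha = .05.
    """
    zmap = np.asarray(zmap)
    if n_tests is None:
        n_tests = zmap.size
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    per_voxel_alpha = alpha if method == "uncorrected" else alpha / n_tests
    thresh = norm.isf(per_voxel_alpha)
    return zmap > thresh


@dataclass
class RoiLabels:
    """Exclusive voxel labels plus the contiguous-cluster FFA sub-mask."""

    labels: np.ndarray  # (n_voxels,) of {'face','object','scene','none'}
    ffa_mask: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label


def define_rois(
    face_mask: np.ndarray,
    object_mask: np.ndarray,
    scene_mask: np.ndarray,
    anatomical_mask: np.ndarray | None = None,
    lattice_shape: tuple[int, int, int] | None = None,
) -> RoiLabels:
    """Exclusive face/object/scene voxel assignment + largest-cluster FFA.

    Voxels significant for more than one contrast are labelled 'none'.
    On a 3-D lattice the FFA is the largest 6-connected component of
    face voxels inside the anatomical mask.
    """
    masks = [np.asarray(m).reshape(-1).astype(bool) for m in (face_mask, object_mask, scene_mask)]
    if len({m.size for m in masks}) != 1:
        raise ValueError("masks must share shape")
    overlap = (masks[0].astype(int) + masks[1] + masks[2]) > 1
    labels = np.full(masks[0].size, "none", dtype=object)
    for name, m in zip(("face", "object", "scene"), masks):
        labels[m & ~overlap] = name

    flags = []
    ffa = None
    face_excl = labels == "face"
    if anatomical_mask is not None:
        anat = np.asarray(anatomical_mask).reshape(-1).astype(bool)
        candidates = face_excl & anat
    else:
        candidates = face_excl
    if lattice_shape is not None:
        vol = candidates.reshape(lattice_shape)
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
        lab, n_comp = ndimage.label(vol, structure=structure)
        if n_comp == 0:
            flags.append("ffa_undefined")
        else:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n_comp + 1))
            best = 1 + int(np.argmax(sizes))
            ffa = (lab == best).reshape(-1)
    elif not candidates.any():
        flags.append("ffa_undefined")
    else:
        ffa = candidates
    out = RoiLabels(labels=labels.astype(str), ffa_mask=ffa, flags=flags)
    # exclusivity is structural; assert it on every output
    for a, b in (("face", "object"), ("face", "scene"), ("object", "scene")):
        assert not np.any(out.mask(a) & out.mask(b))
    return out


def save_lattice_nifti(
    values: np.ndarray,
    lattice_shape: tuple[int, int, int],
    path,
    affine: np.ndarray | None = None,
) -> None:
    """Write a flat per-voxel map as a NIfTI volume on the lattice grid."""
    import nibabel as nib

    vol = np.asarray(values, dtype=float).reshape(lattice_shape)
    img = nib.Nifti1Image(vol, affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def localiser_roi_pipeline(
    Y: np.ndarray,
    schedules: list[RunSchedule],
    anatomical_mask: np.ndarray | None = None,
    lattice_shape: tuple[int, int, int] | None = None,
    alpha: float = 0.05,
    fwe_method: str = "bonferroni",
    hrf_params: dict | None = None,
    filter_matrix: np.ndarray | None = None,
) -> tuple[RoiLabels, pd.DataFrame]:
    """Full localiser chain: block GLM, 3 selectivity contrasts, exclusive ROIs."""
    X = build_block_design(schedules, hrf_params=hrf_params, filter_matrix=filter_matrix)
    fit = fit_glm(Y, X)
    cats = schedules[0].conditions
    zmaps = {}
    for cat in cats:
        others = [c for c in cats if c != cat]
        zmaps[cat] = contrast_zmap(fit, category_contrast(fit.labels, cat, others))
    # Y is (n_voxels, n_trs); one test per voxel
    n_tests = Y.shape[0]
    masks = {
        cat: fwe_threshold(z, alpha=alpha, n_tests=n_tests, method=fwe_method)
        for cat, z in zmaps.items()
    }
    # define_rois expects (face, object, scene) order regardless of the
    # shuffled block order the schedule happens to start with
    order = [c for c in ("faces", "objects", "scenes") if c in masks]
    if len(order) != 3:
        order = sorted(cats)
    rois = define_rois(
        masks[order[0]],
        masks[order[1]],
        masks[order[2]],
        anatomical_mask=anatomical_mask,
        lattice_shape=lattice_shape,
    )
    ztable = pd.DataFrame(zmaps)
    return rois, ztable
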