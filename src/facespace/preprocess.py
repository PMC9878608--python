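"""Percent-signal-change conversion, high-pass filtering, scan concatenation.

Raw intensities are converted per voxel to 100*(x - mean)/mean, then
high-pass filtered by projecting out a discrete-cosine basis below the
cutoff frequency (exact linear-algebra realisation, applied per scan
before concatenation).  Concatenation keeps the scan transition indices
so downstream GLMs can carry per-scan intercept/drift blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boldsim import BoldRun


@dataclass
class PreprocRun:
    """Voxels x TRs array in percent-signal units."""

    data: np.ndarray
    tr: float
    source_id: str = ""
    schedule: object = None
    filter_spec: dict = field(default_factory=dict)


def percent_signal_change(run: BoldRun) -> PreprocRun:
    """100 * (x - voxel mean) / voxel mean; per-voxel mean must be positive."""
    means = run.data.mean(axis=1)
    bad = np.where(means <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive voxel means at indices {bad[:10].tolist()}")
    data = 100.0 * (run.data - means[:, None]) / means[:, None]
    return PreprocRun(
        data=data,
        tr=run.tr,
        source_id=f"sub{run.subject_id}_scan{run.scan_id}_{run.roi}",
        schedule=run.schedule,
    )


def dct_basis(n_trs: int, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Orthonormal DCT-II columns with frequency below the cutoff (incl. DC).

    Column k has frequency k / (2 * n_trs * tr) Hz.
    """
    n_k = int(np.ceil(2 * n_trs * tr * cutoff_hz))  # k = 0 .. n_k-1 below cutoff
    t = np.arange(n_trs)
    cols = [np.full(n_trs, 1.0 / np.sqrt(n_trs))]
    for k in range(1, n_k):
        c = np.cos(np.pi * k * (2 * t + 1) / (2 * n_trs))
        cols.append(c * np.sqrt(2.0 / n_trs))
    return np.column_stack(cols)


def highpass_matrix(n_trs: int, tr: float, cutoff_hz: float = 0.01) -> np.ndarray:
    """Residual-forming matrix of the sub-cutoff DCT basis (I - B B^T)."""
    B = dct_basis(n_trs, tr, cutoff_hz)
    return np.eye(n_trs) - B @ B.T


def highpass(run: PreprocRun, cutoff_hz: float = 0.01) -> PreprocRun:
    """Remove frequency content below the cutoff by DCT projection."""
    n = run.data.shape[1]
    nyquist = 1.0 / (2 * run.tr)
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if n * run.tr < 2.0 / cutoff_hz:
        warnings.warn(
            "run shorter than two cutoff periods; high-pass response is coarse",
            stacklevel=2,
        )
    B = dct_basis(n, run.tr, cutoff_hz)
    filt = run.data - (run.data @ B) @ B.T
    return PreprocRun(
        data=filt,
        tr=run.tr,
        source_id=run.source_id,
        schedule=run.schedule,
        filter_spec={"type": "dct_highpass", "cutoff_hz": cutoff_hz},
    )


def concatenate(runs: list[PreprocRun]) -> tuple[np.ndarray, list[int]]:
    """Concatenate over time; returns (data, transition start indices)."""
    if not runs:
        raise ValueError("no runs to concatenate")
    n_vox = runs[0].data.shape[0]
    if any(r.data.shape[0] != n_vox for r in runs):
        raise ValueError("voxel counts differ across runs")
    transitions = []
    t = 0
    for r in runs:
        transitions.append(t)
        t += r.data.shape[1]
    return np.concatenate([r.data for r in runs], axis=1), transitions


def preprocess_runs(
    runs: list[BoldRun], cutoff_hz: float = 0.01
) -> tuple[np.ndarray, list[int], list[PreprocRun]]:
    """Standard chain: percent signal change + high-pass per scan, then concat."""
    pre = [highpass(percent_signal_change(r), cutoff_hz) for r in runs]
    data, transitions = concatenate(pre)
    return data, transitions, pre
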