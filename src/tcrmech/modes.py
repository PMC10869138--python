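"""PCA of triad-arm and bead-on-chain trajectories.

The configuration of two triads at one frame is flattened into an
18-dimensional vector (6 arms × 3 components); the BOC likewise gives 18
dimensions (6 beads × 3 coordinates).  PCA is a covariance
eigen-decomposition of the fluctuations about the post-equilibration mean,
with equal frame weights.  Mode amplitude is the standard deviation of the
per-frame projections — radians for triad arms (unit-length arm tips, small
displacements ≈ rotation angles) and Å for beads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ConfigurationError
from .geometry import BocModel, Triad
from .trajio import AnalysisWindows

__all__ = [
    "PCAResult",
    "AsymmetryReport",
    "triad_arm_matrix",
    "boc_matrix",
    "pca",
    "pca_triads",
    "pca_boc",
    "mode_similarity",
    "project_onto_mode",
    "amplitude_asymmetry",
    "angle_conditional_stats",
]


@dataclass
class PCAResult:
    """Mean configuration, orthonormal modes, amplitudes and projections."""

    mean: np.ndarray               # (d,)
    modes: np.ndarray              # (k, d) rows are unit mode vectors
    amplitudes: np.ndarray         # (k,) std of projections, descending
    projections: np.ndarray        # (n_frames, k), zero-mean on the interval
    units: str = ""

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]


@dataclass
class AsymmetryReport:
    """Per-mode α-amplitude minus β-amplitude for matched groups."""

    difference: np.ndarray         # (k,), antisymmetric under label swap
    alpha_amplitude: np.ndarray
    beta_amplitude: np.ndarray


def triad_arm_matrix(triads_a, triads_b) -> np.ndarray:
    """(n_frames, 18) arm-tip matrix: e1A e2A e3A e1B e2B e3B."""
    return np.array([
        np.concatenate([a.e1, a.e2, a.e3, b.e1, b.e2, b.e3])
        for a, b in zip(triads_a, triads_b)])


def boc_matrix(boc: BocModel) -> np.ndarray:
    """(n_frames, 18) flattened bead coordinates."""
    return boc.beads.reshape(boc.beads.shape[0], -1)


def _fix_sign(modes: np.ndarray) -> np.ndarray:
    """Deterministic sign: first component above tolerance made positive."""
    out = modes.copy()
    for i, mode in enumerate(out):
        nz = np.flatnonzero(np.abs(mode) > 1e-10)
        if nz.size and mode[nz[0]] < 0:
            out[i] = -mode
    return out


def pca(X: np.ndarray, first_frame: int = 0, units: str = "") -> PCAResult:
    """Covariance eigen-decomposition of the configuration matrix ``X``.

    The mean and covariance are estimated from frames ``first_frame:`` (the
    equilibration exclusion); projections are reported for all frames.
    Modes beyond the covariance rank carry zero amplitude.
    """
    X = np.asarray(X, dtype=float)
    sub = X[first_frame:]
    if sub.shape[0] < 2:
        raise ValueError("need at least 2 frames after the cut")
    mean = sub.mean(axis=0)
    cov = np.cov(sub - mean, rowvar=False, bias=True)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0, None)
    modes = _fix_sign(evecs[:, order].T)
    projections = (X - mean) @ modes.T
    amplitudes = projections[first_frame:].std(axis=0)
    return PCAResult(mean, modes, amplitudes, projections, units)


def pca_triads(triads_a, triads_b,
               windows: AnalysisWindows | None = None,
               dt_save: float | None = None) -> PCAResult:
    """18-dim PCA of two triads' arm tips; amplitudes in radians."""
    X = triad_arm_matrix(triads_a, triads_b)
    first = 0
    if windows is not None and dt_save is not None:
        first = min(windows.equil_frame(dt_save), X.shape[0] - 2)
    return pca(X, first_frame=first, units="rad")


def pca_boc(boc: BocModel,
            windows: AnalysisWindows | None = None) -> PCAResult:
    """18-dim PCA of the six BOC beads; amplitudes in Å."""
    X = boc_matrix(boc)
    first = 0
    if windows is not None:
        first = min(windows.equil_frame(boc.dt_save), X.shape[0] - 2)
    return pca(X, first_frame=first, units="Å")


def mode_similarity(mode_a: np.ndarray, mode_b: np.ndarray) -> float:
    """|a · b| between two unit mode vectors, in [0, 1]."""
    a = np.asarray(mode_a, dtype=float).ravel()
    b = np.asarray(mode_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(
            f"mode dimensions differ: {a.shape} vs {b.shape}")
    return float(abs(a @ b))


def project_onto_mode(X: np.ndarray, mode: np.ndarray,
                      mean: np.ndarray) -> np.ndarray:
    """Per-frame projection of (configuration − interval mean) onto a mode."""
    X = np.asarray(X, dtype=float)
    return (X - np.asarray(mean)) @ np.asarray(mode)


def amplitude_asymmetry(result: PCAResult,
                        group_map: dict[str, list[int]]) -> AsymmetryReport:
    """Per-mode α-minus-β rms displacement within each mode vector.

    ``group_map`` maps ``"alpha"``/``"beta"`` to matched lists of bead (or
    arm) indices; each index selects one 3-component block of the mode
    vector.  The rms of the blocks' norms, scaled by the mode amplitude,
    gives each chain's motion amplitude in that mode.
    """
    try:
        alpha = list(group_map["alpha"])
        beta = list(group_map["beta"])
    except KeyError as exc:
        raise ConfigurationError("group_map needs 'alpha' and 'beta'") from exc
    if len(alpha) != len(beta) or set(alpha) & set(beta):
        raise ConfigurationError(
            "alpha/beta groups must be disjoint and matched in size")
    blocks = result.modes.reshape(result.n_modes, -1, 3)
    amp_a = np.array([
        np.sqrt(np.mean(np.sum(blocks[m, alpha] ** 2, axis=1)))
        * result.amplitudes[m] for m in range(result.n_modes)])
    amp_b = np.array([
        np.sqrt(np.mean(np.sum(blocks[m, beta] ** 2, axis=1)))
        * result.amplitudes[m] for m in range(result.n_modes)])
    return AsymmetryReport(amp_a - amp_b, amp_a, amp_b)


def angle_conditional_stats(angle_series: np.ndarray,
                            scalar_series: np.ndarray,
                            n_bins: int = 20,
                            sparse_count: int = 5) -> pd.DataFrame:
    """Scalar mean ± std binned by angle (e.g. CDR3 distance vs ∠e3).

    Bins with fewer than ``sparse_count`` frames are flagged ``sparse`` —
    statistics deteriorate in the thinly populated angle tails.
    """
    angle = np.asarray(angle_series, dtype=float)
    scalar = np.asarray(scalar_series, dtype=float)
    if angle.shape != scalar.shape:
        raise ValueError("series lengths differ")
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    edges = np.linspace(angle.min(), angle.max() + 1e-9, n_bins + 1)
    which = np.clip(np.digitize(angle, edges) - 1, 0, n_bins - 1)
    records = []
    for b in range(n_bins):
        mask = which == b
        vals = scalar[mask]
        records.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "count": int(mask.sum()),
            "mean": float(vals.mean()) if vals.size else np.nan,
            "std": float(vals.std()) if vals.size else np.nan,
            "sparse": bool(mask.sum() < sparse_count),
        })
    return pd.DataFrame.from_records(records)
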