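"""Restraint-based force estimation and the harmonic-restraint thermal contract.

The applied load is measured from a harmonically restrained anchor as
``F = k · ⟨x − x₀⟩`` (energy convention ``E = ½ k |Δx|²``), converted to
piconewtons via 1 kcal/(mol·Å) = 69.479 pN.  Under the same convention a
restrained coordinate in thermal equilibrium has per-coordinate rms
``sqrt(k_B T / k)`` — 0.772 Å at k = 1 kcal/(mol·Å²) and 300 K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ConfigurationError
from .trajio import AnalysisWindows, SelectionError, StructureModel, Trajectory

__all__ = [
    "KCAL_PER_MOL_ANGSTROM_IN_PN",
    "KB_KCAL_PER_MOL_K",
    "RestraintSpec",
    "ForceEstimate",
    "anchor_positions",
    "estimate_force",
    "thermal_amplitude",
    "force_decomposition",
    "flat_bottom_force",
]

#: 1 kcal/(mol·Å) expressed in pN.
KCAL_PER_MOL_ANGSTROM_IN_PN = 69.479

#: Boltzmann constant in kcal/(mol·K); k_B·T = 0.5962 kcal/mol at 300 K.
KB_KCAL_PER_MOL_K = 0.0019872041


@dataclass
class RestraintSpec:
    """A harmonic positional restraint on an atom or group COM.

    ``anchor`` is a list of (chain, resindex, atom name) triples — one entry
    restrains a single atom (e.g. Cα of MHC I284), several restrain their
    centre of mass (e.g. Cα of αT218 + βA260).  ``center`` is the restraint
    centre at the current extension.  The optional flat-bottom pair restraint
    (10 Å onset, 1 kcal/(mol·Å²)) keeps the two TCR anchor atoms together.
    """

    anchor: list[tuple[str, int, str]]
    center: np.ndarray
    k: float = 1.0                      # kcal/(mol·Å²)
    extension_label: str = ""
    convention: str = "half_k"          # E = ½k|Δx|² (default) or "full_k"
    flat_bottom_onset: float = 10.0     # Å
    flat_bottom_k: float = 1.0          # kcal/(mol·Å²)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("spring constant must be positive")
        if self.convention not in ("half_k", "full_k"):
            raise ValueError("convention must be 'half_k' or 'full_k'")
        self.center = np.asarray(self.center, dtype=float).reshape(3)

    def resolve(self, structure: StructureModel) -> np.ndarray:
        try:
            return np.array([structure.atom_index(*a) for a in self.anchor])
        except KeyError as exc:
            raise SelectionError(
                f"restraint anchor not resolvable: {exc}") from exc


@dataclass
class ForceEstimate:
    """Mean restraint force over the declared interval plus window statistics."""

    mean_vector_pn: np.ndarray
    magnitude_pn: float
    window_table: pd.DataFrame          # per 40-ns window mean force
    window_std_pn: float                # std of the window-mean magnitudes
    longitudinal_pn: float | None = None
    transverse_pn: float | None = None


def anchor_positions(traj: Trajectory, spec: RestraintSpec) -> np.ndarray:
    """(n_frames, 3) anchor (atom or group-COM) positions."""
    idx = spec.resolve(traj.structure)
    return traj.coords[:, idx, :].mean(axis=1)


def _spring_to_pn(spec: RestraintSpec) -> float:
    k_eff = spec.k if spec.convention == "half_k" else 2 * spec.k
    return k_eff * KCAL_PER_MOL_ANGSTROM_IN_PN


def estimate_force(traj: Trajectory, spec: RestraintSpec,
                   windows: AnalysisWindows | None = None,
                   axis: np.ndarray | None = None) -> ForceEstimate:
    """Restraint force from the anchor's average displacement.

    The mean force is ``k·⟨x − x₀⟩`` over the post-equilibration frames;
    window means use the standard 40-ns spans stepping 20 ns from 200 ns, and
    the reported std is over those window-mean magnitudes.  ``axis``
    (optional) adds a longitudinal/transverse decomposition.
    """
    windows = windows or AnalysisWindows()
    pos = anchor_positions(traj, spec)
    disp = pos - spec.center
    scale = _spring_to_pn(spec)
    cut = windows.equil_frame(traj.dt_save)
    cut = min(cut, len(disp) - 1)
    mean_vec = scale * disp[cut:].mean(axis=0)
    magnitude = float(np.linalg.norm(mean_vec))

    records = []
    for start, end in windows.window_spans(traj.total_time):
        i0 = int(round(start / traj.dt_save))
        i1 = int(round(end / traj.dt_save))
        vec = scale * disp[i0:i1].mean(axis=0)
        records.append({"start_ns": start, "end_ns": end,
                        "fx_pn": vec[0], "fy_pn": vec[1], "fz_pn": vec[2],
                        "magnitude_pn": float(np.linalg.norm(vec))})
    table = pd.DataFrame.from_records(records)
    window_std = float(table["magnitude_pn"].std(ddof=0)) if len(
        table) else float("nan")

    longitudinal = transverse = None
    if axis is not None:
        longitudinal, transverse = force_decomposition(
            mean_vec[None, :], axis)
        longitudinal = float(longitudinal[0])
        transverse = float(transverse[0])
    return ForceEstimate(mean_vec, magnitude, table, window_std,
                         longitudinal, transverse)


def thermal_amplitude(k: float, T: float = 300.0,
                      convention: str = "half_k") -> float:
    """Per-coordinate rms fluctuation (Å) of a harmonically restrained atom.

    Equipartition under ``E = ½kΔx²`` gives ``sqrt(k_B·T/k)``: 0.772 Å at
    k = 1 kcal/(mol·Å²) and 300 K, i.e. the ∼0.8 Å scale of a stiff
    positional restraint.
    """
    if k <= 0 or T <= 0:
        raise ValueError("k and T must be positive")
    k_eff = k if convention == "half_k" else 2 * k
    return float(np.sqrt(KB_KCAL_PER_MOL_K * T / k_eff))


def force_decomposition(force_vectors: np.ndarray, axis: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Longitudinal (signed) and transverse (magnitude) components per frame.

    The axis is the line through the two restraint anchor centres; components
    satisfy |F|² = F∥² + F⊥².
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ConfigurationError("zero-length load axis")
    axis = axis / norm
    F = np.atleast_2d(np.asarray(force_vectors, dtype=float))
    longitudinal = F @ axis
    transverse = np.linalg.norm(F - np.outer(longitudinal, axis), axis=1)
    return longitudinal, transverse


def flat_bottom_force(pair_distance: float, onset: float = 10.0,
                      k: float = 1.0) -> float:
    """Restoring force (kcal/(mol·Å)) of the flat-bottom pair restraint.

    Zero below the onset distance; ``k·(d − onset)`` beyond it (harmonic
    ½k(d−onset)² energy).
    """
    if pair_distance < 0:
        raise ValueError("distance must be non-negative")
    return 0.0 if pair_distance <= onset else k * (pair_distance - onset)
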