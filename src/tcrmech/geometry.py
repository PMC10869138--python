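"""Domain triads, the V-C bead-on-chain model, and scalar order parameters.

A triad is an orthonormal frame {e1, e2, e3} fitted to a variable domain's
β-sheet core: e3 runs along the major in-plane axis of the least-squares
plane of the core Cα atoms (parallel to the strands, signed toward the CDR3
loop), e1 points from the inner to the outer β-sheet (orthogonalised against
e3), and e2 = e3 × e1.  The bead-on-chain (BOC) model reduces TCRαβ to six
beads — Vα, Vβ, Cα, Cβ core centroids plus the two V-C hinges — expressed in
a C-module-aligned reference frame so that V-module motion relative to the
C-module can be compared across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .trajio import SelectionError, StructureModel, Trajectory

__all__ = [
    "GeometryError",
    "Triad",
    "TriadSpec",
    "BocSpec",
    "BocModel",
    "ScalarSeries",
    "fit_triad",
    "compute_triads",
    "triad_angles",
    "triad_angle_series",
    "cdr3_distance",
    "cdr3_distance_series",
    "kabsch",
    "align_frames",
    "build_boc",
    "hinge_angles",
    "peptide_angle",
    "rmsf",
    "transverse_rmsf",
    "DEFAULT_TRIAD_SPECS",
    "DEFAULT_BOC_SPEC",
    "DEFAULT_CDR3_RESIDUES",
]


class GeometryError(ValueError):
    """Degenerate geometry (collinear cores, coincident beads, ...)."""


@dataclass
class Triad:
    """Orthonormal right-handed frame (e2 = e3 × e1) plus its centroid."""

    centroid: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray

    def __post_init__(self) -> None:
        for arm in (self.e1, self.e2, self.e3):
            if abs(np.linalg.norm(arm) - 1.0) > 1e-8:
                raise GeometryError("triad arms must be unit vectors")
        if (abs(self.e1 @ self.e2) > 1e-8 or abs(self.e1 @ self.e3) > 1e-8
                or abs(self.e2 @ self.e3) > 1e-8):
            raise GeometryError("triad arms must be pairwise orthogonal")

    @property
    def arms(self) -> np.ndarray:
        """(3, 3) array with rows e1, e2, e3."""
        return np.vstack((self.e1, self.e2, self.e3))


@dataclass
class TriadSpec:
    """Residue bookkeeping for fitting one domain's triad.

    ``segments`` are inclusive (start, end) renumbered-residue ranges of the
    four central β-strands; ``inner``/``outer`` index into that list to give
    the two sheets (default: strands 1+4 vs 2+3).  ``cdr3_base`` holds the
    two residues at the base of the domain's CDR3 loop, used to sign e3.
    """

    chain: str
    segments: tuple = ()
    inner: tuple[int, ...] = (0, 3)
    outer: tuple[int, ...] = (1, 2)
    cdr3_base: tuple[int, int] = (92, 97)

    def core_atoms(self, structure: StructureModel) -> np.ndarray:
        return structure.select_segments(self.chain, self.segments)

    def sheet_atoms(self, structure: StructureModel, which: str) -> np.ndarray:
        picks = self.inner if which == "inner" else self.outer
        return structure.select_segments(
            self.chain, [self.segments[i] for i in picks])

    def cdr3_atoms(self, structure: StructureModel) -> np.ndarray:
        idx = structure.select(chain=self.chain, resindices=list(
            self.cdr3_base), names="CA")
        if len(idx) != 2:
            raise SelectionError(
                f"CDR3 base residues {self.cdr3_base} of chain {self.chain} "
                "not resolvable")
        return idx


#: β-sheet core segments of the A6 variable domains (renumbered indices):
#: Vα S19-Y24, F32-Q37, Y70-I75, Y86-T91; Vβ T20-Q25, S33-D38, F74-L79,
#: V88-S93.  CDR3 bases: αT92/αK97 and βR94/βE103.
DEFAULT_TRIAD_SPECS = {
    "alpha": TriadSpec("D", ((19, 24), (32, 37), (70, 75), (86, 91)),
                       cdr3_base=(92, 97)),
    "beta": TriadSpec("E", ((20, 25), (33, 38), (74, 79), (88, 93)),
                      cdr3_base=(94, 103)),
}

#: CDR3 base Cα residues used for the CDR3 distance: midpoint(αT92, αK97) to
#: midpoint(βR94, βE103).
DEFAULT_CDR3_RESIDUES = (("D", 92), ("D", 97), ("E", 94), ("E", 103))


def fit_triad(core_coords: np.ndarray,
              inner_com: np.ndarray, outer_com: np.ndarray,
              cdr3_point: np.ndarray | None = None,
              prev_e3: np.ndarray | None = None) -> Triad:
    """Fit a triad to a set of core Cα coordinates.

    e3 is the major in-plane axis of the least-squares plane of the core,
    signed so it points toward ``cdr3_point`` (or continuously with
    ``prev_e3``); e1 is the inner→outer sheet direction orthogonalised
    against e3; e2 closes the right-handed frame.
    """
    pts = np.asarray(core_coords, dtype=float)
    if pts.shape[0] < 6:
        raise GeometryError("need at least 6 core points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    if s[1] < 1e-8 * s[0]:
        raise GeometryError("core points are collinear")
    e3 = vt[0]  # major axis of the least-squares plane
    if cdr3_point is not None:
        if e3 @ (np.asarray(cdr3_point) - centroid) < 0:
            e3 = -e3
    elif prev_e3 is not None and e3 @ prev_e3 < 0:
        e3 = -e3
    sheet = np.asarray(outer_com, dtype=float) - np.asarray(
        inner_com, dtype=float)
    e1 = sheet - (sheet @ e3) * e3
    norm = np.linalg.norm(e1)
    if norm < 1e-10:
        raise GeometryError("sheet direction parallel to e3")
    e1 = e1 / norm
    e2 = np.cross(e3, e1)
    return Triad(centroid, e1, e2, e3)


def compute_triads(traj: Trajectory, spec: TriadSpec,
                   sign_from_cdr3: bool = True) -> list[Triad]:
    """Per-frame triads for one domain.

    The e3 sign is fixed toward the CDR3 base midpoint at the first frame and
    kept continuous frame-to-frame thereafter.
    """
    structure = traj.structure
    core = spec.core_atoms(structure)
    inner = spec.sheet_atoms(structure, "inner")
    outer = spec.sheet_atoms(structure, "outer")
    cdr3 = spec.cdr3_atoms(structure) if sign_from_cdr3 else None
    triads: list[Triad] = []
    prev_e3 = None
    for f in range(traj.n_frames):
        coords = traj.coords[f]
        cdr3_mid = coords[cdr3].mean(axis=0) if (
            cdr3 is not None and prev_e3 is None) else None
        triads.append(fit_triad(
            coords[core], coords[inner].mean(axis=0),
            coords[outer].mean(axis=0),
            cdr3_point=cdr3_mid, prev_e3=prev_e3))
        prev_e3 = triads[-1].e3
    return triads


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cosang = np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    return float(np.degrees(np.arccos(cosang)))


def triad_angles(triad_a: Triad, triad_b: Triad) -> tuple[float, float, float]:
    """(∠e1, ∠e2, ∠e3) between matching arms, in degrees."""
    return tuple(_angle_deg(a, b) for a, b in
                 zip(triad_a.arms, triad_b.arms))


def triad_angle_series(triads_a, triads_b) -> np.ndarray:
    """(n_frames, 3) array of the three inter-triad arm angles."""
    return np.array([triad_angles(a, b)
                     for a, b in zip(triads_a, triads_b)])


def cdr3_distance(frame_coords: np.ndarray, structure: StructureModel,
                  residues=DEFAULT_CDR3_RESIDUES) -> float:
    """Distance between the CDR3α and CDR3β base midpoints (Å)."""
    atoms = []
    for chain, resindex in residues:
        atoms.append(structure.atom_index(chain, resindex, "CA"))
    coords = np.asarray(frame_coords, dtype=float)
    mid_a = coords[atoms[:2]].mean(axis=0)
    mid_b = coords[atoms[2:]].mean(axis=0)
    return float(np.linalg.norm(mid_a - mid_b))


def cdr3_distance_series(traj: Trajectory,
                         residues=DEFAULT_CDR3_RESIDUES) -> "ScalarSeries":
    values = np.array([cdr3_distance(traj.coords[f], traj.structure, residues)
                       for f in range(traj.n_frames)])
    return ScalarSeries(values, traj.dt_save, "Å")


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares superposition: returns (rotation matrix, translation).

    Applying ``coords @ R.T + t`` superposes ``mobile`` onto ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    return R, t


def align_frames(traj: Trajectory, align_idx: np.ndarray,
                 reference_coords: np.ndarray) -> np.ndarray:
    """All frames superposed on ``reference_coords`` via ``align_idx`` atoms.

    Returns a new (n_frames, n_atoms, 3) array; the input is untouched.
    """
    align_idx = np.asarray(align_idx, dtype=int)
    ref = np.asarray(reference_coords, dtype=float)[align_idx]
    out = np.empty_like(traj.coords)
    for f in range(traj.n_frames):
        R, t = kabsch(traj.coords[f][align_idx], ref)
        out[f] = traj.coords[f] @ R.T + t
    return out


@dataclass
class BocSpec:
    """Residue bookkeeping for the six-bead V-C bead-on-chain model."""

    v_alpha: TriadSpec
    v_beta: TriadSpec
    c_alpha_chain: str = "D"
    c_alpha_segments: tuple = ((118, 123), (132, 137), (153, 158), (171, 176))
    c_beta_chain: str = "E"
    c_beta_segments: tuple = ((143, 148), (158, 163), (192, 197), (209, 214))
    hinge_alpha: tuple[str, tuple[int, ...]] = ("D", (114,))
    hinge_beta: tuple[str, tuple[int, ...]] = ("E", (117, 118))

    def c_module_atoms(self, structure: StructureModel) -> np.ndarray:
        return np.concatenate([
            structure.select_segments(self.c_alpha_chain,
                                      self.c_alpha_segments),
            structure.select_segments(self.c_beta_chain,
                                      self.c_beta_segments)])

    def hinge_atoms(self, structure: StructureModel, which: str) -> np.ndarray:
        chain, resids = (self.hinge_alpha if which == "alpha"
                         else self.hinge_beta)
        idx = structure.select(chain=chain, resindices=list(resids),
                               names="CA")
        if len(idx) != len(resids):
            raise SelectionError(f"hinge residues {chain}:{resids} missing")
        return idx


#: Bead definitions for the A6 complex (renumbered indices): Cα core
#: A118–R123, V132–D137, Y153–T158, S171–S176; Cβ core T143–A148, L158–N163,
#: S192–V197, F209–Q214; hinges Hα = Cα of αN114 and Hβ = midpoint of
#: βD117/βL118 Cα atoms.
DEFAULT_BOC_SPEC = BocSpec(
    v_alpha=DEFAULT_TRIAD_SPECS["alpha"], v_beta=DEFAULT_TRIAD_SPECS["beta"])

BEAD_NAMES = ("Valpha", "Vbeta", "Calpha", "Cbeta", "Halpha", "Hbeta")


@dataclass
class BocModel:
    """Six beads per frame in the C-module-aligned reference frame."""

    beads: np.ndarray              # (n_frames, 6, 3): Vα Vβ Cα Cβ Hα Hβ
    dt_save: float
    bead_names: tuple = BEAD_NAMES


def build_boc(traj: Trajectory, spec: BocSpec = DEFAULT_BOC_SPEC,
              reference_coords: np.ndarray | None = None) -> BocModel:
    """Build the six-bead chain, aligned to the reference C-module.

    Every frame is superposed on ``reference_coords`` (default: the
    trajectory's own first frame; pass a designated run's first frame to put
    several systems in one common reference) using the C-module core atoms,
    then the beads are emitted: V centroids, C centroids and the two hinges.
    """
    structure = traj.structure
    c_atoms = spec.c_module_atoms(structure)
    if reference_coords is None:
        reference_coords = traj.coords[0]
    aligned = align_frames(traj, c_atoms, reference_coords)

    v_a = spec.v_alpha.core_atoms(structure)
    v_b = spec.v_beta.core_atoms(structure)
    c_a = structure.select_segments(spec.c_alpha_chain, spec.c_alpha_segments)
    c_b = structure.select_segments(spec.c_beta_chain, spec.c_beta_segments)
    h_a = spec.hinge_atoms(structure, "alpha")
    h_b = spec.hinge_atoms(structure, "beta")

    beads = np.empty((traj.n_frames, 6, 3))
    for f in range(traj.n_frames):
        coords = aligned[f]
        beads[f, 0] = coords[v_a].mean(axis=0)
        beads[f, 1] = coords[v_b].mean(axis=0)
        beads[f, 2] = coords[c_a].mean(axis=0)
        beads[f, 3] = coords[c_b].mean(axis=0)
        beads[f, 4] = coords[h_a].mean(axis=0)
        beads[f, 5] = coords[h_b].mean(axis=0)
    return BocModel(beads, traj.dt_save)


def hinge_angles(boc: BocModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame hinge angles ∠TCRα and ∠TCRβ in degrees.

    ∠TCRα is the angle at the Hα bead between Hα→Vα and Hα→Cα; ∠TCRβ is
    defined analogously.
    """
    out = []
    for v, c, h in ((0, 2, 4), (1, 3, 5)):
        u1 = boc.beads[:, v] - boc.beads[:, h]
        u2 = boc.beads[:, c] - boc.beads[:, h]
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
            raise GeometryError("coincident beads; hinge angle undefined")
        cosang = np.clip(np.sum(u1 * u2, axis=1) / (n1 * n2), -1, 1)
        out.append(np.degrees(np.arccos(cosang)))
    return out[0], out[1]


@dataclass
class ScalarSeries:
    """A per-frame scalar with units and interval statistics."""

    values: np.ndarray
    dt_save: float
    units: str = ""

    def interval_stats(self, start_ns: float = 0.0,
                       end_ns: float | None = None) -> tuple[float, float]:
        """(mean, std) over the declared interval."""
        i0 = int(round(start_ns / self.dt_save))
        i1 = (len(self.values) if end_ns is None
              else int(round(end_ns / self.dt_save)))
        window = self.values[i0:i1]
        return float(window.mean()), float(window.std())

    def running_average(self, window_ns: float) -> np.ndarray:
        """Trailing running average over ``window_ns`` (truncated at start)."""
        import pandas as pd

        w = max(1, int(round(window_ns / self.dt_save)))
        return pd.Series(self.values).rolling(
            w, min_periods=1).mean().to_numpy()


def _fit_line_direction(points: np.ndarray) -> np.ndarray:
    """Unit direction of the least-squares line through ``points``."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise GeometryError("need at least 2 points to fit a line")
    _, s, vt = np.linalg.svd(pts - pts.mean(axis=0))
    if s[0] < 1e-10:
        raise GeometryError("coincident points; line direction undefined")
    return vt[0]


def peptide_angle(traj: Trajectory, peptide_ca: np.ndarray,
                  triads_a, triads_b) -> ScalarSeries:
    """Angle between the peptide axis and the Vα→Vβ centroid vector.

    The peptide axis is the least-squares fit line through the peptide
    backbone Cα atoms (undirected), so the angle is reported in [0°, 90°].
    """
    peptide_ca = np.asarray(peptide_ca, dtype=int)
    if peptide_ca.size < 3:
        raise GeometryError("need at least 3 peptide Cα atoms")
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        direction = _fit_line_direction(traj.coords[f][peptide_ca])
        v = triads_b[f].centroid - triads_a[f].centroid
        norm = np.linalg.norm(v)
        if norm < 1e-10:
            raise GeometryError("coincident triad centroids")
        cosang = abs(direction @ v / norm)
        values[f] = np.degrees(np.arccos(np.clip(cosang, 0, 1)))
    return ScalarSeries(values, traj.dt_save, "deg")


def rmsf(traj: Trajectory, selection: np.ndarray,
         alignment_selection: np.ndarray | None = None,
         reference_frame: int = 0) -> np.ndarray:
    """Per-atom RMSF (Å) about the mean position after superposition.

    Frames are aligned on ``alignment_selection`` (default: the selection
    itself) to the coordinates at ``reference_frame``, then each selected
    atom's root-mean-square deviation from its mean position is returned.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty selection")
    if alignment_selection is None:
        alignment_selection = selection
    aligned = align_frames(traj, alignment_selection,
                           traj.coords[reference_frame])
    sub = aligned[:, selection, :]
    mean = sub.mean(axis=0)
    return np.sqrt(np.mean(np.sum((sub - mean) ** 2, axis=2), axis=0))


def transverse_rmsf(traj: Trajectory, group: np.ndarray,
                    axis: np.ndarray) -> float:
    """RMSF of a group's Cα COM in the plane orthogonal to the load axis (Å).

    The load axis is the line through the two restraint anchors; motion along
    it does not contribute.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-10:
        raise ValueError("load axis is undefined (zero vector)")
    axis = axis / norm
    group = np.asarray(group, dtype=int)
    com = traj.coords[:, group, :].mean(axis=1)
    transverse = com - np.outer(com @ axis, axis)
    mean = transverse.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((transverse - mean) ** 2, axis=1))))
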