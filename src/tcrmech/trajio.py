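"""Structure and trajectory I/O with residue renumbering and frame bookkeeping.

Conventions used throughout the package: coordinates in Å, times in ns,
residue indices 1-based and sequential within each chain after renumbering
(crystallographic numbering is retained as per-atom metadata). Frames are
assumed to be saved at a fixed stride ``dt_save`` so that frame ``i``
corresponds to elapsed time ``i * dt_save``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParseError",
    "StructureError",
    "SelectionError",
    "StructureModel",
    "Trajectory",
    "AnalysisWindows",
    "read_structure",
    "read_trajectory",
    "read_charge_table",
    "annotate_polar_atoms",
    "frames_for_duration",
    "slice_trajectory",
    "write_frames_txt",
    "read_frames_txt",
]


class ParseError(ValueError):
    """A structure or trajectory file could not be parsed."""


class StructureError(ValueError):
    """A parsed structure violates a model invariant (e.g. duplicate atom)."""


class SelectionError(KeyError):
    """A requested chain/residue/atom does not exist in the structure."""


# Protein heavy atoms that can act as hydrogen-bond donors / acceptors when
# explicit hydrogens are absent (crystal structures).  A deliberately simple,
# residue-name keyed heuristic: backbone N donates (except proline), backbone
# O/OXT accepts, hydroxyls both donate and accept.
_SIDECHAIN_DONORS = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "ASN": {"ND2"},
    "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"},
    "HSD": {"ND1"},
    "HSE": {"NE2"},
    "TRP": {"NE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "CYS": {"SG"},
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "HIS": {"ND1", "NE2"},
    "HSD": {"NE2"},
    "HSE": {"ND1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "MET": {"SD"},
}

_TWO_LETTER_ELEMENTS = {"CL", "NA", "MG", "ZN", "FE", "BR", "MN", "CA_ION"}


def _element_from_name(name: str) -> str:
    """Guess the element from a PDB atom name (fallback when unannotated)."""
    stripped = "".join(c for c in name if c.isalpha()).upper()
    if not stripped:
        return "X"
    if stripped[:2] in _TWO_LETTER_ELEMENTS:
        return stripped[:2].capitalize()
    return stripped[0]


@dataclass
class StructureModel:
    """Atoms, chains and optional per-atom annotations of one structure.

    ``res_index`` is the sequential (1-based, per chain) renumbered residue
    index; ``orig_res_num`` keeps the numbering found in the source file.
    """

    names: np.ndarray
    elements: np.ndarray
    chain_ids: np.ndarray
    res_index: np.ndarray
    res_names: np.ndarray
    orig_res_num: np.ndarray
    coords: np.ndarray
    charges: np.ndarray | None = None
    is_donor: np.ndarray | None = None
    is_acceptor: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "chain_ids", "res_index", "res_names",
                     "orig_res_num"):
            if len(getattr(self, attr)) != n:
                raise StructureError(f"{attr} length mismatch ({n} atoms)")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if self.charges is not None:
            self.charges = np.asarray(self.charges, dtype=float)
            if self.charges.shape != (n,):
                raise StructureError("charge array length mismatch")
            if not np.all(np.isfinite(self.charges)) or np.any(
                    np.abs(self.charges) >= 3.0):
                raise StructureError(
                    "partial charges must be finite with |q| < 3e")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def chains(self) -> dict[str, list[int]]:
        """Ordered mapping chain id -> sorted unique residue indices."""
        out: dict[str, list[int]] = {}
        for cid in dict.fromkeys(self.chain_ids.tolist()):
            mask = self.chain_ids == cid
            out[cid] = sorted(set(self.res_index[mask].tolist()))
        return out

    def atom_index(self, chain: str, resindex: int, name: str) -> int:
        """Index of a single atom; raises :class:`SelectionError` if absent."""
        hits = np.flatnonzero(
            (self.chain_ids == chain)
            & (self.res_index == int(resindex))
            & (self.names == name)
        )
        if hits.size == 0:
            raise SelectionError(
                f"atom {name} of residue {chain}:{resindex} not found")
        return int(hits[0])

    def select(self, chain: str | None = None,
               resindices=None, names=None) -> np.ndarray:
        """Atom indices matching all given criteria (None = no constraint)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_ids == chain
        if resindices is not None:
            mask &= np.isin(self.res_index, np.atleast_1d(resindices))
        if names is not None:
            mask &= np.isin(self.names, np.atleast_1d(names))
        return np.flatnonzero(mask)

    def select_segments(self, chain: str,
                        segments, names="CA") -> np.ndarray:
        """Atom indices for a list of inclusive (start, end) residue ranges."""
        resids: list[int] = []
        for start, end in segments:
            resids.extend(range(int(start), int(end) + 1))
        idx = self.select(chain=chain, resindices=resids, names=names)
        if len(idx) != len(resids):
            raise SelectionError(
                f"chain {chain}: expected {len(resids)} atoms for segments "
                f"{segments}, found {len(idx)}")
        return idx

    def residue_name(self, chain: str, resindex: int) -> str:
        idx = self.select(chain=chain, resindices=[resindex])
        if idx.size == 0:
            raise SelectionError(f"residue {chain}:{resindex} not found")
        return str(self.res_names[idx[0]])

    def residue_key(self, atom: int) -> tuple[str, int]:
        return str(self.chain_ids[atom]), int(self.res_index[atom])


@dataclass
class Trajectory:
    """Per-frame Cartesian coordinates (Å) tied to a :class:`StructureModel`."""

    coords: np.ndarray              # (n_frames, n_atoms, 3)
    dt_save: float                  # ns per frame
    structure: StructureModel

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.structure.n_atoms:
            raise StructureError(
                "frame atom count differs from the structure's")
        if self.dt_save <= 0:
            raise ValueError("dt_save must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Elapsed time of each frame in ns (frame i at i * dt_save)."""
        return np.arange(self.n_frames) * self.dt_save

    @property
    def total_time(self) -> float:
        return self.n_frames * self.dt_save


@dataclass
class AnalysisWindows:
    """Interval bookkeeping shared by the analysis stages.

    Defaults follow the standard recipe: drop the first 500 ns from averages,
    use 40-ns windows stepping by 20 ns starting at 200 ns for time-resolved
    statistics, and a 40-frame trailing window for instantaneous occupancy.
    """

    equilibration_cut: float = 500.0   # ns excluded from averages
    window: float = 40.0               # ns per analysis window
    step: float = 20.0                 # ns between window starts
    window_start: float = 200.0        # ns of the first window
    rolling_frames: int = 40           # frames in the rolling occupancy window

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise ValueError("require window >= step > 0")
        if self.equilibration_cut < 0:
            raise ValueError("equilibration_cut must be >= 0")
        if self.rolling_frames < 1:
            raise ValueError("rolling_frames must be >= 1")

    def equil_frame(self, dt_save: float) -> int:
        """First frame index at or after the equilibration cut."""
        return int(math.ceil(self.equilibration_cut / dt_save - 1e-9))

    def window_spans(self, total_time: float) -> list[tuple[float, float]]:
        """(start, end) ns spans: window_start..+window, stepping by step."""
        spans = []
        start = self.window_start
        while start + self.window <= total_time + 1e-9:
            spans.append((start, start + self.window))
            start += self.step
        return spans


def frames_for_duration(duration: float, dt_save: float) -> int:
    """Number of saved frames spanning ``duration`` ns at stride ``dt_save``.

    A 20-ps stride over 1000 ns yields 50,000 frames; dropping the first
    500 ns of such a run leaves 25,000.
    """
    if dt_save <= 0:
        raise ValueError("dt_save must be positive")
    if duration < 0:
        raise ValueError("duration must be non-negative")
    return int(math.floor(duration / dt_save + 1e-9))


def slice_trajectory(traj: Trajectory, start: float, end: float) -> Trajectory:
    """Frames with times in [start, end) ns; the original is untouched."""
    if not (0 <= start < end):
        raise ValueError(f"invalid slice range [{start}, {end})")
    if end > traj.total_time + 1e-9:
        raise ValueError(
            f"slice end {end} ns exceeds total time {traj.total_time} ns")
    i0 = frames_for_duration(start, traj.dt_save)
    i1 = frames_for_duration(end, traj.dt_save)
    return Trajectory(traj.coords[i0:i1].copy(), traj.dt_save, traj.structure)


def read_charge_table(path) -> dict[int, float]:
    """Two-column whitespace table: 1-based atom serial, charge (e)."""
    charges: dict[int, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{ln}: expected 'atom_id charge'")
        charges[int(parts[0])] = float(parts[1])
    return charges


def _universe(path, *coordinate_files):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            return mda.Universe(str(path), *(str(p) for p in coordinate_files))
        except Exception as exc:  # noqa: BLE001 - surfaced as ParseError
            raise ParseError(f"cannot parse {path}: {exc}") from exc


def read_structure(path, charge_table=None) -> StructureModel:
    """Read a PDB file into a :class:`StructureModel`.

    Residues are renumbered sequentially (1-based) within each chain in file
    order; the original (possibly non-sequential) numbering is retained in
    ``orig_res_num``.  ``charge_table`` optionally maps the file's 1-based
    atom serial order to partial charges in units of e.
    """
    u = _universe(path)
    if len(u.atoms) == 0:
        raise ParseError(f"{path}: no atoms found")

    names, elements, chain_ids = [], [], []
    res_index, res_names, orig_res_num = [], [], []
    renumber: dict[str, dict[tuple, int]] = {}
    seen_atoms: set[tuple] = set()
    for atom in u.atoms:
        cid = str(atom.segid).strip() or str(
            getattr(atom, "chainID", "") or "A").strip()
        orig = int(atom.resid)
        icode = str(getattr(atom, "icode", "") or "")
        table = renumber.setdefault(cid, {})
        key = (orig, icode, atom.resname)
        if key not in table:
            table[key] = len(table) + 1
        ridx = table[key]
        atom_key = (cid, ridx, atom.name)
        if atom_key in seen_atoms:
            raise StructureError(
                f"duplicate atom {atom.name} in residue {cid}:{ridx}")
        seen_atoms.add(atom_key)
        names.append(str(atom.name))
        try:
            elem = str(atom.element).capitalize()
        except Exception:  # noqa: BLE001 - element not annotated
            elem = _element_from_name(atom.name)
        elements.append(elem or _element_from_name(atom.name))
        chain_ids.append(cid)
        res_index.append(ridx)
        res_names.append(str(atom.resname))
        orig_res_num.append(orig)

    charges = None
    if charge_table is not None:
        if not isinstance(charge_table, dict):
            charge_table = read_charge_table(charge_table)
        charges = np.array(
            [charge_table.get(i + 1, 0.0) for i in range(len(names))])

    model = StructureModel(
        names=np.array(names),
        elements=np.array(elements),
        chain_ids=np.array(chain_ids),
        res_index=np.array(res_index, dtype=int),
        res_names=np.array(res_names),
        orig_res_num=np.array(orig_res_num, dtype=int),
        coords=u.atoms.positions.astype(float),
        charges=charges,
    )
    annotate_polar_atoms(model)
    return model


def annotate_polar_atoms(structure: StructureModel) -> StructureModel:
    """Attach heavy-atom donor/acceptor flags using residue-name tables."""
    donor = np.zeros(structure.n_atoms, dtype=bool)
    acceptor = np.zeros(structure.n_atoms, dtype=bool)
    for i in range(structure.n_atoms):
        name = str(structure.names[i])
        resn = str(structure.res_names[i])
        if name == "N" and resn != "PRO":
            donor[i] = True
        if name in ("O", "OXT"):
            acceptor[i] = True
        if name in _SIDECHAIN_DONORS.get(resn, ()):
            donor[i] = True
        if name in _SIDECHAIN_ACCEPTORS.get(resn, ()):
            acceptor[i] = True
    structure.is_donor = donor
    structure.is_acceptor = acceptor
    return structure


def read_trajectory(structure_path, traj_path=None, dt_save: float = 0.02,
                    charge_table=None) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD or XTC) onto a structure.

    ``dt_save`` is the save stride in ns (default 0.02 ns = 20 ps).
    """
    structure = read_structure(structure_path, charge_table=charge_table)
    if traj_path is not None and str(traj_path).endswith(
            (".txt", ".frames", ".dat")):
        return read_frames_txt(traj_path, structure)
    u = (_universe(structure_path) if traj_path is None
         else _universe(structure_path, traj_path))
    frames = np.array([ts.positions.copy() for ts in u.trajectory],
                      dtype=float)
    return Trajectory(frames, dt_save, structure)


def write_frames_txt(traj: Trajectory, path) -> None:
    """Plain-text frame format: header ``n_atoms dt_save``, then x y z lines."""
    with open(path, "w") as fh:
        fh.write(f"{traj.coords.shape[1]} {traj.dt_save:.6g}\n")
        flat = traj.coords.reshape(-1, 3)
        np.savetxt(fh, flat, fmt="%.4f")


def read_frames_txt(path, structure: StructureModel) -> Trajectory:
    """Read the plain-text frame format produced by :func:`write_frames_txt`."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ParseError(f"{path}: header must be 'n_atoms dt_save'")
        n_atoms, dt_save = int(header[0]), float(header[1])
        data = np.loadtxt(fh)
    if data.size == 0:
        raise ParseError(f"{path}: no coordinate data")
    data = data.reshape(-1, 3)
    if data.shape[0] % n_atoms:
        raise ParseError(f"{path}: coordinate count not divisible by n_atoms")
    coords = data.reshape(-1, n_atoms, 3)
    return Trajectory(coords, dt_save, structure)
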