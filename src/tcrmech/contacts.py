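"""Interfacial contact kinetics: detection, occupancy, Hamming distance, BSA.

Hydrogen bonds (salt bridges included) are scored with a donor–acceptor
heavy-atom distance cutoff of 2.4 Å.  Nonpolar contacts are heavy-atom pairs
within 3.0 Å where both partial charges are below 0.3 e in magnitude.
Occupancy of a contact is the fraction of frames it is present (average
occupancy) or its trailing 40-frame (0.8 ns at a 20-ps stride) rolling mean
(instantaneous occupancy).  Atom pairs between the same residue pair collapse
to a single residue-level contact per kind.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajio import AnalysisWindows, StructureModel, Trajectory

__all__ = [
    "ConfigurationError",
    "ContactCriteria",
    "ContactEvent",
    "ContactTimeline",
    "OccupancyThresholds",
    "HammingSeries",
    "BsaResult",
    "detect_contacts",
    "build_timelines",
    "rolling_occupancy",
    "count_high_occupancy",
    "heatmap_table",
    "hamming_distance",
    "windowed_total_occupancy",
    "shrake_rupley_sasa",
    "compute_bsa",
    "VDW_RADII",
]


class ConfigurationError(ValueError):
    """Analysis requested without the annotations/config it needs."""


@dataclass
class ContactCriteria:
    """Distance/charge criteria for contact detection."""

    hbond_cutoff: float = 2.4     # Å, donor-acceptor distance
    nonpolar_cutoff: float = 3.0  # Å, heavy-atom distance
    charge_cutoff: float = 0.3    # e, both partners below this magnitude
    # When hydrogens are present, optionally score hydrogen-acceptor distance
    # instead of donor(heavy)-acceptor distance.
    hbond_use_hydrogens: bool = False

    def __post_init__(self) -> None:
        if min(self.hbond_cutoff, self.nonpolar_cutoff,
               self.charge_cutoff) <= 0:
            raise ValueError("all contact criteria must be positive")


@dataclass(frozen=True)
class ContactEvent:
    """One residue-level contact observed in a frame."""

    atom_pair: tuple[int, int]                    # representative atom ids
    residue_pair: tuple[tuple[str, int], tuple[str, int]]
    kind: str                                     # "hbond" | "nonpolar"

    @property
    def key(self) -> tuple:
        return (*self.residue_pair, self.kind)


@dataclass
class ContactTimeline:
    """Boolean presence of one contact per frame plus derived occupancies."""

    key: tuple                     # (residueA, residueB, kind)
    presence: np.ndarray           # bool per frame
    dt_save: float
    rolling_frames: int = 40
    inst_occupancy: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        self.inst_occupancy = rolling_occupancy(
            self.presence, self.rolling_frames)

    def avg_occupancy(self, first_frame: int = 0,
                      last_frame: int | None = None) -> float:
        """Fraction of frames present over [first_frame, last_frame)."""
        window = self.presence[first_frame:last_frame]
        return float(window.mean()) if window.size else 0.0

    def max_inst(self, first_frame: int = 0,
                 last_frame: int | None = None) -> float:
        window = self.inst_occupancy[first_frame:last_frame]
        return float(window.max()) if window.size else 0.0


@dataclass
class OccupancyThresholds:
    """Occupancy cutoffs for counting, heat maps, Hamming baseline and BSA."""

    count_avg: float = 0.50
    count_inst_max: float = 0.80
    heatmap_avg: float = 0.30
    heatmap_inst_max: float = 0.80
    hamming_baseline_avg: float = 0.80
    bsa_inst_max: float = 0.80

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if not 0 < value <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


@dataclass
class HammingSeries:
    """Count of initially high-occupancy contacts lost per frame (symbol H)."""

    baseline: list[tuple]
    H: np.ndarray                  # int per frame
    dt_save: float


@dataclass
class BsaResult:
    """Buried surface area of the selected interfacial residues (Å²)."""

    residues: list[tuple[str, int]]
    total_mean: float
    total_std: float
    per_residue_mean: float
    per_frame_total: np.ndarray


def rolling_occupancy(presence: np.ndarray, window: int) -> np.ndarray:
    """Trailing rolling mean over ``window`` frames, truncated at the start."""
    s = pd.Series(np.asarray(presence, dtype=float))
    return s.rolling(window, min_periods=1).mean().to_numpy()


def _hbond_pairs(coords, structure, idx_a, idx_b, criteria):
    if structure.is_donor is None or structure.is_acceptor is None:
        raise ConfigurationError(
            "hbond detection requires donor/acceptor annotations")
    pairs = []
    for src, dst, flag_src, flag_dst in (
            (idx_a, idx_b, structure.is_donor, structure.is_acceptor),
            (idx_a, idx_b, structure.is_acceptor, structure.is_donor)):
        s = src[flag_src[src]]
        d = dst[flag_dst[dst]]
        if s.size == 0 or d.size == 0:
            continue
        tree = cKDTree(coords[d])
        for i, hits in zip(
                s, tree.query_ball_point(coords[s], criteria.hbond_cutoff)):
            pairs.extend((int(i), int(d[j])) for j in hits)
    return pairs


def _nonpolar_pairs(coords, structure, idx_a, idx_b, criteria):
    if structure.charges is None:
        raise ConfigurationError(
            "nonpolar contact detection requires partial charges")
    heavy = structure.elements != "H"
    small_q = np.abs(structure.charges) < criteria.charge_cutoff
    a = idx_a[heavy[idx_a] & small_q[idx_a]]
    b = idx_b[heavy[idx_b] & small_q[idx_b]]
    if a.size == 0 or b.size == 0:
        return []
    tree = cKDTree(coords[b])
    pairs = []
    for i, hits in zip(
            a, tree.query_ball_point(coords[a], criteria.nonpolar_cutoff)):
        pairs.extend((int(i), int(b[j])) for j in hits)
    return pairs


def detect_contacts(frame_coords: np.ndarray, structure: StructureModel,
                    interface: tuple[np.ndarray, np.ndarray],
                    criteria: ContactCriteria | None = None,
                    kinds=("hbond", "nonpolar")) -> set[ContactEvent]:
    """Residue-level contacts between the two atom groups in one frame.

    Multiple qualifying atom pairs between the same residue pair and kind
    collapse to a single :class:`ContactEvent` (closest pair kept as the
    representative).
    """
    criteria = criteria or ContactCriteria()
    coords = np.asarray(frame_coords, dtype=float)
    idx_a = np.asarray(interface[0], dtype=int)
    idx_b = np.asarray(interface[1], dtype=int)
    best: dict[tuple, tuple[float, ContactEvent]] = {}
    for kind in kinds:
        if kind == "hbond":
            pairs = _hbond_pairs(coords, structure, idx_a, idx_b, criteria)
        elif kind == "nonpolar":
            pairs = _nonpolar_pairs(coords, structure, idx_a, idx_b, criteria)
        else:
            raise ValueError(f"unknown contact kind {kind!r}")
        for i, j in pairs:
            res_i, res_j = structure.residue_key(i), structure.residue_key(j)
            if res_i == res_j:
                continue
            key = (res_i, res_j, kind)
            dist = float(np.linalg.norm(coords[i] - coords[j]))
            if key not in best or dist < best[key][0]:
                best[key] = (dist, ContactEvent((i, j), (res_i, res_j), kind))
    return {event for _, event in best.values()}


def build_timelines(traj: Trajectory,
                    interface: tuple[np.ndarray, np.ndarray],
                    criteria: ContactCriteria | None = None,
                    windows: AnalysisWindows | None = None,
                    kinds=("hbond", "nonpolar")) -> list[ContactTimeline]:
    """One presence timeline per residue-pair/kind ever observed."""
    windows = windows or AnalysisWindows()
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    seen: dict[tuple, list[int]] = {}
    for f in range(traj.n_frames):
        events = detect_contacts(
            traj.coords[f], traj.structure, interface, criteria, kinds)
        for event in events:
            seen.setdefault(event.key, []).append(f)
    timelines = []
    for key in sorted(seen):
        presence = np.zeros(traj.n_frames, dtype=bool)
        presence[seen[key]] = True
        timelines.append(ContactTimeline(
            key, presence, traj.dt_save,
            rolling_frames=windows.rolling_frames))
    return timelines


def count_high_occupancy(timelines, thresholds: OccupancyThresholds
                         | None = None,
                         windows: AnalysisWindows | None = None) -> int:
    """Contacts with post-cut average occupancy > 50% and max instantaneous
    occupancy >= 80% (both evaluated after the equilibration cut)."""
    thresholds = thresholds or OccupancyThresholds()
    windows = windows or AnalysisWindows()
    count = 0
    for tl in timelines:
        cut = windows.equil_frame(tl.dt_save)
        if (tl.avg_occupancy(cut) > thresholds.count_avg
                and tl.max_inst(cut) >= thresholds.count_inst_max):
            count += 1
    return count


def heatmap_table(timelines, thresholds: OccupancyThresholds | None = None,
                  bin_ns: float = 40.0) -> pd.DataFrame:
    """Occupancy-per-time-bin table for contacts passing the heat-map cuts.

    Rows are contacts with whole-run average occupancy > 30% and whole-run
    max instantaneous occupancy > 80%; columns are time bins of ``bin_ns``.
    """
    thresholds = thresholds or OccupancyThresholds()
    rows, labels = [], []
    for tl in timelines:
        if not (tl.avg_occupancy() > thresholds.heatmap_avg
                and tl.max_inst() > thresholds.heatmap_inst_max):
            continue
        per_bin = int(round(bin_ns / tl.dt_save))
        n_bins = int(np.ceil(len(tl.presence) / per_bin))
        occ = [tl.presence[b * per_bin:(b + 1) * per_bin].mean()
               for b in range(n_bins)]
        rows.append(occ)
        (ca, ra), (cb, rb), kind = tl.key
        labels.append(f"{ca}{ra}-{cb}{rb}/{kind}")
    if not rows:
        return pd.DataFrame()
    n_bins = max(len(r) for r in rows)
    columns = [f"{i * bin_ns:g}-{(i + 1) * bin_ns:g}ns" for i in range(n_bins)]
    return pd.DataFrame(rows, index=labels, columns=columns)


def hamming_distance(timelines, baseline_interval: float = 50.0,
                     thresholds: OccupancyThresholds | None = None,
                     loss_rule: str = "rolling") -> HammingSeries:
    """Hamming distance H(t): baseline contacts currently lost at frame t.

    The baseline is the set of contacts with average occupancy above 80%
    during the first ``baseline_interval`` ns.  Loss rules:

    - ``"rolling"`` (default): lost at t when the 40-frame rolling occupancy
      drops below 0.5.
    - ``"permanent"``: lost from the frame after its last presence onward.
    """
    if not timelines:
        raise ValueError("no timelines supplied")
    dt = timelines[0].dt_save
    n_frames = len(timelines[0].presence)
    n_base = int(round(baseline_interval / dt))
    if n_base > n_frames:
        raise ValueError("trajectory shorter than the baseline interval")
    thresholds = thresholds or OccupancyThresholds()
    baseline = [tl for tl in timelines
                if tl.avg_occupancy(0, n_base)
                > thresholds.hamming_baseline_avg]
    H = np.zeros(n_frames, dtype=int)
    if not baseline:
        warnings.warn("empty Hamming baseline; H is identically zero",
                      stacklevel=2)
        return HammingSeries([], H, dt)
    for tl in baseline:
        if loss_rule == "rolling":
            lost = tl.inst_occupancy < 0.5
        elif loss_rule == "permanent":
            present = np.flatnonzero(tl.presence)
            lost = np.zeros(n_frames, dtype=bool)
            last = present[-1] if present.size else -1
            lost[last + 1:] = True
        else:
            raise ValueError(f"unknown loss rule {loss_rule!r}")
        H += lost
    return HammingSeries([tl.key for tl in baseline], H, dt)


def windowed_total_occupancy(timelines,
                             windows: AnalysisWindows | None = None,
                             thresholds: OccupancyThresholds | None = None,
                             total_time: float | None = None) -> pd.DataFrame:
    """Total occupancy of the selected contacts in overlapping windows.

    Selection: contacts with whole-run average occupancy > 50% and whole-run
    max instantaneous occupancy > 80%.  Windows are ``window``-ns spans
    stepping by ``step`` ns from ``window_start`` (200–240, 220–260, ...);
    the total is the sum of per-contact window-average occupancies.
    """
    windows = windows or AnalysisWindows()
    thresholds = thresholds or OccupancyThresholds()
    if not timelines:
        raise ValueError("no timelines supplied")
    dt = timelines[0].dt_save
    if total_time is None:
        total_time = len(timelines[0].presence) * dt
    spans = windows.window_spans(total_time)
    if not spans:
        raise ValueError(
            "trajectory shorter than window_start + window")
    selected = [tl for tl in timelines
                if tl.avg_occupancy() > thresholds.count_avg
                and tl.max_inst() > thresholds.count_inst_max]
    records = []
    for start, end in spans:
        i0, i1 = int(round(start / dt)), int(round(end / dt))
        total = sum(tl.avg_occupancy(i0, i1) for tl in selected)
        records.append({"start_ns": start, "end_ns": end,
                        "total_occupancy": total})
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# Solvent-accessible and buried surface area
# ---------------------------------------------------------------------------

#: Heavy-atom van der Waals radii (Å) used for SASA.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "X": 1.70}


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-section spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5 ** 0.5) * i
    return np.column_stack((np.cos(theta) * np.sin(phi),
                            np.sin(theta) * np.sin(phi),
                            np.cos(phi)))


def shrake_rupley_sasa(coords: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960,
                       subset=None) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere sampling (Å²).

    Each atom's solvent sphere (radius + probe) is sampled with ``n_points``
    quasi-uniform points; a point is accessible when it lies outside every
    neighbouring atom's solvent sphere.  960 points keep the single-sphere
    error below 1%.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    subset = np.arange(n) if subset is None else np.asarray(subset, dtype=int)
    unit = _sphere_points(n_points)
    solvent_r = radii + probe
    tree = cKDTree(coords)
    sasa = np.zeros(n)
    max_reach = 2 * solvent_r.max()
    for i in subset:
        pts = coords[i] + solvent_r[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], max_reach)
                      if j != i
                      and np.linalg.norm(coords[j] - coords[i])
                      < solvent_r[i] + solvent_r[j]]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= solvent_r[j]
        sasa[i] = (accessible.mean() * 4 * np.pi * solvent_r[i] ** 2)
    return sasa


def _atom_radii(structure: StructureModel) -> np.ndarray:
    return np.array([VDW_RADII.get(str(e), VDW_RADII["X"])
                     for e in structure.elements])


def compute_bsa(traj: Trajectory, structure: StructureModel,
                side: np.ndarray, partner: np.ndarray,
                timelines=None,
                thresholds: OccupancyThresholds | None = None,
                windows: AnalysisWindows | None = None,
                probe: float = 1.4, n_points: int = 960,
                frame_stride: int = 1) -> BsaResult:
    """Buried surface area of receptor residues in high-occupancy contact.

    Residues of ``side`` (atom indices) are selected when any of their
    contacts with the partner reaches a maximum instantaneous occupancy above
    the ``bsa_inst_max`` threshold (taken from ``timelines``; if ``timelines``
    is None, all ``side`` residues are used).  Per frame,
    ``BSA(residue) = SASA(residue | side alone) - SASA(residue | complex)``;
    the total is the sum over selected residues, reported as mean ± std over
    post-equilibration frames.  Per-residue BSA is total / n_selected.
    """
    thresholds = thresholds or OccupancyThresholds()
    windows = windows or AnalysisWindows()
    side = np.asarray(side, dtype=int)
    partner = np.asarray(partner, dtype=int)

    side_residues = {structure.residue_key(i) for i in side}
    if timelines is not None:
        selected = set()
        for tl in timelines:
            if tl.max_inst() > thresholds.bsa_inst_max:
                for res in tl.key[:2]:
                    if res in side_residues:
                        selected.add(res)
        selected = sorted(selected)
    else:
        selected = sorted(side_residues)
    if not selected:
        warnings.warn("no residues pass the BSA occupancy criterion",
                      stacklevel=2)
        return BsaResult([], 0.0, 0.0, 0.0, np.zeros(0))

    radii = _atom_radii(structure)
    sel_set = set(selected)
    sel_atoms_local = np.flatnonzero(
        [structure.residue_key(i) in sel_set for i in side])
    complex_idx = np.concatenate([side, partner])
    cut = windows.equil_frame(traj.dt_save)
    frames = range(cut, traj.n_frames, frame_stride)
    totals = []
    for f in frames:
        coords = traj.coords[f]
        sasa_alone = shrake_rupley_sasa(
            coords[side], radii[side], probe, n_points,
            subset=sel_atoms_local)
        sasa_cplx = shrake_rupley_sasa(
            coords[complex_idx], radii[complex_idx], probe, n_points,
            subset=sel_atoms_local)  # side atoms come first in complex_idx
        totals.append(float(np.sum(sasa_alone[sel_atoms_local]
                                   - sasa_cplx[sel_atoms_local])))
    totals = np.array(totals)
    total_mean = float(totals.mean()) if totals.size else 0.0
    total_std = float(totals.std()) if totals.size else 0.0
    return BsaResult(list(selected), total_mean, total_std,
                     total_mean / len(selected), totals)
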