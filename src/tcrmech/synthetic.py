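"""Synthetic trajectories with known ground truth.

The generator emulates the three ingredients the analysis stages consume,
without running molecular dynamics:

- rigid pseudo-domains (four 6-residue β-strand cores each for Vα, Vβ, Cα,
  Cβ, plus CDR3-base, hinge and peptide pseudo-atoms) undergoing prescribed
  rotational modes — scissor / flap / twist counter-rotations of the V
  domains and hinge bending of the V-module — as sinusoids of known
  amplitude;
- interfacial pseudo-atom pairs that toggle geometrically across the contact
  cutoffs on prescribed occupancy schedules or switch times;
- a harmonically restrained coordinate in thermal equilibrium
  (Ornstein–Uhlenbeck statistics) at known stiffness, temperature, friction
  and bias.

Everything is deterministic given the seed, and the injected modes,
schedules and restraint parameters are serialised as ground truth so each
analysis output has a closed-form or schedule-derived expectation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import BocSpec, TriadSpec
from .mechanics import KB_KCAL_PER_MOL_K
from .trajio import StructureModel, Trajectory

__all__ = [
    "ModeSpec",
    "ContactSchedule",
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "SyntheticTemplate",
    "make_domain_template",
    "generate_trajectory",
    "simulate_restrained_coordinate",
    "scheduled_presence",
    "write_pdb",
    "TEMPLATE_TRIAD_SPECS",
    "TEMPLATE_BOC_SPEC",
    "TEMPLATE_CDR3_RESIDUES",
]

# Template residue bookkeeping (per chain, sequential from 1 so a PDB
# round-trip through renumbering is the identity):
#   chains D/E: 1-24 V core (4 strands x 6), 25-26 CDR3 base, 27(+28) hinge,
#   then 24 C-core residues, then single-atom contact residues.
TEMPLATE_TRIAD_SPECS = {
    "alpha": TriadSpec("D", ((1, 6), (7, 12), (13, 18), (19, 24)),
                       cdr3_base=(25, 26)),
    "beta": TriadSpec("E", ((1, 6), (7, 12), (13, 18), (19, 24)),
                      cdr3_base=(25, 26)),
}
TEMPLATE_BOC_SPEC = BocSpec(
    v_alpha=TEMPLATE_TRIAD_SPECS["alpha"],
    v_beta=TEMPLATE_TRIAD_SPECS["beta"],
    c_alpha_chain="D",
    c_alpha_segments=((28, 33), (34, 39), (40, 45), (46, 51)),
    c_beta_chain="E",
    c_beta_segments=((29, 34), (35, 40), (41, 46), (47, 52)),
    hinge_alpha=("D", (27,)),
    hinge_beta=("E", (27, 28)),
)
TEMPLATE_CDR3_RESIDUES = (("D", 25), ("D", 26), ("E", 25), ("E", 26))


@dataclass
class ModeSpec:
    """One injected rigid-body rotational mode.

    ``kind`` selects the rotation axes: ``scissor`` counter-rotates the two V
    domains about their e1 (inner→outer) axes, ``flap`` about their e3
    (strand) axes, ``twist`` about their e2 axes, and ``hinge-bend`` rotates
    each listed chain's V domain about the transverse axis through its hinge.
    ``amplitude`` is the peak relative rotation in degrees; the waveform is a
    sinusoid of ``period`` ns (phase in degrees).
    """

    kind: str
    amplitude: float                   # degrees, peak of the sinusoid
    period: float = 10.0               # ns
    phase: float = 0.0                 # degrees
    chains: tuple[str, ...] = ("alpha", "beta")

    def angle(self, t_ns: float) -> float:
        """Relative rotation angle (radians) at time t."""
        return math.radians(self.amplitude) * math.sin(
            2 * math.pi * t_ns / self.period + math.radians(self.phase))


@dataclass
class ContactSchedule:
    """Prescribed presence of one interfacial pseudo-atom pair.

    Exactly one of ``occupancy`` (deterministic fraction of frames present),
    ``off_at`` (present before, absent from that time on) or ``on_at`` may be
    given; default is always present.
    """

    pair: int                          # template pair index
    kind: str = "hbond"                # "hbond" | "nonpolar"
    occupancy: float | None = None
    off_at: float | None = None        # ns
    on_at: float | None = None         # ns

    def __post_init__(self) -> None:
        if self.occupancy is not None and not 0 <= self.occupancy <= 1:
            raise ValueError("occupancy target must lie in [0, 1]")


def scheduled_presence(schedule: ContactSchedule, n_frames: int,
                       dt_save: float) -> np.ndarray:
    """Deterministic boolean presence pattern encoding the schedule.

    Occupancy targets use the Bresenham-style pattern
    ``present[i] = floor((i+1)·o) − floor(i·o)``, which reproduces the target
    to within 1/n_frames exactly.
    """
    if schedule.occupancy is not None:
        i = np.arange(n_frames)
        o = schedule.occupancy
        return (np.floor((i + 1) * o) - np.floor(i * o)) >= 1
    times = np.arange(n_frames) * dt_save
    if schedule.off_at is not None:
        return times < schedule.off_at
    if schedule.on_at is not None:
        return times >= schedule.on_at
    return np.ones(n_frames, dtype=bool)


@dataclass
class SyntheticConfig:
    """Full specification of one generated trajectory."""

    seed: int = 0
    n_frames: int = 2000
    dt_save: float = 0.02              # ns, the standard 20-ps save stride
    modes: list[ModeSpec] = field(default_factory=list)
    contacts: list[ContactSchedule] = field(default_factory=list)
    noise_sigma: float = 0.1           # Å, i.i.d. Gaussian per atom coordinate
    n_contact_pairs: int = 10


@dataclass
class SyntheticGroundTruth:
    """What the generated trajectory encodes, for recovery tests."""

    modes: list[ModeSpec]
    mode_rms_rad: list[float]          # rms of each mode's relative angle
    triad_mode_vectors: list[np.ndarray]   # unit vectors in 18-dim arm space
    triad_mode_rms: list[float]        # rms projection along those vectors
    boc_mode_vectors: list[np.ndarray]     # unit vectors in 18-dim bead space
    boc_mode_rms: list[float]
    contact_occupancy: dict            # key -> scheduled average occupancy
    contact_loss_times: dict           # key -> ns at which the contact is lost
    config: SyntheticConfig = None

    def to_json(self, path) -> None:
        payload = {
            "modes": [vars(m) | {"chains": list(m.chains)}
                      for m in self.modes],
            "mode_rms_rad": self.mode_rms_rad,
            "triad_mode_rms": self.triad_mode_rms,
            "boc_mode_rms": self.boc_mode_rms,
            "triad_mode_vectors": [v.tolist()
                                   for v in self.triad_mode_vectors],
            "boc_mode_vectors": [v.tolist() for v in self.boc_mode_vectors],
            "contact_occupancy": {str(k): v for k, v
                                  in self.contact_occupancy.items()},
            "contact_loss_times": {str(k): v for k, v
                                   in self.contact_loss_times.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _strand_core(origin: np.ndarray, mirror: bool = False) -> np.ndarray:
    """4x6 Cα core: strands 1+4 on the inner sheet, 2+3 on the outer."""
    coords = []
    sheet_y = {0: -2.0, 1: 2.0, 2: 2.0, 3: -2.0}
    strand_x = {0: -2.4, 1: -2.4, 2: 2.4, 3: 2.4}
    for s in range(4):
        for r in range(6):
            local = np.array([strand_x[s], sheet_y[s], 3.4 * r - 8.5])
            coords.append(local)
    coords = np.array(coords)
    if mirror:
        coords[:, 0] *= -1
    return coords + origin


@dataclass
class SyntheticTemplate:
    """Pseudo-complex geometry plus the rigid groups the modes act on."""

    structure: StructureModel
    groups: dict[str, np.ndarray]      # atom-index groups ("Valpha", ...)
    pivots: dict[str, np.ndarray]      # named pivot points (base coords)
    contact_pairs: list[dict]          # per pair: atoms, kind, key
    anchor: tuple[str, int, str]       # restraint anchor (chain A top atom)
    interface: tuple[np.ndarray, np.ndarray]
    peptide_ca: np.ndarray

    @property
    def triad_specs(self):
        return TEMPLATE_TRIAD_SPECS

    @property
    def boc_spec(self):
        return TEMPLATE_BOC_SPEC

    @property
    def cdr3_residues(self):
        return TEMPLATE_CDR3_RESIDUES


def make_domain_template(n_contact_pairs: int = 10,
                         peptide_angle_deg: float = 0.0
                         ) -> SyntheticTemplate:
    """Build the pseudo-complex the generator deforms.

    Two mirror-symmetric V domains (centroids at x = ∓8 Å, z = 30 Å) sit
    above their C domains (z = 0) with hinge pseudo-atoms between them; a
    9-residue peptide line lies across the top; chain A carries the partner
    pseudo-atoms of the interfacial contact pairs and the restraint anchor.
    Half the contact pairs are hydrogen-bond donors/acceptors (placed 2.2 Å
    apart when on), half are weakly charged nonpolar carbons (2.8 Å);
    toggling moves the chain-A partner 10 Å away, across the cutoff.
    """
    names, elements, chain_ids = [], [], []
    res_index, res_names, coords = [], [], []
    charges, is_donor, is_acceptor = [], [], []

    def add_atom(name, element, chain, resindex, resname, xyz,
                 q=0.0, donor=False, acceptor=False):
        names.append(name)
        elements.append(element)
        chain_ids.append(chain)
        res_index.append(resindex)
        res_names.append(resname)
        coords.append(np.asarray(xyz, dtype=float))
        charges.append(q)
        is_donor.append(donor)
        is_acceptor.append(acceptor)
        return len(names) - 1

    groups: dict[str, list[int]] = {
        "Valpha": [], "Vbeta": [], "Calpha": [], "Cbeta": [],
        "Halpha": [], "Hbeta": [], "peptide": [], "mhc": []}

    # V and C cores, CDR3 bases and hinges for both chains
    for chain, mirror, vg, cg, hg in (
            ("D", False, "Valpha", "Calpha", "Halpha"),
            ("E", True, "Vbeta", "Cbeta", "Hbeta")):
        sign = -1.0 if not mirror else 1.0
        v_origin = np.array([8.0 * sign, 0.0, 30.0])
        c_origin = np.array([8.0 * sign, 0.0, 0.0])
        for i, xyz in enumerate(_strand_core(v_origin, mirror)):
            idx = add_atom("CA", "C", chain, i + 1, "GLY", xyz)
            groups[vg].append(idx)
        for j, dy in enumerate((-1.0, 1.0)):
            idx = add_atom("CA", "C", chain, 25 + j, "GLY",
                           v_origin + np.array([0.0, dy, 10.5]))
            groups[vg].append(idx)
        if chain == "D":
            idx = add_atom("CA", "C", chain, 27, "GLY",
                           np.array([-8.0, 0.0, 15.0]))
            groups[hg].append(idx)
            c_first = 28
        else:
            for j, dy in enumerate((-0.5, 0.5)):
                idx = add_atom("CA", "C", chain, 27 + j, "GLY",
                               np.array([8.0, dy, 15.0]))
                groups[hg].append(idx)
            c_first = 29
        for i, xyz in enumerate(_strand_core(c_origin, mirror)):
            idx = add_atom("CA", "C", chain, c_first + i, "GLY", xyz)
            groups[cg].append(idx)

    # Peptide: 9 Cα along x at the top, optionally tilted in the x-z plane.
    tilt = math.radians(peptide_angle_deg)
    direction = np.array([math.cos(tilt), 0.0, math.sin(tilt)])
    for i in range(9):
        xyz = np.array([0.0, 0.0, 48.0]) + (3.4 * (i - 4)) * direction
        idx = add_atom("CA", "C", "C", i + 1, "GLY", xyz)
        groups["peptide"].append(idx)

    # Interfacial contact pairs: V-side atom on chain D/E, partner on chain A.
    contact_pairs = []
    d_res = 52
    e_res = 53
    for p in range(n_contact_pairs):
        kind = "hbond" if p % 2 == 0 else "nonpolar"
        on_dist = 2.2 if kind == "hbond" else 2.8
        side_chain = "D" if p % 4 < 2 else "E"
        x = -6.0 + 12.0 * (p / max(1, n_contact_pairs - 1))
        base = np.array([x, 0.0, 44.0])
        if side_chain == "D":
            resindex = d_res
            d_res += 1
        else:
            resindex = e_res
            e_res += 1
        # names "O"/"N" so the standard polar-atom heuristic re-derives the
        # donor/acceptor flags after a PDB round-trip
        if kind == "hbond":
            i = add_atom("O", "O", side_chain, resindex, "CNT", base,
                         q=-0.5, acceptor=True)
            j = add_atom("N", "N", "A", p + 1, "CNT",
                         base + np.array([0.0, on_dist, 0.0]),
                         q=0.4, donor=True)
        else:
            i = add_atom("CP", "C", side_chain, resindex, "CNT", base,
                         q=0.05)
            j = add_atom("CP", "C", "A", p + 1, "CNT",
                         base + np.array([0.0, on_dist, 0.0]),
                         q=-0.05)
        groups["mhc"].append(j)
        contact_pairs.append({
            "pair": p, "side_atom": i, "partner_atom": j, "kind": kind,
            "key": (("A", p + 1), (side_chain, resindex), kind),
            "on_dist": on_dist})

    # Restraint anchor atom (pMHC-terminal stand-in) and a second base atom.
    anchor_res = n_contact_pairs + 1
    idx = add_atom("CA", "C", "A", anchor_res, "GLY",
                   np.array([0.0, 0.0, 60.0]))
    groups["mhc"].append(idx)
    idx = add_atom("CA", "C", "A", anchor_res + 1, "GLY",
                   np.array([0.0, 0.0, 55.0]))
    groups["mhc"].append(idx)

    structure = StructureModel(
        names=np.array(names), elements=np.array(elements),
        chain_ids=np.array(chain_ids),
        res_index=np.array(res_index, dtype=int),
        res_names=np.array(res_names),
        orig_res_num=np.array(res_index, dtype=int),
        coords=np.array(coords),
        charges=np.array(charges),
    )
    structure.is_donor = np.array(is_donor, dtype=bool)
    structure.is_acceptor = np.array(is_acceptor, dtype=bool)

    pivots = {
        "Valpha": structure.coords[groups["Valpha"][:24]].mean(axis=0),
        "Vbeta": structure.coords[groups["Vbeta"][:24]].mean(axis=0),
        "Halpha": structure.coords[groups["Halpha"]].mean(axis=0),
        "Hbeta": structure.coords[groups["Hbeta"]].mean(axis=0),
    }
    side_atoms = np.array(
        [p["side_atom"] for p in contact_pairs], dtype=int)
    partner_atoms = np.array(
        [p["partner_atom"] for p in contact_pairs], dtype=int)
    return SyntheticTemplate(
        structure=structure,
        groups={k: np.array(v, dtype=int) for k, v in groups.items()},
        pivots=pivots,
        contact_pairs=contact_pairs,
        anchor=("A", anchor_res, "CA"),
        interface=(partner_atoms, side_atoms),
        peptide_ca=np.array(groups["peptide"], dtype=int),
    )


# Local rotation axes of each V domain in the template's base orientation:
# e1 = inner->outer sheet (+y), e3 = strand axis toward CDR3 (+z),
# e2 = e3 x e1.
_MODE_AXES = {"scissor": "e1", "flap": "e3", "twist": "e2"}
_LOCAL_AXIS = {"e1": np.array([0.0, 1.0, 0.0]),
               "e3": np.array([0.0, 0.0, 1.0])}
_LOCAL_AXIS["e2"] = np.cross(_LOCAL_AXIS["e3"], _LOCAL_AXIS["e1"])


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def _apply_modes(coords: np.ndarray, template: SyntheticTemplate,
                 modes, t_ns: float) -> np.ndarray:
    """Compose the rigid-body rotations of all modes, in declared order."""
    out = coords
    for mode in modes:
        theta = mode.angle(t_ns)
        if mode.kind in _MODE_AXES:
            axis = _LOCAL_AXIS[_MODE_AXES[mode.kind]]
            for chain, sign in (("alpha", 0.5), ("beta", -0.5)):
                if chain not in mode.chains:
                    continue
                group = template.groups[
                    "Valpha" if chain == "alpha" else "Vbeta"]
                pivot = template.pivots[
                    "Valpha" if chain == "alpha" else "Vbeta"]
                R = _rotation_matrix(axis, sign * theta)
                out = out.copy()
                out[group] = (out[group] - pivot) @ R.T + pivot
        elif mode.kind == "hinge-bend":
            axis = np.array([1.0, 0.0, 0.0])   # transverse bending axis
            for chain in mode.chains:
                group = template.groups[
                    "Valpha" if chain == "alpha" else "Vbeta"]
                pivot = template.pivots[
                    "Halpha" if chain == "alpha" else "Hbeta"]
                R = _rotation_matrix(axis, theta)
                out = out.copy()
                out[group] = (out[group] - pivot) @ R.T + pivot
        else:
            raise ValueError(f"unknown mode kind {mode.kind!r}")
    return out


def _mode_direction(template: SyntheticTemplate, mode: ModeSpec,
                    space: str, delta: float = 1e-4
                    ) -> tuple[np.ndarray, float]:
    """Injected unit mode vector in triad-arm or BOC space, by central
    difference of the noise-free generator, plus the configuration-space
    speed |d(config)/dθ| used to convert angle rms into projection rms."""
    from . import modes as modes_mod

    base = template.structure.coords

    def config(theta: float) -> np.ndarray:
        probe = ModeSpec(mode.kind, math.degrees(theta), period=4.0,
                         phase=90.0, chains=mode.chains)
        # phase 90° puts the sinusoid at its peak at t=0
        coords = _apply_modes(base.copy(), template, [probe], 0.0)
        traj = Trajectory(coords[None], 0.02, template.structure)
        if space == "triad":
            ta = geometry.compute_triads(traj, template.triad_specs["alpha"])
            tb = geometry.compute_triads(traj, template.triad_specs["beta"])
            return modes_mod.triad_arm_matrix(ta, tb)[0]
        boc = geometry.build_boc(traj, template.boc_spec,
                                 reference_coords=base)
        return modes_mod.boc_matrix(boc)[0]

    diff = config(delta) - config(-delta)
    speed = float(np.linalg.norm(diff) / (2 * delta))
    if speed < 1e-12:
        return np.zeros_like(diff), 0.0
    return diff / np.linalg.norm(diff), speed


def generate_trajectory(config: SyntheticConfig,
                        template: SyntheticTemplate | None = None
                        ) -> tuple[Trajectory, SyntheticGroundTruth]:
    """Generate frames by composing rigid mode rotations, scheduled contact
    toggling and i.i.d. Gaussian noise; deterministic given the seed."""
    template = template or make_domain_template(config.n_contact_pairs)
    structure = template.structure
    rng = np.random.default_rng(config.seed)
    base = structure.coords
    n = config.n_frames

    presence = {}
    for schedule in config.contacts:
        pair = template.contact_pairs[schedule.pair]
        if schedule.kind != pair["kind"]:
            raise ValueError(
                f"pair {schedule.pair} is {pair['kind']}, schedule says "
                f"{schedule.kind}")
        presence[schedule.pair] = scheduled_presence(
            schedule, n, config.dt_save)

    frames = np.empty((n, structure.n_atoms, 3))
    for i in range(n):
        t = i * config.dt_save
        coords = _apply_modes(base.copy(), template, config.modes, t)
        for schedule in config.contacts:
            pair = template.contact_pairs[schedule.pair]
            if not presence[schedule.pair][i]:
                coords[pair["partner_atom"]] += np.array([0.0, 10.0, 0.0])
        frames[i] = coords
    if config.noise_sigma > 0:
        frames += rng.normal(0.0, config.noise_sigma, size=frames.shape)

    # Ground truth: injected directions and rms amplitudes.
    angle_rms = []
    triad_vecs, triad_rms, boc_vecs, boc_rms = [], [], [], []
    times = np.arange(n) * config.dt_save
    for mode in config.modes:
        thetas = np.array([mode.angle(t) for t in times])
        rms = float(thetas.std())
        angle_rms.append(rms)
        tvec, tspeed = _mode_direction(template, mode, "triad")
        bvec, bspeed = _mode_direction(template, mode, "boc")
        triad_vecs.append(tvec)
        triad_rms.append(rms * tspeed)
        boc_vecs.append(bvec)
        boc_rms.append(rms * bspeed)

    occupancy = {}
    loss_times = {}
    for schedule in config.contacts:
        key = template.contact_pairs[schedule.pair]["key"]
        pattern = presence[schedule.pair]
        occupancy[key] = float(pattern.mean())
        if schedule.off_at is not None:
            loss_times[key] = float(schedule.off_at)

    truth = SyntheticGroundTruth(
        modes=list(config.modes), mode_rms_rad=angle_rms,
        triad_mode_vectors=triad_vecs, triad_mode_rms=triad_rms,
        boc_mode_vectors=boc_vecs, boc_mode_rms=boc_rms,
        contact_occupancy=occupancy, contact_loss_times=loss_times,
        config=config)
    return Trajectory(frames, config.dt_save, structure), truth


def simulate_restrained_coordinate(k: float, T: float, friction: float,
                                   dt: float, n_steps: int,
                                   bias: float = 0.0, seed: int = 0,
                                   n_dim: int = 1) -> np.ndarray:
    """Overdamped Langevin (Ornstein–Uhlenbeck) series for a restrained
    coordinate.

    Stationary statistics under ``E = ½kΔx²``: variance ``k_B·T/k`` per
    coordinate and mean displacement ``bias/k``.  Uses the exact OU update,
    so the discretisation is unbiased; the ``dt > friction/k`` safety bound
    still raises, matching the declared stability contract.

    Units: k in kcal/(mol·Å²), T in K, friction γ in kcal·ns/(mol·Å²),
    dt in ns, bias in kcal/(mol·Å).  Returns an (n_steps, n_dim) array in Å.
    """
    if min(k, T, friction, dt) <= 0 or n_steps <= 0:
        raise ValueError("k, T, friction, dt and n_steps must be positive")
    if dt > friction / k:
        raise ValueError(
            f"dt={dt} exceeds the stability bound friction/k="
            f"{friction / k}")
    from scipy.signal import lfilter

    tau = friction / k
    mean = bias / k
    sigma = math.sqrt(KB_KCAL_PER_MOL_K * T / k)
    decay = math.exp(-dt / tau)
    kick = sigma * math.sqrt(1 - decay ** 2)
    rng = np.random.default_rng(seed)
    # exact AR(1) recursion y[i] = decay·y[i-1] + kick·ξ[i], run as a linear
    # filter; the initial state is drawn from the stationary distribution
    state0 = rng.normal(0.0, sigma, size=n_dim)
    noise = kick * rng.standard_normal((n_steps, n_dim))
    zi = (decay * state0)[None, :]
    y, _ = lfilter([1.0], [1.0, -decay], noise, axis=0, zi=zi)
    return mean + y


def write_pdb(structure: StructureModel, path,
              trajectory: Trajectory | None = None) -> None:
    """Write a PDB-style topology (and optionally multi-model frames)."""
    def atom_lines(coords):
        lines = []
        for i in range(structure.n_atoms):
            name = str(structure.names[i])
            pad = f" {name:<3s}" if len(name) < 4 else name
            lines.append(
                f"ATOM  {i + 1:5d} {pad:<4s}{structure.res_names[i]:>4s} "
                f"{structure.chain_ids[i]:1s}{structure.orig_res_num[i]:4d}"
                f"    {coords[i, 0]:8.3f}{coords[i, 1]:8.3f}"
                f"{coords[i, 2]:8.3f}  1.00  0.00          "
                f"{str(structure.elements[i]):>2s}")
        return lines

    with open(path, "w") as fh:
        if trajectory is None:
            fh.write("\n".join(atom_lines(structure.coords)) + "\nEND\n")
            return
        for m in range(trajectory.n_frames):
            fh.write(f"MODEL {m + 1:8d}\n")
            fh.write("\n".join(atom_lines(trajectory.coords[m])))
            fh.write("\nENDMDL\n")
        fh.write("END\n")
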