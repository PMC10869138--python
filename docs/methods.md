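# Methods

This note documents the models and numerical choices behind `tcrmech`, the
assumptions they carry, and what the synthetic-data tests do and do not
establish about real trajectories.

## Coordinate and bookkeeping conventions

Coordinates are Å, times ns, forces pN. Frames are assumed to be saved at a
fixed stride `dt_save` (default 0.02 ns = 20 ps, so 50,000 frames per µs);
frame *i* is at elapsed time `i·dt_save`. Residues are renumbered
sequentially from 1 within each chain on reading, because crystallographic
numbering of TCR chains is non-sequential; the original numbering is kept as
per-atom metadata. All default residue selections (triad cores, BOC beads,
CDR3 bases, hinges) refer to these renumbered indices for the A6 TCRαβ–pMHC
complex and are fully configurable for other receptors. Interval statistics
exclude an equilibration period (default 500 ns) and time-resolved
statistics use 40-ns windows stepping 20 ns from 200 ns; both live in
`AnalysisWindows` so short (synthetic or test) runs can scale them down.

## Contact model

A hydrogen bond (salt bridges included) is a donor–acceptor pair within
2.4 Å. The cutoff is applied to the donor and acceptor heavy atoms as
stated; since 2.4 Å is short for heavy-atom pairs, an optional mode scores
the hydrogen–acceptor distance instead when explicit hydrogens exist. When
a structure carries no explicit donor/acceptor annotations, a residue-name
table assigns them (backbone N donates except proline, backbone O accepts,
hydroxyls do both, etc.); the synthetic generator sets the flags explicitly.
A nonpolar contact is a heavy-atom pair within 3.0 Å with both partial
charges below 0.3 e in magnitude; charges come from a user-supplied
force-field table and are never computed here. Multiple atom pairs between
one residue pair collapse to a single contact per kind, matching
per-residue-pair heat maps.

Average occupancy is the fraction of frames a contact is present over a
declared interval. Instantaneous occupancy is a trailing 40-frame rolling
mean, truncated at the trajectory start (the first frames average over
shorter windows); any fixed alignment convention works, this one is chosen
and tested. Consequences worth knowing: an evenly spread 60 %-occupancy
contact never reaches 0.8 instantaneous occupancy, and the first frame's
truncated window equals its own presence.

The Hamming distance *H* counts baseline contacts (>80 % average occupancy
in the first 50 ns) currently lost. The criterion for "lost" at frame *t*
is not fully pinned down by the published description, so it is a
configurable rule: the default declares a baseline contact lost when its
40-frame rolling occupancy falls below 0.5; a "permanent" alternative marks
it lost after its final presence. Under the permanent rule *H* is
non-decreasing; under the default it can recover.

BSA selects receptor-side residues whose contact with the partner exceeds
80 % maximum instantaneous occupancy, and reports, per frame,
`SASA(residue | receptor alone) − SASA(residue | complex)` summed over the
selection; per-residue BSA divides by the number of selected residues. SASA
is Shrake–Rupley sphere sampling with 960 quasi-uniform points per atom
(golden-section spiral), probe 1.4 Å and standard heavy-atom van der Waals
radii (C 1.70, N 1.55, O 1.52, S/P 1.80, H 1.20 Å). 960 points keep the
isolated-sphere error below 1 %; the two-sphere spherical-cap closed form is
the occlusion oracle in the tests. BSA frames may be strided
(`frame_stride`) since SASA is the most expensive primitive.

## Triads, BOC and order parameters

Each variable domain's triad is fitted to the backbone Cα atoms of four
6-residue β-strand segments. The centroid is their mean; e3 is the major
in-plane axis of the least-squares plane (SVD of the centered coordinates),
parallel to the strands; e1 is the direction from the inner-sheet to the
outer-sheet centre of mass, orthogonalised against e3; e2 = e3 × e1 closes
the right-handed frame. The inner/outer partition of the four listed
segments is not tabulated in the source material; segments 1+4 vs 2+3 is
the default and it is configurable. The e3 sign points toward the CDR3-base
midpoint at the first frame and is propagated by continuity afterwards, so
a transient large rotation cannot silently flip the frame. Degenerate
(collinear) cores raise rather than return a garbage frame.

Inter-triad angles are ∠ek = arccos(ekA·ekB) in degrees. A pure scissor
(counter-rotation of the domains about their e1 axes) moves ∠e2 and ∠e3
reciprocally and leaves ∠e1 fixed; flap and twist move ∠e1 together with
one of the others. The CDR3 distance is the distance between the midpoints
of the two CDR3-base Cα pairs.

The V–C bead-on-chain model has six beads: Vα/Vβ triad centroids, Cα/Cβ
core centroids, and hinges Hα (one Cα atom) and Hβ (midpoint of two Cα
atoms). Every frame is superposed (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`) on a reference frame's
C-module core atoms — by default the trajectory's own first frame; passing
a designated run's first frame places several systems in one common
reference so average BOCs can be compared. Hinge angles ∠TCRα/∠TCRβ are the
angles at each hinge bead between the hinge→V-bead and hinge→C-bead arms;
the construction is configurable since the original definition is
pictorial. Because the angle depends on the magnitude of the bend, a
sinusoidal hinge bend of peak amplitude A spans [180°−A, 180°].

The peptide angle is between the least-squares line through the peptide
backbone Cα atoms (an undirected direction) and the Vα→Vβ centroid unit
vector, folded into [0°, 90°]; acute-angle reporting makes the choice of
Vα→Vβ vs Vβ→Vα immaterial. RMSF is the per-atom rms deviation from the mean
position after aligning a declared atom set to the first production frame;
transverse RMSF projects the peptide-Cα COM onto the plane orthogonal to
the load axis (the line through the two restraint anchors) before taking
the rms.

## PCA of triads and beads

The two-triad configuration per frame is the 18-vector of six arm tips;
the BOC configuration is the 18-vector of six bead positions. PCA is an
eigen-decomposition of the covariance of fluctuations about the
post-equilibration mean with equal frame weights — no temporal filtering.
Mode amplitude is the standard deviation of the per-frame projections:
radians for triad arms (unit arm tips make small displacements equal
rotation angles), Å for beads. This equals the square root of the
eigenvalue under this normalisation; either convention would do, this one
is stated and used consistently. Mode signs are fixed by making the first
non-negligible component positive (similarity comparisons use |a·b| and are
sign-blind). Covariance is estimated after the equilibration cut;
projections are reported for all frames. Rank-deficient covariances yield
zero amplitudes beyond the rank rather than an error.

The α−β amplitude asymmetry takes matched index groups (e.g. beads {Vα, Hα}
vs {Vβ, Hβ}), computes for each mode the rms norm of the mode's
3-component blocks within each group scaled by the mode amplitude, and
reports the α minus β difference per mode. It is antisymmetric under label
swap and zero for mirror-symmetric motion, both asserted in tests.

## Force from restraints

The applied load is estimated from the restrained anchor (an atom or a
group COM) as F = k·⟨x − x₀⟩ with the energy convention E = ½k|Δx|², so
that the force is "displacement times spring constant" *and* equipartition
gives a per-coordinate rms of sqrt(k_B·T/k) = 0.772 Å at k = 1 kcal/(mol·Å²)
and T = 300 K (k_B·T = 0.5962 kcal/mol at 300 K) — consistent with the
~0.8 Å fluctuation scale of that restraint. The alternative E = kΔx²
convention is selectable but non-default. Conversion: 1 kcal/(mol·Å) =
69.479 pN. The mean force uses post-equilibration frames; window means use
the standard 40/20-ns spans and the reported window std is over the
window-mean magnitudes (not over frames). The flat-bottom pair restraint
contributes zero force below its 10 Å onset and k·(d − 10) beyond.

## Synthetic generator

The generator is first-class, tested code, and every analysis stage has at
least one end-to-end recovery test driven solely by it. It emulates:

- **Rigid-domain modes.** Four-strand, 6-residue-per-strand Cα cores for
  Vα/Vβ/Cα/Cβ arranged as two sheets 4 Å apart (strands 1+4 inner, 2+3
  outer), CDR3-base pseudo-atoms, hinge pseudo-atoms and a 9-residue
  peptide line, mirror-symmetric in α↔β. Modes are rigid rotations with
  sinusoidal angle θ(t) = A·sin(2πt/T + φ): scissor/flap/twist
  counter-rotate the two V domains (±θ/2) about their local e1/e3/e2 axes,
  and hinge-bend rotates a chain's V domain about the transverse axis
  through its hinge. Modes compose in declared order. Noise is i.i.d.
  Gaussian per atom coordinate, added after mode composition so injected
  directions remain the exact covariance eigenvectors in expectation.
  Ground truth stores the injected unit mode vectors in triad-arm and BOC
  space (central differences of the noise-free generator) and the expected
  projection rms (angle rms × configuration-space speed).
- **Contact schedules.** Interfacial pseudo-atom pairs placed 2.2 Å
  (donor–acceptor) or 2.8 Å (weakly charged carbons) apart when "on";
  toggling moves the partner atom 10 Å across the cutoff, so the real
  geometric detection path is exercised, never a label. Occupancy targets
  use the Bresenham pattern `present[i] = ⌊(i+1)o⌋ − ⌊io⌋`, exact to
  1/n_frames; switch times give programmed Hamming losses.
- **Restrained coordinate.** An exact-discretisation Ornstein–Uhlenbeck
  update (AR(1) run as a linear filter) with stationary variance k_B·T/k
  and mean bias/k, deterministic given the seed. The update is unbiased for
  any step, but a `dt > friction/k` guard still raises, as declared.

Defaults (2000 frames at the standard 20-ps stride, 0.1 Å noise, 10 contact
pairs) are chosen once as a realistic desk-scale stand-in for the study
conditions: the noise is small against the ~0.15 rad arm-space signal of a
12° mode (SNR well above 5) and the trajectory lengths keep the full suite
in seconds. What passing these tests shows is that the analysis operators
are correct on data satisfying their assumptions — rigid cores, stationary
noise, geometric contact toggling. What they cannot show is robustness to
real-trajectory pathologies: partially unfolded cores, correlated solvent
noise, water-mediated contacts, or drift across the equilibration cut.

## Pipeline

`run_analysis` runs contacts → (optional BSA) → triads/CDR3/triad-PCA →
BOC/hinges/BOC-PCA → peptide angle/RMSF → force from one configuration,
with per-stage isolation: a failing stage is recorded under `skipped` with
its reason and the rest proceed; the exit is nonzero only on total failure
(e.g. missing input files). Reports carry the thresholds actually used and
a SHA-1 of the input coordinates for reproducibility audits; re-running on
identical inputs gives identical JSON up to the timestamp field.
`compare_systems` builds pairwise PC1 similarity matrices, side-by-side
high-occupancy counts, and bead displacements of each system's average BOC
from a reference system's.

## Known limitations

- The 2.4 Å hydrogen-bond criterion on heavy atoms is strict; detection on
  hydrogen-free crystal-derived frames will undercount relative to
  energy-based or hydrogen-resolved criteria.
- The donor/acceptor table covers standard amino acids only; modified
  residues need explicit annotations.
- SASA sampling error (~1 % per sphere) propagates into BSA; BSA of a
  residue with no partner atom within reach is exactly zero, but small
  negative per-frame values within sampling noise are possible and are not
  clipped.
- The Hamming "lost" rule and the hinge-angle arm construction are
  documented defaults for under-specified definitions, not unique choices;
  both are configurable and comparisons across tools should state them.
- No time-lagged or independent-component analysis; PCA assumes
  equal-weight frames from a stationary interval.
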