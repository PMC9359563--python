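# Methods

This note documents the models and conventions behind each analysis, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Coordinate model and residue identity

Structures are chain → residue → atom hierarchies in ångströms. Residue
identity is the author identity `(chain, number, insertion code)`; the
package never renumbers internally, because the receptors this toolkit
grew up on are discussed in two numbering systems at once (PDB deposition
numbering vs UniProt numbering, offset by 29 for the C5aR1 crystal
structures). Reports print author numbering; contact maps can apply a
joined-numbering offset per chain (receptor keeps UniProt numbering, Gα
shifted by a stated constant, default receptor-max + 100) purely for
display.

Altloc conformers: the highest-occupancy conformer is kept, ties broken
by altloc letter — deterministic by construction. Trajectory times are
converted to nanoseconds from the picosecond convention of the MDAnalysis
DCD/XTC readers; a `time_unit` override exists because trajectory
dialects disagree about header time units.

## Membrane frame

Following the OPM convention, the membrane is represented by a unit
normal plus two phosphoryl-plane levels. The normal is the smallest-
eigenvalue eigenvector of the covariance of the pooled phosphoryl
coordinates; leaflets are separated by an exact 1-D 2-means split of the
projections (the sorted split minimising within-class sum of squares —
deterministic, unlike iterative k-means), and the levels are per-leaflet
mean projections. A leaflet separation below 10 Å is rejected as a
degenerate membrane. The sign convention (normal points extracellular)
is fixed either by a user-supplied extracellular reference selection or,
by default, by the deterministic positive-z rule. The frame is estimated
once from a chosen structure and held fixed over a trajectory; per-frame
re-estimation is possible by calling the estimator on individual frames,
but a fixed frame is the default because the phosphoryl plane of an
equilibrated bilayer drifts far less than the protein of interest.

## Contact criteria and maps

Two residues are in contact when their Cβ atoms are within 8 Å **or**
their Cα atoms within 12 Å; glycine substitutes Cα for its missing Cβ
(the standard convention). Whole-complex maps use a plain Cα–Cα cutoff
(default 20 Å), the scale at which receptor–Gα interface blocks are
visible in one panel. Occupancy ("gradient") maps are per-pair means of
the boolean indicator over (optionally strided) frames; a difference map
lists pairs whose occupancy changes by at least `min_change` (default
0.5), sorted by |Δ| with a residue-number tie-break. Self-pairs and
|i−j| ≤ 2 neighbours are trivially in contact; a helper mask exists to
drop them from displays. Boundary behaviour is inclusive (`≤ cutoff`),
so raising a cutoff can only add contacts.

## Distances, salt bridges, triads

"Centre of mass of a residue" means the mass-weighted centre of its
heavy atoms; the side-chain-only variant (mass lumped beyond the N/CA/C/O
backbone) is used for salt bridges and alternation, since that is where
the charge lives. Salt bridges are (Asp/Glu) × (Lys/Arg/His) pairs whose
side-chain centres stay within 6 Å (default) in at least `occupancy_min`
of frames; histidine is counted positively charged by default because
protonation is unknown at this resolution — both choices are flags.

A *triad* is a residue triple spanning at least two chains whose three
pairs each satisfy the contact rule in at least 80 % of frames. The 0.8
default operationalises "close to each other during essentially the whole
trajectory"; it is a parameter, not a law. With the charge filter on,
all three residues must be charged with at least one opposite-charge
pair, which is the (−, −, +) Glu–Glu–Lys pattern of the receptor/Gα/Gβ
interface this detector was built for. When a triad has a unique
odd-charge residue, that residue is taken as the centre and the per-frame
nearest partner (side-chain centres) is labelled with a sticky tie rule
(exact ties keep the previous label); the alternation count is the number
of label switches between consecutive sampled frames.

## Helix detection, axis and H8 orientation

Detection uses Cα-geometry windows rather than hydrogen-bond (DSSP-style)
assignment: residue *i* opens a helical window when |Cα(i)−Cα(i+3)| ∈
[4.5, 5.5] Å and |Cα(i)−Cα(i+4)| ∈ [5.0, 6.5] Å (the ideal α-helix gives
5.05 and 6.20 Å); maximal runs of windows, extended to their full i..i+4
span, become segments. The H-bond-free criterion is deliberate: coarse
and synthetic models carry no reliable backbone H-bond geometry. The
windows are package constants exposed for tuning.

The segment axis is fitted from the chord bisectors
Cα(k−1) + Cα(k+1) − 2 Cα(k), which point radially toward the helix axis
(axial components cancel); the axis is their smallest-variance direction,
signed N→C. A plain principal component of the Cα cloud is biased
whenever the span is not a whole number of turns (≈ 0.03 tilt at 18
residues) and is kept only as the fallback for near-straight degenerate
spans.

"Inverted H8" is not defined quantitatively anywhere in the literature
this package follows; the operationalisation here is one reasonable
choice and is therefore explicit: the reference direction is the
in-membrane-plane projection of (TM1 intracellular end − TM7
intracellular end), where the intracellular end of a TM helix is its
terminal residue with the smaller projection on the membrane normal
(orientation-agnostic). An H8 axis within 90° of the reference
(inclusive) is *normal*, beyond it *inverted*; the tilt is the angle of
the axis out of the membrane plane. An H8 axis within 5° of the membrane
normal has no meaningful in-plane projection and is reported as a
degenerate-projection error.

## Amphipathicity, faces, immersion

The hydrophobic moment is μH = |Σₖ Hₖ **u**ₖ| with Hₖ the Eisenberg
consensus hydrophobicity (bundled default, swappable) and **u**ₖ the unit
vector from the helix axis to residue k's side-chain centroid, projected
perpendicular to the axis. A sequence-only mode replaces **u**ₖ by the
ideal helical-wheel direction at 100°/residue; on an ideal generator
helix the two agree within 2 %. The moment is reported as the raw sum
(no 1/N), so values scale with helix length.

Face partition: a residue whose **u**ₖ projects onto the membrane normal
beyond cos 80° is lipid-facing (positive side) or cytosol-facing
(negative side); the ±10° band around the membrane plane is *border*.
Histidine is always border-class, and residues without a side-chain
representative (glycine) are skipped with a warning and counted border.
Face composition fractions use the hydrophobic set {A, V, L, I, M, F, W,
C, P}. Immersion depth of a residue is the projection of its
whole-residue centre of mass on the normal minus the intracellular
phosphoryl level — positive means inside the bilayer; the report includes
the N-vs-C terminal depth difference, which captures one helix end
dipping toward the lipids.

## Superposition, RMSD, stabilization

Superposition is the least-squares proper rotation + translation
(Kabsch, via `scipy.spatial.transform.Rotation.align_vectors`);
reflections are never returned and collinear point sets are rejected.
RMSD series fit each frame on one atom selection and measure over
another without re-fitting; "heavy-atom backbone" means N, Cα, C, O.
With fit = measure the series equals the plain per-frame
optimal-superposition RMSD exactly. Note that a recovered RMSD of ~1e−7
on a perfect transform is expected double-precision behaviour: it is the
square root of an ε-level residual sum at ~50 Å coordinate scale.

Stabilization time: the series is scanned with a sliding mean of
`window` frames (default 50) and the reported time is the first frame of
the earliest window from which *every* windowed mean stays within
`tolerance` (default 0.5 Å) of the final windowed mean. If only the
final window satisfies this, the criterion is vacuous and the series is
reported as not stabilized — this is what a monotone drift produces.
Because the entering window may still overlap the tail of a drift, the
estimate can precede the visual end of the drift by up to roughly
√(2·tolerance·window/slope) frames; the tests pin this closed form.

## Sequence comparison

Global Needleman–Wunsch alignment with affine gaps via Biopython's
`PairwiseAligner`, defaults BLOSUM62 / open 10 / extend 0.5 (the EMBOSS
needle conventions). Regions are annotated in UniProt numbering;
a region selects the contiguous alignment-column span via the annotated
sequence, so gap columns inside it are countable for either sequence.
Region identity is 100 × identical columns / columns with at least one
residue. The bundled annotation for the two C5a receptors anchors TM
boundaries on functionally assigned residues (P5.50 at W213/P214, the
FWLPY motif in TM6, NPIIY closing TM7, the H8-forming Leu/Val cluster at
315–324) and draws ICL3 as the 234–245 block that is 12 residues in
C5aR1 and 7 in C5aR2; the exact loop ends at the frayed TM5/ICL3/TM6
junctions are approximate and user-overridable, and the deletion-block
positions they bracket are stable across BLOSUM62/50 and gap penalties
8–15 / 0.5–2. An optional preprocessing flag truncates the disordered
extracellular N-termini (C5aR1 1–29, C5aR2 1–27) before aligning;
default off.

The bundled FASTA carries the two full-length human receptor sequences
(P21730: 350 aa; Q9P296: 337 aa). They were transcribed for offline use
and verified against ~45 independent residue-level anchors (motif
positions, functional-residue tables, substitution pairs, region
compositions) before being frozen into the package.

## Synthetic data: what it emulates, what it does not

The generator produces ideal α-helices (rise 1.5 Å, twist 100°, Cα
radius 2.3 Å) with a single Cβ pseudo-atom per side chain placed 1.5 Å
radially beyond Cα and carrying the residue's side-chain mass; N, C, O
follow a rigid schematic template with chemically sane bond lengths.
Toy complexes place receptor/Gα/Gβ helices (chains R, A, B) between two
flat phosphoryl pseudo-atom planes and refuse assemblies whose protein
chains approach below 2 Å. Trajectories add per-atom isotropic Gaussian
noise in the lab frame (so E[RMSD] ≈ σ√3 against the base structure, an
analytic check the tests use), rigidly translate an event residue so its
noiseless COM distance equals the bound distance from the formation
frame on, and pin a planted triad's three COMs to a prescribed triangle
for all frames. The same seed yields bitwise-identical output.

Deliberately *not* emulated: force fields, lipid packing, side-chain
rotamers, correlated motions, periodic boundaries. Passing tests
therefore demonstrate the correctness of the geometric analyses and
their estimators under known ground truth — not that any biological
conclusion transfers to real trajectories. The reference study systems
(orientation toy, planted-triad system, random oracle complexes,
half-plane amphipathic helix) live in `h8kit.scenarios` so tests and the
reproduction script share identical conditions; the planted-triad system
uses 100-frame trajectories with σ = 0.25 Å and 30 Å chain separation,
sizes chosen to keep the whole validation suite fast on a single CPU
while leaving the planted signal orders of magnitude above noise.

The "crystal H8" scenario is an ideal-geometry *synthetic reconstruction*
of the crystallographically resolved C5aR1 H8 residue range (UniProt
315–324 plus an extended C-terminal flank): real sequence and numbering,
synthetic coordinates. It exercises helix detection on the real H8
sequence span; it makes no claim about experimental geometry, for which
the deposited structures themselves must be used.

## Known limitations

- PDB parsing is single-conformer after altloc resolution and ignores
  waters; unknown ligand residues are retained under a generic pseudo
  type with element-based masses only.
- The helix detector reports segments as short as one 5-residue window;
  on very noisy coordinates a hydrogen-bond-based assignment will
  disagree near frayed helix ends by a residue or two.
- Occupancy maps hold the residue list of the topology fixed; they do not
  track residues entering/leaving a selection over time.
- The stabilization-time definition is one concrete reading of
  "fluctuations stabilized after t"; window and tolerance materially
  affect the answer and are therefore explicit parameters.
- Region boundaries for the receptor annotation are approximate at loop
  junctions, as discussed above; conclusions that hinge on a boundary
  residue should be re-run with user-supplied spans.
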