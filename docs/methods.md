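# Methods

`foldswitchlab` studies metamorphic (fold-switching) proteins with a
coarse-grained model in which one sequence is driven between two reference
folds. This note records the model, the protocols, the numerical choices
and the limits of what the synthetic experiments demonstrate.

## Representation

Each residue carries three beads (CA, CB, O); everything else is
reconstructed from ideal backbone geometry. The virtual amide N used by
the hydrogen-bonding term is a fixed affine combination of CA(i-1), CA(i)
and O(i-1) (coefficients rescaled to sum exactly to 1, so all terms are
exactly invariant under rigid motions). Glycine receives a virtual CB
placed 1.53 Å from CA in the local backbone frame and is flagged as
virtual. Internal residue numbering is 1-based and contiguous, with the
author numbering of a source PDB retained for reporting.

## Order parameters

* **Q_diff** — a dual-reference progress coordinate. A Gaussian-weighted
  similarity `q` is summed over the union of contacts present in either
  reference (CA-CA <= 9.5 Å, inclusive, sequence separation > 2), with
  per-pair widths sigma_ij = |j-i|^0.15 Å, and affinely renormalized so
  that reference A maps to 0 and reference B to 1. Both Gaussian terms are
  evaluated for every union pair, including against a masked (99 Å
  sentinel) reference distance, which keeps the coordinate smooth; the
  value is not clamped to [0, 1]. Exclusion masks (a rigid domain, or
  interdomain contacts of one state) are stored as booleans and only
  materialized as the 99 Å sentinel on export.
* **Q_W** — a single-reference similarity with the 2/((N-2)(N-3))
  normalization. Two conventions are implemented and always named: the
  default `all_pairs` sums every j > i+2 pair, so native self-similarity
  is exactly 1 (only this convention is consistent with classifying
  folded structures near 0.75 and unfolded ones below 0.1); the
  `contact_restricted` variant sums only native contacts (reference
  distance strictly < 9.5 Å), which for realistic proteins saturates near
  0.1–0.2. Reports record which variant produced a number.

A finite-size caveat: for chains of ~30–60 residues the all-pairs Q_W of
*any* physically bonded coil has a floor near 0.1, because short-range
pairs quasi-match every reference. The random-coil generator therefore
draws from alternating extended- and compact-biased angle families and
verifies Q_W < 0.1 against the designated reference before accepting a
coil; the backbone-dynamics unfolded-start protocol (below) is reliable
only for chains long enough that this floor sits below the threshold, and
fails loudly otherwise.

## The potential

Five physical term groups (energies in kcal/mol, lengths in Å,
k_B = 1.987e-3 kcal/mol/K):

* **backbone** — harmonic virtual bonds (CA-CA 3.8, CA-CB 1.53, CA-O 2.40,
  O-CA' 2.76, spring 100 kcal/mol/Å^2); a flat-bottom chirality penalty on
  the normalized scalar triple product of the local frame (activates only
  below 0.2, i.e. for mirror-like geometry); double Gaussian "basin" wells
  on the (i,i+2)/(i,i+3) CA distances centered on the ideal helical
  (5.40/5.04 Å) and extended (6.60/10.08 Å) values measured on the ideal
  builders; compact excluded-volume repulsion (CA 3.6 Å, CB 2.8 Å cores).
* **contact** — CB-CB pair wells for |j-i| > 2 with residue-type depths
  from the packaged 20x20 matrix (hydrophobicity-driven with salt-bridge
  bonuses and like-charge penalties; SHA-256 checksummed TSV). The wells
  are single-peaked (quintic switch up to 5.5 Å, down by 7.2 Å, plus a
  longer-range well peaked at 8.2 Å carrying 30% of the depth as a stand-in
  for water-mediated interactions): a flat-bottomed well was found to leave
  helix packing free to shear — with no restoring force, tertiary structure
  diffuses away from any reference — so packed pairs always feel a gradient.
* **burial** — a smooth CB-neighbour density (unit weight below 6 Å,
  switching off by 8 Å) scored against three overlapping density-class
  windows (boundaries at 2 and 5 neighbours, tanh sharpness 1.5) with
  per-type preferences from the packaged table.
* **hydrogen bonding** — Gaussian O···N wells gated by the CA-CA registry
  distance. Helical (i, i+4) geometry and the antiparallel sheet rung are
  calibrated on the ideal builders (O-N 5.91/5.04 Å, CA-CA 6.20/5.16 Å
  — the absolute O placement of the three-bead model is coarser than a
  real carbonyl, so the centers are model-consistent rather than
  experimental). Sheet cooperativity sums the product of three
  consecutive rung occupancies along antiparallel and parallel
  diagonals: ladders shorter than 3 rungs contribute exactly zero, so
  3-residue strands can form but are not spuriously rewarded. The
  chain's first residue has no reconstructible amide N and cannot form a
  rung.
* **memory** — the fragment bias: overlapping 9-residue windows (stride
  1, clipped to >= 3 at region ends) pull CA-CA and CB-CB distances with
  |j-i| >= 2 inside each window toward a reference structure,
  V = -lambda * sum_m omega_m * sum_ij exp(-(r-r_m)^2 / 2 sigma_ij^2),
  lambda = 0.3. Regions never span an uncovered linker, so a
  memory-free connector breaks the continuity of the bias. Fragment
  weights default to omega_m = 1 per fragment (overlapping windows
  accumulate; identical pair entries are merged exactly by summing
  weights): per-residue coverage normalization is available
  (`weight_mode="coverage"`) but makes the local bias too weak to fold
  the toys against the transferable terms. Dual memory concatenates two
  single-reference libraries at equal strength.

Two steering terms complete the model: the umbrella bias
½ k (Q_diff - Q0)^2 (protocol default k = 1500 kcal/mol) with analytic
forces propagated through the q-function Gaussians, and a flat-bottom
interdomain separation restraint on group centroids (defaults 30 Å,
10 kcal/mol/Å^2). Every term depends only on internal coordinates;
analytic forces match central finite differences to < 1e-5 relative error
on random configurations (in practice ~1e-9).

## Dynamics

BAOAB Langevin integration, 5 fs timestep, uniform 60 g/mol bead masses,
friction 5e-4 fs^-1 (0.5 ps^-1; low friction speeds conformational search
at desk scale and BAOAB remains canonical at any friction). Noise is
pre-drawn from a seeded PCG64 generator, so a fixed seed + configuration
reproduces scalar trajectories bit-identically. Non-finite energies abort
with the offending step and term. Frames record the energy breakdown,
Q_diff, and Q_W/RMSD against any registered references; scalars are
reproducible from stored coordinates.

## Protocols and desk-scale presets

* **Unfolded starts** — either the backbone-only dynamics protocol
  (100,000 steps at high temperature, restart every 10,000, lowest-Q_W
  restart returned, automatic extension before failing) or verified
  self-avoiding random-walk coils (the robust choice for short toys, and
  the default for annealing replicas).
* **Umbrella scans** — default 51 centers at Q0 = 0.00…1.00 step 0.02
  with k = 1500. Windows can start all-from-unfolded (full-scale
  protocol), sequentially chained, or — the desk-scale study preset —
  independently from the relaxed reference nearest to each center, with
  transition-region centers run from both endpoints and all trajectories
  pooled (21 centers, k = 700 matched to the 0.05 spacing, 100,000 steps
  per window at 1.05 T_f). At short window lengths, dragging one chain of
  windows across the transition produces over-melted mid-coordinate
  configurations whose inflated entropy dominates the reweighted surface;
  endpoint initialization avoids this, at the documented cost of relying
  on the metastability of the two folds (verified over 3x10^5 steps).
  The first 1/6 of each window's frames is discarded as equilibration
  (the full-scale protocol's 4,000 of 24,000 frames, kept proportional).
* **Annealing refolding** — independent replicas, fresh coil starts,
  linear ramp 1.5 T_f -> 0.6 T_f; desk scale runs 500,000 steps (the
  efficiency is insensitive between 5x10^5 and 1.2x10^6 steps at these
  system sizes). T_f of the toy is anchored at 220 K, near the tertiary
  stability midpoint of the relaxed hairpin under the default constants.

## WHAM

The solver is binless (MBAR-style self-consistent iteration on per-window
offsets, log-sum-exp throughout, zero initialization, tolerance 1e-7 on
the offsets, 1e5 iteration cap), which treats mixed temperatures and
arbitrary harmonic biases uniformly. Umbrella windows must form a single
connected support graph; disconnected supports raise an error naming the
gap. Free-energy surfaces are histograms of unbiased frame weights
(default 0.02 bins in Q_diff, 0.5 Å in RMSD axes), minimum-shifted to 0,
with unsampled bins masked (never reported as 0). Heat capacity comes
from reweighted energy fluctuations, C_v = (<E^2> - <E>^2) / (k_B T^2),
with peaks located as local maxima; the first peak of the designated
folded system defines T_f. The adjacent-window overlap report integrates
the minimum of normalized histograms and annotates off-center (trapped)
windows for exclusion.

## Refolding analysis

Endpoints classify by Q_W (all-pairs) against the reference: folded at
>= 0.7, intermediate in [0.4, 0.6], misfolded/unfolded below, and the
(0.6, 0.7) gap takes the nearest class with a low-confidence flag — so
classification is monotone in Q_W. Final structures cluster by
complete-linkage on pairwise best-fit CA RMSD (Kabsch), threshold 2 Å,
deterministic tie-breaks by lowest index. Secondary structure is assigned
from CA-trace geometry (helical and extended bands on the (i-1,i+1) and
(i,i+3) distances, plus a 5-residue straightness gate that separates
strands from wide turn arcs; runs shorter than 3 become coil) — a
deliberately coarse stand-in for an all-atom assigner, adequate for H/E/C
run statistics of generated and simulated structures but not calibrated
against crystallographic assignments. Per-contact frustration is the
z-score of a native contact's pair energy against identity-shuffled
decoys drawn from the chain's composition (optionally also resampling the
pair distance within the wells); minimal above +0.78, high below -1.0,
with degenerate-decoy contacts (e.g. homopolymers) marked neutral.
Refolding efficiency carries an exact (Clopper-Pearson) binomial CI.

## The synthetic study system

One 33-residue sequence is realized as an alpha-helical hairpin (state A)
and a 3-stranded antiparallel beta meander (state B); an optional variant
fuses a 16-residue anchor domain through a 10-residue memory-free linker,
with anchor-internal pairs masked in both reference matrices and
anchor-to-rest pairs additionally masked in state B, mirroring the
exclusion scheme for a rigid non-switching domain. The default sequence
is *designed*: hydrophobic residues (L/I/V) sit where CB points at the
partner helix in the hairpin geometry, the turn is small and polar, and
the rest cycles charged/polar types — without this, native helix packing
is not the optimum of the transferable terms and refolding cannot
discriminate the correct docking. Ideal-geometry builders are not minima
of the potential, so the study presets relax each reference under the
model (two anneals with single memory to itself) before freezing it; the
relaxed references define the contact sets, memory targets and
classification.

Fragment weight 0.5 is the study value: at weight 1.0 the local bias is
so stiff that umbrella windows freeze at the sampling temperature, while
coverage-normalized weights (~0.15) are too weak to fold the hairpin at
all; 0.5 folds 100% of desk-scale annealing replicas and keeps windows
mobile.

**What the toys do and do not show.** Passing the synthetic experiments
demonstrates that the order parameters, biases, integrator, WHAM
machinery and classification behave correctly and reproduce two-state
fold-switching thermodynamics end-to-end on a system where the answer is
known by construction. They do not demonstrate transferable-term realism
for natural sequences: the contact/burial tables are simplified, the
toy's designed sequence makes docking easier than a natural interface,
and desk-scale sampling (10^5–10^6 steps) is ~100x shorter than the
full-scale protocol the method is meant for. Free energies from
endpoint-initialized windows inherit the metastability assumption above;
barrier heights in particular should be read as desk-scale estimates with
hysteresis-limited accuracy, which is why reports carry the sampling
protocol alongside the numbers.

## Known limitations

* No electrostatics, explicit solvent or side-chain rotamers; no
  numerical equivalence with any published force-field implementation.
* The hydrogen-bond geometry is calibrated to this model's O placement,
  not to experimental hydrogen-bond geometry.
* mmCIF, ligands, nucleic acids, insertion codes and gap modelling are
  out of scope for structure input.
* The frustration scan scores the model's own pair potential; it will not
  numerically match external frustration servers.
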