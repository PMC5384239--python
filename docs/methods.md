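# Methods

## Model

Each residue is one bead at its Cα position carrying the full residue
mass.  The potential is a standard Gō-style construction in reduced
units (k_BT = 1 at the reference temperature, so the original study
temperature of 303.15 K maps to T* = 1; lengths stay in Å):

* **bonds** between consecutive residues, E = ½ k_b (b − b₀)² with b₀
  the Cα–Cα distance observed in the source structure and
  k_b = 100 k_BT/Å² (bond fluctuation σ ≈ 0.1 Å — effectively rigid
  chain connectivity);
* **native contacts** for intra-chain residue pairs with |i−j| ≥ 3 and
  reference Cα distance below the 8 Å contact cutoff:
  E = ε [5 (r₀/r)¹² − 6 (r₀/r)¹⁰], minimum −ε at r₀, default
  ε = 1 k_BT — deep enough to keep folds intact, shallow enough to let
  loosely contacted segments (the disordered tail) fluctuate;
* **excluded volume** for every remaining pair,
  E = ε_ev [(σ/r)¹² − 1] truncated to zero at σ = 4.0 Å;
* **interface contacts** (optional, from run configuration): Gō
  contacts between chains at rest distances measured from a native
  reference complex, default depth 2 k_BT each.  These define the bound
  state.  They matter: with purely repulsive inter-chain interactions
  the two chains have no metastable complex, so the unrestrained
  exploration stage would simply dissociate — whereas the system this
  protocol emulates stays associated throughout its 90 ns of free
  dynamics.  A dozen-to-twenty contacts at 2 k_BT put the total binding
  strength at 25–40 k_BT, the scale of a micromolar-to-nanomolar
  protein–protein complex.

**Phosphorylation** is a topology edit, not an energy constant: the
phospho-residue's intra-chain native contacts within ±2 residues are
removed (local disorder release — the mechanism by which modification
frees the tail to explore), and optionally attractive contacts are added
from the phospho-bead to configured pocket beads on the receptor.  Both
knobs are explicit configuration.

## Dynamics

Overdamped (Brownian) Langevin dynamics with the Euler–Maruyama update

    r ← r + (dt/γ) F + sqrt(2 T* dt / γ) ξ,  ξ ~ N(0,1) per coordinate,

one seeded generator, Gaussians drawn in fixed coordinate order —
identical inputs reproduce the trajectory bitwise.  An inertial
thermostatted integrator is deliberately out of scope: the quantities of
interest here are protocol behavior and analysis mathematics, not
kinetic prefactors.

Numerical choices.  dt = 0.001, γ = 1.  The stability constraint comes
from the stiffest normal mode of the harmonic chain, whose eigenvalue
approaches 4 k_b: Euler–Maruyama requires dt < 2γ/(4 k_b) = 0.005, and
dt = 0.001 leaves a 5× margin for contact and excluded-volume
curvature.  (A single-bond estimate, dt < 2γ/k_b, is wrong by the
factor 4 and diverges in practice.)  Divergence is detected by a
coordinate-magnitude bound and reported with the failing step.

## The staged protocol

Three contiguous regions over 10,000 / 90,000 / 10,000 steps (the
10/90/10 proportion of the original 110 ns protocol):

* **Region I** — upper walls E = ½k(d−d₀)² for d > d₀ on two
  anchor-residue→receptor-group COM distances, d₀ = 5 Å,
  k = 10 k_BT/Å²;
* **Region II** — no bias (recorded bias energy is identically zero);
* **Region III** — six two-sided harmonics at distances taken verbatim
  from a table or measured from the native reference complex,
  k = 10 k_BT/Å².

Bias forces are distributed to group members by mass fraction (the
chain rule through the mass-weighted COM), so group A's total bias
force is exactly minus group B's.  Initial placement separates the two
chain COMs by 60 Å along x with seeded random orientations — the
original study states the separation but not the orientation.

Wall softness: at k = 10 the thermal width of a restrained CV is
√(T*/k) ≈ 0.32 Å, so a satisfied wall condition reads as a CV
fluctuating around ≈ d₀, and convergence statements are made on
time-averages (the last 10 % of a region), never on single frames.

## Synthetic fixtures and what they do (not) show

The toy dimer is two compact self-avoiding Cα chains (3.8 Å steps,
3.0 Å exclusion), docked to a 4.2 Å closest approach; the docked pose
is the native complex.  From it the generator derives, by construction:

* two anchor residues on the mobile chain (spaced two apart in
  sequence, outside the disordered tail) mapped to receptor groups of
  4 and 3 residues — the group is the bead subset whose COM sits
  nearest the anchor, i.e. a surface ring around the contact point, so
  the 5 Å approach condition has a wide capture basin rather than a
  single exact pose;
* a six-pair distance table drawn from the 4.8–12 Å band (outside the
  excluded-volume radius, mirroring the several-Å character of
  residue-COM tables), satisfied by the native pose to < 10⁻⁶ Å;
* interface contacts (inter-chain bead pairs within 5.5 Å of the native
  pose) defining the bound state;
* apo structures: the same folds, randomly re-oriented, COMs 60 Å
  apart.

Default sizes are 14 + 12 beads with a 4-residue tail.  The size is a
physical mapping decision: the capture stage can only do its job if its
duration spans the chains' rotational relaxation (the original 10 ns
Region I is comparable to a protein's rotational correlation time), and
τ_rot ~ N·Rg²·γ/(T*·dt) grows as N^(5/3) — at 28+24 beads Region I
would cover only a few percent of an orientational search.

What passing tests show: the staged protocol's contract (capture to the
walls, bias-free exploration that stays associated, convergence onto
the native distance table) and the exactness of every analysis metric
on ground-truth inputs.  What they do not show: anything about real
protein energetics, sequence effects, solvent, electrostatic steering,
or the kinetic prefactors of fly-casting — the toy dimer has none of
these by design.

Other generators: `make_jitter_trajectory` (iid Gaussian noise σ per
coordinate; no-fit RMSF converges to σ√3) and `make_breathing_helix`
(ideal Cα helix, rise 1.5 Å, 100°/residue, radius 2.3 Å, breathing
uniformly so the capture-radius series is exactly proportional to the
imposed scale factor).  `make_synthetic_phospho_pocket` is a hand-built
all-atom fragment — synthetic, not from any crystal structure — whose
three phosphate-oxygen→basic-nitrogen contacts validate residue-level
contact counting.

## Analysis conventions

* RMSD/RMSF: mass-unweighted Kabsch superposition on the fit selection
  per frame (reflection branch excluded by sign-correcting the smallest
  singular vector), deviation measured on the measure selection; RMSF
  is about the time-mean position.
* SASA: Shrake–Rupley with a deterministic golden-spiral point set
  (default 960 points, probe 1.4 Å) on a fixed element radii table
  (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, H 1.20, Se 1.90 Å).  Each
  atom's point set is deterministically re-oriented so discretization
  errors decorrelate across atoms.  The total's rigid-motion invariance
  is limited by point sampling: ~0.1–0.4 % worst-case at 960 points
  (the same scale an independent implementation shows), ≲ 0.03 % at
  7680 points; invariance-sensitive comparisons should raise the point
  count.  Coarse-grained structures use a uniform 3.0 Å bead radius — a
  stand-in whose percentages are not comparable to all-atom values.
* Normalized complex SASA: 100 × SASA(complex) / (SASA(monomer 1) +
  SASA(monomer 2)), each monomer taken alone in its complex
  conformation.  ≤ 100 by construction; symmetric in the partition.
* Polar contacts: heavy-atom N/O–N/O distance cutoff (default 3.5 Å),
  no angular term, so hydrogen-free crystal inputs work unchanged;
  atom-pair or distinct-residue counting is an explicit parameter.
* Capture radius: per-frame mass-weighted radius of gyration of a
  selection; single-bead selections are rejected (Rg ≡ 0) with advice
  to use a residue window.

## Known limitations

* Six COM-distance conditions determine the relative pose only up to
  discrete alternatives (including near-mirror solutions): a Region-III
  end state can satisfy the table to < 0.5 Å yet sit far in RMSD from
  the reference pose.  The original protocol's all-atom force field
  breaks this degeneracy; the desk-scale model relies on the interface
  contacts to favor the native branch and does not always land on it.
* Region-III convergence is seed-dependent: across ten dynamics seeds,
  eight runs brought all six time-averaged CVs within 0.5 Å of their
  targets; the others stalled ~1 Å off on one CV (a wedged contact
  arrangement).
* The Brownian engine has no hydrodynamics and no inertia; time has no
  absolute calibration, only relaxation-time ratios.
* CG-mode SASA percentages and the monomer-sum normalization were
  validated for invariants (bounds, symmetry, rigid motion) on
  synthetic complexes; no comparison against a crystallographic complex
  is bundled, since the pipeline ships no downloaded structures.
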