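# Methods

This note records the models implemented by `introntoggle`, the defaults and
their rationale, what the synthetic generators do and do not emulate, and the
numerical choices made where the underlying literature leaves the design open.

## Active-site descriptors and state classification

The catalytically competent configuration of the group II intron active site
is a triple helix in which the J2/3 junction (A287-G288-C289) and the
two-nucleotide bulge pair with the D5 catalytic triad (C358-G359-C360). Two
scalar descriptors track its integrity:

* **d_289-358** — the heavy-atom distance between O2 of C289 and N4 of C358,
  in Å. (The wild-type residues carry these atoms; for mutant constructs the
  catalog entry should be redirected to the closest Watson–Crick-face
  donor–acceptor pair of the construct, and the catalog records whatever
  choice was used.)
* **α** — the angle between the nucleobase planes of residue 358 and its
  Watson–Crick partner 385, in rad. Each plane is the least-squares plane
  through the residue's full ring-atom set (9 atoms for purines, 6 for
  pyrimidines), obtained as the smallest-variance principal direction of the
  centered ring coordinates. The angle is folded to [0, π/2] via
  arccos(|n_a·n_b|), so it is independent of normal orientation and of which
  ring is listed first. No convention for the plane fit or the angle branch is
  canonical; this one is recorded here and used consistently.

A frame is labeled `TRIPLE_HELIX` iff d_289-358 ≤ 3 Å **and** α ≤ 0.35 rad,
otherwise `DISRUPTED`. Both bounds are inclusive, matching the "values ≤
threshold" phrasing in which these criteria are conventionally stated.
Classification is monotone by construction: increasing either descriptor can
only move a frame toward `DISRUPTED`.

Ion roles (K1 at the junction, M1/M2 in the catalytic metal cluster) are a
modelling judgement, not a property of deposited coordinate files, so the
caller assigns them explicitly (selector strings, typically by serial
number). `suggest_ion_roles` proposes candidates by proximity — the potassium
nearest O5′ of residue 359 for K1, the two magnesiums nearest the triad
phosphates for M1/M2 — but the suggestions are advisory.

**Ion release.** A release event is a sustained excursion of an ion–anchor
distance: the ion must first be bound (d < 3.5 Å), and the event is placed at
the first time the distance exceeds 6.0 Å and stays above it for a full dwell
window (default 1 ns). The two cutoffs and the dwell are package defaults
chosen to separate coordination-shell fluctuations (~0.3 Å) from departure to
bulk solvent (> 6 Å); they are exposed in the configuration. Re-binding
re-arms the detector, so intermittent coordination produces one event per
departure.

**Summaries.** Trajectory statistics discard the first 25 ns as equilibration
(the convention under which the reference trajectory statistics were
collected) and report the arithmetic mean and sample (ddof = 1) standard
deviation of the remainder.

## Path collective variables

A conformational transition is discretized as an ordered set of P reference
nodes (default P = 16) over the heavy atoms of the path residues (default
285–290, the junction that rearranges during toggling). Nodes are obtained by
linearly morphing between the two endpoint conformations (the end structure is
first rigid-body superposed onto the start) and resampling the morph at equal
arc length, where arc length is accumulated adjacent-frame RMSD. Resampling
tolerates 5% spacing non-uniformity; a stored path tolerates 20% ("equally
spaced" nodes are part of the path-CV contract). The morphing here is pure
linear Cartesian interpolation; per-intermediate energy minimization, as done
when such paths are built from full-RNA models, is intentionally not
performed — the path machinery is agnostic to how its nodes were relaxed.

For a trial conformation with per-node distances d_i (RMSD after optimal
superposition onto each node — alignment is per node, and this choice is
recorded because un-aligned variants exist):

    S = Σ_{i=1..P} i·e^{−λ d_i²} / Σ_i e^{−λ d_i²}
    Z = −(1/λ)·ln Σ_i e^{−λ d_i²}

S is reported on the node-index scale 1..P (not normalized to [0, 1]); Z is
in Å². The exponent uses the *squared* RMSD with λ in Å⁻², and λ is chosen by
the standard overlap prescription λ = 2.3/(mean spacing)², which makes
adjacent nodes contribute weight e^{−2.3} ≈ 0.1 at a node. A 16-node path
with ~0.312 Å spacing therefore gives λ ≈ 23.66 Å⁻². Both sums are evaluated
with log-sum-exp, so arbitrarily large λd² cannot overflow; the identities
1 ≤ S ≤ P and Z ≥ −ln(P)/λ hold for every input.

Note that with the overlap λ the value of S *at* a node equals the node index
only away from the path ends (the terminal nodes have a one-sided neighbour
and read ≈1.09 and ≈P−0.09); the exact node identity S(node_i) = i, Z = 0
holds in the sharp-λ regime (λ·spacing² ≳ 15), which the tests use when they
assert it to 10⁻³. S at the node sequence is strictly increasing for any λ.

## Metadynamics

Hill logs store Gaussians with per-coordinate widths; heights are given in
kJ/mol at the I/O boundary (0.3 kJ/mol default, the deposition height used in
the reference protocol) and held internally in kcal/mol (all energies in this
package are kcal/mol internally; 1 kcal = 4.184 kJ exactly). Widths follow
the adaptive-width protocol — the per-coordinate sample standard deviation of
the collective variables over a trailing window (default 1 ps at a 1 ps
deposition stride) with a lower floor of 0.03 in each coordinate's own unit
(S dimensionless, Z in Å²; the floor is interpreted in the CV's native unit).

The free-energy estimate is the plain non-well-tempered identity
F(p) = −V_bias(p) shifted so the grid minimum is exactly 0, on a default
200×200 grid spanning the hill centers padded by 3σ of the widest hill. A
**barrier** between two basins is defined as the minimax path value — the
lowest achievable maximum F along any 8-connected grid path between the basin
minima — minus F of the starting basin. This definition is used because a
single ΔG‡ per 2-D landscape requires a path-extraction rule and the minimax
rule is parameter-free and monotone under raising the saddle. Basins are
located as the minimum inside a caller-supplied hint box and must be an
interior local minimum, otherwise the query fails loudly.

The published toggling barriers (~20 kcal/mol for the protonated
post-cleavage state, ~25 kcal/mol non-protonated, with the toggled state ~+5
kcal/mol above the triple helix) come from full-RNA path-metadynamics and are
**not** desk-reproducible; what this package validates is the identical
deposition/reconstruction/barrier machinery on analytic landscapes: an
overdamped Langevin sampler (Euler–Maruyama, kT = k_B·T with T in kelvin,
unit mobility) fills a 3 kcal/mol double well and the reconstructed minimax
barrier lands within 20% of the analytic value; the "three-state" preset
encodes the +5 kcal/mol final-state offset topology exactly. Sampler runs are
bit-reproducible given a seed. Reconstruction quality is assessed on the
final surface; with 0.0717 kcal/mol hills the residual bias ripple is well
below the barriers of interest (~0.1–0.3 kcal/mol RMS in the sampled region
of the test problems).

## Splicing kinetics and the Eyring bridge

Splicing is modeled as two irreversible first-order steps
precursor →(k1) intermediate →(k2) linear intron, with closed-form fractions

    f_P = e^{−k1 t},  f_I = k1/(k2−k1)·(e^{−k1 t} − e^{−k2 t}),  f_E = 1 − f_P − f_I

evaluated through φ(x) = (e^x−1)/x with its Taylor limit at x → 0, so the
degenerate point k1 = k2 (f_I = k1·t·e^{−k1 t}) is reached continuously and
the fractions sum to 1 exactly at every t.

Fitting minimizes the weighted squared residuals of all three species
simultaneously over (log k1, log k2) (Levenberg–Marquardt, five log-spaced
starts around the inverse median sampling time, best residual wins); a fit
whose rate collapses to the parameter boundary raises instead of returning
numbers. Weights are inverse-s.e.m. when the dataset carries per-point
standard errors, else uniform. Uncertainties come either from the
Jacobian covariance at the optimum (fast, but approximate: with few
replicates the per-point s.e.m. weights are themselves noisy and the
covariance intervals under-cover) or from residual bootstrap refits that
resample whole time points, preserving the cross-species correlation induced
by per-lane renormalization — the bootstrap is the calibrated choice and is
what the acceptance checks use (coverage of the 95% interval ≥ 90% on
generated data). Both are exposed; intervals are formed on the log-rate
scale. Whether published fits of this kind were per-species or simultaneous,
and whether their ± values are s.e. or s.d. across replicates, is generally
not stated; both weighting modes and both uncertainty estimators are
available so either convention can be matched.

The Eyring–Polanyi equation ΔG‡ = −R·T·ln(k·h/(k_B·T)) (transmission
coefficient 1, k converted from min⁻¹ to s⁻¹) bridges rate constants and
activation free energies. The default temperature is **310.0 K**: it is the
thermostat temperature of the reference simulations, and it maps the
wild-type rate constants k1 = 0.031 min⁻¹ and k2 = 0.026 min⁻¹ onto 22.83
and 22.94 kcal/mol, matching the published 22.8/22.9 pair to the printed
precision (at 310.15 K — 37 °C exactly — the second value rounds to 23.0).
The conversion is exactly invertible: eyring_rate(eyring_barrier(k, T), T)
returns k to 10⁻⁹ relative.

## Synthetic generators

The generators produce inputs with the statistical structure the analyses
assume, so the full pipeline is testable with no external downloads.

* **Active-site fragments** are idealized: planar hexagon/fused-pentagon ring
  templates (1.39 Å bonds) placed so that the descriptors hit caller-chosen
  targets exactly at zero noise (d_289-358 by direct placement of O2 relative
  to N4; α by rotating the 385 ring plane; ion distances by construction).
  They are synthetic stand-ins, not deposited coordinates: correct for
  exercising descriptor geometry, classification, selection, superposition,
  and I/O, but not real RNA geometry (no backbone, no base-pair propeller,
  no crystallographic context). Tests passing on them demonstrate the
  machinery, not agreement with any particular deposited entry.
* **Two-state toggling dynamics** is a discrete-time sampling (default 0.1 ns
  frames) of a continuous-time two-state Markov chain started in the triple
  helix, with default rates 1/50 ns⁻¹ (helix → toggled; toggling onsets tens
  of ns after the first splicing step in the protonated reference
  trajectories) and 1/500 ns⁻¹ back, so the disrupted ensemble dominates once
  toggling has begun. Emissions are Gaussian per state with means mirroring
  the reference values — triple helix (2.70 Å, 0.17 rad, K1 bound at 2.98 Å),
  toggled (4.88 Å, 0.63 rad, K1 released at 8.0 Å). Emission standard
  deviations default to one quarter of each mean's margin to its
  classification threshold (d: 0.075/0.47 Å, α: 0.045/0.07 rad), i.e. the
  ≥ 4σ-separated regime in which per-frame labels are statistically
  recoverable; real trajectory fluctuations are broader (e.g. ~0.24 Å for the
  helical d_289-358 and ~1.05 Å toggled), overlap the thresholds, and put a
  ceiling of roughly 94% on per-frame label agreement — users probing that
  regime pass the broader σ values explicitly. The K1 channel is tied to the
  *first* toggling event (one-way by default, mirroring the observed ordering
  in which K1 release precedes sustained toggling); a reversible mode
  re-binds K1 with the state. Gaussian emissions are a simplification: no
  heavy tails, no intra-state drift, no autocorrelation within a state beyond
  the state process itself.
* **Band time courses** add truncated (clipped at zero) Gaussian noise of
  s.d. 0.02 — gel-quantification scale — to the closed-form fractions per
  replicate (default 3 replicates, 12 time points over 240 min),
  renormalize each lane to sum to 1, and report the replicate mean with
  s.e.m. columns.
* **Toy landscapes**: "double-well" is B(x²−1)² + (5/2)y² with barrier
  exactly B at (0,0); "three-state" is three well-separated negative
  Gaussians (depths 10, 8, 10−offset; σ = 0.6, centers 3 apart) emulating the
  triple-helix → intermediate → toggled basin topology with the final basin
  exactly `offset` (default +5) kcal/mol above the first.

All generators are deterministic given their seed.

## Problem sizes used in validation

The shipped checks run at sizes chosen to make their statistical tolerances
meaningful on a single CPU: 250 000 Langevin steps (≈5 000 hills) for the
double-well reconstruction, 100 seeded replicates for classifier agreement,
release-time detection, and interval coverage (with 200 bootstrap refits per
fit), 10⁵ frames for occupancy convergence, and 12-point/3-replicate time
courses for kinetics. These sizes are validation choices, not limits of the
implementation.

## Numerical and I/O choices

* Coordinates are Å and times ns everywhere; no unit autodetection.
* PDB parsing and writing are delegated to gemmi, with a pre-validation pass
  over ATOM/HETATM coordinate columns because gemmi silently zeroes
  unparsable fields; atom order is restored by serial after reading (gemmi
  merges split residue blocks). Altloc resolution keeps the
  highest-occupancy conformer, ties broken toward altloc A. HETATM ions
  (K/Na/Mg/Ca) are retained as ordinary atoms. mmCIF and binary trajectory
  formats are out of scope; a plain-text frame dialect (`t=<ns>` header plus
  `name x y z` lines, full float precision) covers trajectory interchange.
* Superposition uses the Kabsch algorithm (proper rotation, det = +1) via
  scipy's `Rotation.align_vectors`, unweighted by default with optional mass
  weighting; degenerate (collinear) inputs produce a warning and a
  best-effort transform.
* Selection expressions are conjunctions/disjunctions/negations of residue
  number (with ranges), residue name, atom name, element, chain, serial, and
  the `heavy`/`ion`/`all` shorthands; evaluation is deterministic and
  order-preserving, and empty selections are legal.
* The minimax barrier search is a Dijkstra variant with max-cost composition;
  tests cross-check it against an exhaustive threshold/flood-fill oracle.
* Tie-breaks: basin hints must contain an interior local minimum; equal-cost
  minimax paths are equivalent by definition (the barrier value is unique).

## Known limitations

* The crystal-state descriptor validations run on constructed stand-in
  fragments; with deposited PDB entries supplied by the user the identical
  code path applies, but no deposited coordinates ship with the package.
* The free-energy machinery is non-well-tempered and single-walker; no
  reweighting estimators are provided.
* The kinetic model is the irreversible linear two-step scheme; branching
  (lariat) schemes, reversible steps, and global multi-construct fits are out
  of scope.
* Inter-structure RMSD reproduction for full deposited structures depends on
  the atom selection used, which published values typically leave unstated;
  the superposition tool supports such experiments but no specific value is
  asserted.
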