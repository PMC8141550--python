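# Methods

## The statistical model

A replica study treats each of *n* short independent trajectories as one
Bernoulli trial per binding site: the first time an ion occupies the site,
or right-censoring at the window end *T*. Under a constant pseudo-first-order
rate *b* (well-mixed bulk at fixed concentration *c*, binding-competent
protein), first-binding times are exponential and the expected cumulative
count across replicas is

    y(t) = N · (1 − e^(−b t)),    N = n_replicas.

The primary estimator fits this curve to the observed cumulative counts by
least squares with *N* fixed — the plateau is constrained on the assumption
that every starting conformation can bind, so censored replicas inform the
fit through the unsaturated curve rather than being discarded. The fitted
*b* converts as t½ = ln2/*b* and k_on = *b*·10⁹/*c* (b in ns⁻¹, k_on in
M⁻¹s⁻¹; the 10⁹ appears in exactly one function).

Least squares on a cumulative count has correlated residuals, so the
closed-form censored-exponential MLE

    b̂ = n_events / (Σ observed tᵢ + n_censored · T)

is always computed alongside as an independent estimator; the two agree
within a few percent whenever a handful of events exist, and their
disagreement is itself a useful diagnostic (non-exponential first-passage
behaviour). Uncertainty comes from a replica-level percentile bootstrap
(default 200 resamples) of the MLE; all-censored resamples are redrawn and
counted.

Note on the plateau constraint: the fitted form is y(t) = N(1 − e^(−bt))
with y(0) = 0 and y(∞) = N. A literal transcription of the constrained
formula as sometimes printed, A·(N − e^(−bt)), is dimensionally
inconsistent (nonzero intercept); the zero-intercept reading is the one
implemented.

## Event definitions

*Vestibule entry.* The extracellular gate is modelled as the plane through
the midpoint of two anchor atoms (the R104 guanidinium and E493 carboxylate
carbons in SERT numbering), normal to the vestibule axis, intersected with
a cylinder of `lateral_radius` (default 1.2 nm) to exclude ions passing
beside the protein. One event per maximal inside-interval; the gate's
`min_dwell` defaults to 0 ns (any crossing counts), since entry is a
transport, not a bound state.

*Site occupancy.* An ion occupies a site when its distance to the
unweighted centroid of the coordinating atoms drops below `entry_cutoff`
(default 0.30 nm) and stops occupying it only beyond `exit_cutoff`
(default 0.50 nm). The hysteresis gap suppresses frame-level flicker that
a single cutoff would double-count; a `min_dwell` (default 1 ns) removes
transient touches. An interval still open at the final frame is censored
and kept even if its observed dwell is shorter than `min_dwell` (the dwell
is unresolved, not short). Censoring is an explicit flag, never a sentinel
time, because "bound at T" and "never bound" must stay distinguishable
downstream.

*Binding order.* Replicas partition into six exclusive categories
(NA2-first, NA1-first, tie, only-NA1, only-NA2, neither); equal first
times are reported as ties, never broken randomly, so the counts are
deterministic and always sum to n_replicas.

*Release routing.* For an initially bound ion, the release time is the
first frame beyond `exit_cutoff`; the escape is flagged as passing through
a second site if the ion comes within that site's `entry_cutoff` during
the 1 ns window after release.

## Spatial fields

Both maps live on axis-aligned grids with 0.1 nm spacing in the common
reference frame; all frames are first superposed on the Cα set by
mass-unweighted Kabsch (Cα masses are equal, so weighting is moot).
Density is a raw occupancy histogram (one count per selected ion per
sampled frame, default every 5 ps); displacement is the mean of
|x(t+lag) − x(t)|/lag with lag = 10 ps, attributed to the voxel of the
*start* position. Voxel membership is half-open, [edge, edge+spacing), so
each point belongs to exactly one voxel; samples outside the grid go to an
explicit overflow tally, making mass conservation exact by construction.
Voxels without displacement samples carry a sentinel (−1.0, documented in
the OpenDX header) rather than a fake zero. No smoothing is applied to
either map. Superposed coordinates are not periodic, so out-of-grid ions
are tallied, never wrapped.

## Site geometry

Compactness is the mean distance of a site's coordinating atoms from their
unweighted centroid, sampled at 100 ps; a mass-weighted variant exists
behind a flag but the default is unweighted, since the coordinating O and
C atoms differ too little in mass to change any ranking. Series are
smoothed for display by a centred 1 ns running mean truncated at the
edges. Pre/post splits use samples strictly before the binding time as
"pre"; the value at binding is the nearest sample (the signal is sampled,
not continuous); histogram bin width is 0.005 nm. The all-vs-all RMSD
matrix at 10 ns stride superposes each frame pair on the same coordinating
atoms before the RMSD (local-geometry similarity); a global-frame variant
is available. Rows are ordered bound-replicas-first by ascending binding
time with censored replicas after, and the replica block boundaries are
emitted alongside.

## The synthetic generator

The generator emulates the study design the analyses target: 51 replicas
of 150 ns at 150 mM NaCl, a fast mono-exponential vestibule entry
(t½ = 5.7 ns default), a short-dwell transient site at the gate and one in
the substrate pocket, and two absorbing deep sites with NA1 faster than
NA2 (defaults 4.2·10⁷ and 1.9·10⁷ M⁻¹s⁻¹). Concentration honesty is
enforced by bookkeeping: n_ions/(N_A·V) must match the configured molarity
within 5% or a warning is raised (the default 20 ions in a 6 nm box give
0.154 M).

*Hybrid mode* draws event times exactly from the configured exponential
laws and renders them onto scripted ion paths: one tracer ion per event
class (deep-site tracers enter the vestibule ~1 ns before binding; a
separate tracer realises vestibule entry and the gate-site dwell). The
final approach is expressed as a distance schedule against the *realised*
coordinating-atom centroid, so the drawn binding time is exactly the first
instant the ion is inside the entry cutoff — this is what makes
frame-exact ground-truth recovery a meaningful test. Because deep-site
tracers also cross the gate, the realised first-entry process is the
minimum over tracers and is recorded as such in the ground truth.
Remaining ions diffuse in a reflecting bulk compartment above the gate.
An optional order-coupling switch makes NA1 conditional on NA2 occupancy
(off by default); an optional chloride starts bound near NA1 and escapes
through it at a configurable rate (off by default).

*Spatial mode* integrates non-interacting ions by overdamped
Euler–Maruyama, Δx = D·F·Δt + √(2DΔt)·ξ with F in kT/nm (D defaults to
1.3 nm²/ns, free Na⁺ in water), in a smooth Gaussian vestibule well plus
Gaussian site wells with absorbing capture. The potential is a
phenomenological stand-in with a known force field, not an electrostatics
model; its effective association rate is emergent, which is why kinetics
recovery is tested in hybrid mode and geometric structure in spatial mode.

*Coordinating-atom process.* Each coordinating pseudo-atom is an
Ornstein–Uhlenbeck walker (correlation time 0.2 ns) about an anchor at
radius R(t) along a fixed symmetric direction set (octahedral for 6 atoms,
triangular for 3). On binding, R relaxes exponentially (τ = 2 ns) from the
apo radius (0.35 nm for NA1) to the bound radius (0.25 nm — a 0.1 nm
closure), and the noise amplitude halves (0.04 → 0.02 nm), giving the
compaction-plus-rigidification induced-fit signature by construction.

What the generator does *not* emulate: water, membrane, protein
flexibility beyond the coordinating shell, ion–ion interactions, absolute
association rates from the toy potential, or electrostatics. Passing
tests therefore demonstrate that the *analyses* recover known inputs under
the study's sampling design — not that the toy dynamics resemble a force
field.

Determinism: one global seed expands via `numpy` `SeedSequence.spawn` into
per-replica children, each split into schedule/geometry/path substreams,
so any replica regenerates in isolation and identical (config, seed) give
bit-identical output.

## Numerical choices and problem sizes

- Units: nm and ns everywhere internally; Å/ps conversions live only in
  the MDAnalysis-facing I/O layer. XTC stores time as float32, so the
  uniform-spacing check tolerates the storage rounding and snaps times
  back to the exact grid.
- The Kabsch rotation comes from `scipy`'s `align_vectors`; pairwise RMSD
  matrices use a batched SVD but take the RMSD from actual residuals after
  rotating, because the closed-form singular-value expression loses
  ~10⁻⁸ nm to cancellation on near-identical frames.
- Fit initialisation: log-linear estimate on the first half-rise of the
  cumulative curve, optimised in log *b* (positivity built in). Flat-zero
  and already-saturated curves are fit errors, not numbers.
- Degenerate superpositions (< 3 atoms or collinear sets) raise in the
  primary path; the RMSD matrix falls back to translation-only RMSD for
  collinear pairs and flags nothing silently.
- Default pipeline sizes are desk-scale: frames every 0.05 ns
  (3001/replica) rather than the 5 ps output interval of a production MD
  study, which keeps the full 51-replica pipeline around a minute while
  leaving every per-frame analysis identical in kind. The spatial-mode
  integrator substeps at 0.5 ps below each output frame.
- The pipeline manifest records config hash, seed, package version, stage
  status and every applied default; wall-clock timings go to a separate
  sidecar so the manifest stays deterministic.

## Known limitations

- The gate predicate is a plane+cylinder proxy for a salt-bridge cutoff;
  topologies where the vestibule axis is far from the anchor-midpoint
  normal need the axis set explicitly.
- Serine's hydroxyl oxygen is named OG in standard topologies; selection
  strings written with OH must be mapped by the user (the synthetic
  topology uses OG). The D98 coordination proxy uses the CG carboxylate
  carbon as named.
- Occupancy thresholds are geometric; no hidden-Markov or committor state
  assignment is attempted.
- Real-mode trajectories are loaded fully into memory per replica; very
  large systems should be pre-stripped to the ions and the selections of
  interest.
- Only orthorhombic boxes are supported, and unwrapping assumes
  consecutive-frame displacements below half a box edge.
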