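# Methods

`plectosearch` studies how the topology of supercoiled DNA minicircles
shapes the target search of DNA-binding proteins.  It generates synthetic
minicircle ensembles and protein-on-DNA traces, analyses them with the
standard descriptors of the field, and closes with a discrete-state
stochastic model of facilitated diffusion.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
system does and does not show about real data.

## The minicircle model

A closed DNA minicircle of `n_bp` base pairs is a twistable discrete
worm-like chain: one bead per bp center (rise b = 3.34 Å per bp), plus a
scalar twist increment per junction.  A freshly built circle is planar
with uniform twist carrying linking number

    Lk = n_bp / helical_repeat + ΔLk,

so the relaxed 336-bp circle has Lk0 = 336/10.5 = 32 helical turns and
the topoisomers ΔLk = −4…+5 span Lk = 28…37 and superhelical densities
σ = ΔLk/Lk0 from −0.1250 to +0.15625.

Energies (units of kT at 300 K):

* bending, `(lp/b)·(1 − cos θ)` per joint, with persistence length
  lp = 500 Å (canonical B-DNA);
* twisting, `(lt/2b)·(φ − φ0)²` per junction, with torsional persistence
  lt = 750 Å and relaxed increment φ0 = 2π/10.5;
* hard excluded volume of diameter 20 Å between beads whose contour
  separation exceeds the core diameter (8 bp at these parameters — beads
  closer along the chain than the core are necessarily inside it, so the
  core applies only to pairs that can belong to distinct duplex
  segments).

Sequence-dependent mechanics, electrostatics and melting are outside the
model: the chain is a homogeneous elastic rod.  One consequence is that
the ensemble statistics are symmetric in the sign of ΔLk apart from
sampling noise; any asymmetry between under- and overwound real
minicircles is sequence-driven and not reproduced here.

## Monte Carlo relaxation and topology bookkeeping

Relaxation uses Metropolis Monte Carlo with four move types: twist
transfer between two random junctions (the fast torsional degree of
freedom; no geometry change), small crankshaft rotations of 3–20-bead
arcs, occasional large crankshafts of up to half the circle (the
collective mode that lets the circle buckle into plectonemes), and small
single-bead displacements (bonds must stay within ±20% of the rise).

The linking number is conserved exactly by construction.  Writhe is
computed with the exact pairwise solid-angle formula for polygons; a
crankshaft rotates its arc rigidly, so only (moved × unmoved) segment
pairs change and the writhe increment of a move costs O(m·(n−m)) pair
evaluations.  Each accepted geometry move shifts the twist increments of
the moved arc uniformly by −2πΔWr/m, making the Tw ↔ Wr exchange
explicit; with the twist-transfer moves the twist field then
re-equilibrates along the circle.  Strand passage is excluded by
rejecting any move whose half-way or final position puts sequence-distant
beads inside the hard core.  Along every trajectory Tw + Wr equals the
built Lk to ~1e−7 (float accumulation), far inside the 0.05 tolerance the
analyses assume.

Desk-scale problem sizes: 4·10³ attempted moves per topoisomer suffice
for the conservation checks; 4–6·10⁴ moves let ΔLk = ±4…5 circles buckle
and reach mean writhe of the expected magnitude (|Wr| ≈ 1–3, about half
of ΔLk absorbed as writhe); the trend analyses average over the second
half of each trajectory.  These are equilibrium-trend conditions, not
converged free-energy calculations: tail quantities (e.g. the modal
juxtaposition count of the most supercoiled topoisomers) still drift on
this budget, and the logged distributions should be read accordingly.

## Topology descriptors

Twist is Σφ/2π.  Writhe uses the Klenin–Langowski solid-angle method
(method 1a), exact for polygons, with right-handed crossings positive;
mirror images negate it.  The radius of gyration is the RMS distance of
bp centers from their centroid.  Ellipticity projects the chain onto its
best-fit plane and reports the square root of the ratio of the two
leading planar second moments; the procedure used for the published
minicircle ellipticity band is not specified anywhere we can check, so
the package logs the full per-frame distribution rather than asserting a
band.  Local curvature is the angle between the chain tangents half a
window before and after a site (default window 10 bp, reported in
degrees), which gives the closed-form 360·w/n_bp for a circle and
recovers built-in kinks.

Shape classes follow deterministic rules on top of the juxtaposition
census: no site and |Wr| < 0.5 → open circle; no site otherwise → open
figure-8; one site → figure-8, or racquet when the minor loop is under
25% of the contour; otherwise binned by site count (2, 3, >3).  The two
thresholds are configuration parameters; the published shape census is
pictorial, so these rules are the package's own operationalisation,
chosen to be monotone in intertwining.

## Juxtaposition sites

Detection follows the five-step scanning algorithm with N_c = 50 bp and
d_cutoff = 60 Å: walk the circle; the first bp whose minimum distance to
any partner more than N_c away (circular separation) drops below the
cutoff opens a site; skip N_c bp and take the partner closest to the
opening bp as the site's end; resume scanning after the end.  Two
additions the printed algorithm leaves open: scanning resumes after the
end index, and a candidate site whose begin/end fall within N_c/2 of an
already-recorded site's end/begin is suppressed — it is the same physical
crossing rescanned from the other arm.  An independent brute-force
implementation (plain loops over all pairs) is kept in the test suite and
must agree exactly on random self-approaching loops.

Sites are tracked across frames by nearest circular-index linking with a
20-bp identity threshold (larger moves start a new series).  The site
diffusivity D1_jp is half the slope of the mean-squared circular
displacement of the site midpoint over the first ten lags.

The roughness of the effective potential confining a site follows the
cubic-cell construction with 10 Å cells: with per-sample energies U (kT),
μ_cell = −ln⟨e^(−U)⟩ over the samples in the cell; without energies, the
occupancy Boltzmann inversion μ_cell = −ln(n_cell/n_total) + const.  The
roughness σ(μ) is the standard deviation over visited cells and is
invariant to the additive constant, so both modes give the same σ for
Boltzmann sampling; tests pin the occupancy mode against an analytic
two-level fixture (levels 2 kT apart → σ = 1 kT exactly).

## Synthetic protein traces

Two generators feed the trajectory analyses.

The *coupled walker* is a single probe bead with a short-range attractive
well (depth 4 kT, range 10 Å) diffusing over a relaxed chain ensemble in
the 600 Å periodic box: 3D diffusion while detached, capture near the
chain, groove-coupled sliding while bound (rotation advancing at
`groove_coupling · 2π` per helical repeat of contour advance), brief
hopping excursions, detachment, and intersegmental jumps with probability
`jump_rate_at_jp` per step whenever the bound bp lies within d_cutoff of
a bp more than N_c away — i.e. exactly at juxtaposition sites, so the
channel is structurally gated: it is silent on a relaxed circle and
active on plectonemes.

The *labeled walk* is a parametric ground-truth generator: sliding
segments with known diffusivity d1 (optionally a two-state slow/fast
model with a free rate ratio and per-frame state records), hopping
excursions with R in [15, 30) Å rebinding nearby, 3D segments with large
R, and intersegmental events that teleport the bp index across a stated
pair (> N_c apart by construction) while moving the probe only a few Å.
It exists to validate the classifier and estimators by parameter
recovery, not to emulate any particular protein.

## Trajectory analyses

Mode classification assigns exactly one label per frame, in priority
order: intersegmental (sequence jump > 50 bp with spatial displacement
< 60 Å), sliding (R < 15 Å and |Δbp| ≤ 2), hopping (R in [15, 30) Å,
|Δbp| ≤ 50, rebinding below the sliding shell within 20 frames),
otherwise 3D diffusion.  The numeric thresholds are package defaults
exposed in configuration: the sliding shell matches the contact-well
range, the hopping shell twice that — the conventional choices of
facilitated-diffusion analyses.

D1 comes from the MSD of the circularly-unwrapped bp coordinate over
attached segments, fit to 2·D1·τ + c over lags 1–10.  The free intercept
absorbs the lag-independent variance contributed by integer-bp
discretization (the analogue of localization noise in single-particle
tracking); without it small diffusivities are biased upward.
Intersegmental frames are excised and the flanking segments stitched with
zero displacement, so transfers do not inflate D1 (the opposite
convention — keeping the jumps — is available by passing no labels).
Replicas are pooled by averaging MSD curves, not D1 values.  Standard
errors come from a bootstrap over segments, and a superlinear MSD flags
drift instead of reporting a spurious D1.

Rotation coupling is the Pearson correlation of per-frame (Δθ, Δz) over
sliding frames; for a coupled increment k·ds plus Gaussian noise σ_n the
expected value is 1/√(1 + σ_n²/(k²σ_ds²)), which the recovery tests use
as a closed-form oracle.  Unique intersegmental transfers are counted at
10-bp source/destination granularity, direction-insensitive.  The
scanned-by-transfer fraction is the share of unique visited bp first
reached during a run opened by a transfer and closed by detachment or the
next transfer.  Residence statistics count per-bp visits and mean dwell
per visit.

## Twist propagation

Per junction, a_i is the unit vector between consecutive bp centers,
b_i = (a_{i−1} × a_i)/‖·‖ the discrete binormal, and c_i = a_i × b_i.
These are curve (Frenet-style) frames of the chain axis; a model with
explicit base-pair orientations could define material frames instead, and
the distinction matters only for torsion-free motions that slide the
curve through itself, which the analysis does not target.  Near-collinear
junctions inherit the previous binormal parallel-transported by the
minimal rotation; a fully straight chain is refused.

The landscape C(t, i) = ⟨c_i(0)·c_i(t)⟩ averages over time origins and
replicas; C(0, i) = 1 exactly.  The decorrelation boundary is the first
lag with C < 0.8 (the printed landscapes are color maps with no stated
threshold; 0.8 is exposed in configuration), and the propagation speed
over an index window is the inverse magnitude of the least-squares slope
of the boundary.  Programmed traveling-front fixtures recover their
construction speeds within 20%.

## Target search model

The discrete-state model has L = 336 binding sites on a reflecting
lattice with an absorbing target at site L.  From solution the protein
binds with total rate k_on = 112 500 s⁻¹ distributed uniformly over sites
(k_on = k_off/K_D with k_off = 9·10⁻⁵ s⁻¹ and K_D = 0.8 nM), unbinds at
k_off, slides at u = 10³ s⁻¹ per direction, and crosses each
juxtaposition link at k_t = 10⁶ s⁻¹ both ways.  The total-rate reading of
k_on is forced by the closed form below (a per-site reading would put
k_off·1 instead of k_off·L in the numerator); the per-site variant
remains available behind a flag.

The closed-form search time is

    T = (k_off·L + k_on·[L − S(0)]) / (k_on·k_off·S(0)),

where S(0) = Σ_i F_i sums the splitting probabilities F_i of reaching the
target before dissociating, starting bound at site i.  This is exact: for
exponential killing at rate k_off, 1 − F_i = k_off·E[bound exit time],
which turns the mean bound-excursion times into (L − S)/k_off and
collapses the renewal sum over binding rounds into the expression above.
S(0) and L − S(0) are obtained by two separate linear solves (solving the
complement directly avoids catastrophic cancellation when F_i → 1), with
iterative refinement because realistic rate sets span eleven decades.
Equality with the brute-force master-equation first-passage solve to
better than 1e−8 relative over randomized models is the module's central
consistency suite.

A juxtaposition "placed at p" is mapped to the link (p, L): in the
minicircle the plectoneme apex at contour position p is spatially
adjacent to the target-bearing end of the lattice, and the layouts for
1–3 sites use the conventional placements L/2; (L/2, L/3);
(L/4, 3L/8, L/2).  This is one defensible reading of a pictorial
convention; arbitrary link pairs are first-class in the model, and all
reported ratios T/T0 state their layouts.  T/T0 decreases strictly with
the number of sites at the stated rates.

The Gillespie sampler simulates the identical process exactly (the mean
over walkers converges to the analytic MFPT as 1/√n).  The mobile-link
variant adds endpoint-hop channels at rate `jp_mobility` per endpoint per
direction, interleaved exactly with the search events.  Mobility helps
when links do not already touch the target — a sweeping juxtaposition
ferries the walker into fresh lattice regions — and the package's
mobility sweeps therefore use a generic non-target link; for a link
pinned at the target, motion away from the optimal shortcut can slow the
search, which is a property of the layout mapping, not of the sampler.

## What the synthetic system does not show

The elastic chain has no sequence, no explicit electrostatics and no
protein structure, so absolute diffusivities, mode-propensity
percentages, the measured rotation-coupling value, the published
ellipticity band, and protein-specific comparisons are out of reach by
construction; the test suite replaces them with parameter-recovery and
ordering checks whose expected values are known exactly.  Trend
statements (writhe, compaction and juxtaposition counts growing with
|ΔLk|; search acceleration with juxtaposition count and mobility) are the
quantities this system is designed to reproduce and are asserted.

## Reproducibility

Every stochastic component takes an explicit seed; replica seeds are
spawned from the base seed with numpy's SeedSequence and logged in every
output.  Identical seeds and parameters reproduce trajectories bit for
bit (the Monte Carlo kernel uses a single compiled RNG stream).
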