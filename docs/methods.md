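# Methods

## Model

A point ligand diffuses with constant diffusion coefficient D around a
spherical receptor. The interaction is a central potential U(r): either
zero or a continuum Coulomb term. With the signed Onsager length

    r_c = Q_c Q_s e² / (4π ε₀ ε_r k_B T)      (negative for attraction)

the reduced potential is U(r)/k_B T = r_c/r. Distances are in Å, times in
ps, temperatures in K; diffusion coefficients enter in cm²/s and are stored
in Å²/ps; bimolecular rates leave the package in M⁻¹s⁻¹. All physical
constants are pinned in `spherokin.constants` and attached to every results
document.

Geometry is a set of concentric spherical **milestones**, indexed from the
innermost surface outward. One or more inner surfaces are *bound* (reaction)
sinks, the outermost is the *escape* sink, and the *b*-surface is the
milestone at which external bimolecular flux is delivered.

## Closed forms (the oracles)

For radial diffusion the steady-state theory gives everything exactly:

* arrival rate at an absorbing sphere of radius b:
  `k(b) = 4π [∫_b^∞ e^{U/k_BT}/(r²D) dr]⁻¹`, which reduces to `4πbD`
  for U = 0 and to the Debye form `4πD r_c / (e^{r_c/b} − 1)` for Coulomb;
* committor (splitting probability) from s between absorbers a < q:
  `β = [W(q) − W(s)] / [W(q) − W(a)]` with W an antiderivative of
  `e^{U/k_BT}/r²` (W = −1/r free; W = −e^{r_c/r}/r_c Coulomb);
* MFPT from a delta source at s: solve the piecewise stationary
  unit-source problem, u = e^{−U/k_BT} v with v linear in W on each side of
  the source, and return N/J (particles in the domain over absorbed
  current).

`k_general` evaluates the rate integral for arbitrary U(r), D(r) by
substituting x = 1/r, which maps the improper integral onto the finite
interval (0, 1/b]; it matches the closed forms to better than 1e−10 and is
used as an independent cross-check in the tests.

## Rate composition

With k_b and k_q the arrival rates at the b- and q-surfaces and β the
binding probability from the b-surface,

    k_on = k_b β / (1 − (1 − β) k_b / k_q)

corrects the naive k_b·β for ligands that wander outward past b but return
before escaping. For radial diffusion with the analytic committor this
composition is an identity: it equals the direct arrival rate at the
reaction surface, which the property tests verify to 1e−9 over random
radii.

## Milestoning estimator

From observed crossing events (source milestone, destination milestone,
transit time) the estimator forms counts N_ij and summed transit times R_i
and computes

* kernel `K_ij = N_ij / Σ_k N_ik`, incubation times `t_i = R_i / Σ_k N_ik`;
* stationary flux q solving q(I − K) = 0 (dense left eigenvector; residual
  must be < 1e−10) and stationary probability `p_i ∝ q_i t_i`;
* MFPT `⟨τ⟩ = start · (I − K̃)⁻¹ · t`, where K̃ zeroes the sink rows;
* β from the b-surface, computed two independent ways and cross-checked to
  1e−10: (i) stationary flux of the *recycled* chain in which all sink
  outflow re-enters at the b-surface, normalised by total sink flux, and
  (ii) the fundamental-matrix absorption probability into the bound set;
* free energies `ΔG_i = −k_B T ln(p_i / p_ref)` (reference exactly 0,
  zero-probability milestones NaN).

Rows never exited are flagged, not imputed; multiple bound sinks are
supported and β decomposes into per-sink absorption probabilities (the
`two_site_toy` fixture exercises this against exact arithmetic).

## Brownian-dynamics engine (synthetic data)

The simulator integrates the overdamped position Langevin equation

    x(t+dt) = x + (D dt r_c / r³) x + √(2 D dt) w,   w ~ N(0, I₃)

(the drift term is (D/k_BT)F dt for the Coulomb force). A spec-level
invariant requires √(2D dt) < (minimum milestone gap)/4, so a step cannot
silently skip a surface; any step that still crosses two stop radii raises.

Crossing detection: a sign change of r − r_stop between consecutive
positions, with the crossing time and position interpolated linearly in
radius along the chord and the endpoint renormalised onto the stop sphere.
In addition, steps that start and end on the *same* side of a stop radius
are tested for an unresolved within-step excursion with the Brownian-bridge
probability `exp(−2 d_old d_new / σ²)` (d = signed distance to the
surface, σ² = 2D dt); accepted excursions absorb at mid-step. Without this
correction the endpoint-only detector systematically overestimates first
passage times — measured at ≈ +7% for the MFPT and a low-biased β at
dt = 0.01 ps on the benchmark geometry — an O(√dt) boundary bias; with it,
dt-halving tests show no statistically resolvable change and the pipeline
is unbiased against the closed forms.

Reproducibility: every trajectory has its own counter-based stream,
`Philox(SeedSequence([master_seed, traj_id]))`, consumed in fixed-size
blocks, so a trajectory's outcome is independent of batch composition and
execution order (asserted in the tests).

**FHPD sampling.** The first-hitting point distribution on a milestone is
sampled by launching trajectories from uniform points on the adjacent
*non-sink* milestones (a sink surface feeds no first hits: nothing returns
from it) and recording the first arrival point on the target; launches
absorbed elsewhere are discarded, and the collected hits are subsampled
uniformly so neither launch side is over-represented. For a central
potential the FHPD is uniform on the sphere by isotropy, which the tests
verify with a Kolmogorov–Smirnov test on direction cosines.

**Milestone trajectories.** From each non-sink milestone, trajectories
start at FHPD points and run to the first crossing of an adjacent
milestone (between concentric spheres the adjacent pair is the complete
stopping set). Censored trajectories (> 0.1% hitting the step cap) abort
the run rather than biasing the statistics.

## Uncertainty

Counts out of a milestone are multinomial, so kernel rows get conjugate
Dirichlet(N_ij + ½) draws over the observed (or declared) support, and the
mean incubation time gets a gamma draw with shape equal to the row count
and the observed mean preserved (relative spread 1/√count). Each posterior
sample is pushed through the full estimator; central 95% intervals are
reported for β, k_on, the MFPT and ΔG. Frequentist calibration is tested:
over 100 synthetic replicates from the exact committor chain at 100
transitions per milestone, the 95% β interval covers the true value in
≥ 90. A convergence table of running estimates over growing prefixes of the
event stream monitors sampling adequacy.

## Benchmark parameters

D = 1.33×10⁻⁵ cm²/s, T = 300 K, milestones 6–11 Å (1 Å spacing), bound
6 Å, b-surface 10 Å, escape 11 Å, dt = 0.01 ps. Charged variant: Q_c = −1e,
Q_s = +1e, ε_r = 92 (r_c ≈ −6.054 Å). Closed-form values: uncharged
β = 0.120, k_on = 6.039×10⁹ M⁻¹s⁻¹, MFPT = 13.53 ps; charged β = 0.1456,
k_on = 9.590×10⁹ M⁻¹s⁻¹, MFPT = 13.96 ps.

## Limitations

* Single spherical ligand in an implicit solvent; no hydrodynamic
  interactions, no rotation, no flexible receptor.
* Potentials are radial; the milestoning estimator itself is generic, but
  the simulator and closed forms assume central symmetry.
* The Coulomb interaction is unscreened (no ionic strength/Debye–Hückel
  screening).
* The steady-state MFPT (N/J) is the mean over the stationary injection
  ensemble; for strongly attractive systems at coarse milestone spacing the
  milestoning MFPT carries the usual semi-Markov approximation error, kept
  below the Monte-Carlo noise here by the 1 Å spacing.
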