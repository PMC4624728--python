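# spherokin

Association kinetics of a diffusing ligand around a spherical receptor,
estimated by **milestoning** on concentric spherical surfaces.

A point ligand diffuses in a central potential (none, or a screened
Coulomb attraction/repulsion) around a receptor whose reaction surface is
an absorbing sphere. The package answers three questions about that
system, both in closed form and from simulated trajectory statistics:

* **β** — the probability that a ligand starting on the *b*-surface
  (where bimolecular flux is delivered) reaches the reaction surface
  before escaping to bulk;
* **k_on** — the bimolecular association rate, composed from the
  diffusion-limited arrival rate at the *b*-surface and β;
* **MFPT** — the mean first passage time from the *b*-surface to
  absorption (binding or escape), plus the stationary probability and
  free-energy profile across the milestones.

Because every closed form is available for the spherical system, the
stochastic machinery (Brownian-dynamics simulator → first-hitting-point
distributions → milestone-crossing statistics → transition-kernel
estimator → posterior uncertainty) can be validated end to end against
exact answers. That is the point of the package: a fully checkable
milestoning stack on a geometry where nothing has to be taken on faith.

## Worked example

The benchmark system: a ligand with D = 1.33×10⁻⁵ cm²/s (sodium-like),
milestones at 6, 7, 8, 9, 10, 11 Å, reaction (bound) surface at 6 Å,
*b*-surface at 10 Å, escape at 11 Å, T = 300 K. The charged variant adds
a +1e ligand attracted by a −1e central charge in a dielectric of 92.

Closed forms, directly from the API:

```python
>>> import spherokin as sk
>>> unch = sk.uncharged_reference()        # D = 1.33e-5 cm^2/s, T = 300 K
>>> sk.splitting_probability(6, 10, 11, unch)   # beta
0.12000000000000006
>>> sk.kon_two_regime(sk.k_free(10, unch), sk.k_free(11, unch), 0.12)
6038980161.898242                               # == k_free(6, unch), M^-1 s^-1
>>> sk.mfpt_theory(6, 10, 11, unch)             # ps
13.533834586466167

>>> chg = sk.charged_reference()           # +1/-1 e, eps_r = 92
>>> sk.splitting_probability(6, 10, 11, chg)
0.1455739841899827
>>> sk.k_coulomb(6, chg)                        # M^-1 s^-1
9589847588.258366
>>> sk.mfpt_theory(6, 10, 11, chg)              # ps
13.955465184676267
```

The same numbers through the simulation pipeline, from the command line:

```sh
cat > config.yaml <<'YAML'
physics:    {kind: coulomb, Q_c: -1.0, Q_s: 1.0, eps_r: 92.0, T: 300.0, D_cm2_s: 1.33e-5}
geometry:   {radii: [6, 7, 8, 9, 10, 11], bound: [6.0], escape: 11.0, b_radius: 10.0}
simulation: {dt: 0.01, n: 1000, seed: 42}
YAML

spherokin theory   --config config.yaml                  # closed forms
spherokin run      --config config.yaml --out events.tsv # BD -> crossing events
spherokin estimate --config config.yaml --events events.tsv --out results.json
spherokin uncertainty --config config.yaml --events events.tsv \
    --out unc.json --convergence-out conv.tsv
```

`run` samples ≥ n first-hitting points on each non-sink milestone, launches
n milestone-to-milestone trajectories from them, and writes a TSV of
crossing events (`traj_id  src_milestone  dst_milestone  transit_time_ps`).
`estimate` fits the transition kernel, reports β, k_on, the MFPT and the
free-energy profile, and attaches 95% posterior intervals; the JSON carries
a provenance block (config hash, seed, pinned constants). `fixture` writes
small bundled demo datasets (`uncharged_sphere`, `charged_sphere`,
`two_site_toy`).

## Layout

| module | contents |
| --- | --- |
| `spherokin.smoluchowski` | closed-form and quadrature rates, committors, steady-state MFPT |
| `spherokin.milestoning` | kernel estimation, stationary flux, MFPT, β, k_on, ΔG |
| `spherokin.bd` | overdamped Brownian simulator, FHPD sampling, event harvesting |
| `spherokin.uncertainty` | Dirichlet/gamma posterior sampling, intervals, convergence |
| `spherokin.io` / `spherokin.cli` | config, event TSV, results JSON, `spherokin` CLI |
| `spherokin.network` / `spherokin.physics` | milestone geometry, central potentials, constants |

See `docs/methods.md` for the model, estimators and numerical choices.
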