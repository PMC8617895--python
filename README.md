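# pullfold

Kinetics of mechanical protein (un)folding from single-molecule pulling
experiments: rupture-force survival analysis, Bell–Evans fits of
force-dependent rates, worm-like-chain elasticity, and force-dependent
transition-state mapping in amino-acid units.

## The problem

In optical-tweezers pulling experiments a protein tethered between two beads
is loaded at a constant rate r (pN/s) until it unfolds, then relaxed until it
refolds. Kinetically stable proteins such as the 110-residue barnase show
strong hysteresis: unfolding ruptures cluster at 16–23 pN while refolding
happens below 5 pN, so equilibrium hopping is unobservable and the rates must
be extracted from the statistics of first-rupture forces:

    P_N(f) = 1 − ∫ ρ→(f′) df′          k→(f) = r ρ→(f) / P_N(f)
    P_U(f) = 1 − ∫_f ρ←(f′) df′        k←(f) = r ρ←(f) / P_U(f)

The Bell–Evans (BE) model, k→(f) = k0→ exp(βf x†) and
k←(f) = k0← exp(−βf x*), turns the log-rate slopes into the distances x†
and x* from the barrier (transition state, TS) to the native and unfolded
wells. For barnase the fitted sum x† + x* ≈ 11 nm falls far short of the
~21 nm released extension predicted at the coexistence force by the
inextensible worm-like chain (WLC, persistence length 0.8 nm, 0.37 nm per
residue) minus the freely-jointed-chain (FJC) extension of the 3 nm folded
core. `pullfold` implements the resolution of this discrepancy: converting
x† into unzipped residues naa†(f) with the WLC at each force shows the TS
moving toward the native state as force rises (the Leffler–Hammond shift),
while naa*(f) = N − naa†(f) maps back to a strongly force-dependent x*(f)
and a monotonically decreasing mechanical fragility
μ(f) = (x† − x*)/(x† + x*).

Because the original recordings are not deposited, a first-class synthetic
module generates the study conditions — 6 pN/s ramps between ~1 and 30 pN,
1 kHz sampling, 0.2 pN Gaussian force noise, BE hazards sampled exactly in
the force domain — with ground-truth sidecars, so the whole chain
(trace → event detection → rates → BE fit → TS map) is testable end to end.

## Worked example

```sh
pullfold run-all --out demo --seed 7 --n-cycles 150
```

simulates 150 pulling cycles (300 traces) of a barnase-like molecule
(x† = 3 nm, x* = 8 nm), detects every rupture, extracts the rates and prints

```
x_dagger=2.83 nm  x_star=8.08 nm  fc=8.00 pN  x_m_exp=10.91 nm  x_m_th(fc)=20.03 nm
```

i.e. the fitted barrier distances recover the generating values, and the
apparent molecular extension from the BE fit (x_m_exp ≈ 10.9 nm) sits far
below the elastic-theory released extension at the fitted coexistence force
(≈ 20 nm) — the central observation the TS-mapping step then explains. The
output directory contains the rupture table, density/survival/rate tables
per branch, the BE fit, the TS profile (naa†, naa*, x*(f), μ(f) on a
2–25 pN grid) and the moving-TS folding-rate prediction, every file stamped
with a configuration digest.

The same stages are available individually (`simulate`, `detect`, `rates`,
`fit-be`, `map-ts`) and as Python functions; see `docs/methods.md` for the
model details and numerical choices.

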