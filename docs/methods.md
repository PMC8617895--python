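# Methods

## Models

**Thermal scale.** All energies are in pN·nm with kB = 0.0138065 pN·nm/K;
the default temperature is 298 K (kBT ≈ 4.114 pN·nm, β ≈ 0.243 (pN·nm)⁻¹).
Forces are pN, lengths nm throughout.

**Worm-like chain (WLC).** The unfolded polypeptide follows the
inextensible-WLC interpolation formula
f(z) = (kBT/4Lp)[(1−z)⁻² + 4z − 1], z = X/L, with persistence length
Lp = 0.8 nm and contour length L = N·d_aa (N = 110 residues,
d_aa = 0.37 nm for barnase). The inverse (extension at given force) is
computed by bisection on z ∈ [0, 1−10⁻¹²] to absolute tolerance 10⁻¹²;
the algebraic rearrangement is a cubic with spurious roots outside (0,1),
and bisection on the monotone physical branch converges unconditionally.
Forward/inverse round trips agree to better than 10⁻⁸ relative over
0.1–50 pN.

**FJC dipole.** The folded core under tension is a single orientable
segment of length d0 = 3 nm (the N–C termini distance); its mean extension
is d0·[coth(βfd0) − 1/(βfd0)]. Below βfd0 < 10⁻⁴ the Langevin function is
evaluated by its series b/3 − b³/45 to avoid catastrophic cancellation, so
the zero-force limit is exactly 0. The theoretical released extension is
x_m,th(f) = X(f) − x_d(f).

**Monomer conversions.** Distances along the extension coordinate convert
to residue counts as n = x/(z(f)·d_aa). Counts are real-valued by design;
rounding belongs at the reporting stage. An optional convention adds the
FJC dipole extension to the native-side distance before converting
(`dipole_length=` / `include_dipole=`). It is off by default: with
x† = 3 nm at 3 pN the plain conversion gives ≈26 residues and the dipole
convention ≈41, bracketing published-style values near 37, and the package
deliberately reports its own derivation rather than forcing agreement —
per-molecule barrier distances, not the averaged 3 nm, may underlie such
numbers. Both conventions are exposed so users can compare side by side.

**Bell–Evans kinetics.** k→(f) = exp(log k0→ + βf x†),
k←(f) = exp(log k0← − βf x*). The attempt rate and the barrier heights
enter only through the two zero-force log-prefactors; these are the only
combinations a straight-line fit to log-rates can identify, so the package
stores and fits exactly those and never reports an attempt rate or barrier
height separately. The coexistence force is the closed form
fc = (log k0← − log k0→)/(β(x† + x*)). All rate evaluation is in log space
and cannot overflow over 0–50 pN.

**Moving-TS folding-rate prediction.** When x*(f) varies, the default
prediction integrates the local slope,
ln k←(f) = ln k(f_a) − β∫_{f_a}^{f} x*(f′) df′ (trapezoid on the profile
grid), which is thermodynamically consistent with dB/df = x*(f) and reduces
exactly to the straight BE line for constant x*. Direct substitution
ln k← = ln k(f_a) − β(f·x*(f) − f_a·x*(f_a)) is available behind
`integral=False`; with an increasing x*(f) both are concave in ln k vs f.

## Rate extraction

First-rupture forces are binned at 0.5 pN by default (resolving both the
16–23 pN unfolding range and the 2–5 pN folding range). Survival curves
are exact cumulative integrals of the histogram density, evaluated on bin
edges; the hazard is k = r·ρ/P with the survival taken at bin midpoints
(the edge average, exact for a histogram). Bins with midpoint survival
below 0.05 or fewer than 5 events are dropped rather than set to zero —
the ratio blows up on noise where survival is tiny. Standard errors of
ln k come from a 200-resample multinomial bootstrap over events, seeded
from the configuration. Fits of ln k vs f are weighted least squares with
inverse-variance weights (unweighted when errors are absent); when several
molecules are present, branches are fitted per molecule and averaged with
the standard error of the mean across molecules.

Folding events below 2 pN are recorded as censored and excluded from
densities: such events are detectable but not exhaustively so, and keeping
a biased subsample would distort the density. Window normalisation of the
density cancels between ρ and P in the hazard ratio, so truncating the
observation window does not bias k(f) where survival is well resolved.

Known bias: averaging an exponentially varying density over a 0.5 pN bin
shifts the fold-branch slope slightly (βx*·Δf/2 ≈ 0.5), giving a few
percent downward bias on x* at the default binning; it stays within the
10% recovery bound of the tests and shrinks with the bin width.

## Event detection

Traces are median-filtered (default window 11 samples ≈ 11 ms at 1 kHz;
edges use a symmetrically shrinking window so monotone data is a fixed
point). The folded baseline f = k_eff·λ is fitted through the origin
(intercept optional) on the lowest 20% of the λ range of unfolding traces;
folding traces share the baseline of their cycle's unfolding trace, since
the stiffness belongs to the construct and the low-λ region of a folding
trace is contaminated by the unfolded branch. The residual off the
baseline is classified by a two-component Gaussian model with equal
priors: native at 0, unfolded at the expected force jump
k_eff·x_m,th(f) at the local force (first-order in the trap response;
≈0.5 pN near 3 pN with k_eff = 0.05 pN/nm), common sigma from the robust
(MAD) baseline scale. A state change is committed only after 5 consecutive
maximum-posterior samples of the new state whose mean posterior exceeds
0.9: median filtering correlates neighbouring samples, so a marginal noise
excursion can hold a wrong label for several samples, but only a genuine
branch change carries saturated posteriors. Below the 2 pN cutoff the two
branches are separated by less than about twice the filtered noise and
cannot be resolved reliably; folding events found there are returned as
censored, and apparent unfolding transitions there are skipped.

## Synthetic data

The generator emulates the study conditions: constant 6 pN/s loading
between 1 and 30 pN, 1 kHz sampling, trap-plus-construct stiffness
0.05 pN/nm, Gaussian force noise of 0.2 pN (an instrument-like default).
Rupture forces are sampled exactly in the force domain by inverse
transform of the closed-form ramp survival function — the ramp is
deterministic, so no time-stepping is needed; a quadrature-based
time-domain sampler serves as an independent cross-check in the tests.
Full force–distance curves put the folded branch on f = k_eff·λ and offset
the unfolded branch by the local first-order force jump k_eff·x_m,th(f);
a self-consistent trap+WLC force balance is out of scope, as the
first-order geometry is sufficient for testing detection. Hopping traces
are two-level telegraph signals with exponential dwells.

The barnase-like kinetic defaults are x† = 3 nm and x* = 8 nm with
log-prefactors ln k0→ = −12.7427 and ln k0← = 9.2622, chosen once to put
the modal unfolding force near 19.5 pN (inside the observed 16–23 pN
range) and the modal folding force near 3.5 pN (below 5 pN) at 6 pN/s;
the implied coexistence force is ≈8.2 pN. Zero-force prefactors are not
published for barnase, so these are package choices constrained by the
observed force ranges, not measured values.

What the generator does not emulate: bead–handle Langevin dynamics,
instrument drift and calibration error, intermediate states, and the
force-dependence of the noise spectrum. Passing closure tests therefore
demonstrates the correctness of the analysis chain under the stated model,
not robustness to every artefact of real recordings.

## Problem sizes and determinism

The test suite recovers the barrier distances from 2000 rupture forces per
branch over 20 seeds (bias under 10%), runs trace-level closure on 400
simulated cycles, and checks detection on 160 noisy cycles per run over
20 seeds — sizes chosen to exercise the statistics at a few seconds per
test. All randomness flows from numpy Generators seeded per stage via
`SeedSequence`; identical configuration and seed reproduce every output
byte for byte, and each output table carries a short digest of the
scientific configuration.

## Limitations

* Two-state molecules only; no intermediates, no multi-barrier landscapes.
* The Bell–Evans fits assume log-linear branches inside each fitting
  window; the moving-TS analysis holds x† constant, which is itself an
  approximation the data only supports to first order.
* Dudko–Hummer–Szabo-style γ-family fits are out of scope.
* Elastic parameters for nucleic-acid hairpins are user-supplied; only the
  monomer count of the reference 44-nt hairpin is bundled.
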