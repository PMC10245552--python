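# Methods

`pmcerr` studies how the uncertainty of perturbation Monte Carlo (pMC)
estimates of spatially resolved diffuse reflectance grows with the size of an
optical-property perturbation, and how well that growth can be predicted
*a priori* from the reference simulation alone.

## Transport model

Photons random-walk through a homogeneous semi-infinite medium occupying
`z > 0`, launched at the origin along +z with unit weight from a collimated
point source. The medium is characterized by the absorption coefficient
`mua`, scattering coefficient `mus` (per mm), Henyey–Greenstein anisotropy
`g` and refractive index `n`. The canonical study media are parameterized by
the reduced-scattering-to-absorption ratio `musp/mua` in {5, 10, 20, 50, 100}
at a fixed transport mean free path `lstar = 1 mm`, `g = 0.8`, `n = 1.4`.

**Continuous absorption weighting (CAW).** Inter-collision distances are
sampled from an exponential with rate `mus`; collisions are pure scattering
events and absorption enters only through the continuous attenuation
`exp(-mua * L)` of the photon weight along its accumulated path `L`. The
sampling density times the weight then equals the physical scattering kernel
`mus * exp(-mut * s)` exactly, which has two consequences exploited
throughout the package: absorption perturbations are reweighted exactly for
any perturbation size, and the detected weight is a deterministic function
of the trajectory, `W = exp(-mua * L) * p**(-n_rr)`, so `ln W` and `L` are
perfectly anticorrelated in runs without Russian Roulette.

**Boundary.** The canonical configuration uses an index-matched boundary:
every photon exits, and is tallied, at its first surface crossing. This is
the convention that reproduces both the published proximal/distal detected
counts for this geometry and the exact `corr(ln W, L) = -1.000` diagnostic;
an air–tissue boundary with probabilistic unpolarized Fresnel reflection
(full exit or full internal reflection, never weight splitting) is available
through `SimulationConfig.n_outside` for mismatched studies, and reduces the
proximal count by roughly half at `n = 1.4`.

**Detectors.** Annuli on `z = 0` with half-open membership
`[rho_min, rho_max)`, evaluated at the exit point: proximal `[0, 0.2) mm`
and distal `[3, 3.2) mm` by default.

**Russian Roulette (RR).** After each collision the weight
(`exp(-mua*L) * p**(-n_rr)`) is compared against the threshold `w_thr`
(default 1e-3); below it the photon survives with probability `p`
(default 0.1), its weight amplified by `1/p`, or terminates. The game is
unbiased; its purpose here is to truncate the long, sparsely populated tails
of the weight, collision and path-length distributions.

**Termination guards.** A photon whose CAW weight underflows double
precision (`mua * L > 745`) can never contribute to any tally at double
precision and is terminated; without this guard, runs without RR in weakly
absorbing media spend unbounded time on recurrent deep trajectories (the
first-passage time of the photon's depth coordinate has infinite mean). A
collision-count cap (default 1e6) guards against pathological trajectories.
Both terminations are counted in the database diagnostics.

**Randomness.** One SplitMix64 stream per photon, seeded by mixing the run
seed with the photon index: databases are bit-reproducible and independent
of execution order. The azimuthal scattering angle is sampled trig-free by
rejection from the unit disk; the polar deflection uses the
Henyey–Greenstein inverse CDF.

## pMC reweighting (the rigorous route)

For a global change `mus -> mus*(1+eps_s)`, `mua -> mua*(1+eps_a)`, each
tallied photon's weight is reweighted as

    W_P = W_R * (mus_P/mus_R)**j * exp(-(mut_P - mut_R) * L),

evaluated in log space (`ln W_P = ln W_R + j*a - b*L`, `a = ln(1+eps_s)`,
`b = mut_P - mut_R`) to avoid overflow at large collision counts. Untallied
photons carry zero weight for the detector, so the full-population mean and
variance over all `N` launched photons follow from the tallied records and
the counts `N_T`, `N_U` alone:

    var_WP = (1/N) * [ N_T*(var_WPT + phi_bar**2) + N_U*w_bar_P**2 ],

with `phi_bar = w_bar_P - w_bar_PT`. The implementation always computes this
decomposition *and* the direct population sum and asserts their agreement to
1e-12 relative — a permanent consistency check on the untallied bookkeeping.
All variances are population-normalized (1/N, no Bessel correction), which
makes the decomposition identity exact and is immaterial at the photon
counts used. The degradation degree

    dbar_P = (sigma_WP / w_bar_P) / (sigma_WR / w_bar_R)

reports the growth of the relative error with perturbation size; it is 1 at
`eps = 0` by construction.

## A-priori error estimation (the proposed route)

The moment pipeline predicts the pMC uncertainty for any perturbation from
the reference database alone:

1. **Moments.** Per detector, population means, variances, skewnesses and
   pairwise covariances of `{ln W_R, j, L}` over the tallied records,
   computed by two-pass accumulation (means first, then central moments) to
   avoid catastrophic cancellation on heavy-tailed samples.
2. **Propagation.** `var(ln W_P)` through the generic nine-term propagation
   template: first-order variance terms, covariance cross terms, and
   third-order skewness terms with second derivatives. The derivatives are
   supplied per transform so nonlinear transforms remain expressible; for
   the log-linear reweighting transform the second derivatives vanish, so
   the skewness terms contribute exactly zero and the propagated
   log-variance is *exact* (asserted against the directly computed variance
   of `ln W_P` to 1e-10 relative in the tests). This cancellation is easy to
   miss: the skewness machinery matters only for transforms with curvature.
3. **Back-transformation.** `var(W_PT) ~= w_bar_RT**2 * var(ln W_PT)`, the
   first-order delta method, with the tallied *reference* mean substituted
   for the unknown perturbed mean.
4. **Assembly.** The tallied/untallied decomposition above with the
   reference means substituted throughout; its square root is
   `sigma_WP_est`.

The quality metric is `delta = (sigma_est - sigma_true)/sigma_true` against
the rigorous reweighting result.

### Known limitation: the delta-method step

Steps 1–2 and 4 are exact or near-exact; the error of the pipeline is
concentrated in step 3, whose accuracy requires `var(ln W_T) << 1`. With RR
references in this geometry, `var(ln W_T)` is ~0.13 at the proximal detector
but ~1.8 at the distal one, where the left-skewed `ln W` distribution makes
`w_bar**2 * var(ln W)` overestimate the true tallied variance several-fold.
The consequence, computed honestly by this package: `delta` is conservative
(positive) nearly everywhere, ~+5% at the proximal detector at zero
perturbation and rising to ~+33% (musp/mua = 5) to ~+55% (musp/mua = 100)
at `eps_s = -15%`, and ~+40% at the distal detector even at zero
perturbation. RR improves matters dramatically
relative to no-RR references (where distal `delta` exceeds +300%), because
RR compresses `var(ln W)` by an order of magnitude — but it does not make
the distal delta-method step accurate. Published accuracy figures for this
pipeline that are substantially tighter could not be reproduced from the
printed equations despite the reference simulations matching the published
moment diagnostics to ~1%; the sweep tables report what the equations give.

## Study design, problem sizes and jackknife margins

`run_study` reproduces the canonical design: five media x two detectors x a
scattering-perturbation grid (default [-20%, +20%] in 5% steps) x RR on/off,
with one simulation per medium and RR setting, emitting sweep tables, moment
tables (normalized variance `sigma**2/mean**2`, correlation, skewness — the
scale-free diagnostics) and fixed-bin histogram summaries (log-spaced bins
for `W`, linear for `j` and `L`; counts only).

Default problem size is 2e6 photons per simulation — a tenfold scale-down
from the full-scale 2e7-photon runs the study design targets — chosen so the
whole suite executes on one CPU core in minutes. Detected-photon fractions
(~3.4% proximal at `musp/mua = 5`) leave tallied samples of ~7e4 photons per
detector, ample for the moment diagnostics. Stochastic assertions carry
explicit margins: binomial standard errors for detected counts, and
3 delete-one-block jackknife standard errors (20 photon-index blocks; a
deleted block removes its launched photons from both the records and the
total count) for `delta` and `dbar_P`. The RR-impact moment comparison runs
all five media at 2e5 photons per RR setting — the compared reductions are
order-of-magnitude effects, far larger than the estimator noise at that
size.

## What the generator does and does not emulate

The simulator *is* the study's data source, so the synthetic conditions are
the study conditions: homogeneous semi-infinite medium, collimated point
source, index-matched surface, global perturbations. It does not model
layered or heterogeneous tissue, time-resolved detection, polarization,
external specular reflection at launch (a constant factor that cancels in
every relative metric used), or sub-domain perturbations — the package's
conclusions about estimator accuracy therefore speak to the worst case of
whole-medium perturbations, and transfer to voxel-restricted perturbations
only qualitatively (those reweight fewer collisions and degrade more
slowly).

## Numerical choices

- Lengths in mm, coefficients per mm; derived optical quantities are always
  computed from `(mua, mus, g, n)`, never stored, so invariants cannot
  drift.
- Record validation on read enforces `W > 0`, `j >= 1`, `L > 0` and the
  CAW/RR identity `|ln W + mua*L - n_rr*ln(1/p)| < 1e-9`.
- CSV interchange writes shortest-round-trip doubles at 17 significant
  digits and reads with round-trip float parsing; write-read is bit-exact.
- Annulus membership is half-open; ties at `rho_max` fall outside.
- `perturb_weight` raises on non-finite results rather than propagating
  infinities into population statistics.
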