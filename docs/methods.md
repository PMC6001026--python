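# Methods

## Model

Two genes X and Y with expression levels `x = (X, Y)` evolve under
Hill-type synthesis, mutual repression, morphogen activation and
first-order degradation. Four circuit variants are implemented
(`boundsharp.models`):

* **MRSA** — both genes self-activate (`x^n/(S^n + x^n)`), repress each
  other through the factor `1 − R + R·S^n/(S^n + y^n)`, and receive the
  morphogen input `a1·M^n/(S^n + M^n)`. Gene X's basal synthesis is
  reduced by the asymmetry ratio A (`b/A` vs `b`), so gene Y is favoured.
* **SA** — only Y self-activates; X keeps the repressive input from Y
  but has constant basal synthesis (`b1`, `b2`). The Y equation carries
  a self-activation gain `k_selfact` (default 1), the quantity swept in
  the switching-time analysis of this variant.
* **MR** — a morphogen-driven toggle switch (no self-activation).
* **MRSA_CROSS** — the MRSA circuit with two opposed gradients, M1
  acting on X and M2 on Y.

Stochastic dynamics: `dx = F(x) dt + d·x·dW` (Euler–Maruyama,
independent Wiener increments per cell and gene, states clamped at 0).
`d` is the gene-expression noise amplitude (a coefficient of
variation). Each cell additionally reads its column's morphogen level
through a multiplicative readout fluctuation `max(0, 1 + eps_m·ξ)`
redrawn once per unit time — morphogen noise is treated as an
uncorrelated per-cell readout error rather than a column-shared field
fluctuation. This choice is deliberate: with a column-shared
realization all cells of a column commit and switch coherently, so no
within-column mixing (and hence no boundary roughness) can arise at
`d = 0`, contrary to the phenomenology the model is meant to produce.
The ratio `L = eps_m/d` is the morphogen-to-gene noise amplitude ratio
used in the noise-plane scans.

Cells are independent given the morphogen: no movement, division,
adhesion or intercellular coupling. The tissue is an
`n_rows × n_columns` grid; the morphogen varies only along the column
axis and increases to the right, so the Y-dominated domain forms on
the right.

## Parameters and calibration

Published constants are pinned: MRSA `k_deg = 0.7, b = 0.7, R = 0.6,
A = 1.4`; MR `R = 1, k_deg = 1, b = 1`. The remaining constants
(`a, a1, S, n, b1, b2`) are not published and were calibrated by the
seeded grid scans in `scripts/calibrate.py` against two targets:

1. **Regime sequence.** At the reference morphogen levels
   (MRSA 0.5/0.8/1.2, SA 0.4/0.6/1.2, MR 0.2/0.4/0.8, cross
   (1,0.38)/(0.61,0.61)/(0.38,1)) the fixed-point structure must read
   *bistable → asymmetric bistable → monostable-Y* (for the cross
   variant: X-biased bistable → near-balanced → monostable-Y).
2. **Noise window (MRSA).** On the default tissue the terminal mean
   sharpening index must be lower at `d = 0.01` than at `d = 0` and
   `d = 0.02`, with the initial condition robustly inside the X basin
   over the bistable range.

The shipped sets (`src/boundsharp/data/circuits.toml`):

| variant | a | a1 | S | n | other |
|---|---|---|---|---|---|
| MRSA | 0.95 | 0.0475 | 0.76 | 4 | b=0.7, A=1.4, R=0.6, k=0.7 |
| SA | 1.0 | 0.2 | 0.9 | 4 | b1=0.6, b2=0.2, R=0.6, k=0.7 |
| MR | 1.0 | 0.3 | 0.5 | 4 | b=1, A=1.4, R=1, k=1 |
| MRSA_CROSS | 1.0 | 0.25 | 0.95 | 4 | b=0.7, A=1.1, R=0.6, k=0.7 |

Notes on the open choices:

* Hill coefficient `n = 4` throughout (standard for bistable toggle
  models); exposed in the config and never perturbed.
* The cross variant uses `A = 1.1`: near-symmetry makes the centre
  position balanced while keeping the high-M2 end monostable-Y.
* The MRSA morphogen coupling is weak (`a1 = 0.0475`). This is what
  places the saddle-node fold of the X state inside the gradient with
  a shallow X basin over the transition zone — the requirement for the
  noise window — but it also makes the fold position sensitive to
  parameter perturbation. A strongly coupled MRSA is robust to
  perturbation but loses the window; with the pinned published
  constants the two cannot be had simultaneously, and the window was
  given priority. The perturbation comparison across topologies should
  be read with this trade-off in mind.
* Initial conditions `(X0, Y0) = (0.5 + 0.05·N(0,1), 0.01)` (X_HIGH)
  or mirrored (Y_HIGH).
* Default morphogen profile: linear, 0 on the left to 1.5 on the
  right, so the bistable→monostable transition falls mid-domain.
  Cross-gradient profiles are opposed exponentials anchored at
  1.0/0.38 with centre value sqrt(0.38) ≈ 0.616.
* Default `eps_m = 0.12`, calibrated together with the circuit
  constants: large enough that readout fluctuations freeze a mixed
  zone near the fold at `d = 0`, small enough that `d = 0.01`
  completes the X→Y conversion there.
* Integration: `dt = 0.01`, save times {10, 50, 100, 200, 350, 500}.
  The SI trace peaks during the initial commitment transient
  (t ≲ 50) and then declines to a plateau; "terminal" quantities are
  read at t = 500, where the trace has flattened.

## Landscape computation

The probability density of the noisy circuit is evolved by the
Fokker–Planck equation with **constant, isotropic** diffusion D —
deliberately decoupled from the multiplicative SDE noise (the common
approximation in probabilistic-landscape work). The stationary
solution is computed by a Scharfetter–Gummel (exponentially fitted)
finite-volume discretization on a uniform grid (default 200×200 over
[0,3]²), reflecting boundaries, followed by a direct sparse
null-space solve (one balance row replaced by the normalization). The
scheme conserves probability at machine precision, yields a
non-negative stationary vector, and is exact for linear drift — the
Ornstein–Uhlenbeck benchmark reproduces the Gaussian stationary
density to ~1e-11 relative error.

`U = −ln(max(Pss, floor))` with `floor = 1e-12·max(Pss)`. Two numerical
limits matter:

* Well-to-well density contrasts beyond `e^27` hit the floor, and
  beyond ~`e^36` the linear solver's round-off; deeper wells are
  unresolvable in double precision. `D = 0.005` keeps every calibrated
  regime resolvable.
* At that D the mid-gradient X well is genuinely shallow (depth
  0.05–0.2 potential units). `find_attractors` therefore takes an
  explicit basin-depth (prominence) threshold; the conservative
  default 0.5 suits noisy or empirical landscapes, while regime
  analyses of the calibrated circuits use `min_depth = 0.01` (the
  solver is smooth, so no spurious minima appear).

Attractor prominence and saddle points are computed exactly on the
discrete landscape by activating cells in ascending U order with
union-find (8-connectivity); the cell whose activation first connects
two basins is their minimax saddle. Barrier heights are
`U(saddle) − U(attractor)` and are direction-dependent.

## Switching times

MFPTs are estimated from trajectories of the multiplicative-noise SDE:
each run starts at the X attractor and stops on entering a max-norm
ball (radius 0.1) around the Y attractor; runs not switching by
`t_max` are censored and excluded from the mean (censoring counts are
reported; sweep points are chosen so censoring is rare). Conditions
that lose bistability are flagged rather than estimated. The
estimator is validated against the Kramers closed form on the 1-D
quartic double well `U = (x²−1)²` with additive noise: at
`ΔU/D ≥ 5` simulated and analytic times agree within a factor of two.

Sweep design (6 points each, n_runs = 200, seeded substreams per
condition): noise `d ∈ [0.02, 0.16]` at M = 0.8; morphogen
`M ∈ [0.62, 0.82]` at d = 0.05; asymmetry `A ∈ [1.25, 1.50]` and
repression `R ∈ [0.60, 0.675]` at M = 0.75 (the R dependence is so
steep that a wider range censors entirely); SA self-activation gain
`∈ [1.05, 1.30]` at M = 0.6. The barrier–MFPT correspondence pairs the
X→Y barrier (D = 0.005, 150² grid) with the MFPT (d = 0.05) across the
bistable window.

## Synthetic data: what it does and does not emulate

The morphogen generator provides (a) a reaction–diffusion
extracellular/intracellular RA system (explicit Euler–Maruyama,
no-flux anterior boundary, Robin "leaky" posterior boundary,
multiplicative space-time noise) and (b) the parametric noisy-gradient
generator used by the headline simulations. The RA parameters
(production profile, exchange and degradation rates) are illustrative
defaults, not fits to embryo data; the degradation response `Cyp` is a
basal rate plus optional Hill term. Tissue results therefore
demonstrate circuit-level mechanisms on an idealized monotone
gradient; they say nothing about real RA kinetics, growth, cell
rearrangement, or 2-D morphogen transport.

## Problem sizes

Tests and the acceptance script use a 10×30 grid (20/15/12 seeds per
condition), t_end = 500, n_runs = 200 for MFPTs, and 150²–200²
landscape grids; headline-quality runs at 10×100 and 100 replicates
are a `SDEConfig`/CLI flag away. All randomness flows from explicit
seeds through `numpy.random.SeedSequence` spawning, so every table and
figure is bit-reproducible.

## Known limitations

* The constant-D landscape and the multiplicative-noise SDE are
  different noise models; barriers and MFPTs are compared as ranks,
  never as absolute Kramers predictions.
* The sharpening index counts **all** mixed columns (no boundary
  window); stray far-field cells and genuine boundary roughness are
  not distinguished.
* With the published constants pinned, MRSA cannot simultaneously
  maximize noise-window sharpening and perturbation robustness (see
  calibration notes); topology-robustness conclusions depend on the
  unpublished full parameter tables.
* Cross-gradient two-way switching is asymmetric under the default
  calibration: the Y→X (red→blue) conversion acts only near the
  left-hand end of the gradient, so the Y_HIGH boundary settles close
  to the left edge.
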