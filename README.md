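# boundsharp

Stochastic simulation and potential-landscape analysis of
morphogen-driven **gene-expression boundary sharpening**.

During tissue patterning, a smooth morphogen gradient must be read out
into sharply bounded gene-expression domains. `boundsharp` models this
with two-gene regulatory motifs — mutual repression with
self-activation (MRSA), self-activation only (SA), pure mutual
repression (MR), and MRSA driven by two opposed gradients — in which
genes X and Y are activated by a morphogen M through Hill kinetics,
e.g. for the MRSA circuit

```
dX/dt = a (b/A + X^n/(S^n+X^n)) (1 - R + R S^n/(S^n+Y^n)) + a1 M^n/(S^n+M^n) - k X
dY/dt = a (b   + Y^n/(S^n+Y^n)) (1 - R + R S^n/(S^n+X^n)) + a1 M^n/(S^n+M^n) - k Y
```

Each cell of a 2-D grid integrates this system as an SDE with
multiplicative gene-expression noise `d·x·dW` and a noisy per-cell
morphogen readout. The package then

* solves the stationary 2-D Fokker–Planck equation
  `0 = -∇·(F P) + D ∇²P` with reflecting boundaries (an exactly
  conservative Scharfetter–Gummel finite-volume scheme) and builds the
  probabilistic potential landscape `U = −ln Pss`;
* extracts attractors, saddles (exact discrete minimax via union-find)
  and barrier heights `ΔU = U(saddle) − U(attractor)`;
* estimates mean first passage times (MFPT) between attractors from
  SDE trajectories, benchmarked against the Kramers escape rate;
* quantifies boundary sharpness by the **sharpening index** (SI): the
  number of grid columns containing both X- and Y-state cells;
* compares circuit topologies under random parameter perturbation.

## Worked example

```python
import boundsharp as bs

params = bs.default_params("MRSA")          # calibrated constants
field = bs.parametric_gradient(bs.linear_profile(), 0.0, 30, 1, seed=0)

for d in (0.0, 0.01, 0.02):                  # gene-expression noise
    si = [bs.si_trace(bs.simulate_tissue(
              params, field, (10, 30), bs.SDEConfig(d=d, seed=s))).terminal()
          for s in range(20)]
    print(f"d={d}: terminal SI = {sum(si)/len(si):.2f}")
```

prints

```
d=0.0: terminal SI = 1.95
d=0.01: terminal SI = 1.65
d=0.02: terminal SI = 2.35
```

— the noise window: without gene noise the boundary stays rough
(morphogen-readout fluctuations freeze a mixed zone near the fold),
at `d = 0.01` noise-induced X→Y switching cleans it up, and at
`d = 0.02` over-switching roughens it again.

The landscape behind this behaviour:

```python
land = bs.solve_fokker_planck(params, 0.8, bs.FPConfig(D=0.005))
attrs = bs.find_attractors(land, min_depth=0.01)
xa = [a for a in attrs if a.x > a.y][0]
ya = [a for a in attrs if a.y > a.x][0]
print(bs.barrier(land, xa, ya).height)      # 0.081  (shallow X basin)
print(bs.barrier(land, ya, xa).height)      # 19.4   (deep Y basin)
```

A thin CLI mirrors the library:
`boundsharp tissue --model MRSA --d 0.01 --rows 10 --cols 30 --seed 7`.

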