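# earlydetect

Tumor–immune dynamics with awareness-driven early detection: simulation,
equilibrium and stability analysis, parameter sensitivity, bifurcation and
basin-of-attraction exploration, and parameter estimation from (synthetic)
tumor time series.

The package is aimed at mathematical-oncology modellers and public-health
analysts who want a tested, scriptable implementation of a planar
tumor–immune model in which screening programmes and public awareness enter
the tumor equation as a saturating removal term.

## The model

Tumor cells `C(t)` grow logistically, are killed by cytotoxic lymphocytes
`L(t)` at a saturating rate, and are removed by early detection at a
Michaelis–Menten rate in tumor size.  After rescaling both populations by
their carrying capacities (`x = C/a2`, `y = L/a6`) and time by the tumor
growth rate (`τ = a1 t`), the dimensionless system is

    dx/dτ = x(1 − x) − β x y/(γ + y) − κ x/(α + δ x)
    dy/dτ = ρ y(1 − y) x/(μ + x) − σ x y − η y

with immune kill rate β, kill half-saturation γ, maximum detection-driven
removal κ, baseline detection constant α, awareness–threshold product δ,
immune proliferation ρ, activation half-saturation μ, tumor-induced immune
death σ and immune apoptosis η.  The tumor-free state `(0, 0)` has Jacobian
eigenvalues `1 − κ/α` and `−η`, so detection eradicates the tumor locally
exactly when `κ > α`; interior (coexistence) equilibria solve
`y*(x) = 1 − (μ + x)(σx + η)/(ρx)` substituted into the tumor equilibrium
equation.  Normalized forward sensitivity indices
`S_p = (p/x(T)) ∂x(T)/∂p` quantify which parameters move the tumor burden
most.  See `docs/methods.md` for assumptions, numerical choices and known
limitations (including model behaviours near the detection threshold that
simple narratives get wrong).

## Worked example

```python
from earlydetect import (NondimParams, simulate, cancer_free_report,
                         find_coexistence, sensitivity_forward, rank_parameters)

params = NondimParams(beta=0.5, gamma=0.1, kappa=3.0, delta=1.0, alpha=0.65,
                      rho=1.0, mu=0.1, sigma=0.3, eta=0.1)

traj = simulate(params, x0=0.35, y0=0.08)
print(f"terminal state at tau=50: x={traj.x[-1]:.3e}, y={traj.y[-1]:.3e}")

rep = cancer_free_report(params)
print(f"tumor-free eigenvalues: {rep.eigenvalues[0].real:.4f}, "
      f"{rep.eigenvalues[1].real:.4f}  (stable: {rep.locally_stable})")

weak = params.replace(kappa=0.1)
(eq,) = find_coexistence(weak)
print(f"kappa=0.1 coexistence state: x*={eq.location[0]:.4f}, y*={eq.location[1]:.4f} "
      f"(stable: {eq.locally_stable})")

sens = sensitivity_forward(params.replace(kappa=0.3), 0.35, 0.08, horizon=10.0)
print(rank_parameters(sens)[["parameter", "index", "sign", "rank"]].head(4).to_string(index=False))
```

prints

```
terminal state at tau=50: x=3.951e-56, y=7.955e-04
tumor-free eigenvalues: -3.6154, -0.1000  (stable: True)
kappa=0.1 coexistence state: x*=0.4729, y*=0.7070 (stable: True)
parameter     index  sign  rank
     beta -1.802777    -1     1
    kappa -1.352459    -1     2
    alpha  0.918589     1     3
    delta  0.433869     1     4
```

With the default strong detection (`κ = 3.0 > α = 0.65`) the tumor
collapses to numerical zero well before `τ = 50` while the immune level
relaxes at rate η.  Weak detection (`κ = 0.1`) leaves a stable coexistence
state at about 47% of the tumor carrying capacity.  On the
persistent-tumor benchmark (`κ = 0.3`), immune kill strength β and
detection strength κ carry the largest tumor-reducing elasticities, while
α and δ — which weaken the detection term from its denominator — carry
positive ones.

The same analyses are available from the shell:

```
earlydetect simulate --kappa-off --out no_detection.csv
earlydetect bifurcate --param kappa --grid 0.05,3.0,201 --out sweep.csv
earlydetect run-all --seed 1 --out-dir results/
```

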