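# metacoop

Metapopulation dynamics of microbial public-goods cooperation under daily
serial dilution on heterogeneous migration networks.

## The problem

Many populations live as networks of subpopulations linked by migration,
and migration on heterogeneous networks is naturally *asymmetric*: if every
node exports the same fraction of individuals split evenly among its
neighbours, net flow runs from poorly connected nodes toward hubs. This
package models a laboratory instance of that situation — budding-yeast
wells growing on sucrose, connected by daily pipetted migration — in which
one strain produces a public good (secreted invertase activity) and a
second strain free-rides on it. It is intended for researchers studying
cooperation, tipping points, and the stability/resilience of spatially
structured populations who want a tested, scriptable implementation of the
whole pipeline: growth model, dispersal operator, cycle simulation,
bifurcation/resilience analysis, and noisy synthetic observations.

## The model

Within a well, producer and non-producer densities `Np`, `Nnp` (cells/µL)
grow for `t_grow` hours per cycle according to

    dNnp/dt = r · Nnp · (1 − (Np+Nnp)/K) · Np / (Np + k_M)
    dNp/dt  = r(1−c) · Np · (1 − (Np+Nnp)/K) · (Np + ε) / (Np + ε + k_M)

(logistic crowding toward a shared carrying capacity `K`; Monod dependence
on the public good, proportional to `Np`; production cost `c`; private
benefit `ε`). Each day every well is diluted `D`-fold, a fraction `m` of
cells migrates along the network (split evenly among neighbours, so the
dispersal matrix is column-stochastic and cell-conserving), and the wells
regrow. Defaults are the fitted yeast values: `r = 0.5 h⁻¹`, `K = 9×10⁴
cells/µL`, `c = 0.07`, `ε = 14`, `k_M = 26` cells/µL, `t_grow = 22 h`,
`D = 650`, `m = 0.6`.

The combination of frequency-dependent selection, density-dependent
selection and a public-good Allee effect yields three characteristic
results, all reproduced by the package: star networks enrich producers in
*every* node (sides through lower density, the centre through immigration);
star networks nonetheless collapse at *milder* dilution factors than
isolated wells (their side nodes are the weakest link); and star networks
recover from *larger* one-cycle shocks (their centre is the strongest
element and reseeds the sides).

## Worked example

```python
from metacoop import Protocol, isolated, star, steady_state

iso = steady_state(isolated(1), Protocol(D=650.0, m=0.0, n_cycles=1000))
net = steady_state(star(9),     Protocol(D=650.0, m=0.6, n_cycles=1000))

def frac(s):
    return s[:, 0].sum() / s.sum()

print(f"isolated equilibrium fraction: {frac(iso.states):.3f}")
print(f"star equilibrium fraction:     {frac(net.states):.3f}")
print(f"enrichment:                    {frac(net.states)/frac(iso.states):.2f}x")
print(f"centre fraction: {net.states[0,0]/net.states[0].sum():.3f}  "
      f"side fraction: {net.states[1,0]/net.states[1].sum():.3f}")
```

prints

```
isolated equilibrium fraction: 0.073
star equilibrium fraction:     0.160
enrichment:                    2.18x
centre fraction: 0.120  side fraction: 0.167
```

An isolated well settles at ~7% producers; wiring ten such wells into a
star with 60% migration per cycle more than doubles the network-wide
producer fraction, and *both* node roles end up above the isolated
equilibrium — the sides because asymmetric emigration keeps them sparse
(sparse wells favour producers), the centre because it is flooded with
producer-rich immigrants from the sides.

The same analyses are available from the shell, e.g.

```
metacoop simulate --topology star --n-side 9 --D 650 --m 0.6 --cycles 100 --out traj.csv
metacoop critical-d --topology star --n-side 9 --m 0.6
metacoop resilience --topology star --n-side 9 --D 750 --kind-shock dilution
metacoop synth --topology star --n-side 9 --seed 1 --out synthetic.csv
```

Every run writes a JSON manifest sufficient to repeat it bit-for-bit.

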