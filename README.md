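# hodgeflow

Helmholtz–Hodge decomposition of single-cell RNA-velocity fields.

RNA velocity assigns each cell a vector describing where its transcriptional
state is heading; projected into a 2D embedding (UMAP, t-SNE) these vectors
form a flow whose qualitative features — rotating cell-cycle loops,
source/sink regions, lineage through-flow, bifurcation saddles — are usually
read off a streamline plot by eye. `hodgeflow` makes that reading principled:
it splits the velocity field **v** on a bounded domain *M* into three
mutually orthogonal components

```
v = ∇f + J∇r + h
```

— a curl-free part ∇f (sources and sinks), a divergence-free part J∇r
(rotation; J is the 90° rotation), and a harmonic part **h** (curl- and
divergence-free; the boundary-to-boundary transport and any
topology-induced circulation). Both scalar potentials f and r vanish on
∂M, which is what makes the three parts L²-orthogonal and ties the harmonic
space's dimension to the first Betti number of the domain.

The pipeline:

1. **Domain extraction** — a kernel density ρ(x) = Σᵢ exp(−‖x−xᵢ‖²/η²)
   (flexibility-rigidity-index density, η = 1) is thresholded at a fraction
   of its minimum over the cells, carving a grid-face mask that contains the
   cloud; its Betti numbers (b0, b1) are computed.
2. **Field construction** — each grid vertex takes the Gaussian-weighted
   average velocity of its 50 nearest cells.
3. **Decomposition** — discrete exterior calculus on the masked grid:
   `d` as signed incidence (dd = 0 exactly), diagonal Hodge stars with
   boundary-clipped dual cells, and two sparse SPD Dirichlet solves for
   f and r; the harmonic part is the remainder.

Everything runs on synthetic or real inputs from plain csv
(`x,y,vx,vy[,label]`) or AnnData `.h5ad` (`obsm` keys).

## Worked example

```python
import hodgeflow as hf
from hodgeflow.synthetic import SyntheticScenario, synthetic_cells

# a noisy ring of 500 cells with tangential velocities (cell-cycle analogue)
cells = synthetic_cells(SyntheticScenario("ring_cells", {"n": 500}, seed=0))
res = hf.VelocityFieldModel(cells).fit()
print(res.summary())
```

```
      Helmholtz-Hodge Decomposition Results
====================================================
No. cells:                                       500
Grid (nx x ny vertices):                   101 x 101
Active faces:                                   1414
All cells contained:                            True
Betti numbers (b0, b1):                       (1, 1)
----------------------------------------------------
Energy fractions
  curl-free (exact):          0.000041
  divergence-free:            0.003474
  harmonic:                   0.996485
----------------------------------------------------
Orthogonality residuals (|<a,b>| / ||omega||^2)
  exact/coexact:             7.233e-22
  exact/harmonic:            2.553e-20
  coexact/harmonic:          1.389e-18
Solver residuals
  exact potential:           2.206e-14
  coexact potential:         2.192e-15
Harmonic saddles:                                  0
====================================================
```

Reading it: the extracted domain is an annulus (b1 = 1), so one independent
circulating harmonic mode exists — and indeed the tangential flow loads
almost entirely (99.6%) on the harmonic component, the discrete analogue of
ideal flow around an island. On a *filled* cloud (b1 = 0) the same rotation
would appear in the divergence-free part instead. The orthogonality
residuals at ~1e−18 confirm the three parts are numerically orthogonal.
`res.component_fields()` returns the three vertex vector fields,
`res.saddles("harmonic")` locates bifurcation saddles (Poincaré index −1),
and `res.plot_components()` draws the four streamline panels.

The same pipeline is scriptable:

```
hodgeflow synthesize ring_cells --n 500 --seed 0 -o ring.csv
hodgeflow decompose ring.csv -o out/ring          # fields + diagnostics
hodgeflow sweep ring.csv --parameter eta --values 0.5,1,2 -o out/sweep
```

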