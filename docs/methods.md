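# Methods

## The model

`hodgeflow` decomposes a two-dimensional cell-state velocity field — per-cell
velocity vectors attached to a low-dimensional embedding such as UMAP or
t-SNE — into three mutually orthogonal parts:

    v = ∇f + J∇r + h

where `f` is a scalar (curl) potential and `r` a stream potential, both
required to vanish on the boundary ∂M of the analysis domain, `J` rotates a
vector counterclockwise by π/2, and `h` is the harmonic remainder, which is
simultaneously curl-free and divergence-free. The three parts are the
vector-field counterparts of the Hodge–Morrey splitting of a 1-form on a
compact manifold with boundary,

    ω = dα_n + δβ_t + h,

with the normal (Dirichlet) condition on α and the tangential condition on
β. Those two boundary conditions are exactly what makes the splitting
orthogonal in the L² inner product: the boundary term of the
integration-by-parts identity ⟨dξ, ζ⟩ = ⟨ξ, δζ⟩ + ∮ ξ∧★ζ vanishes when ξ is
normal or ζ is tangential.

Biologically, the curl-free part captures source/sink behaviour
(proliferation origins, terminal fates), the divergence-free part captures
rotational motifs such as the cell cycle, and the harmonic part carries the
boundary-to-boundary through-flow — the overall lineage direction — plus any
circulation demanded by the topology of the domain. The dimension of the
space of tangential harmonic fields equals the first Betti number b1 of the
domain, so an annular cell cloud supports exactly one independent
circulating harmonic mode.

## Discretization

All operators are realized with discrete exterior calculus (DEC) on a masked
Cartesian grid:

* **Cells.** The domain is a union of closed grid squares (a cubical
  complex). Vertices carry 0-cochains, edges 1-cochains (x-edges oriented
  +x, y-edges +y), faces 2-cochains (counterclockwise). Index maps are
  row-major by (j, i), x-edges before y-edges — fully deterministic.
* **d** is the signed incidence matrix; `d1 @ d0 = 0` holds over the
  integers, so curl(grad) and div(rot) vanish exactly, not approximately.
* **★** is diagonal: dual measure / primal measure. With the default
  `dual_clip=True` the dual cells of boundary vertices/edges are intersected
  with the domain, giving half/quarter dual areas at straight/corner
  boundary — ★ stays strictly positive definite either way. A config switch
  turns clipping off for comparison.
* **δ** is assembled as `δ_k = ★_{k-1}^{-1} d_{k-1}^T ★_k`. The sign is fixed
  by requiring the discrete adjointness ⟨d f, g⟩ = ⟨f, δ g⟩ for
  interior-supported forms (with this convention δ on 1-forms is −div);
  the choice is validated by a property test, not assumed.
* **flat/sharp.** A vertex vector field becomes a 1-cochain by the
  trapezoidal edge integral ω(e) = ½(v(p)+v(q))·(q−p); the inverse averages
  incident edge values per axis. The round trip is exact on affine fields at
  interior vertices.

## The two potential solves

Applying δ and d to the splitting gives two Poisson problems:

* vertex system `(d0^T ★1 d0) α = d0^T ★1 ω` on interior vertices, α = 0 on
  boundary vertices;
* face system `(d1 ★1^{-1} d1^T) r = d1 ω` on interior faces, r = 0 on
  boundary faces (r = ★2 β is the stream scalar; in 2D the gauge condition
  dβ = 0 is vacuous for top-degree forms).

Both matrices are symmetric positive definite per connected component once
the Dirichlet rows are eliminated — strict boundary grounding sidesteps the
rank deficiency that otherwise requires cohomology-aware null-space
handling. Disconnected domains need no special code: the systems are block
diagonal and the sparse solves handle them transparently. The harmonic part
is obtained by subtraction, `h = ω − dα − δβ`; no extra projection is
applied, so any leakage shows up in the diagnostics rather than being
silently removed.

The default solver is a sparse direct factorization (`scipy spsolve`);
diagonally preconditioned conjugate gradient is available (`solver="cg"`,
tolerance 1e−10, at most 10·n iterations, raising with the residual on
non-convergence). Exact⊥coexact orthogonality is structural
((d1 d0)^T = 0 makes ⟨dα, δβ⟩ vanish identically); the other two pairs are
orthogonal up to the solver residual. Observed pairwise residuals are
~1e−17 of ‖ω‖² with the direct solver.

Solver residuals are measured on the interior equations (the Dirichlet rows
are constraints, not equations); likewise the harmonic component is closed
and coclosed on interior cells up to those residuals, while boundary cells
retain the discretization residue the boundary conditions impose.

## Domain extraction

The domain is the superlevel set of a kernel density built by superposing a
decaying correlation function at each cell point:

    ρ(x) = Σ_i Φ(‖x − x_i‖; η),  Φ(d; η) = exp(−(d/η)^κ),

with scale η = 1 embedding unit and κ = 2 by default (a generalized Lorentz
kernel is available as a stub). Contributions beyond 6η (< 1.6e−16) are
dropped by default via a KD-tree; exact summation is a config switch. The
grid is the tight bounding box of the points padded by 3η per side, square
cells, 100 faces along the longer axis by default — padding keeps the
superlevel set from being truncated by the box.

The isovalue is c = t · min_i ρ(x_i) with t = 0.9, which guarantees every
cell point lies strictly inside the continuous superlevel set. A grid face
is active iff all four corner vertices have ρ ≥ c (conservative; the
complex needs whole faces). **Resolution condition:** because the face test
samples at corners up to h/√2 away from a point, a point is only guaranteed
to land in an active face when the density drops by less than the fraction
(1 − t) across one cell, i.e. h·‖∇ρ‖/ρ < 1 − t locally. Near steep ridge
tips (e.g. the free ends of a branching cloud) the default 100-face grid
can violate this and a handful of points fall just outside; the pipeline
reports the count honestly (`all_contained`, `n_outside`) instead of
silently enlarging the domain. Doubling `grid_faces` (or lowering t)
restores containment.

## Velocity averaging

Each active vertex receives the Gaussian-weighted average of the velocities
of its k = 50 nearest cells, weights exp(−d²/2b²). The bandwidth default is
adaptive: the median distance from active vertices to their k-th nearest
cell, divided by 3 — large enough to avoid underflow at vertices far from
cells, small enough to stay local; it is exposed in the config. If all
weights underflow anyway, the unweighted k-mean is used and a warning
logged. Weights are normalized (a convex combination), so the averaged
field is bounded by the neighbouring velocities and invariant to duplicating
or reordering the cell set.

## Synthetic scenarios

The generators stand in for real droplet scRNA-seq embeddings; they
reproduce the geometric/flow structure the decomposition responds to, not
library-size noise, dropout, or embedding distortion, so green tests show
the machinery is correct, not that any particular biological dataset will
decompose cleanly.

* `gradient` / `rotation`: ∇f and J∇f for a Gaussian bump whose value and
  gradient are < 1e−12 on ∂M (σ = 0.17 × centre-to-boundary distance), giving
  pure curl-free / divergence-free references. Recovery at 64×64 is
  ≥ 0.9999 of the energy; the spurious remainder shrinks under refinement.
* `annulus_harmonic`: (−y, x)/(x²+y²) on an annular mask — the circulating
  harmonic generator; rejected on simply connected masks.
* `mixture`: unit-energy gradient and rotation parts combined with stated
  weights; expected energy fractions are the normalized squared weights.
* `ring_cells` (n = 500): a noisy circle of radius 5 (position jitter
  σ = 0.1, well inside the annularity bound of ~0.1 × radius) with unit
  tangential velocities — the cell-cycle motif. The extracted domain has
  b1 = 1 and the circulation loads almost entirely (> 0.99) on the harmonic
  component, as it must: with the stream potential grounded on both boundary
  circles, a one-signed circulation admits no stream function, and the
  harmonic fraction of a constant tangential speed on an annulus [r0, r1]
  is 2(r1−r0)/((r1+r0) ln(r1/r0)) → 1 for a thin band. On filled (b1 = 0)
  clouds the same rotation would appear in the divergence-free part.
* `branch_cells` (n = 500): an upward-flowing trunk splitting into two
  outward-and-downward arms. Above the junction the opposing vertical
  velocities of trunk and arms produce an interior stagnation point with
  negative Jacobian determinant; it survives in the harmonic through-flow
  and is detected as a face of Poincaré index −1 (winding of the corner
  vectors), excluding boundary-touching faces whose winding reflects the
  boundary condition.

All generators are bit-reproducible under their seed.

## Problem sizes and numerical choices

Unit tests run on 4–64 face grids; the orthogonality sweep uses five mask
shapes (disk, annulus, two components, two random staircase blobs) at
64×64 with 20 random fields; recovery checks use 64×64 with one 128×128
refinement point; the end-to-end pipelines use the default 100-face grid
with 500 cells. Dense least-squares oracles are limited to masks with
≤ 100 vertices. Degenerate inputs are well-defined: a zero field returns
zero components with zero energy fractions; a domain so small that every
vertex (or face) is boundary yields a zero potential for that solve; an
empty mask or an isovalue above the maximum density raises a specific
error. kNN ties break by cell index; all cell orderings are deterministic.

## Known limitations

* 2D only; 3D grids and the vector-potential form of the splitting are out
  of scope, as are simplicial meshes and curved-boundary cut cells.
* The harmonic space is never explicitly spanned (no eigen-basis of the
  1-form Laplacian); harmonic is defined by subtraction.
* The five-way refinement of the splitting (separating topological from
  boundary-driven harmonic content) is not implemented.
* The divergence-free component's tangential boundary condition produces
  artificial vortices in a band along ∂M; the diagnostics expose this as
  the coexact boundary-band energy fraction rather than correcting it.
* Velocities are consumed, never estimated: spliced/unspliced kinetics,
  embedding construction and velocity projection belong to upstream tools
  (velocyto, scVelo and kin).
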