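"""Model/Results interface over the full decomposition pipeline.

``VelocityFieldModel`` holds the per-cell data plus every tunable of the
pipeline; ``fit()`` extracts the FRI-density domain, averages velocities onto
the grid, and performs the orthogonal decomposition, returning a
``HodgeDecompositionResults`` with the component fields, energy fractions,
diagnostics and a ``summary()`` table.

    >>> model = VelocityFieldModel.from_dataframe(df)
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .decompose import (
    HarmonicReport,
    HodgeDecomposition,
    component_fields,
    decompose,
    harmonic_consistency,
)
from .density import DomainSpec, domain_complex
from .fields import (
    CellEmbedding,
    VectorFieldGrid,
    auto_bandwidth,
    find_saddles,
    flat,
    interpolate_velocity,
)
from .grid import DomainTopology, GridComplex, compute_topology

if TYPE_CHECKING:  # pragma: no cover
    from .io import RunConfig


class VelocityFieldModel:
    """Helmholtz–Hodge decomposition model for a 2D cell-velocity embedding.

    Parameters
    ----------
    cells : CellEmbedding
        Per-cell coordinates and velocities (2D embedding such as UMAP/t-SNE).
    eta : float
        FRI density kernel scale (embedding units, default 1.0).
    kernel, kappa : str, float
        Correlation function and exponent of the density kernel.
    containment_fraction : float
        Isovalue is this fraction of the minimum cell-point density.
    grid_faces : int
        Faces along the longer bounding-box axis (square cells).
    padding_multiplier : float
        Bounding-box padding in units of eta.
    k_neighbors : int
        Cells averaged per grid vertex (default 50).
    bandwidth : float or None
        Gaussian averaging bandwidth; None = adaptive (median k-th neighbour
        distance / 3).
    solver, tolerance : str, float
        'direct' (sparse factorization) or 'cg'; iterative tolerance.
    dual_clip : bool
        Clip dual cells to the domain when building Hodge stars.
    """

    def __init__(
        self,
        cells: CellEmbedding,
        *,
        eta: float = 1.0,
        kernel: str = "gaussian",
        kappa: float = 2.0,
        containment_fraction: float = 0.9,
        grid_faces: int = 100,
        padding_multiplier: float = 3.0,
        k_neighbors: int = 50,
        bandwidth: float | None = None,
        solver: str = "direct",
        tolerance: float = 1e-10,
        dual_clip: bool = True,
    ):
        self.cells = cells
        self.eta = eta
        self.kernel = kernel
        self.kappa = kappa
        self.containment_fraction = containment_fraction
        self.grid_faces = grid_faces
        self.padding_multiplier = padding_multiplier
        self.k_neighbors = k_neighbors
        self.bandwidth = bandwidth
        self.solver = solver
        self.tolerance = tolerance
        self.dual_clip = dual_clip

    # ---- constructors ----------------------------------------------------

    @classmethod
    def from_arrays(cls, coords, velocities, labels=None, **kwargs):
        return cls(CellEmbedding(coords, velocities, labels), **kwargs)

    @classmethod
    def from_dataframe(
        cls, df, x="x", y="y", vx="vx", vy="vy", label=None, **kwargs
    ):
        """Build from a DataFrame with coordinate/velocity columns."""
        labels = df[label].to_numpy() if label is not None else None
        return cls.from_arrays(
            df[[x, y]].to_numpy(float), df[[vx, vy]].to_numpy(float), labels, **kwargs
        )

    @classmethod
    def from_anndata(
        cls,
        adata,
        embedding_key: str = "X_umap",
        velocity_key: str = "velocity_umap",
        labels_key: str | None = None,
        **kwargs,
    ):
        """Build from an AnnData with embedding/velocity arrays in ``obsm``."""
        for key in (embedding_key, velocity_key):
            if key not in adata.obsm:
                raise KeyError(
                    f"obsm key {key!r} not found; available: {list(adata.obsm.keys())}"
                )
        labels = (
            adata.obs[labels_key].to_numpy() if labels_key is not None else None
        )
        return cls.from_arrays(
            np.asarray(adata.obsm[embedding_key], float),
            np.asarray(adata.obsm[velocity_key], float),
            labels,
            **kwargs,
        )

    @classmethod
    def from_config(cls, cells: CellEmbedding, config: "RunConfig"):
        bw = None if config.bandwidth == "auto" else float(config.bandwidth)
        return cls(
            cells,
            eta=config.eta,
            kernel=config.kernel,
            kappa=config.kappa,
            containment_fraction=config.containment_fraction,
            grid_faces=config.grid_faces,
            padding_multiplier=config.padding_multiplier,
            k_neighbors=config.k_neighbors,
            bandwidth=bw,
            solver=config.solver,
            tolerance=config.tolerance,
            dual_clip=config.dual_clip,
        )

    # ---- fitting ---------------------------------------------------------

    def fit(self) -> "HodgeDecompositionResults":
        """Run domain extraction, velocity averaging and the decomposition."""
        complex_, spec, density = domain_complex(
            self.cells.coords,
            eta=self.eta,
            kernel=self.kernel,
            kappa=self.kappa,
            containment_fraction=self.containment_fraction,
            grid_faces=self.grid_faces,
            padding_multiplier=self.padding_multiplier,
        )
        bw = self.bandwidth
        if bw is None:
            bw = auto_bandwidth(self.cells, complex_, self.k_neighbors)
        grid_field = interpolate_velocity(
            self.cells, complex_, k=self.k_neighbors, bandwidth=bw
        )
        omega = flat(grid_field)
        dec = decompose(
            omega,
            complex_,
            tol=self.tolerance,
            solver=self.solver,
            dual_clip=self.dual_clip,
        )
        topo = compute_topology(complex_)
        return HodgeDecompositionResults(
            model=self,
            complex=complex_,
            domain=spec,
            density=density,
            field=grid_field,
            bandwidth_used=float(bw),
            decomposition=dec,
            topology=topo,
        )


@dataclass
class HodgeDecompositionResults:
    """Fitted decomposition of a cell-velocity field.

    Carries the grid complex, the extracted domain, the averaged vertex field
    and the three orthogonal components with their diagnostics.
    """

    model: VelocityFieldModel
    complex: GridComplex
    domain: DomainSpec
    density: object
    field: VectorFieldGrid
    bandwidth_used: float
    decomposition: HodgeDecomposition
    topology: DomainTopology

    @property
    def energy_fractions(self) -> dict[str, float]:
        return self.decomposition.energy_fractions()

    @property
    def diagnostics(self):
        return self.decomposition.diagnostics

    def component_fields(self) -> tuple[VectorFieldGrid, VectorFieldGrid, VectorFieldGrid]:
        return component_fields(self.decomposition)

    def harmonic_report(self, threshold: float = 0.05) -> HarmonicReport:
        return harmonic_consistency(self.decomposition, self.topology, threshold)

    def saddles(self, component: str = "harmonic") -> np.ndarray:
        """Saddle locations (Poincare index -1) of a component's vertex field."""
        fields = dict(zip(("exact", "coexact", "harmonic"), self.component_fields()))
        fields["input"] = self.field
        if component not in fields:
            raise ValueError(f"component must be one of {sorted(fields)}")
        return find_saddles(fields[component])

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        d = self.diagnostics
        fr = self.energy_fractions
        lines = [
            "      Helmholtz-Hodge Decomposition Results",
            "=" * 52,
            f"{'No. cells:':<28}{self.model.cells.n_cells:>24}",
            f"{'Grid (nx x ny vertices):':<28}"
            f"{f'{self.complex.grid.counts[0]} x {self.complex.grid.counts[1]}':>24}",
            f"{'Active faces:':<28}{self.complex.n_faces:>24}",
            f"{'All cells contained:':<28}{str(self.domain.all_contained):>24}",
            f"{'Betti numbers (b0, b1):':<28}"
            f"{f'({self.topology.b0}, {self.topology.b1})':>24}",
            "-" * 52,
            "Energy fractions",
            f"  curl-free (exact):      {fr['exact']:>12.6f}",
            f"  divergence-free:        {fr['coexact']:>12.6f}",
            f"  harmonic:               {fr['harmonic']:>12.6f}",
            "-" * 52,
            "Orthogonality residuals (|<a,b>| / ||omega||^2)",
            f"  exact/coexact:          {d.orth_exact_coexact:>12.3e}",
            f"  exact/harmonic:         {d.orth_exact_harmonic:>12.3e}",
            f"  coexact/harmonic:       {d.orth_coexact_harmonic:>12.3e}",
            "Solver residuals",
            f"  exact potential:        {d.residual_exact_solve:>12.3e}",
            f"  coexact potential:      {d.residual_coexact_solve:>12.3e}",
            f"{'Harmonic saddles:':<28}{len(self.saddles()):>24}",
            "=" * 52,
        ]
        return "\n".join(lines)

    # ---- plotting --------------------------------------------------------

    def _full_grid_arrays(self, fld: VectorFieldGrid):
        nx, ny = self.complex.grid.counts
        U = np.full((ny, nx), np.nan)
        V = np.full((ny, nx), np.nan)
        ij = self.complex.vertex_ij()
        U[ij[:, 1], ij[:, 0]] = fld.vectors[:, 0]
        V[ij[:, 1], ij[:, 0]] = fld.vectors[:, 1]
        return U, V

    def plot_components(self, density: float = 1.2, figsize=(16, 4)):
        """Streamline plots of the input field and its three components."""
        import matplotlib.pyplot as plt

        grid = self.complex.grid
        xs = grid.origin[0] + grid.spacing[0] * np.arange(grid.counts[0])
        ys = grid.origin[1] + grid.spacing[1] * np.arange(grid.counts[1])
        panels = [("input", self.field)] + list(
            zip(("curl-free", "divergence-free", "harmonic"), self.component_fields())
        )
        fig, axes = plt.subplots(1, 4, figsize=figsize, sharex=True, sharey=True)
        for ax, (title, fld) in zip(axes, panels):
            U, V = self._full_grid_arrays(fld)
            speed = np.hypot(U, V)
            ax.streamplot(xs, ys, np.nan_to_num(U), np.nan_to_num(V), density=density)
            ax.scatter(
                self.model.cells.coords[:, 0],
                self.model.cells.coords[:, 1],
                s=2,
                alpha=0.2,
                color="gray",
            )
            ax.set_title(f"{title}\n(max |v| = {np.nanmax(speed):.3g})")
            ax.set_aspect("equal")
        fig.tight_layout()
        return fig
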