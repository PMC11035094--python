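"""Readers, writers, run configuration and the batch pipeline.

Input formats: delimited text with header columns ``x,y,vx,vy[,label]`` or
AnnData ``.h5ad`` with embedding/velocity arrays in ``obsm``.  Output formats
are all plain text: per-component vertex fields, a 0/1 face-mask grid with
its header, a JSON diagnostics file carrying the full configuration (and its
hash) for provenance, and an optional legacy-VTK structured-points file for
streamline rendering in standard viewers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import CellEmbedding, VectorFieldGrid, find_saddles
from .grid import CartesianGrid, GridComplex
from .model import HodgeDecompositionResults, VelocityFieldModel

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; every field has a usable default.

    The defaults k_neighbors = 50 and eta = 1.0 are the standard choices for
    velocity-grid averaging and the FRI density scale.
    """

    input: str = ""
    format: str | None = None  # csv | h5ad | None (infer from suffix)
    embedding_key: str = "X_umap"
    velocity_key: str = "velocity_umap"
    labels_key: str | None = None
    grid_faces: int = 100
    padding_multiplier: float = 3.0
    eta: float = 1.0
    kernel: str = "gaussian"
    kappa: float = 2.0
    containment_fraction: float = 0.9
    k_neighbors: int = 50
    bandwidth: float | str = "auto"
    solver: str = "direct"
    tolerance: float = 1e-10
    dual_clip: bool = True
    seed: int = 0
    output_prefix: str = "hodgeflow_run"
    write_vtk: bool = False

    def validate(self) -> None:
        if not 0 < self.containment_fraction <= 1:
            raise ValueError("containment_fraction must be in (0, 1]")
        if self.grid_faces < 2:
            raise ValueError("grid_faces must be at least 2")
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be at least 1")
        if self.bandwidth != "auto" and not float(self.bandwidth) > 0:
            raise ValueError("bandwidth must be positive or 'auto'")
        if self.solver not in ("direct", "cg"):
            raise ValueError("solver must be 'direct' or 'cg'")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def read_cells(
    path: str | Path,
    format: str | None = None,
    embedding_key: str = "X_umap",
    velocity_key: str = "velocity_umap",
    labels_key: str | None = None,
) -> CellEmbedding:
    """Load a cell embedding from csv (columns x,y,vx,vy[,label]) or .h5ad.

    Rows with non-finite coordinates or velocities are dropped (logged).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "h5ad" if path.suffix == ".h5ad" else "csv"
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        needed = ["x", "y", "vx", "vy"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise KeyError(
                f"missing columns {missing}; available: {list(df.columns)}"
            )
        coords = df[["x", "y"]].to_numpy(float)
        vel = df[["vx", "vy"]].to_numpy(float)
        labels = df["label"].to_numpy() if "label" in df.columns else None
    elif format == "h5ad":
        import anndata

        adata = anndata.read_h5ad(path)
        for key in (embedding_key, velocity_key):
            if key not in adata.obsm:
                raise KeyError(
                    f"obsm key {key!r} not found; available: {list(adata.obsm.keys())}"
                )
        coords = np.asarray(adata.obsm[embedding_key], dtype=float)
        vel = np.asarray(adata.obsm[velocity_key], dtype=float)
        labels = None
        if labels_key is not None:
            if labels_key not in adata.obs.columns:
                raise KeyError(
                    f"obs column {labels_key!r} not found; "
                    f"available: {list(adata.obs.columns)}"
                )
            labels = adata.obs[labels_key].to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'h5ad'")
    if coords.shape[1] != 2 or vel.shape[1] != 2:
        raise ValueError("only 2D embeddings supported in v1")
    ok = np.isfinite(coords).all(axis=1) & np.isfinite(vel).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d rows with non-finite values", dropped)
    if labels is not None:
        labels = labels[ok]
    return CellEmbedding(coords=coords[ok], velocities=vel[ok], labels=labels)


def write_cells(path: str | Path, cells: CellEmbedding) -> None:
    """Write a cell embedding in the standard csv layout (full precision)."""
    df = pd.DataFrame(
        {
            "x": cells.coords[:, 0],
            "y": cells.coords[:, 1],
            "vx": cells.velocities[:, 0],
            "vy": cells.velocities[:, 1],
        }
    )
    if cells.labels is not None:
        df["label"] = cells.labels
    df.to_csv(path, index=False, float_format="%.17g")


def write_vertex_field(path: str | Path, field: VectorFieldGrid) -> None:
    """Dump a vertex field as rows i,j,x,y,vx,vy."""
    ij = field.complex.vertex_ij()
    xy = field.complex.vertex_coords()
    df = pd.DataFrame(
        {
            "i": ij[:, 0],
            "j": ij[:, 1],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "vx": field.vectors[:, 0],
            "vy": field.vectors[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_mask(path: str | Path, grid: CartesianGrid, mask: np.ndarray) -> None:
    """Face mask as a 0/1 grid preceded by a grid header."""
    with open(path, "w") as fh:
        fh.write(f"# origin {grid.origin[0]:.17g} {grid.origin[1]:.17g}\n")
        fh.write(f"# spacing {grid.spacing[0]:.17g} {grid.spacing[1]:.17g}\n")
        fh.write(f"# counts {grid.counts[0]} {grid.counts[1]}\n")
        np.savetxt(fh, mask.astype(int), fmt="%d")


def read_mask(path: str | Path) -> tuple[CartesianGrid, np.ndarray]:
    header = {}
    with open(path) as fh:
        for _ in range(3):
            tag, *vals = fh.readline().lstrip("# ").split()
            header[tag] = vals
    mask = np.loadtxt(path, dtype=int, comments="#").astype(bool)
    grid = CartesianGrid(
        origin=tuple(float(v) for v in header["origin"]),
        spacing=tuple(float(v) for v in header["spacing"]),
        counts=tuple(int(v) for v in header["counts"]),
    )
    return grid, np.atleast_2d(mask)


def write_vtk_structured(
    path: str | Path, complex: GridComplex, fields: dict[str, VectorFieldGrid]
) -> None:
    """Legacy-VTK STRUCTURED_POINTS file with one VECTORS block per field.

    Vertices outside the domain get zero vectors so viewers can render
    streamlines on the full rectangular lattice.
    """
    grid = complex.grid
    nx, ny = grid.counts
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nhodgeflow vertex fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {grid.origin[0]} {grid.origin[1]} 0\n")
        fh.write(f"SPACING {grid.spacing[0]} {grid.spacing[1]} 1\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        for name, field in fields.items():
            full = np.zeros((nx * ny, 2))
            full[field.complex._vert_idx] = field.vectors
            fh.write(f"VECTORS {name} float\n")
            for vx, vy in full:
                fh.write(f"{vx:.9g} {vy:.9g} 0\n")


@dataclass
class PipelineResult:
    results: HodgeDecompositionResults
    outputs: dict[str, str]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Read -> domain -> field -> decomposition -> write everything.

    Writes one vertex-field file per component, the input-field dump, the
    face mask, streamline seeds (saddles of the harmonic field), and a JSON
    diagnostics file embedding the config and its hash.  Reruns with an
    identical config produce byte-identical outputs.
    """
    config.validate()
    t0 = time.perf_counter()
    cells = read_cells(
        config.input,
        format=config.format,
        embedding_key=config.embedding_key,
        velocity_key=config.velocity_key,
        labels_key=config.labels_key,
    )
    t_read = time.perf_counter()
    logger.info("read %d cells in %.2fs", cells.n_cells, t_read - t0)

    model = VelocityFieldModel.from_config(cells, config)
    results = model.fit()
    t_fit = time.perf_counter()
    logger.info("pipeline fit in %.2fs", t_fit - t_read)

    prefix = Path(config.output_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    exact_f, coexact_f, harmonic_f = results.component_fields()
    for name, fld in (
        ("input_field", results.field),
        ("exact", exact_f),
        ("coexact", coexact_f),
        ("harmonic", harmonic_f),
    ):
        p = f"{prefix}_{name}.csv"
        write_vertex_field(p, fld)
        outputs[name] = p
    p = f"{prefix}_mask.txt"
    write_mask(p, results.complex.grid, results.complex.face_mask)
    outputs["mask"] = p

    saddles = find_saddles(harmonic_f)
    p = f"{prefix}_saddle_seeds.csv"
    pd.DataFrame(saddles, columns=["x", "y"]).to_csv(p, index=False, float_format="%.17g")
    outputs["saddle_seeds"] = p

    diag = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "n_cells": int(cells.n_cells),
        "isovalue": results.domain.isovalue,
        "all_contained": bool(results.domain.all_contained),
        "betti": {"b0": results.topology.b0, "b1": results.topology.b1},
        "euler_characteristic": results.topology.euler_characteristic,
        "n_saddles_harmonic": int(len(saddles)),
        "diagnostics": results.decomposition.diagnostics.as_dict(),
    }
    p = f"{prefix}_diagnostics.json"
    with open(p, "w") as fh:
        json.dump(diag, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["diagnostics"] = p

    if config.write_vtk:
        p = f"{prefix}_fields.vtk"
        write_vtk_structured(
            p,
            results.complex,
            {
                "input": results.field,
                "exact": exact_f,
                "coexact": coexact_f,
                "harmonic": harmonic_f,
            },
        )
        outputs["vtk"] = p
    logger.info("wrote %d outputs in %.2fs", len(outputs), time.perf_counter() - t_fit)
    return PipelineResult(results=results, outputs=outputs)


def sweep(config: RunConfig, parameter: str, values: list) -> pd.DataFrame:
    """Rerun the pipeline varying one RunConfig field; returns a comparison
    table of energy fractions, Betti numbers and containment per value."""
    if not values:
        raise ValueError("sweep needs a non-empty list of values")
    if not hasattr(config, parameter):
        raise ValueError(f"unknown RunConfig field {parameter!r}")
    rows = []
    for value in values:
        cfg = dataclasses.replace(config, **{parameter: value})
        cfg.output_prefix = f"{config.output_prefix}_{parameter}_{value}"
        res = run_pipeline(cfg).results
        d = res.decomposition.diagnostics
        rows.append(
            {
                parameter: value,
                "exact_fraction": d.energy_fraction_exact,
                "coexact_fraction": d.energy_fraction_coexact,
                "harmonic_fraction": d.energy_fraction_harmonic,
                "b0": res.topology.b0,
                "b1": res.topology.b1,
                "all_contained": res.domain.all_contained,
            }
        )
    return pd.DataFrame(rows)
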