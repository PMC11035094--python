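"""Synthetic fixtures with known decomposition structure.

Two families:

* ``analytic_field`` — vector fields sampled on an existing grid complex that
  realize each orthogonal subspace by construction: a gradient of a compactly
  supported bump (curl-free), its 90-degree rotation (divergence-free), the
  circulating field ``(-y, x) / (x^2 + y^2)`` on an annulus (harmonic), and a
  weighted mixture with known energy fractions.

* ``synthetic_cells`` — point clouds with per-cell velocities that emulate the
  two qualitative flow motifs of single-cell velocity maps: ``ring_cells``, a
  noisy annulus with tangential velocities (the cell-cycle analogue, whose
  rotation is picked up by the divergence-free component), and
  ``branch_cells``, a trunk feeding two diverging arms (the lineage-
  bifurcation analogue, whose harmonic through-flow contains a saddle).

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import CellEmbedding, VectorFieldGrid, flat
from .grid import GridComplex, compute_topology, inner_product

ANALYTIC_SCENARIOS = ("gradient", "rotation", "annulus_harmonic", "mixture")
CELL_SCENARIOS = ("ring_cells", "branch_cells")


@dataclass
class SyntheticScenario:
    """A named fixture recipe; same seed + parameters give identical output."""

    name: str
    parameters: dict = field(default_factory=dict)
    seed: int = 0


def _bump_and_gradient(
    complex: GridComplex, center: np.ndarray | None, sigma: float | None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Gaussian bump f = exp(-||x - c||^2 / sigma^2) at active vertices and
    its analytic gradient.  The default sigma (0.17 x the centre-to-boundary
    distance) makes both f and its gradient < 1e-12 on the boundary."""
    coords = complex.vertex_coords()
    if center is None:
        center = coords.mean(axis=0)
    center = np.asarray(center, dtype=float)
    if sigma is None:
        bdist = np.linalg.norm(coords[complex.vertex_boundary] - center, axis=1)
        sigma = 0.17 * float(bdist.min())
    r2 = ((coords - center) ** 2).sum(axis=1)
    f = np.exp(-r2 / sigma**2)
    grad = -2.0 * (coords - center) / sigma**2 * f[:, None]
    return f, grad, float(sigma)


def analytic_field(
    scenario: SyntheticScenario, complex: GridComplex
) -> tuple[VectorFieldGrid, dict]:
    """Sample an analytic scenario on the complex.

    Returns the vertex field and a reference dict with the dominant component
    label and, for mixtures, the expected energy fractions.
    """
    name = scenario.name
    p = scenario.parameters
    if name not in ANALYTIC_SCENARIOS:
        raise ValueError(f"unknown analytic scenario {name!r}")
    if name == "gradient":
        _, grad, _ = _bump_and_gradient(complex, p.get("center"), p.get("sigma"))
        return VectorFieldGrid(complex, grad), {"reference": "exact"}
    if name == "rotation":
        _, grad, _ = _bump_and_gradient(complex, p.get("center"), p.get("sigma"))
        rotated = np.column_stack([-grad[:, 1], grad[:, 0]])  # J grad
        return VectorFieldGrid(complex, rotated), {"reference": "coexact"}
    if name == "annulus_harmonic":
        if compute_topology(complex).b1 < 1:
            raise ValueError(
                "annulus_harmonic needs a non-simply-connected mask (b1 >= 1)"
            )
        coords = complex.vertex_coords()
        center = np.asarray(p.get("center", coords.mean(axis=0)), dtype=float)
        d = coords - center
        r2 = (d**2).sum(axis=1)
        r2 = np.maximum(r2, 1e-300)
        vec = np.column_stack([-d[:, 1], d[:, 0]]) / r2[:, None]
        return VectorFieldGrid(complex, vec), {"reference": "harmonic"}
    # mixture: unit-energy gradient and rotation parts with stated weights
    w = np.asarray(p.get("weights", (1.0, 1.0, 0.0)), dtype=float)
    grad_f, ref_g = analytic_field(SyntheticScenario("gradient", p), complex)
    rot_f, ref_r = analytic_field(SyntheticScenario("rotation", p), complex)
    parts = [grad_f.vectors, rot_f.vectors]
    if w[2] != 0:
        harm_f, _ = analytic_field(SyntheticScenario("annulus_harmonic", p), complex)
        parts.append(harm_f.vectors)
    else:
        parts.append(np.zeros_like(grad_f.vectors))
    norms = []
    for vec in parts:
        fld = VectorFieldGrid(complex, vec)
        om = flat(fld)
        norms.append(np.sqrt(max(inner_product(om, om), 1e-300)))
    combined = sum(
        wi / ni * vec for wi, ni, vec in zip(w, norms, parts) if wi != 0
    )
    energies = w**2
    fractions = energies / energies.sum()
    return (
        VectorFieldGrid(complex, np.asarray(combined)),
        {
            "reference": "mixture",
            "expected_fractions": {
                "exact": float(fractions[0]),
                "coexact": float(fractions[1]),
                "harmonic": float(fractions[2]),
            },
        },
    )


def synthetic_cells(scenario: SyntheticScenario) -> CellEmbedding:
    """Generate a synthetic cell cloud with velocities.

    ``ring_cells``: n points on a circle of radius ``radius`` (default 5, in
    units of the density scale eta = 1) with isotropic position jitter
    ``noise_sigma`` (default 0.1 — small enough that the extracted domain
    stays annular at the default 100-face grid) and tangential unit
    velocities with jitter ``velocity_noise``.

    ``branch_cells``: a vertical trunk flowing upward into a junction from
    which two arms diverge outward and downward; the opposing vertical
    velocity components above the junction create an interior saddle in the
    averaged field's harmonic part.  Labels mark trunk / arm membership.
    """
    name = scenario.name
    p = scenario.parameters
    if name not in CELL_SCENARIOS:
        raise ValueError(f"unknown cell scenario {name!r}")
    n = int(p.get("n", 500))
    if n < 10:
        raise ValueError("need at least 10 cells")
    rng = np.random.default_rng(scenario.seed)

    if name == "ring_cells":
        radius = float(p.get("radius", 5.0))
        noise = float(p.get("noise_sigma", 0.1))
        vnoise = float(p.get("velocity_noise", 0.1))
        speed = float(p.get("speed", 1.0))
        theta = rng.uniform(0.0, 2 * np.pi, size=n)
        coords = radius * np.column_stack([np.cos(theta), np.sin(theta)])
        coords += rng.normal(scale=noise, size=(n, 2))
        vel = speed * np.column_stack([-np.sin(theta), np.cos(theta)])
        vel += rng.normal(scale=vnoise, size=(n, 2))
        labels = np.array(
            [f"phase_{int(t // (np.pi / 2))}" for t in theta], dtype=object
        )
        return CellEmbedding(coords=coords, velocities=vel, labels=labels)

    # branch_cells
    noise = float(p.get("noise_sigma", 0.1))
    vnoise = float(p.get("velocity_noise", 0.05))
    trunk_len = float(p.get("trunk_length", 8.0))
    arm_end = np.asarray(p.get("arm_end", (6.0, -5.0)), dtype=float)
    n_trunk = n // 2
    n_arm = (n - n_trunk) // 2
    n_arm2 = n - n_trunk - n_arm
    t = rng.uniform(0.0, 1.0, size=n_trunk)
    trunk = np.column_stack([np.zeros(n_trunk), -trunk_len * (1.0 - t)])
    trunk_v = np.tile([0.0, 1.0], (n_trunk, 1))
    arm_dir = arm_end / np.linalg.norm(arm_end)
    segs, vels, labels = [trunk], [trunk_v], ["trunk"] * n_trunk
    for sign, m, tag in ((1.0, n_arm, "arm_right"), (-1.0, n_arm2, "arm_left")):
        s = rng.uniform(0.0, 1.0, size=m)
        end = arm_end * np.array([sign, 1.0])
        segs.append(np.outer(s, end))
        vels.append(np.tile(arm_dir * np.array([sign, 1.0]), (m, 1)))
        labels.extend([tag] * m)
    coords = np.vstack(segs) + rng.normal(scale=noise, size=(n, 2))
    vel = np.vstack(vels) + rng.normal(scale=vnoise, size=(n, 2))
    return CellEmbedding(
        coords=coords, velocities=vel, labels=np.array(labels, dtype=object)
    )
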