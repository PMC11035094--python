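"""Shared mask/complex factories for the test suite."""

import numpy as np

import hodgeflow as hf


def square_complex(n, h=None, origin=(0.0, 0.0)):
    """Full n x n face block (disk topology)."""
    h = 1.0 / n if h is None else h
    grid = hf.CartesianGrid(origin, (h, h), (n + 1, n + 1))
    return hf.build_complex(grid, np.ones((n, n), bool))


def annulus_complex(n, r_in=0.3, r_out=0.95):
    """Annular mask on [-1, 1]^2 from face-centre radii."""
    grid = hf.CartesianGrid((-1.0, -1.0), (2.0 / n, 2.0 / n), (n + 1, n + 1))
    jj, ii = np.mgrid[0:n, 0:n]
    cx = (ii + 0.5) * 2.0 / n - 1.0
    cy = (jj + 0.5) * 2.0 / n - 1.0
    r = np.hypot(cx, cy)
    return hf.build_complex(grid, (r > r_in) & (r < r_out))


def two_blocks_complex(n=10):
    """Two face blocks sharing no edge (b0 = 2)."""
    grid = hf.CartesianGrid((0.0, 0.0), (1.0 / n, 1.0 / n), (n + 1, n + 1))
    mask = np.zeros((n, n), bool)
    k = max(n // 3, 1)
    mask[:k, :k] = True
    mask[-k:, -k:] = True
    return hf.build_complex(grid, mask)


def staircase_complex(n=16, seed=0, n_faces=None):
    """Random staircase blob grown face-by-face from the centre (seeded)."""
    rng = np.random.default_rng(seed)
    mask = np.zeros((n, n), bool)
    frontier = [(n // 2, n // 2)]
    mask[n // 2, n // 2] = True
    target = n_faces if n_faces is not None else (n * n) // 3
    while mask.sum() < target and frontier:
        j, i = frontier[rng.integers(len(frontier))]
        moves = [
            (j + dj, i + di)
            for dj, di in ((0, 1), (0, -1), (1, 0), (-1, 0))
            if 0 <= j + dj < n and 0 <= i + di < n and not mask[j + dj, i + di]
        ]
        if not moves:
            frontier.remove((j, i))
            continue
        nj, ni = moves[rng.integers(len(moves))]
        mask[nj, ni] = True
        frontier.append((nj, ni))
    grid = hf.CartesianGrid((0.0, 0.0), (1.0 / n, 1.0 / n), (n + 1, n + 1))
    return hf.build_complex(grid, mask)


def standard_mask_suite(n=64):
    """The five domain shapes used by the orthogonality sweeps."""
    return {
        "disk": square_complex(n),
        "annulus": annulus_complex(n),
        "two_components": two_blocks_complex(n),
        "staircase": staircase_complex(n, seed=1),
        "staircase2": staircase_complex(n, seed=5),
    }


def random_cochain(complex, seed, degree=1):
    rng = np.random.default_rng(seed)
    return hf.Cochain(degree, rng.normal(size=complex.n_cells(degree)), complex)
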