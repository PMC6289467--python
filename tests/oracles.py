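"""Independent reference computations used to check the implementation.

These deliberately avoid the code paths they verify: the pseudo-inverse
oracle uses a dense shifted solve instead of eigendecomposition, the
chain-spectrum oracle uses the closed-form eigensystem of the free linear
chain, and the rank oracle counts comparisons directly.
"""

import numpy as np


def laplacian_pseudoinverse_diag(lap: np.ndarray) -> np.ndarray:
    """Diagonal of the Moore–Penrose pseudo-inverse of a connected-graph
    Laplacian via the exact rank-one shift (L + J/n)^-1 - J/n."""
    n = lap.shape[0]
    jn = np.full((n, n), 1.0 / n)
    return np.diag(np.linalg.inv(lap + jn) - jn).copy()


def free_chain_msf(n: int) -> np.ndarray:
    """Closed-form pseudo-inverse diagonal of the nearest-neighbour path
    Laplacian: eigenvalues 2 - 2cos(pi k / n) with cosine eigenvectors."""
    k = np.arange(1, n)
    lam = 2.0 - 2.0 * np.cos(np.pi * k / n)
    i = np.arange(n)
    vec = np.sqrt(2.0 / n) * np.cos(np.pi * np.outer(i + 0.5, k) / n)
    return (vec**2 / lam).sum(axis=1)


def count_rank(scores) -> np.ndarray:
    """Brute-force percentile rank: #(<= s) / n for each score."""
    arr = np.asarray(scores, dtype=float)
    return np.array([(arr <= s).sum() for s in arr]) / arr.size


def helix_ca_distance(sep: int, rise=1.5, radius=2.3, twist_deg=100.0) -> float:
    """Cα–Cα distance at sequence separation `sep` in an ideal α-helix."""
    theta = np.deg2rad(twist_deg * sep)
    chord = np.sqrt(
        (radius - radius * np.cos(theta)) ** 2 + (radius * np.sin(theta)) ** 2
    )
    return float(np.hypot(chord, rise * sep))
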