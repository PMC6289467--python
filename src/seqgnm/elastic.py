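"""Gaussian-network elastic models: Kirchhoff matrices and fluctuations.

The Gaussian network model (GNM) treats a protein as beads joined by
identical harmonic springs; residue mean-square fluctuations (MSF) due to
thermal motion are the diagonal of the pseudo-inverse of the network's
Kirchhoff (graph Laplacian) matrix,

    <(dR_i)^2>  ∝  [Γ⁻¹]_ii ,        B_i = 8π² <(dR_i)^2> / 3 .

Two Kirchhoff constructions are provided:

* the classical structure-based one, where residues whose Cα atoms lie
  within a distance cutoff (default 10 Å) are connected with spring
  constant 1;
* the sequence-based one, which needs no 3D structure: Γ = Γ_chain + Γ_nb,
  where Γ_chain connects each residue to its i±1..3 backbone neighbours
  (a Rouse-chain term with unit springs) and Γ_nb connects top-ranked
  evolutionarily coupled pairs with spring constant equal to their
  coupling percentile rank, so spring strength attenuates with coupling
  strength.

No global force constant is applied — MSF values are in arbitrary units
and are compared across models via Pearson correlation or percentile
ranks, where any overall constant cancels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .couplings import ContactNetwork, percentile_rank, threshold_contacts
from .io import CouplingTable, ProteinChain

__all__ = [
    "Kirchhoff",
    "FluctuationProfile",
    "DegeneracyError",
    "BFACTOR_CONSTANT",
    "chain_kirchhoff",
    "nonbonded_kirchhoff",
    "structure_kirchhoff",
    "combine",
    "fluctuations",
    "pearson",
    "seq_gnm",
    "structure_gnm",
    "DEFAULT_CUTOFF",
    "ZERO_MODE_RTOL",
]

#: Cα–Cα contact cutoff of the structure-based model, Å
DEFAULT_CUTOFF = 10.0
#: eigenvalues with |λ| <= rtol·λ_max are treated as zero modes
ZERO_MODE_RTOL = 1e-8
#: B = 8π²/3 · msf (Debye–Waller); display only, cancels in all comparisons
BFACTOR_CONSTANT = 8.0 * np.pi**2 / 3.0


class DegeneracyError(np.linalg.LinAlgError):
    """More numerical zero modes than connected components."""


@dataclass
class Kirchhoff:
    """Symmetric graph-Laplacian connectivity matrix of an elastic network."""

    matrix: np.ndarray
    provenance: str = "combined"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n) or n < 2:
            raise ValueError(f"Kirchhoff must be square with n >= 2, got {self.matrix.shape}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self, atol: float = 1e-9) -> None:
        """Check the Laplacian invariants: symmetry, zero row sums, sign pattern."""
        m = self.matrix
        if not np.allclose(m, m.T, atol=atol):
            raise ValueError("Kirchhoff is not symmetric")
        if not np.allclose(m.sum(axis=1), 0.0, atol=atol * max(1.0, np.abs(m).max())):
            raise ValueError("Kirchhoff row sums are not zero")
        off = m - np.diag(np.diag(m))
        if np.any(off > atol):
            raise ValueError("off-diagonal entries must be <= 0")
        if np.any(np.diag(m) < -atol):
            raise ValueError("diagonal entries must be >= 0")

    def n_components(self) -> int:
        """Connected components of the contact graph (nonzero off-diagonals)."""
        adj = (self.matrix != 0.0) & ~np.eye(self.n, dtype=bool)
        return connected_components(adj, directed=False)[0]


@dataclass
class FluctuationProfile:
    """Per-residue mean-square fluctuations with their percentile ranks.

    ``msf`` is in arbitrary units (no force constant); ``percentile`` is the
    within-protein rank of each residue's msf so that profiles of different
    proteins can be compared on a common [0, 1] scale.
    """

    msf: np.ndarray
    percentile: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.msf = np.asarray(self.msf, dtype=float)
        if self.msf.ndim != 1 or self.msf.size == 0:
            raise ValueError("msf must be a non-empty 1-D array")
        if np.any(self.msf <= 0):
            raise ValueError("msf must be positive for every residue")
        if self.percentile is None:
            self.percentile = percentile_rank(self.msf)
        else:
            self.percentile = np.asarray(self.percentile, dtype=float)
            if self.percentile.shape != self.msf.shape:
                raise ValueError("percentile length mismatch")

    @property
    def n_residues(self) -> int:
        return self.msf.size

    @property
    def bfactor(self) -> np.ndarray:
        """Debye–Waller B-factor scale, 8π²·msf/3 (arbitrary units)."""
        return BFACTOR_CONSTANT * self.msf


def _from_offdiag(off: np.ndarray, provenance: str) -> Kirchhoff:
    """Laplacian from a symmetric non-negative interaction-strength matrix."""
    m = -np.asarray(off, dtype=float)
    np.fill_diagonal(m, 0.0)
    np.fill_diagonal(m, -m.sum(axis=1))
    return Kirchhoff(matrix=m, provenance=provenance)


def chain_kirchhoff(
    n: int, max_neighbor: int = 3, segments: Sequence[int] | None = None
) -> Kirchhoff:
    """Backbone-connectivity (Rouse chain) Kirchhoff.

    Residues i and j are connected with spring constant 1 whenever
    ``1 <= |i - j| <= max_neighbor`` and both lie in the same chain
    segment.  ``segments`` gives per-chain lengths for multi-chain inputs
    (no bonded term ever crosses a chain boundary); default is one chain.
    """
    if n < 2:
        raise ValueError(f"chain needs n >= 2, got {n}")
    if max_neighbor < 1:
        raise ValueError("max_neighbor must be >= 1")
    if segments is None:
        segments = [n]
    if sum(segments) != n or any(s < 1 for s in segments):
        raise ValueError(f"segments {segments} do not partition {n} residues")
    strength = np.zeros((n, n))
    start = 0
    for seg in segments:
        for k in range(1, max_neighbor + 1):
            idx = np.arange(start, start + seg - k)
            strength[idx, idx + k] = 1.0
            strength[idx + k, idx] = 1.0
        start += seg
    return _from_offdiag(strength, "chain")


def nonbonded_kirchhoff(net: ContactNetwork) -> Kirchhoff:
    """Non-bonded Kirchhoff from thresholded couplings: entry (i, j) is
    −1 × (coupling percentile rank) for each selected pair."""
    if net.length < 2:
        raise ValueError("network length must be >= 2")
    strength = np.zeros((net.length, net.length))
    for i, j, w in net.contacts:
        strength[i - 1, j - 1] = w
        strength[j - 1, i - 1] = w
    return _from_offdiag(strength, "nonbonded")


def structure_kirchhoff(chain: ProteinChain, cutoff: float = DEFAULT_CUTOFF) -> Kirchhoff:
    """Classical structure-based Kirchhoff: unit springs between Cα pairs
    within ``cutoff`` Å, including cross-chain pairs of an oligomer."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if chain.coords is None or len(chain.coords) != chain.n_residues:
        raise ValueError("chain has no usable coordinates")
    dist = squareform(pdist(chain.coords))
    strength = (dist <= cutoff).astype(float)
    np.fill_diagonal(strength, 0.0)
    return _from_offdiag(strength, "structure")


def combine(chain_term: Kirchhoff, nonbonded_term: Kirchhoff) -> Kirchhoff:
    """Total Kirchhoff Γ = Γ_chain + Γ_nb (element-wise sum)."""
    if chain_term.n != nonbonded_term.n:
        raise ValueError(
            f"dimension mismatch: {chain_term.n} vs {nonbonded_term.n}"
        )
    return Kirchhoff(matrix=chain_term.matrix + nonbonded_term.matrix, provenance="combined")


def fluctuations(gamma: Kirchhoff | np.ndarray, rtol: float = ZERO_MODE_RTOL) -> FluctuationProfile:
    """Mean-square fluctuations: diagonal of the Kirchhoff pseudo-inverse.

    The matrix is eigendecomposed; eigenvalues with ``|λ| <= rtol·λ_max``
    are discarded as rigid-body zero modes (one per connected component)
    and ``msf_i = Σ_k v_ik² / λ_k`` over the remaining modes.  Finding more
    zero modes than connected components signals numerical degeneracy and
    raises rather than returning a silently wrong profile.
    """
    if not isinstance(gamma, Kirchhoff):
        gamma = Kirchhoff(matrix=np.asarray(gamma, dtype=float))
    m = gamma.matrix
    if not np.allclose(m, m.T, atol=1e-9 * max(1.0, np.abs(m).max())):
        raise ValueError("Kirchhoff must be symmetric")
    n_comp = gamma.n_components()
    if n_comp > 1:
        warnings.warn(
            f"contact graph has {n_comp} connected components; "
            "fluctuations are computed per component",
            stacklevel=2,
        )
    eigval, eigvec = np.linalg.eigh(m)
    lam_max = float(np.max(np.abs(eigval)))
    if lam_max == 0.0:
        raise DegeneracyError("Kirchhoff is identically zero")
    nonzero = np.abs(eigval) > rtol * lam_max
    n_zero = int(np.sum(~nonzero))
    if n_zero != n_comp:
        raise DegeneracyError(
            f"{n_zero} numerical zero modes for {n_comp} connected components"
        )
    inv_diag = (eigvec[:, nonzero] ** 2 / eigval[nonzero]).sum(axis=1)
    return FluctuationProfile(msf=inv_diag)


def pearson(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length profiles."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(scipy.stats.pearsonr(x, y).statistic)


def seq_gnm(
    table: CouplingTable,
    tau: float | None = None,
    min_separation: int = 4,
    rank_universe: str = "file",
    segments: Sequence[int] | None = None,
) -> FluctuationProfile:
    """Full sequence-based GNM: couplings → contacts → Γ → fluctuations.

    Builds the chain term for ``table.length`` residues, thresholds the
    coupling table at ``tau`` (default 0.98) and inverts the combined
    Kirchhoff.  With an empty post-threshold network the model degrades
    gracefully to the pure chain (a warning is emitted by the thresholder).
    """
    from .couplings import DEFAULT_TAU, EmptyNetworkWarning

    if tau is None:
        tau = DEFAULT_TAU
    if len(table) == 0:
        warnings.warn(
            "coupling table is empty; the model reduces to the pure chain",
            EmptyNetworkWarning,
            stacklevel=2,
        )
        net = ContactNetwork(length=table.length, contacts=[], threshold=tau)
    else:
        net = threshold_contacts(
            table, tau=tau, min_separation=min_separation, rank_universe=rank_universe
        )
    gamma = combine(
        chain_kirchhoff(table.length, segments=segments), nonbonded_kirchhoff(net)
    )
    return fluctuations(gamma)


def structure_gnm(chain: ProteinChain, cutoff: float = DEFAULT_CUTOFF) -> FluctuationProfile:
    """Structure-based GNM profile at the given Cα distance cutoff."""
    return fluctuations(structure_kirchhoff(chain, cutoff=cutoff))
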