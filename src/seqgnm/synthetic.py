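"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators emulate the tool's three inputs at desk scale:

* :func:`make_chain` — toy folded Cα traces.  ``helix`` uses ideal
  α-helix geometry (1.5 Å rise, 2.3 Å radius, 100°/residue) whose 10 Å
  contact pattern (i, i±4..6) is analytically predictable; ``compact_walk``
  grows a seeded self-avoiding walk on a 3.8 Å cubic lattice with a
  centroid-attraction bias, giving globule-like traces with genuine
  long-range contacts.  The experimental-B column is filled from the
  chain's own structure-model fluctuations plus seeded Gaussian noise, so
  it behaves like a crystallographic B-factor column with known truth.
* :func:`make_couplings` — coupling score tables over the chain's true
  10 Å contact map with tunable top-tier precision ``p_true`` and score
  noise sigma, mimicking the fact that only a fraction of top-ranked
  couplings are native contacts.
* :func:`make_variants` — labelled variant sets whose disease sites are
  biased toward rigid (low-percentile) positions with strength gamma;
  gamma = 0 is the uniform null.

All randomness flows through one seeded generator per call; identical
seeds give identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elastic import DEFAULT_CUTOFF, fluctuations, structure_kirchhoff
from .io import CouplingTable, ProteinChain, Residue, VariantRecord, VariantSet

__all__ = [
    "SyntheticSpec",
    "make_chain",
    "make_couplings",
    "make_variants",
    "true_contacts",
    "HELIX_RISE",
    "HELIX_RADIUS",
    "HELIX_TWIST_DEG",
    "CA_STEP",
]

HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TWIST_DEG = 100.0  # degrees per residue
CA_STEP = 3.8  # Å, consecutive-Cα distance / lattice constant

_AA_CODES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    """One bundle of generator settings for a full synthetic study."""

    n_residues: int = 100
    fold: str = "compact_walk"
    p_true: float = 1.0
    sigma: float = 0.1
    b_noise: float = 0.1
    n_disease: int = 200
    n_neutral: int = 200
    gamma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_true <= 1.0):
            raise ValueError("p_true must lie in [0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if min(self.n_disease, self.n_neutral) < 0:
            raise ValueError("variant counts must be >= 0")


def _helix_coords(n: int) -> np.ndarray:
    theta = np.deg2rad(HELIX_TWIST_DEG) * np.arange(n)
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * np.arange(n)]
    )


_LATTICE_STEPS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _compact_walk(n: int, rng: np.random.Generator, max_restarts: int = 1000) -> np.ndarray:
    """Self-avoiding walk on a 3.8 Å cubic lattice, biased toward its own
    centroid so the trace collapses into a compact globule.  Trapped walks
    restart (seeded, bounded)."""
    for _ in range(max_restarts):
        occupied = {(0, 0, 0)}
        path = [np.zeros(3, dtype=int)]
        centroid = np.zeros(3)
        ok = True
        for _step in range(n - 1):
            cur = path[-1]
            cands = [c for c in cur + _LATTICE_STEPS if tuple(c) not in occupied]
            if not cands:
                ok = False
                break
            cands = np.array(cands)
            d = np.linalg.norm((cands - centroid) * CA_STEP, axis=1)
            w = np.exp(-d / (2.0 * CA_STEP))
            nxt = cands[rng.choice(len(cands), p=w / w.sum())]
            occupied.add(tuple(nxt))
            path.append(nxt)
            centroid = centroid + (nxt - centroid) / len(path)
        if ok:
            return np.array(path, dtype=float) * CA_STEP
    raise RuntimeError(f"self-avoiding walk failed after {max_restarts} restarts")


def make_chain(
    n: int,
    fold: str = "helix",
    seed: int = 0,
    b_noise: float = 0.1,
    chain_id: str = "A",
) -> ProteinChain:
    """Generate a toy folded chain with a known structure and noisy B column.

    ``b_noise`` scales the Gaussian noise added to the structure-model
    B-factors (as a fraction of their spread) when filling the
    experimental-B column; 0 gives noiseless "crystallographic" values.
    """
    if n < 10:
        raise ValueError(f"synthetic chains need n >= 10, got {n}")
    rng = np.random.default_rng(seed)
    if fold == "helix":
        coords = _helix_coords(n)
    elif fold == "compact_walk":
        coords = _compact_walk(n, rng)
    else:
        raise ValueError(f"unknown fold {fold!r}")
    aas = rng.choice(list(_AA_CODES), size=n)
    residues = [Residue(chain_id=chain_id, seqnum=k + 1, icode="", aa=str(a))
                for k, a in enumerate(aas)]
    chain = ProteinChain(residues=residues, coords=coords)
    b = fluctuations(structure_kirchhoff(chain)).bfactor
    noisy = b + rng.normal(0.0, b_noise * np.std(b), size=n)
    chain.exp_bfactor = np.clip(noisy, 1e-6, None)
    return chain


def true_contacts(
    chain: ProteinChain, cutoff: float = DEFAULT_CUTOFF, min_separation: int = 4
) -> list[tuple[int, int]]:
    """Ground-truth long-range contact pairs (1-based, i < j) of a chain."""
    d = np.linalg.norm(chain.coords[:, None, :] - chain.coords[None, :, :], axis=-1)
    n = chain.n_residues
    pairs = []
    for i in range(n):
        for j in range(i + min_separation, n):
            if d[i, j] <= cutoff:
                pairs.append((i + 1, j + 1))
    return pairs


def make_couplings(
    chain: ProteinChain,
    p_true: float = 1.0,
    sigma: float = 0.1,
    seed: int = 0,
    n_decoys: int | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    min_separation: int = 4,
) -> CouplingTable:
    """Coupling table whose top tier has a controlled contact precision.

    Every true long-range contact scores ~ Normal(1, sigma).  To dilute
    top-tier precision to ``p_true``, ``T·(1 − p_true)/p_true`` false pairs
    are promoted into the same score tier; the remaining ``n_decoys``
    false pairs (default: twice the top-tier size) score ~ Normal(0, sigma)
    and pad the bottom of the ranking.  With sigma = 0 the table is an
    exact indicator: ties put the whole top tier at percentile rank 1.
    Entry order is shuffled (seeded).
    """
    if not (0.0 < p_true <= 1.0):
        raise ValueError("p_true must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n = chain.n_residues
    true = true_contacts(chain, cutoff=cutoff, min_separation=min_separation)
    t = len(true)
    if t == 0:
        raise ValueError("chain has no long-range contacts to encode")
    eligible = {
        (i + 1, j + 1)
        for i in range(n)
        for j in range(i + min_separation, n)
    }
    false_pool = sorted(eligible - set(true))
    n_promoted = int(round(t * (1.0 - p_true) / p_true))
    top_size = t + n_promoted
    if n_promoted > len(false_pool):
        raise ValueError(
            f"p_true={p_true} needs {n_promoted} promoted false pairs but only "
            f"{len(false_pool)} exist"
        )
    if n_decoys is None:
        # twice the top tier, capped by how many false pairs the chain offers
        n_decoys = min(2 * top_size, len(false_pool) - n_promoted)
    if n_promoted + n_decoys > len(false_pool):
        raise ValueError(
            f"p_true={p_true} with {n_decoys} decoys needs "
            f"{n_promoted + n_decoys} false pairs but only {len(false_pool)} exist"
        )
    chosen = rng.choice(len(false_pool), size=n_promoted + n_decoys, replace=False)
    promoted = [false_pool[k] for k in chosen[:n_promoted]]
    decoys = [false_pool[k] for k in chosen[n_promoted:]]

    entries = []
    for i, j in true:
        entries.append((i, j, float(1.0 + sigma * rng.standard_normal())))
    for i, j in promoted:
        entries.append((i, j, float(1.0 + sigma * rng.standard_normal())))
    for i, j in decoys:
        entries.append((i, j, float(0.0 + sigma * rng.standard_normal())))
    rng.shuffle(entries)
    return CouplingTable(length=n, entries=entries)


def make_variants(
    profile,
    n_disease: int,
    n_neutral: int,
    gamma: float = 2.0,
    seed: int = 0,
    protein: str = "synthetic",
    replace: bool = True,
) -> VariantSet:
    """Labelled variant positions with a tunable rigidity bias.

    Disease positions are sampled with probability ∝ (1 − percentile)^gamma
    and neutral positions ∝ percentile^gamma; gamma = 0 gives the uniform
    null for both classes.  Reference/alternate amino acids are drawn
    uniformly from distinct one-letter codes.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    rng = np.random.default_rng(seed)
    pct = np.asarray(profile.percentile, dtype=float)
    n_sites = pct.size
    if not replace and max(n_disease, n_neutral) > n_sites:
        raise ValueError("more variants requested than available positions")

    def _sample(weights: np.ndarray, count: int) -> np.ndarray:
        w = weights / weights.sum()
        return rng.choice(n_sites, size=count, replace=replace, p=w)

    records: list[VariantRecord] = []
    for label, count, w in (
        ("disease", n_disease, (1.0 - pct) ** gamma if gamma > 0 else np.ones(n_sites)),
        ("neutral", n_neutral, pct**gamma if gamma > 0 else np.ones(n_sites)),
    ):
        if w.sum() <= 0:
            raise ValueError(f"degenerate sampling weights for class {label}")
        for pos in _sample(w, count):
            ref, alt = rng.choice(list(_AA_CODES), size=2, replace=False)
            records.append(
                VariantRecord(
                    protein=protein,
                    position=int(pos) + 1,
                    ref=str(ref),
                    alt=str(alt),
                    label=label,
                )
            )
    return VariantSet(records=records)
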