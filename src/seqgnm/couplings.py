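"""Percentile ranking and contact selection for evolutionary couplings.

Raw coupling scores from different inference pipelines live on different
scales, so they are first converted to percentile ranks within their own
table; a single rank threshold tau (default 0.98, i.e. the top 2% of
pairs) then selects which pairs become contacts.  The kept pairs form a
weighted contact network whose edge weights are the ranks themselves —
the spring strength of each non-bonded contact in the sequence-based
elastic model attenuates with coupling strength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .io import CouplingTable

__all__ = [
    "ContactNetwork",
    "EmptyNetworkWarning",
    "percentile_rank",
    "threshold_contacts",
    "sweep_threshold",
    "DEFAULT_TAU",
    "DEFAULT_MIN_SEPARATION",
    "SWEEP_TAUS",
]

DEFAULT_TAU = 0.98
DEFAULT_MIN_SEPARATION = 4
#: threshold sweep grid: 0.92 .. 0.99 in steps of 0.01
SWEEP_TAUS = tuple(np.round(np.arange(0.92, 0.995, 0.01), 2))


class EmptyNetworkWarning(UserWarning):
    """Thresholding removed every pair; the elastic model reduces to the chain."""


@dataclass
class ContactNetwork:
    """Thresholded, rank-weighted residue contacts on an N-residue sequence."""

    length: int
    contacts: list[tuple[int, int, float]] = field(default_factory=list)
    threshold: float = 0.0

    def __post_init__(self) -> None:
        for i, j, w in self.contacts:
            if not (1 <= i < j <= self.length):
                raise ValueError(f"contact ({i}, {j}) outside [1, {self.length}]")
            if not (self.threshold < w <= 1.0):
                raise ValueError(
                    f"contact weight {w} must lie in ({self.threshold}, 1]"
                )
        pairs = [(i, j) for i, j, _ in self.contacts]
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate contacts")

    def __len__(self) -> int:
        return len(self.contacts)


def percentile_rank(scores: Sequence[float]) -> np.ndarray:
    """Percentile rank of each score within the list, in input order.

    ``rank(s) = #(scores <= s) / len(scores)``; ties share the maximum
    rank, so equal scores always fall on the same side of a threshold.
    The result lies in ``(0, 1]`` with the maximum exactly 1.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty score list")
    if not np.all(np.isfinite(arr)):
        raise ValueError("scores must be finite")
    return rankdata(arr, method="max") / arr.size


def _entry_ranks(table: CouplingTable, rank_universe: str) -> np.ndarray:
    scores = table.scores()
    if rank_universe == "file":
        return percentile_rank(scores)
    if rank_universe == "all_pairs":
        # pairs absent from the file count as -inf scores below every entry
        total = table.length * (table.length - 1) // 2
        n_missing = total - scores.size
        return (rankdata(scores, method="max") + n_missing) / total
    raise ValueError(f"rank_universe must be 'file' or 'all_pairs', got {rank_universe!r}")


def threshold_contacts(
    table: CouplingTable,
    tau: float = DEFAULT_TAU,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    rank_universe: str = "file",
) -> ContactNetwork:
    """Select the top-ranked couplings as rank-weighted contacts.

    A pair is kept iff its percentile rank exceeds ``tau`` and its sequence
    separation ``|i - j|`` is at least ``min_separation`` (closer pairs are
    the backbone chain term's job).  ``rank_universe`` controls whether
    ranks are taken over the entries present in the file (servers truncate
    their pair lists differently) or over all N(N-1)/2 possible pairs with
    missing pairs ranked below every present one.
    """
    if not (0.0 <= tau < 1.0):
        raise ValueError(f"tau must lie in [0, 1), got {tau}")
    if len(table) == 0:
        raise ValueError("coupling table has no entries")
    ranks = _entry_ranks(table, rank_universe)
    contacts = [
        (i, j, float(r))
        for (i, j, _), r in zip(table.entries, ranks)
        if r > tau and j - i >= min_separation
    ]
    if not contacts:
        warnings.warn(
            f"no couplings survive tau={tau} with min_separation={min_separation}; "
            "the model reduces to the pure chain",
            EmptyNetworkWarning,
            stacklevel=2,
        )
    return ContactNetwork(length=table.length, contacts=contacts, threshold=tau)


def sweep_threshold(
    table: CouplingTable,
    reference,
    taus: Sequence[float] = SWEEP_TAUS,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    rank_universe: str = "file",
) -> list[tuple[float, float]]:
    """Correlation of the sequence-model profile with a reference, per tau.

    ``reference`` is a fluctuation profile (or plain msf array) of the same
    length, typically from the structure model or experiment.  Each tau is
    evaluated by running the full sequence-based model at that threshold.
    """
    from .elastic import pearson, seq_gnm  # local import: couplings <-> elastic

    ref = np.asarray(getattr(reference, "msf", reference), dtype=float)
    if ref.shape != (table.length,):
        raise ValueError(
            f"reference length {ref.shape} does not match table length {table.length}"
        )
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", EmptyNetworkWarning)
        for tau in taus:
            prof = seq_gnm(
                table, tau=tau, min_separation=min_separation, rank_universe=rank_universe
            )
            out.append((float(tau), pearson(prof.msf, ref)))
    return out
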