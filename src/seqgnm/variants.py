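"""Mapping missense variants onto fluctuation profiles and bin enrichment.

Disease-associated substitutions cluster at rigid (low-fluctuation) sites,
neutral ones at flexible sites.  To quantify this without per-protein
scale effects, every residue's fluctuation is expressed as a percentile
rank within its own protein; variant sites are then binned into five
percentile bins of width 0.2 and compared against the background
distribution of all residue sites pooled across proteins.  The
observed/expected ratio per bin is the enrichment; departure from
uniformity is tested both with a chi-square goodness-of-fit (4 df) and a
seeded permutation test that redraws variant-sized samples from the
background.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .elastic import FluctuationProfile
from .io import VariantRecord, VariantSet

__all__ = [
    "BIN_EDGES",
    "MappedVariant",
    "EnrichmentResult",
    "map_variants",
    "enrichment",
]

#: percentile bins of width 0.2; [lo, hi) with the last bin closed at 1.0
BIN_EDGES = np.array([0.0, 0.2, 0.4, 0.6, 0.8, 1.0])


@dataclass(frozen=True)
class MappedVariant:
    record: VariantRecord
    percentile: float


@dataclass
class EnrichmentResult:
    """Observed/expected variant counts per percentile bin, per class."""

    bin_edges: np.ndarray
    observed: dict[str, np.ndarray]
    expected: dict[str, np.ndarray]
    ratio: dict[str, np.ndarray]
    chi2_stat: dict[str, float]
    chi2_p: dict[str, float]
    permutation_p: dict[str, float | None]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cls in self.observed:
            for b in range(len(self.bin_edges) - 1):
                rows.append(
                    {
                        "class": cls,
                        "bin_lo": self.bin_edges[b],
                        "bin_hi": self.bin_edges[b + 1],
                        "observed": self.observed[cls][b],
                        "expected": self.expected[cls][b],
                        "ratio": self.ratio[cls][b],
                    }
                )
        return pd.DataFrame(rows)


def map_variants(
    vs: VariantSet,
    profiles: Mapping[str, FluctuationProfile],
    mappings: Mapping[str, Mapping[int, int]] | None = None,
) -> tuple[list[MappedVariant], list[tuple[VariantRecord, str]]]:
    """Attach the site percentile fluctuation to each variant record.

    ``profiles`` maps protein id -> profile.  ``mappings`` optionally maps
    protein id -> {author position -> 1-based profile index} for proteins
    whose author numbering differs from profile order (see
    ``ProteinChain.mapping_table``).  Records whose position falls off the
    profile are returned in the second list with a reason, never silently
    dropped; an unknown protein id is an error.
    """
    mapped: list[MappedVariant] = []
    unmapped: list[tuple[VariantRecord, str]] = []
    for rec in vs.records:
        if rec.protein not in profiles:
            raise KeyError(f"no profile for protein {rec.protein!r}")
        profile = profiles[rec.protein]
        pos = rec.position
        if mappings is not None and rec.protein in mappings:
            table = mappings[rec.protein]
            if pos not in table:
                unmapped.append((rec, f"position {pos} absent from mapping table"))
                continue
            pos = table[pos]
        if not (1 <= pos <= profile.n_residues):
            unmapped.append(
                (rec, f"position {pos} outside profile of length {profile.n_residues}")
            )
            continue
        mapped.append(MappedVariant(record=rec, percentile=float(profile.percentile[pos - 1])))
    return mapped, unmapped


def _bin_counts(values: np.ndarray) -> np.ndarray:
    # np.histogram closes the last bin, so percentile 1.0 lands in [0.8, 1.0]
    return np.histogram(values, bins=BIN_EDGES)[0].astype(float)


def _chi2_gof(observed: np.ndarray, expected: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Chi-square goodness-of-fit over bins with nonzero expectation."""
    ok = expected > 0
    obs, exp = observed[ok], expected[ok]
    # rescale so totals match exactly on the included bins (scipy requires it)
    exp = exp * obs.sum() / exp.sum()
    stat, p = stats.chisquare(obs, exp)
    return float(stat), float(p), ok


def enrichment(
    mapped: Sequence[MappedVariant],
    background: Sequence[float],
    n_permutations: int = 10_000,
    seed: int | np.random.Generator | None = 0,
) -> EnrichmentResult:
    """Observed-to-expected enrichment of variant sites across percentile bins.

    ``background`` pools the percentile fluctuations of every residue site
    across all proteins; the expected count in bin b for a class with n
    variants is ``n × (background fraction in b)``.  For each class the
    chi-square statistic is complemented by a permutation p-value obtained
    by drawing ``n_permutations`` variant-sized multinomial samples from
    the background bin distribution (``n_permutations = 0`` skips it).
    Bins with zero expected count get an undefined (NaN) ratio and are
    excluded from the chi-square.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background must be non-empty")
    if np.any((bg < 0) | (bg > 1)):
        raise ValueError("background percentiles must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bg_counts = _bin_counts(bg)
    bg_frac = bg_counts / bg_counts.sum()

    by_class: dict[str, list[float]] = {}
    for mv in mapped:
        by_class.setdefault(mv.record.label, []).append(mv.percentile)

    observed: dict[str, np.ndarray] = {}
    expected: dict[str, np.ndarray] = {}
    ratio: dict[str, np.ndarray] = {}
    chi2_stat: dict[str, float] = {}
    chi2_p: dict[str, float] = {}
    permutation_p: dict[str, float | None] = {}
    for cls, pcts in by_class.items():
        obs = _bin_counts(np.asarray(pcts))
        n = obs.sum()
        exp = bg_frac * n
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(exp > 0, obs / np.where(exp > 0, exp, 1.0), np.nan)
        stat, p, _ = _chi2_gof(obs, exp)
        observed[cls], expected[cls], ratio[cls] = obs, exp, r
        chi2_stat[cls], chi2_p[cls] = stat, p
        if n_permutations > 0:
            draws = rng.multinomial(int(n), bg_frac, size=n_permutations).astype(float)
            ok = bg_frac > 0
            perm_stats = (
                (draws[:, ok] - exp[ok]) ** 2 / exp[ok]
            ).sum(axis=1)
            permutation_p[cls] = float(
                (1 + np.sum(perm_stats >= stat)) / (1 + n_permutations)
            )
        else:
            permutation_p[cls] = None

    return EnrichmentResult(
        bin_edges=BIN_EDGES.copy(),
        observed=observed,
        expected=expected,
        ratio=ratio,
        chi2_stat=chi2_stat,
        chi2_p=chi2_p,
        permutation_p=permutation_p,
    )
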