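"""Plain-text I/O for the formats the tool touches.

Four families of input/output are handled here:

* PDB coordinate files, reduced to the Cα trace plus the experimental
  B-factor column (the structural reference for the sequence-based model);
* evolutionary-coupling score tables in the common three-column
  ``i j score`` dialects (contact-probability and direct-information style);
* labelled missense-variant tables (TSV);
* per-residue fluctuation profiles (TSV), the tool's main output.

Residue identity in a PDB file is the triple (chain id, residue number,
insertion code).  Profile indices are 1-based positions in file order,
decoupled from author numbering; :meth:`ProteinChain.mapping_table` gives
the translation so variant positions expressed in author numbering can be
placed on a profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Residue",
    "ProteinChain",
    "CouplingTable",
    "VariantRecord",
    "VariantSet",
    "PDBFormatError",
    "EmptySelectionError",
    "CouplingFormatError",
    "read_ca_trace",
    "write_ca_trace",
    "read_coupling_table",
    "read_variants",
    "write_variants",
    "write_profile",
    "read_profile",
]

VARIANT_COLUMNS = ("protein", "position", "ref", "alt", "label")
VARIANT_LABELS = ("disease", "neutral")

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}


class PDBFormatError(ValueError):
    """The PDB text does not contain what the Cα-trace reader needs."""


class EmptySelectionError(ValueError):
    """A chain filter matched nothing in the file."""


class CouplingFormatError(ValueError):
    """A coupling table line or header violates the dialect contract."""


@dataclass(frozen=True)
class Residue:
    """Identity of one residue site: (chain, author number, insertion code, aa)."""

    chain_id: str
    seqnum: int
    icode: str = ""
    aa: str = "X"


@dataclass
class ProteinChain:
    """Ordered Cα trace for one or more chains of a protein.

    ``coords`` is an (N, 3) array in Å; ``exp_bfactor`` holds the
    crystallographic B-factor column (Å²) when present.
    """

    residues: list[Residue]
    coords: np.ndarray
    exp_bfactor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.residues)
        if n < 2:
            raise ValueError(f"a chain needs at least 2 residues, got {n}")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinates shape {self.coords.shape} does not match {n} residues"
            )
        if self.exp_bfactor is not None:
            self.exp_bfactor = np.asarray(self.exp_bfactor, dtype=float)
            if self.exp_bfactor.shape != (n,):
                raise ValueError("experimental B-factor length mismatch")
            if np.any(self.exp_bfactor < 0):
                raise ValueError("experimental B-factors must be non-negative")
        for cid, group in self._runs():
            nums = [r.seqnum for r in group]
            if any(b <= a for a, b in zip(nums, nums[1:])):
                raise ValueError(
                    f"residue numbers not strictly increasing within chain {cid!r}"
                )

    def _runs(self) -> list[tuple[str, list[Residue]]]:
        runs: list[tuple[str, list[Residue]]] = []
        for r in self.residues:
            if runs and runs[-1][0] == r.chain_id:
                runs[-1][1].append(r)
            else:
                runs.append((r.chain_id, [r]))
        return runs

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def chain_lengths(self) -> list[int]:
        """Length of each consecutive chain segment, in file order."""
        return [len(group) for _, group in self._runs()]

    def mapping_table(self) -> pd.DataFrame:
        """Author numbering -> 1-based profile index, one row per residue."""
        return pd.DataFrame(
            {
                "index": np.arange(1, self.n_residues + 1),
                "chain": [r.chain_id for r in self.residues],
                "resseq": [r.seqnum for r in self.residues],
                "icode": [r.icode for r in self.residues],
                "aa": [r.aa for r in self.residues],
            }
        )

    def index_of(self, chain_id: str, seqnum: int, icode: str = "") -> int:
        """1-based profile index of the residue (chain, seqnum, icode)."""
        for i, r in enumerate(self.residues, start=1):
            if r.chain_id == chain_id and r.seqnum == seqnum and r.icode == icode:
                return i
        raise KeyError(f"no residue ({chain_id!r}, {seqnum}, {icode!r})")


@dataclass
class CouplingTable:
    """Raw evolutionary-coupling scores for residue pairs of an N-residue query.

    Pairs are stored canonically with ``i < j`` (1-based); duplicates are
    forbidden and self-pairs rejected at read time.
    """

    length: int
    entries: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("coupling table needs length >= 2")
        seen: dict[tuple[int, int], float] = {}
        canonical: list[tuple[int, int, float]] = []
        for i, j, s in self.entries:
            i, j = int(i), int(j)
            if i == j:
                raise CouplingFormatError(f"self-pair ({i}, {j}) is not a coupling")
            if i > j:
                i, j = j, i
            if not (1 <= i < j <= self.length):
                raise CouplingFormatError(
                    f"pair ({i}, {j}) outside [1, {self.length}]"
                )
            s = float(s)
            if not math.isfinite(s):
                raise CouplingFormatError(f"non-finite score for pair ({i}, {j})")
            if (i, j) in seen:
                kind = "conflicting" if seen[(i, j)] != s else "repeated"
                raise CouplingFormatError(f"duplicate pair ({i}, {j}) with {kind} score")
            seen[(i, j)] = s
            canonical.append((i, j, s))
        self.entries = canonical

    def __len__(self) -> int:
        return len(self.entries)

    def scores(self) -> np.ndarray:
        return np.array([s for _, _, s in self.entries], dtype=float)


@dataclass(frozen=True)
class VariantRecord:
    protein: str
    position: int
    ref: str
    alt: str
    label: str


@dataclass
class VariantSet:
    """Labelled missense variants, optionally with extra precomputed features.

    ``features`` carries any additional columns of the input table (e.g.
    conservation rates) aligned row-by-row with ``records``; the package
    never computes such features itself.
    """

    records: list[VariantRecord]
    features: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for r in self.records:
            if r.position < 1:
                raise ValueError(f"variant position must be >= 1, got {r.position}")
            if r.label not in VARIANT_LABELS:
                raise ValueError(f"label must be one of {VARIANT_LABELS}, got {r.label!r}")
        if self.features is not None and len(self.features) != len(self.records):
            raise ValueError("feature table length does not match records")

    def __len__(self) -> int:
        return len(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])


# ---------------------------------------------------------------------------
# PDB Cα trace


def read_ca_trace(pdb_text: str, chains: Sequence[str] | None = None) -> ProteinChain:
    """Extract the Cα trace (and B-factor column) from PDB-format text.

    Only ATOM records contribute; HETATM is ignored.  For residues with
    alternate locations the first-listed Cα is kept.  ``chains`` selects and
    orders chain ids; the result concatenates them in the given order, which
    is how oligomer (multi-chain) reference models are assembled.
    """
    try:
        structure = gemmi.read_pdb_string(pdb_text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"unreadable PDB text: {exc}") from exc
    if len(structure) == 0:
        raise PDBFormatError("no model found in PDB text")
    model = structure[0]
    by_name: dict[str, list[gemmi.Chain]] = {}
    order: list[str] = []
    for ch in model:
        by_name.setdefault(ch.name, []).append(ch)
        if ch.name not in order:
            order.append(ch.name)

    if chains is None:
        selected = order
    else:
        selected = list(chains)
        missing = [c for c in selected if c not in by_name]
        if missing:
            raise EmptySelectionError(
                f"chain filter {missing} matched nothing (file has {order})"
            )

    residues: list[Residue] = []
    coords: list[list[float]] = []
    bfac: list[float] = []
    for cid in selected:
        for ch in by_name[cid]:
            for res in ch:
                if res.het_flag != "A":
                    continue
                ca = next((a for a in res if a.name == "CA"), None)
                if ca is None:
                    continue
                info = gemmi.find_tabulated_residue(res.name)
                one = info.one_letter_code.upper() if info else "X"
                residues.append(
                    Residue(
                        chain_id=cid,
                        seqnum=res.seqid.num,
                        icode=res.seqid.icode.strip(),
                        aa=one if one.isalpha() else "X",
                    )
                )
                coords.append([ca.pos.x, ca.pos.y, ca.pos.z])
                bfac.append(ca.b_iso)
    if not residues:
        raise PDBFormatError("no Cα ATOM records in the selected chains")
    return ProteinChain(residues=residues, coords=np.array(coords), exp_bfactor=np.array(bfac))


def write_ca_trace(chain: ProteinChain) -> str:
    """Serialize a Cα trace as minimal PDB ATOM records (round-trips through
    :func:`read_ca_trace`)."""
    lines = []
    b = chain.exp_bfactor if chain.exp_bfactor is not None else np.zeros(chain.n_residues)
    prev_cid = None
    for serial, (res, xyz, bi) in enumerate(zip(chain.residues, chain.coords, b), start=1):
        if prev_cid is not None and res.chain_id != prev_cid:
            lines.append("TER")
        prev_cid = res.chain_id
        resname = _AA3.get(res.aa, "UNK")
        lines.append(
            f"ATOM  {serial % 100000:5d}  CA  {resname:>3s} {res.chain_id[:1]:1s}"
            f"{res.seqnum:4d}{(res.icode or ' '):1s}   "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{min(bi, 999.99):6.2f}"
            f"           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Coupling tables


def _parse_triplet_lines(text: str) -> list[tuple[int, int, float]]:
    entries = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 3:
            raise CouplingFormatError(f"line {lineno}: expected 'i j score', got {raw!r}")
        try:
            i, j, s = int(parts[0]), int(parts[1]), float(parts[2])
        except ValueError as exc:
            raise CouplingFormatError(f"line {lineno}: {exc}") from exc
        entries.append((i, j, s))
    return entries


def read_coupling_table(text: str, dialect: str = "generic", length: int | None = None) -> CouplingTable:
    """Parse a residue-pair coupling score table.

    Dialects
    --------
    ``generic`` / ``raptorx``
        Whitespace-separated ``i j score`` triplets, ``#`` comments.  The
        raptorx flavour carries contact probabilities but is syntactically
        identical.
    ``evcouplings``
        Delimited table with a header row; the columns named ``i``, ``j``
        and ``di`` (case-insensitive; ``cn`` or ``score`` accepted as the
        score column) are extracted.

    Indices are 1-based sequence positions; ``length`` is the number of
    residues in the query sequence and bounds the indices.
    """
    if length is None or length < 2:
        raise ValueError("the query sequence length (>= 2) is required")
    dialect = dialect.lower()
    if dialect in ("generic", "raptorx"):
        entries = _parse_triplet_lines(text)
    elif dialect == "evcouplings":
        sep = "," if "," in text.splitlines()[0] else None
        df = pd.read_csv(StringIO(text), sep=sep, engine="python", comment="#")
        cols = {c.lower().strip(): c for c in df.columns}
        if "i" not in cols or "j" not in cols:
            raise CouplingFormatError("evcouplings header must name columns 'i' and 'j'")
        score_col = next((cols[k] for k in ("di", "cn", "score") if k in cols), None)
        if score_col is None:
            raise CouplingFormatError("no score column ('di', 'cn' or 'score') in header")
        entries = list(
            zip(df[cols["i"]].astype(int), df[cols["j"]].astype(int), df[score_col].astype(float))
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return CouplingTable(length=length, entries=entries)


# ---------------------------------------------------------------------------
# Variant tables


def read_variants(text: str) -> VariantSet:
    """Read a variant TSV with header ``protein  position  ref  alt  label``.

    Any further columns are kept as a per-variant feature table.
    """
    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table is missing columns {missing}")
    records = [
        VariantRecord(
            protein=str(row.protein),
            position=int(row.position),
            ref=str(row.ref),
            alt=str(row.alt),
            label=str(row.label),
        )
        for row in df.itertuples()
    ]
    extra = [c for c in df.columns if c not in VARIANT_COLUMNS]
    features = df[extra].reset_index(drop=True) if extra else None
    return VariantSet(records=records, features=features)


def write_variants(vs: VariantSet) -> str:
    df = pd.DataFrame(
        {
            "protein": [r.protein for r in vs.records],
            "position": [r.position for r in vs.records],
            "ref": [r.ref for r in vs.records],
            "alt": [r.alt for r in vs.records],
            "label": [r.label for r in vs.records],
        }
    )
    if vs.features is not None:
        df = pd.concat([df, vs.features.reset_index(drop=True)], axis=1)
    return df.to_csv(sep="\t", index=False)


# ---------------------------------------------------------------------------
# Fluctuation profiles


def write_profile(profile, header_lines: Iterable[str] = ()) -> str:
    """Serialize a fluctuation profile as TSV: index, msf, bfactor, percentile.

    Floats are written with 17 significant digits so a write/read round trip
    is exact to double precision.
    """
    if profile.n_residues == 0:
        raise ValueError("refusing to write an empty profile")
    out = [f"# {line}" for line in header_lines]
    out.append("index\tmsf\tbfactor\tpercentile")
    for k in range(profile.n_residues):
        out.append(
            f"{k + 1}\t{profile.msf[k]:.17g}\t{profile.bfactor[k]:.17g}"
            f"\t{profile.percentile[k]:.17g}"
        )
    return "\n".join(out) + "\n"


def read_profile(text: str):
    """Read a profile TSV written by :func:`write_profile`."""
    from .elastic import FluctuationProfile  # local import: io <-> elastic

    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    for col in ("index", "msf", "percentile"):
        if col not in df.columns:
            raise ValueError(f"profile table is missing column {col!r}")
    if len(df) == 0:
        raise ValueError("profile table has no rows")
    return FluctuationProfile(
        msf=df["msf"].to_numpy(float), percentile=df["percentile"].to_numpy(float)
    )
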