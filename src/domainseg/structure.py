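"""Structural features of a single predicted protein chain.

Parses coordinate files (mmCIF/PDB) and AFDB-style predicted-aligned-error
(PAE) JSON, and derives the geometric quantities the rest of the pipeline
consumes: the minimal heavy-atom inter-residue distance matrix, the
symmetrized PAE matrix, secondary-structure elements from DSSP codes, and
per-residue long-range contact sets.

Conventions
-----------
Residues are renumbered 1..L in file order; all residue numbers in this
package are 1-based, intervals are half-open over those numbers, and the
matrix entry for residue pair (i, j) is ``values[i-1, j-1]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.distance import cdist

#: channels a pair matrix may carry
CHANNELS = (
    "distance",
    "pae",
    "position_i",
    "position_j",
    "evidence_seq",
    "evidence_struct",
    "probability",
    "target",
)

_DSSP_ALPHABET = set("HBEGITS- ")
_STRAND_CODES = set("BE")
_HELIX_CODES = set("GHI")

MIN_STRAND_LEN = 3
MIN_HELIX_LEN = 6


@dataclass
class ChainModel:
    """One predicted protein chain.

    ``heavy_atom_coords[i]`` holds the (n_atoms, 3) float array of all
    non-hydrogen atom positions (Å) of residue ``residue_ids[i]``.
    """

    residue_ids: np.ndarray  # (L,) int, contiguous 1..L
    sequence: str
    heavy_atom_coords: list[np.ndarray]
    plddt: np.ndarray  # (L,) float in [0, 100]

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.plddt = np.asarray(self.plddt, dtype=float)
        L = len(self.residue_ids)
        if not np.array_equal(self.residue_ids, np.arange(1, L + 1)):
            raise ValueError("residue_ids must be contiguous 1..L")
        if len(self.sequence) != L or len(self.heavy_atom_coords) != L or len(self.plddt) != L:
            raise ValueError("per-residue field lengths disagree")
        for rid, xyz in zip(self.residue_ids, self.heavy_atom_coords):
            if len(xyz) == 0:
                raise ValueError(f"residue {rid} has no heavy atoms")

    @property
    def L(self) -> int:
        return len(self.residue_ids)


@dataclass
class PairMatrix:
    """An L×L residue-pair matrix with channel semantics."""

    channel: str
    values: np.ndarray
    raw: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("pair matrix must be square")

    @property
    def length(self) -> int:
        return self.values.shape[0]


class SSEKind(str, Enum):
    strand = "strand"
    helix = "helix"


@dataclass(frozen=True)
class SecondaryStructureElement:
    """A strand or helix as a half-open residue interval [start, stop)."""

    kind: SSEKind
    start: int  # 1-based
    stop: int  # exclusive

    def residues(self) -> range:
        return range(self.start, self.stop)

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True)
class ContactConfig:
    """3D-contact definition: closer than ``max_distance`` Å but more than
    ``min_sequence_separation`` residues apart in sequence."""

    max_distance: float = 6.0
    min_sequence_separation: int = 6

    def __post_init__(self) -> None:
        if self.max_distance <= 0 or self.min_sequence_separation <= 0:
            raise ValueError("contact thresholds must be positive")


def load_model(path: str | Path) -> ChainModel:
    """Read a single-chain mmCIF or PDB model.

    Residues are renumbered 1..L preserving file order; per-residue pLDDT is
    taken from the B-factor/confidence field of the first atom of each
    residue (AFDB stores the same value on every atom). Hydrogens and
    waters/ligands are dropped; only the first altloc is kept.
    """
    structure = gemmi.read_structure(str(path))
    structure.setup_entities()
    structure.remove_alternative_conformations()
    structure.remove_hydrogens()
    structure.remove_ligands_and_waters()
    model = structure[0]
    chains = [ch for ch in model if len(ch) > 0]
    if len(chains) != 1:
        names = ", ".join(ch.name for ch in chains)
        raise ValueError(f"expected a single polypeptide chain, found {len(chains)}: {names}")
    chain = chains[0]

    coords: list[np.ndarray] = []
    seq: list[str] = []
    plddt: list[float] = []
    for residue in chain:
        xyz = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in residue if not a.is_hydrogen()])
        if xyz.size == 0:
            raise ValueError(f"residue {residue.seqid.num} {residue.name} has no coordinates")
        coords.append(xyz)
        seq.append(gemmi.find_tabulated_residue(residue.name).one_letter_code.upper()
                   if gemmi.find_tabulated_residue(residue.name) else "X")
        plddt.append(residue[0].b_iso)

    L = len(coords)
    return ChainModel(
        residue_ids=np.arange(1, L + 1),
        sequence="".join(seq),
        heavy_atom_coords=coords,
        plddt=np.array(plddt),
    )


def distance_matrix(model: ChainModel) -> PairMatrix:
    """Minimal heavy-atom distance (Å) between every residue pair."""
    atoms = np.concatenate(model.heavy_atom_coords, axis=0)
    counts = np.array([len(xyz) for xyz in model.heavy_atom_coords])
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    d_atoms = cdist(atoms, atoms)
    # reduce atom-pair distances to per-residue-pair minima (atoms are
    # contiguous per residue, so two reduceat passes suffice)
    by_row = np.minimum.reduceat(d_atoms, starts, axis=0)
    out = np.minimum.reduceat(by_row, starts, axis=1)
    np.fill_diagonal(out, 0.0)
    out = np.minimum(out, out.T)  # guard symmetry against fp noise
    return PairMatrix("distance", out)


def load_pae(path: str | Path, L: int) -> PairMatrix:
    """Read an AFDB PAE JSON file (nested-list or residue1/residue2/distance
    triplet dialect) of declared size L×L.

    The raw matrix may be asymmetric; the returned matrix ``values`` is the
    elementwise-minimum symmetrization ``min(raw[i,j], raw[j,i])``, which is
    what every downstream consumer uses. The raw matrix is kept on ``.raw``.
    """
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, list):
        if len(payload) != 1:
            raise ValueError("PAE JSON list must contain exactly one record")
        payload = payload[0]
    if "predicted_aligned_error" in payload:
        raw = np.asarray(payload["predicted_aligned_error"], dtype=float)
    elif {"residue1", "residue2", "distance"} <= set(payload):
        r1 = np.asarray(payload["residue1"], dtype=int)
        r2 = np.asarray(payload["residue2"], dtype=int)
        d = np.asarray(payload["distance"], dtype=float)
        if len(r1) != L * L:
            raise ValueError(f"PAE triplet list has {len(r1)} entries, expected {L * L}")
        raw = np.empty((L, L))
        raw[r1 - 1, r2 - 1] = d
    else:
        raise ValueError("unrecognized PAE JSON dialect")
    if raw.shape != (L, L):
        raise ValueError(f"PAE matrix shape {raw.shape} does not match declared L={L}")
    if np.any(raw < 0):
        raise ValueError("PAE values must be non-negative")
    sym = np.minimum(raw, raw.T)
    return PairMatrix("pae", sym, raw=raw)


def secondary_structure(ss_codes: str) -> list[SecondaryStructureElement]:
    """Collapse a per-residue DSSP-alphabet string into strand/helix elements.

    Maximal runs of B/E of length ≥3 become strands; maximal runs of G/H/I of
    length ≥6 become helices. Shorter runs produce nothing.
    """
    bad = set(ss_codes) - _DSSP_ALPHABET
    if bad:
        raise ValueError(f"non-DSSP codes in input: {sorted(bad)}")
    elements: list[SecondaryStructureElement] = []
    i, L = 0, len(ss_codes)
    while i < L:
        c = ss_codes[i]
        if c in _STRAND_CODES:
            group, kind, min_len = _STRAND_CODES, SSEKind.strand, MIN_STRAND_LEN
        elif c in _HELIX_CODES:
            group, kind, min_len = _HELIX_CODES, SSEKind.helix, MIN_HELIX_LEN
        else:
            i += 1
            continue
        j = i
        while j < L and ss_codes[j] in group:
            j += 1
        if j - i >= min_len:
            elements.append(SecondaryStructureElement(kind, i + 1, j + 1))
        i = j
    return elements


def read_dssp_codes(path: str | Path) -> str:
    """Extract the per-residue summary (column 'S') codes from a DSSP file.

    Only the residue summary table after the ``#  RESIDUE`` header is read;
    chain breaks ('!') are skipped.
    """
    codes: list[str] = []
    in_table = False
    for line in Path(path).read_text().splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_table = True
            continue
        if not in_table or len(line) < 17:
            continue
        if line[13] == "!":
            continue
        code = line[16]
        codes.append(code if code in _DSSP_ALPHABET else "-")
    return "".join(codes)


def residue_contacts(
    model: ChainModel | None,
    cfg: ContactConfig = ContactConfig(),
    dist: PairMatrix | None = None,
) -> list[set[int]]:
    """Per-residue contact sets (1-based): j ∈ contacts(i) iff the minimal
    heavy-atom distance is < max_distance and |i−j| > min_sequence_separation.

    Accepts either a model (distances computed here) or a precomputed
    distance matrix.
    """
    if dist is None:
        if model is None:
            raise ValueError("need a model or a distance matrix")
        dist = distance_matrix(model)
    d = dist.values
    L = dist.length
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    close = (d < cfg.max_distance) & (sep > cfg.min_sequence_separation)
    return [set((np.nonzero(close[i])[0] + 1).tolist()) for i in range(L)]
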