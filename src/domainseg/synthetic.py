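"""Self-contained synthetic fixtures with planted ground truth.

Generates toy single-chain "predicted structures" (compact random blobs per
domain, extended linkers), matching PAE matrices with planted block
contrast, homology hit tables, and noisy same-domain probability matrices —
everything the pipeline consumes, so tests and examples run without any
database or download.

Geometry is deliberately unphysical (blobs, not folds): the pipeline only
consumes inter-residue distances and PAE contrast, which these fixtures
plant directly. Real predicted models differ in error structure (smoothly
varying PAE, partial disorder, shared interfaces); passing here shows
algorithmic correctness, not benchmark-level accuracy on real models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domains import DomainSet
from .evidence import SEQUENCE, STRUCTURE, HitAlignment
from .structure import ChainModel, PairMatrix

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
_AA = "".join(_THREE)


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic protein.

    ``domain_sizes`` are drawn in [60, 150] when not given; ``linker_lengths``
    (between consecutive sequence segments) default to 10. With
    ``discontinuous=True`` the first domain is split into two sequence
    segments wrapped around the second domain.
    """

    n_domains: int = 2
    domain_sizes: tuple[int, ...] | None = None
    linker_length: int = 10
    discontinuous: bool = False
    coord_jitter: float = 0.4
    pae_low: tuple[float, float] = (2.0, 5.0)
    pae_high: tuple[float, float] = (15.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_domains < 1:
            raise ValueError("need at least one domain")
        if self.domain_sizes is not None:
            if len(self.domain_sizes) != self.n_domains:
                raise ValueError("one size per domain")
            if min(self.domain_sizes) < 20:
                raise ValueError("domains must have at least 20 residues")
        if self.discontinuous and self.n_domains < 2:
            raise ValueError("a discontinuous layout needs at least two domains")


def _blob(rng: np.random.Generator, size: int, center: np.ndarray) -> np.ndarray:
    """Compact confined random walk: CA positions of one domain."""
    radius = max(8.0, 3.0 * size ** (1 / 3) + 2.0)
    pts = np.empty((size, 3))
    pos = center.copy()
    pts[0] = pos
    for t in range(1, size):
        for _ in range(50):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = pos + step
            if np.linalg.norm(cand - center) <= radius:
                pos = cand
                break
        else:
            pos = center + rng.normal(size=3)  # recenter on packing failure
        pts[t] = pos
    return pts


def make_protein(
    spec: SyntheticSpec,
) -> tuple[ChainModel, PairMatrix, DomainSet, str]:
    """Build (model, PAE, truth, ss_codes) with planted domain structure.

    Domains are compact blobs ≥25 Å apart; linkers are extended paths between
    them; PAE is low (pae_low range) within a domain and high (pae_high)
    everywhere else; secondary structure alternates helices and strands
    inside domains with loops on linkers.
    """
    rng = np.random.default_rng(spec.seed)
    sizes = (
        list(spec.domain_sizes)
        if spec.domain_sizes is not None
        else [int(rng.integers(60, 151)) for _ in range(spec.n_domains)]
    )
    # sequence layout: list of (kind, domain_index, length)
    layout: list[tuple[str, int, int]] = []
    if spec.discontinuous:
        first_part = sizes[0] // 2
        layout.append(("domain", 0, first_part))
        layout.append(("linker", -1, spec.linker_length))
        layout.append(("domain", 1, sizes[1]))
        layout.append(("linker", -1, spec.linker_length))
        layout.append(("domain", 0, sizes[0] - first_part))
        for k in range(2, spec.n_domains):
            layout.append(("linker", -1, spec.linker_length))
            layout.append(("domain", k, sizes[k]))
    else:
        for k in range(spec.n_domains):
            if k:
                layout.append(("linker", -1, spec.linker_length))
            layout.append(("domain", k, sizes[k]))

    # one blob per domain on a line, centers spaced to keep blobs ≥25 Å apart
    radii = [max(8.0, 3.0 * s ** (1 / 3) + 2.0) for s in sizes]
    centers = []
    x = 0.0
    for k, r in enumerate(radii):
        if k:
            x += radii[k - 1] + r + 25.0
        centers.append(np.array([x, 0.0, 0.0]))
    blob_pts = [_blob(rng, s, c) for s, c in zip(sizes, centers)]
    used = [0] * spec.n_domains  # residues of each blob consumed so far

    ca: list[np.ndarray] = []
    domain_id: list[int] = []
    ss: list[str] = []
    for pos_in_layout, (kind, k, length) in enumerate(layout):
        if kind == "domain":
            pts = blob_pts[k][used[k] : used[k] + length]
            used[k] += length
            ca.extend(pts)
            domain_id.extend([k] * length)
            ss.append(_domain_ss(rng, length))
        else:
            start = ca[-1] if ca else np.zeros(3)
            # aim the linker at the next domain segment's first unused point
            nxt = start + np.array([30.0, 0.0, 0.0])
            for kind2, k2, _ in layout[pos_in_layout + 1 :]:
                if kind2 == "domain":
                    nxt = blob_pts[k2][used[k2]]
                    break
            for t in range(length):
                frac = (t + 1) / (length + 1)
                ca.append(start + frac * (nxt - start) + rng.normal(scale=0.5, size=3))
            domain_id.extend([-1] * length)
            ss.append("-" * length)

    L = len(ca)
    coords = []
    for pos in ca:
        n_atoms = int(rng.integers(1, 4))
        atoms = [pos]
        for _ in range(n_atoms - 1):
            atoms.append(pos + rng.normal(scale=spec.coord_jitter, size=3) + [0, 0, 1.5])
        coords.append(np.array(atoms))
    plddt = np.where(np.array(domain_id) >= 0, 90.0, 40.0)
    seq = "".join(rng.choice(list(_AA), size=L))
    model = ChainModel(np.arange(1, L + 1), seq, coords, plddt)

    dom = np.array(domain_id)
    same = (dom[:, None] == dom[None, :]) & (dom[:, None] >= 0)
    lo, hi = spec.pae_low, spec.pae_high
    pae_vals = rng.uniform(hi[0], hi[1], size=(L, L))
    pae_vals[same] = rng.uniform(lo[0], lo[1], size=int(same.sum()))
    pae_vals = np.minimum(pae_vals, pae_vals.T)
    np.fill_diagonal(pae_vals, lo[0])
    pae = PairMatrix("pae", pae_vals, raw=pae_vals.copy())

    domains = [set((np.nonzero(dom == k)[0] + 1).tolist()) for k in range(spec.n_domains)]
    truth = DomainSet(domains, set((np.nonzero(dom < 0)[0] + 1).tolist()))
    return model, pae, truth, "".join(ss)


def _domain_ss(rng: np.random.Generator, length: int) -> str:
    """Alternate helices (8 H) and strands (4 E) separated by short loops."""
    out: list[str] = []
    helix = bool(rng.integers(0, 2))
    while len(out) < length:
        run = "H" * 8 if helix else "E" * 4
        out.extend(run)
        out.extend("--")
        helix = not helix
    return "".join(out[:length])


def make_hits(
    truth: DomainSet,
    flavor: str = SEQUENCE,
    n_decoys: int = 0,
    seed: int = 0,
) -> list[HitAlignment]:
    """Per-domain homology hits with planted coverage.

    Each true domain gets 1–5 hits covering a contiguous 60–100% stretch of
    it, scored high (sequence probability 60–99, or Z 8–30). Decoy hits
    straddle a boundary between consecutive domains at low score.
    """
    if flavor not in (SEQUENCE, STRUCTURE):
        raise ValueError(f"unknown flavor {flavor!r}")
    rng = np.random.default_rng(seed)
    hits: list[HitAlignment] = []
    for k, domain in enumerate(truth.domains):
        residues = sorted(domain)
        for j in range(int(rng.integers(1, 6))):
            frac = rng.uniform(0.6, 1.0)
            n = max(20, int(frac * len(residues)))
            n = min(n, len(residues))
            start = int(rng.integers(0, len(residues) - n + 1))
            picked = residues[start : start + n]
            score = float(rng.uniform(60, 99)) if flavor == SEQUENCE else float(rng.uniform(8, 30))
            mapping = {q: i + 1 for i, q in enumerate(picked)}
            hits.append(HitAlignment(flavor, f"d{k + 1}_{flavor[:3]}{j + 1}", score, mapping))
    for j in range(n_decoys):
        if len(truth.domains) < 2:
            break
        k = int(rng.integers(0, len(truth.domains) - 1))
        left = sorted(truth.domains[k])[-25:]
        right = sorted(truth.domains[k + 1])[:25]
        picked = left + right
        score = 25.0 if flavor == SEQUENCE else 2.5
        mapping = {q: i + 1 for i, q in enumerate(picked)}
        hits.append(HitAlignment(flavor, f"decoy{j + 1}_{flavor[:3]}", score, mapping))
    return hits


def make_probability(
    truth: DomainSet, L: int, flip_rate: float = 0.0, seed: int = 0
) -> PairMatrix:
    """Noisy stand-in for the network output.

    Same-domain pixels draw from a high mode (0.55 + 0.45·Beta(8,2)), all
    others from a low mode (0.45·Beta(2,8)); a ``flip_rate`` fraction of
    pixels swaps mode. With flip_rate 0, thresholding at 0.5 recovers the
    planted target exactly.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    dom_of = truth.domain_of()
    labels = np.array([dom_of.get(r, -1) for r in range(1, L + 1)])
    same = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    flip = rng.random((L, L)) < flip_rate
    use_high = same ^ flip
    high = 0.55 + 0.45 * rng.beta(8, 2, size=(L, L))
    low = 0.45 * rng.beta(2, 8, size=(L, L))
    vals = np.where(use_high, high, low)
    vals = np.triu(vals, 1)
    vals = vals + vals.T
    diag_high = 0.55 + 0.45 * rng.beta(8, 2, size=L)
    diag_low = 0.45 * rng.beta(2, 8, size=L)
    np.fill_diagonal(vals, np.where(labels >= 0, diag_high, diag_low))
    return PairMatrix("probability", vals)


@dataclass
class SuiteProtein:
    """One member of the seeded benchmark suite, fully featurized."""

    model: ChainModel
    pae: PairMatrix
    truth: DomainSet
    ss_codes: str
    hits: list[HitAlignment]
    channels: np.ndarray  # (24, L, L)
    cluster_id: str


def make_suite(n_proteins: int = 30, seed: int = 0) -> list[SuiteProtein]:
    """The seeded synthetic benchmark suite.

    Domain-count mixture 1/2/3 at 30/40/30% (multidomain-dominated, as in
    real classified-structure sets), sizes 60–140 residues, 10-residue
    linkers, sequence and structure hits per domain, and roughly one in
    fifteen proteins carrying a discontinuous (wrapped) first domain. Each
    protein is its own redundancy cluster.
    """
    rng = np.random.default_rng(seed)
    # imported here: pipeline depends on several sibling modules
    from .pipeline import build_channels

    suite: list[SuiteProtein] = []
    for i in range(n_proteins):
        nd = int(rng.choice([1, 2, 3], p=[0.3, 0.4, 0.3]))
        sizes = tuple(int(rng.integers(60, 141)) for _ in range(nd))
        discont = nd >= 2 and rng.random() < 1 / 15
        spec = SyntheticSpec(
            n_domains=nd,
            domain_sizes=sizes,
            discontinuous=discont,
            seed=int(rng.integers(0, 2**31)),
        )
        model, pae, truth, ss = make_protein(spec)
        hits = make_hits(truth, SEQUENCE, seed=int(rng.integers(0, 2**31))) + make_hits(
            truth, STRUCTURE, seed=int(rng.integers(0, 2**31))
        )
        channels = build_channels(model, pae, hits)
        suite.append(
            SuiteProtein(model, pae, truth, ss, hits, channels, f"cluster{i:02d}")
        )
    return suite


# ---------------------------------------------------------------------------
# text-format writers for fixture files


def write_pdb(model: ChainModel, path) -> None:
    """Write the chain as a minimal single-chain PDB file (pLDDT in the
    B-factor column, atoms named CA/CB/CG)."""
    names = ["CA", "CB", "CG"]
    lines = []
    serial = 1
    for i, xyz in enumerate(model.heavy_atom_coords):
        res3 = _THREE.get(model.sequence[i], "UNK")
        for a, pos in enumerate(xyz):
            name = names[a % 3]
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s}{res3:>4s} A{i + 1:4d}    "
                f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{model.plddt[i]:6.2f}"
                f"          {'C':>2s}"
            )
            serial += 1
    lines.append("TER")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pae_json(pae: PairMatrix, path, dialect: str = "nested") -> None:
    """Write a PAE matrix in either AFDB JSON dialect (uses ``.raw``)."""
    import json

    raw = pae.raw if pae.raw is not None else pae.values
    L = raw.shape[0]
    if dialect == "nested":
        payload = [{"predicted_aligned_error": raw.tolist()}]
    elif dialect == "triplet":
        r1, r2 = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
        payload = [{
            "residue1": r1.ravel().tolist(),
            "residue2": r2.ravel().tolist(),
            "distance": raw.ravel().tolist(),
        }]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        json.dump(payload, fh)
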