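"""Homology evidence channels.

Sequence-profile hits (HH-suite style, scored by probability 0–100) and
structural-alignment hits (Dali style, scored by Z) against a classified
domain database are filtered, partitioned by reference-domain boundaries,
grouped by query coverage, and rendered into at most ten residue-pair
evidence matrices per source.

Scores are put on a comparable [0, 1) scale before entering the matrices:
sequence probabilities are divided by 100, structural Z-scores are squashed
by z/(z+10). Both transforms are monotone and isolated in
:func:`scaled_score`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .ranges import parse_range_intervals
from .structure import ChainModel, PairMatrix

SEQUENCE = "sequence"
STRUCTURE = "structure"


@dataclass
class HitAlignment:
    """One homology hit: a scored, one-to-one query↔hit residue mapping.

    ``mapping`` maps 1-based query residue numbers to 1-based hit residue
    numbers. Sequence hits carry an HH-suite probability in [0, 100];
    structure hits carry a Dali Z-score ≥ 0.
    """

    source: str
    ref_domain_id: str
    score: float
    mapping: dict[int, int]

    def __post_init__(self) -> None:
        if self.source not in (SEQUENCE, STRUCTURE):
            raise ValueError(f"unknown hit source {self.source!r}")
        if self.score < 0:
            raise ValueError("hit score must be non-negative")
        if self.source == SEQUENCE and self.score > 100:
            raise ValueError("sequence probability exceeds 100")

    @property
    def coverage(self) -> frozenset[int]:
        """Query residues covered by this hit."""
        return frozenset(self.mapping)

    @property
    def aligned_length(self) -> int:
        return len(self.mapping)


@dataclass(frozen=True)
class ReferenceDomainDefinition:
    """A classified domain on a reference chain, as inclusive residue ranges."""

    domain_id: str
    chain_ranges: tuple[tuple[int, int], ...]

    def __contains__(self, residue: int) -> bool:
        return any(s <= residue <= e for s, e in self.chain_ranges)


@dataclass
class EvidenceGroup:
    """Hits of one source whose query coverages barely overlap."""

    hits: list[HitAlignment]

    @property
    def source(self) -> str:
        return self.hits[0].source

    @property
    def coverage(self) -> set[int]:
        out: set[int] = set()
        for h in self.hits:
            out |= h.coverage
        return out

    @property
    def best_score(self) -> float:
        return max(h.score for h in self.hits)


@dataclass(frozen=True)
class AcceptabilityConfig:
    """Per-source thresholds deciding which hits count as evidence.

    The exact published criteria are not printed here; these defaults are
    deliberately permissive placeholders and every threshold is meant to be
    tuned per database.
    """

    seq_min_probability: float = 20.0
    seq_min_aligned: int = 10
    struct_min_z: float = 2.0
    struct_min_aligned: int = 20

    def accepts(self, hit: HitAlignment) -> bool:
        if hit.source == SEQUENCE:
            return hit.score >= self.seq_min_probability and hit.aligned_length >= self.seq_min_aligned
        return hit.score >= self.struct_min_z and hit.aligned_length >= self.struct_min_aligned


def scaled_score(hit: HitAlignment) -> float:
    """Map a hit score into [0, 1): probability/100 or z/(z+10)."""
    if hit.source == SEQUENCE:
        return hit.score / 100.0
    return hit.score / (hit.score + 10.0)


def hit_sort_key(hit: HitAlignment):
    """Rank hits by score descending, ties broken by reference domain id."""
    return (-hit.score, hit.ref_domain_id)


def partition_hit_by_reference_domains(
    chain_hit: HitAlignment, defs: Sequence[ReferenceDomainDefinition]
) -> list[HitAlignment]:
    """Split a whole-chain hit into per-reference-domain hits.

    Each output keeps only the mapping pairs whose *hit* residue falls inside
    that domain's ranges; domains with no mapped residue produce nothing.
    The score is inherited unchanged.
    """
    out: list[HitAlignment] = []
    for d in defs:
        sub = {q: h for q, h in chain_hit.mapping.items() if h in d}
        if sub:
            out.append(
                HitAlignment(chain_hit.source, d.domain_id, chain_hit.score, sub)
            )
    return out


def iterative_structural_alignment(
    query: ChainModel,
    hit_id: str,
    aligner: Callable[[Sequence[int], str], HitAlignment | None],
    min_remaining: int = 20,
) -> list[HitAlignment]:
    """Repeatedly align a hit to the yet-unaligned part of the query.

    Mirrors the iterative structural-search loop used when a query contains
    several copies of one domain: the residues aligned in earlier rounds are
    excluded and the remainder re-searched until the aligner finds nothing or
    fewer than ``min_remaining`` query residues remain. Returned alignments
    have pairwise-disjoint query coverage.
    """
    remaining = list(range(1, query.L + 1))
    results: list[HitAlignment] = []
    iteration = 0
    while len(remaining) >= min_remaining:
        iteration += 1
        try:
            hit = aligner(tuple(remaining), hit_id)
        except Exception as exc:  # propagate with context
            raise RuntimeError(f"aligner failed at iteration {iteration}") from exc
        if hit is None or not hit.mapping:
            break
        stale = set(hit.mapping) - set(remaining)
        if stale:
            raise ValueError(
                f"iteration {iteration}: aligner mapped excluded residues {sorted(stale)[:5]}"
            )
        results.append(hit)
        covered = set(hit.mapping)
        remaining = [r for r in remaining if r not in covered]
    return results


def filter_acceptable(
    hits: Iterable[HitAlignment], cfg: AcceptabilityConfig = AcceptabilityConfig()
) -> list[HitAlignment]:
    """Keep hits passing their source's thresholds, preserving order."""
    return [h for h in hits if cfg.accepts(h)]


def group_hits(hits: Sequence[HitAlignment], overlap_frac: float = 0.20) -> list[EvidenceGroup]:
    """Greedy coverage-overlap grouping of same-source hits.

    Hits are taken best-first; a hit joins the first group where its overlap
    with the group's collective coverage is below ``overlap_frac`` of either
    the hit's own coverage or the group's, otherwise it founds a new group.
    """
    if len({h.source for h in hits}) > 1:
        raise ValueError("group_hits expects hits from a single source")
    ordered = sorted(hits, key=hit_sort_key)
    groups: list[EvidenceGroup] = []
    coverages: list[set[int]] = []
    for hit in ordered:
        cov = set(hit.coverage)
        placed = False
        for g, gcov in zip(groups, coverages):
            overlap = len(cov & gcov)
            if overlap < overlap_frac * len(cov) or overlap < overlap_frac * len(gcov):
                g.hits.append(hit)
                gcov |= cov
                placed = True
                break
        if not placed:
            groups.append(EvidenceGroup([hit]))
            coverages.append(set(cov))
    return groups


def hit_matrix(hit: HitAlignment, L: int) -> np.ndarray:
    """Residue-pair matrix for one hit: scaled score where both residues are
    mapped, zero elsewhere."""
    m = np.zeros((L, L))
    idx = np.array(sorted(hit.coverage)) - 1
    if idx.size:
        m[np.ix_(idx, idx)] = scaled_score(hit)
    return m


def build_evidence_channels(
    groups: Sequence[EvidenceGroup], L: int, max_channels: int = 10
) -> list[PairMatrix]:
    """Render hit groups into at most ``max_channels`` evidence matrices.

    Within a group the per-hit matrices are combined by elementwise maximum;
    groups are ranked by their best member's score (ties by that member's
    reference domain id) and only the top ``max_channels`` are kept.
    """
    if not groups:
        return []
    sources = {g.source for g in groups}
    if len(sources) > 1:
        raise ValueError("evidence channels must come from a single source")
    channel = "evidence_seq" if sources.pop() == SEQUENCE else "evidence_struct"

    def group_key(g: EvidenceGroup):
        best = min(g.hits, key=hit_sort_key)
        return hit_sort_key(best)

    ranked = sorted(groups, key=group_key)[:max_channels]
    out: list[PairMatrix] = []
    for g in ranked:
        m = np.zeros((L, L))
        for hit in g.hits:
            np.maximum(m, hit_matrix(hit, L), out=m)
        out.append(PairMatrix(channel, m))
    return out


# ---------------------------------------------------------------------------
# file readers / writers


def read_hits_tsv(path: str | Path) -> list[HitAlignment]:
    """Read the pre-digested hits TSV.

    Columns (tab-separated, header allowed, ``#`` comments ignored):
    ``source  ref_domain_id  score  q_res  h_res`` — one row per aligned
    residue pair; rows sharing (source, ref_domain_id, score) form one hit.
    """
    hits: dict[tuple[str, str, float], dict[int, int]] = {}
    order: list[tuple[str, str, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "source":
            continue
        source, ref_id, score, q_res, h_res = parts[:5]
        key = (source, ref_id, float(score))
        if key not in hits:
            hits[key] = {}
            order.append(key)
        hits[key][int(q_res)] = int(h_res)
    return [HitAlignment(src, rid, sc, hits[(src, rid, sc)]) for src, rid, sc in order]


def write_hits_tsv(hits: Iterable[HitAlignment], path: str | Path) -> None:
    lines = ["source\tref_domain_id\tscore\tq_res\th_res"]
    for h in hits:
        for q in sorted(h.mapping):
            lines.append(f"{h.source}\t{h.ref_domain_id}\t{h.score:g}\t{q}\t{h.mapping[q]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_definitions_tsv(path: str | Path) -> list[ReferenceDomainDefinition]:
    """Read a domain-definition TSV: ``domain_id<TAB>range_string`` per line,
    range strings like ``A:1-100,A:150-200``."""
    defs: list[ReferenceDomainDefinition] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("domain_id"):
            continue
        domain_id, ranges = line.split("\t")[:2]
        defs.append(ReferenceDomainDefinition(domain_id, tuple(parse_range_intervals(ranges))))
    return defs


def read_hhr(path: str | Path) -> list[HitAlignment]:
    """Parse an HH-suite ``.hhr`` result file into sequence hits.

    Reads the alignment blocks (``No <n>`` / ``><id>`` / ``Probab=..`` /
    paired ``Q``/``T`` alignment lines) and derives the residue mapping from
    aligned non-gap columns. The consensus and secondary-structure rows are
    skipped.
    """
    text = Path(path).read_text().splitlines()
    hits: list[HitAlignment] = []
    i = 0
    cur: dict | None = None
    while i < len(text):
        line = text[i]
        if line.startswith("No "):
            if cur is not None:
                hits.append(_finish_hhr_hit(cur))
            cur = {"mapping": {}, "id": None, "prob": None}
        elif cur is not None and line.startswith(">") and cur["id"] is None:
            cur["id"] = line[1:].split()[0]
        elif cur is not None and line.startswith("Probab="):
            cur["prob"] = float(line.split("Probab=")[1].split()[0])
        elif cur is not None and line.startswith("Q ") and "Consensus" not in line:
            q_parts = line.split()
            # matching T line within the same block
            j = i + 1
            while j < len(text) and not (text[j].startswith("T ") and "Consensus" not in text[j]):
                j += 1
            if j < len(text):
                t_parts = text[j].split()
                _merge_hhr_block(cur["mapping"], q_parts, t_parts)
                i = j
        i += 1
    if cur is not None:
        hits.append(_finish_hhr_hit(cur))
    return hits


def _merge_hhr_block(mapping: dict[int, int], q_parts: list[str], t_parts: list[str]) -> None:
    q_start, q_seq = int(q_parts[2]), q_parts[3]
    t_start, t_seq = int(t_parts[2]), t_parts[3]
    q_pos, t_pos = q_start, t_start
    for qc, tc in zip(q_seq, t_seq):
        if qc != "-" and tc != "-":
            mapping[q_pos] = t_pos
        if qc != "-":
            q_pos += 1
        if tc != "-":
            t_pos += 1


def _finish_hhr_hit(cur: dict) -> HitAlignment:
    if cur["id"] is None or cur["prob"] is None:
        raise ValueError("malformed hhr alignment block")
    return HitAlignment(SEQUENCE, cur["id"], cur["prob"], cur["mapping"])


def read_dali_equivalences(path: str | Path) -> list[HitAlignment]:
    """Parse a simplified structural-alignment equivalence file.

    Format: one ``><hit_id> Z=<z>`` header per hit followed by equivalence
    lines ``<qstart>-<qend> = <hstart>-<hend>`` (equal-length intervals).
    """
    hits: list[HitAlignment] = []
    cur: dict | None = None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith(">"):
            if cur is not None:
                hits.append(HitAlignment(STRUCTURE, cur["id"], cur["z"], cur["mapping"]))
            head = line[1:].split()
            z = next(tok.split("=")[1] for tok in head if tok.startswith("Z="))
            cur = {"id": head[0], "z": float(z), "mapping": {}}
        else:
            if cur is None:
                raise ValueError("equivalence line before any hit header")
            qpart, hpart = [p.strip() for p in line.split("=")]
            qs, qe = (int(x) for x in qpart.split("-"))
            hs, he = (int(x) for x in hpart.split("-"))
            if qe - qs != he - hs:
                raise ValueError(f"unequal interval lengths in {line!r}")
            for off in range(qe - qs + 1):
                cur["mapping"][qs + off] = hs + off
    if cur is not None:
        hits.append(HitAlignment(STRUCTURE, cur["id"], cur["z"], cur["mapping"]))
    return hits
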