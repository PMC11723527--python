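"""From a same-domain probability matrix to discrete domain definitions.

Pipeline order: disorder masking (PAE-neighbor counts), helical-linker
detection, partition into five-residue segments, greedy agglomerative
segment clustering on mean same-domain probability, contact-based boundary
refinement, and a minimum-size filter. Each stage's effect is recorded in a
provenance log.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .domains import DomainSet
from .structure import PairMatrix, SecondaryStructureElement, SSEKind


@dataclass(frozen=True)
class DisorderConfig:
    """A residue's "PAE neighbors" are residues ≥ ``min_sequence_separation``
    away in sequence with PAE below ``pae_cutoff``; a ``window``-residue
    segment is disordered when its residues have ≤ ``max_neighbors`` PAE
    neighbors in total."""

    min_sequence_separation: int = 20
    pae_cutoff: float = 6.0
    window: int = 5
    max_neighbors: int = 10

    def __post_init__(self) -> None:
        if min(self.min_sequence_separation, self.pae_cutoff, self.window, self.max_neighbors) <= 0:
            raise ValueError("disorder parameters must be positive")


@dataclass(frozen=True)
class LinkerConfig:
    """Helical-linker variant of the disorder test: neighbors within the same
    secondary-structure element are not counted, and a window qualifies only
    if its fraction of candidate intra-domain residues (covered by acceptable
    homology hits) is at most ``max_candidate_fraction``."""

    max_candidate_fraction: float = 0.40
    disorder: DisorderConfig = field(default_factory=DisorderConfig)
    #: restrict flagged windows to those intersecting a helix element
    helix_only: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.max_candidate_fraction <= 1:
            raise ValueError("max_candidate_fraction must be in [0, 1]")


@dataclass(frozen=True)
class ClusterConfig:
    """Greedy segment-clustering thresholds.

    ``p_min`` (the grid-searched x) is the minimum mean same-domain
    probability for a segment pair to be considered; ``ratio_max`` (y) bounds
    the within/between cohesion ratio allowed when merging.
    """

    p_min: float = 0.89
    ratio_max: float = 1.12
    segment_len: int = 5
    #: segments with at least this many disordered/linker residues are dropped
    max_bad_residues_per_segment: int = 3
    min_domain_size: int = 20
    refine_max_sweeps: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.p_min < 1:
            raise ValueError("p_min must be in (0, 1)")
        if self.ratio_max <= 1:
            raise ValueError("ratio_max must exceed 1")


def _pae_neighbor_counts(pae: PairMatrix, min_sep: int, cutoff: float) -> np.ndarray:
    d = pae.values
    L = pae.length
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    close = (d < cutoff) & (sep >= min_sep)
    return close.sum(axis=1)


def _tiled_windows(L: int, window: int) -> list[range]:
    """Non-overlapping windows 1–w, w+1–2w, …; trailing remnant included."""
    return [range(s, min(s + window, L + 1)) for s in range(1, L + 1, window)]


def detect_disorder(pae: PairMatrix, cfg: DisorderConfig = DisorderConfig()) -> set[int]:
    """Residues in five-residue windows whose total PAE-neighbor count is low.

    A residue's PAE neighbors are residues far in sequence (≥ min separation)
    yet mutually well-placed (PAE < cutoff); windows with ≤ ``max_neighbors``
    such neighbors in total have no long-range structural support and are
    flagged as disordered.
    """
    counts = _pae_neighbor_counts(pae, cfg.min_sequence_separation, cfg.pae_cutoff)
    flagged: set[int] = set()
    for win in _tiled_windows(pae.length, cfg.window):
        if counts[[r - 1 for r in win]].sum() <= cfg.max_neighbors:
            flagged.update(win)
    return flagged


def detect_helical_linkers(
    pae: PairMatrix,
    sses: Sequence[SecondaryStructureElement],
    candidate_residues: set[int],
    cfg: LinkerConfig = LinkerConfig(),
) -> set[int]:
    """Flexible helical linkers between domains.

    Same windowed neighbor-count test as :func:`detect_disorder`, except that
    (a) residue pairs within one secondary-structure element never count as
    neighbors, (b) a window qualifies only when its fraction of candidate
    intra-domain residues is ≤ ``max_candidate_fraction``, and (c) only
    windows intersecting a helix are eligible.
    """
    dcfg = cfg.disorder
    d = pae.values
    L = pae.length
    idx = np.arange(L)
    sep = np.abs(idx[:, None] - idx[None, :])
    close = (d < dcfg.pae_cutoff) & (sep >= dcfg.min_sequence_separation)
    # mask out pairs inside one SSE
    sse_id = np.full(L, -1)
    for k, sse in enumerate(sses):
        sse_id[sse.start - 1 : sse.stop - 1] = k
    same_sse = (sse_id[:, None] == sse_id[None, :]) & (sse_id[:, None] >= 0)
    counts = (close & ~same_sse).sum(axis=1)

    helix_residues: set[int] = set()
    for sse in sses:
        if sse.kind is SSEKind.helix:
            helix_residues.update(sse.residues())

    flagged: set[int] = set()
    for win in _tiled_windows(L, dcfg.window):
        residues = set(win)
        if cfg.helix_only and not residues & helix_residues:
            continue
        if len(residues & candidate_residues) / len(residues) > cfg.max_candidate_fraction:
            continue
        if counts[[r - 1 for r in win]].sum() <= dcfg.max_neighbors:
            flagged.update(win)
    return flagged


def partition_segments(
    L: int, excluded: set[int], cfg: ClusterConfig = ClusterConfig()
) -> list[tuple[int, ...]]:
    """Non-overlapping five-residue segments; the trailing remnant is kept as
    a short segment; segments with ≥ ``max_bad_residues_per_segment`` excluded
    residues are dropped."""
    segments: list[tuple[int, ...]] = []
    for win in _tiled_windows(L, cfg.segment_len):
        residues = tuple(win)
        if len(set(residues) & excluded) >= cfg.max_bad_residues_per_segment:
            continue
        segments.append(residues)
    return segments


def segment_psame(prob: PairMatrix, segments: Sequence[tuple[int, ...]]) -> np.ndarray:
    """Mean same-domain probability between every pair of segments.

    Entry (a, b) averages the |a|×|b| residue-pair block of the probability
    matrix (diagonal entries average a segment against itself).
    """
    p = prob.values
    n = len(segments)
    out = np.empty((n, n))
    idx = [np.array(s) - 1 for s in segments]
    for a in range(n):
        for b in range(a, n):
            val = p[np.ix_(idx[a], idx[b])].mean()
            out[a, b] = out[b, a] = val
    return out


def cluster_segments(
    prob: PairMatrix,
    segments: Sequence[tuple[int, ...]],
    cfg: ClusterConfig = ClusterConfig(),
) -> list[list[int]]:
    """Greedy agglomeration of segments by mean same-domain probability.

    Segment pairs with Psame > ``p_min`` are visited in descending Psame
    order (ties by segment indices). For each pair: if neither segment is
    grouped, the pair founds a group; if exactly one is grouped, the free
    segment joins that group when (mean within-group Psame)/(mean Psame
    between it and the group) < ``ratio_max``, else it founds its own group;
    if both sit in different groups, the groups merge when Psame1 <
    ratio_max·Psame12 or Psame2 < ratio_max·Psame12. A within-group mean over
    zero pairs (singleton group) is treated as equal to the between mean.
    Returns clusters with ≥2 segments; singletons stay ungrouped.
    """
    n = len(segments)
    ps = segment_psame(prob, segments)
    pairs = [
        (a, b) for a in range(n) for b in range(a + 1, n) if ps[a, b] > cfg.p_min
    ]
    pairs.sort(key=lambda ab: (-ps[ab[0], ab[1]], ab[0], ab[1]))

    group_of: dict[int, int] = {}
    groups: dict[int, list[int]] = {}
    next_id = 0

    def mean_between(members_a: Iterable[int], members_b: Iterable[int]) -> float:
        vals = [ps[a, b] for a in members_a for b in members_b]
        return float(np.mean(vals))

    def mean_within(members: list[int]) -> float | None:
        vals = [ps[a, b] for i, a in enumerate(members) for b in members[i + 1 :]]
        return float(np.mean(vals)) if vals else None

    def new_group(*members: int) -> None:
        nonlocal next_id
        groups[next_id] = list(members)
        for m in members:
            group_of[m] = next_id
        next_id += 1

    for a, b in pairs:
        ga, gb = group_of.get(a), group_of.get(b)
        if ga is None and gb is None:
            new_group(a, b)
        elif (ga is None) != (gb is None):
            free, gid = (a, gb) if ga is None else (b, ga)
            members = groups[gid]
            between = mean_between([free], members)
            within = mean_within(members)
            if within is None:
                within = between
            if between > 0 and within / between < cfg.ratio_max:
                members.append(free)
                group_of[free] = gid
            else:
                new_group(free)
        elif ga != gb:
            m1, m2 = groups[ga], groups[gb]
            p12 = mean_between(m1, m2)
            p1 = mean_within(m1)
            p2 = mean_within(m2)
            if p1 is None:
                p1 = p12
            if p2 is None:
                p2 = p12
            if p1 < cfg.ratio_max * p12 or p2 < cfg.ratio_max * p12:
                for m in m2:
                    group_of[m] = ga
                m1.extend(m2)
                del groups[gb]
        # both in the same group: nothing to do
    return [sorted(members) for _, members in sorted(groups.items()) if len(members) >= 2]


def refine_boundaries(
    clusters: Sequence[set[int]],
    contacts: Sequence[set[int]],
    L: int,
    cfg: ClusterConfig = ClusterConfig(),
) -> DomainSet:
    """Contact-based boundary refinement and minimum-size filter.

    Sweeping N- to C-terminal (removals before additions, up to
    ``refine_max_sweeps`` sweeps or until a fixed point): a residue at a
    domain boundary (terminus of a contiguous run) with strictly more
    contacts outside its domain than inside is dropped; an unassigned residue
    sequence-adjacent to a domain with strictly more contacts inside that
    domain than outside is added. Domains below ``min_domain_size`` residues
    are then discarded.
    """
    domains = [set(c) for c in clusters if c]
    all_res = set(range(1, L + 1))

    def contacts_in_out(r: int, domain: set[int]) -> tuple[int, int]:
        cs = contacts[r - 1] - {r}  # contact sets are irreflexive anyway
        inside = len(cs & domain)
        return inside, len(cs) - inside

    for _ in range(cfg.refine_max_sweeps):
        changed = False
        # removals
        for domain in domains:
            for r in sorted(domain):
                if not domain:
                    break
                if r not in domain:
                    continue
                if (r - 1) in domain and (r + 1) in domain:
                    continue  # interior of a contiguous run
                inside, outside = contacts_in_out(r, domain)
                if outside > inside:
                    domain.discard(r)
                    changed = True
        domains = [d for d in domains if d]
        # additions
        assigned = set().union(*domains) if domains else set()
        for r in sorted(all_res - assigned):
            adjacent = [d for d in domains if (r - 1) in d or (r + 1) in d]
            best, best_inside = None, -1
            for d in adjacent:
                inside, outside = contacts_in_out(r, d)
                if inside > outside and inside > best_inside:
                    best, best_inside = d, inside
            if best is not None:
                best.add(r)
                changed = True
        if not changed:
            break

    kept = [d for d in domains if len(d) >= cfg.min_domain_size]
    assigned = set().union(*kept) if kept else set()
    return DomainSet(kept, all_res - assigned)


@dataclass
class ParseConfigs:
    disorder: DisorderConfig = field(default_factory=DisorderConfig)
    linker: LinkerConfig = field(default_factory=LinkerConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)


def parse_domains(
    prob: PairMatrix,
    pae: PairMatrix,
    sses: Sequence[SecondaryStructureElement],
    contacts: Sequence[set[int]],
    candidate_residues: set[int],
    configs: ParseConfigs = ParseConfigs(),
) -> tuple[DomainSet, dict]:
    """Full probability→domains conversion with a provenance log.

    Stages in order: disorder detection, helical-linker detection, segment
    partition, greedy clustering, contact-based boundary refinement,
    minimum-size filter. ``candidate_residues`` are the query residues covered
    by acceptable homology hits.
    """
    L = prob.length
    disorder = detect_disorder(pae, configs.disorder)
    linker_cfg = replace(configs.linker, disorder=configs.disorder)
    linkers = detect_helical_linkers(pae, sses, candidate_residues, linker_cfg)
    excluded = disorder | linkers
    segments = partition_segments(L, excluded, configs.cluster)
    clusters = cluster_segments(prob, segments, configs.cluster)
    cluster_residues = [set().union(*(set(segments[s]) for s in c)) for c in clusters]
    result = refine_boundaries(cluster_residues, contacts, L, configs.cluster)
    log = {
        "disordered": sorted(disorder),
        "helical_linkers": sorted(linkers),
        "n_segments": len(segments),
        "n_clusters": len(clusters),
        "cluster_sizes": [len(c) for c in cluster_residues],
        "n_domains": len(result.domains),
        "domain_sizes": [len(d) for d in result.domains],
    }
    return result, log
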