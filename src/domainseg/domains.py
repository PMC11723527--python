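"""Domain definitions: disjoint, possibly sequence-discontinuous residue sets."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .ranges import format_range_string, parse_range_string


@dataclass
class DomainSet:
    """Disjoint residue-number sets plus the residues assigned to none.

    Residue numbers are 1-based; a domain may be discontinuous in sequence.
    """

    domains: list[set[int]]
    unassigned: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for d in self.domains:
            if not d:
                raise ValueError("empty domain")
            if seen & d:
                raise ValueError("domains overlap")
            seen |= d
        if seen & self.unassigned:
            raise ValueError("unassigned residues overlap a domain")

    @property
    def assigned(self) -> set[int]:
        out: set[int] = set()
        for d in self.domains:
            out |= d
        return out

    def domain_of(self) -> dict[int, int]:
        """Residue → domain index map over assigned residues."""
        return {r: k for k, d in enumerate(self.domains) for r in d}

    def range_strings(self) -> list[str]:
        return [format_range_string(d) for d in self.domains]


def write_domains_tsv(ds: DomainSet, path: str | Path) -> None:
    """Write domains as ``index<TAB>range_string<TAB>nres`` rows."""
    lines = ["domain\trange\tnres"]
    for k, d in enumerate(ds.domains, start=1):
        lines.append(f"{k}\t{format_range_string(d)}\t{len(d)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_domains_tsv(path: str | Path, L: int | None = None) -> DomainSet:
    """Read a domains TSV written by :func:`write_domains_tsv` (or any file
    whose second column is a range string)."""
    domains: list[set[int]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("domain\t"):
            continue
        parts = line.split("\t")
        domains.append(parse_range_string(parts[1]))
    assigned: set[int] = set()
    for d in domains:
        assigned |= d
    unassigned = set(range(1, L + 1)) - assigned if L is not None else set()
    return DomainSet(domains, unassigned)
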