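"""End-to-end glue: build the 24-channel input stack and run the pipeline.

Channel layout (fixed order): distance, symmetrized PAE, residue-position i,
residue-position j, 10 sequence-evidence channels, 10 structure-evidence
channels. Missing evidence channels are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .cropping import position_channels
from .domains import DomainSet
from .evidence import (
    SEQUENCE,
    AcceptabilityConfig,
    HitAlignment,
    build_evidence_channels,
    filter_acceptable,
    group_hits,
)
from .network import N_INPUT_CHANNELS, Network, predict_protein
from .postprocess import ParseConfigs, parse_domains
from .structure import (
    ChainModel,
    ContactConfig,
    PairMatrix,
    distance_matrix,
    residue_contacts,
    secondary_structure,
)

MAX_EVIDENCE_CHANNELS = 10
#: distances (Å) are capped here and scaled to [0, 1] in the network input
DISTANCE_CAP = 50.0
#: PAE cap (Å); AFDB reports PAE up to 31.75
PAE_CAP = 31.75


def evidence_channel_stack(
    hits: Sequence[HitAlignment],
    L: int,
    acceptability: AcceptabilityConfig = AcceptabilityConfig(),
    max_channels: int = MAX_EVIDENCE_CHANNELS,
) -> tuple[np.ndarray, np.ndarray, set[int]]:
    """Filter, group and render hits into (10, L, L) stacks per source.

    Returns (sequence stack, structure stack, candidate residues), where the
    candidate residues are those covered by any acceptable hit.
    """
    accepted = filter_acceptable(hits, acceptability)
    candidates: set[int] = set()
    for h in accepted:
        candidates |= h.coverage
    stacks = []
    for source in (SEQUENCE, "structure"):
        of_source = [h for h in accepted if h.source == source]
        stack = np.zeros((max_channels, L, L), dtype=np.float32)
        if of_source:
            groups = group_hits(of_source)
            for i, pm in enumerate(build_evidence_channels(groups, L, max_channels)):
                stack[i] = pm.values
        stacks.append(stack)
    return stacks[0], stacks[1], candidates


def build_channels(
    model: ChainModel,
    pae: PairMatrix,
    hits: Sequence[HitAlignment] = (),
    acceptability: AcceptabilityConfig = AcceptabilityConfig(),
) -> np.ndarray:
    """The (24, L, L) float32 network input stack for one protein.

    The distance and PAE channels are capped (50 Å / 31.75 Å) and scaled to
    [0, 1] so every channel lives on a comparable range; evidence and
    position channels are already bounded.
    """
    L = model.L
    if pae.length != L:
        raise ValueError("PAE size does not match the model")
    dist = distance_matrix(model)
    seq_stack, struct_stack, _ = evidence_channel_stack(hits, L, acceptability)
    channels = np.concatenate(
        [
            np.minimum(dist.values, DISTANCE_CAP)[None] / DISTANCE_CAP,
            np.minimum(pae.values, PAE_CAP)[None] / PAE_CAP,
            position_channels(L),
            seq_stack,
            struct_stack,
        ]
    ).astype(np.float32)
    assert channels.shape[0] == N_INPUT_CHANNELS
    return channels


@dataclass
class PipelineConfig:
    acceptability: AcceptabilityConfig = field(default_factory=AcceptabilityConfig)
    contact: ContactConfig = field(default_factory=ContactConfig)
    parse: ParseConfigs = field(default_factory=ParseConfigs)


def run_pipeline(
    model: ChainModel,
    pae: PairMatrix,
    ss_codes: str,
    hits: Sequence[HitAlignment],
    net: Network,
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[DomainSet, dict]:
    """Structure + evidence → network → domains, with provenance log."""
    channels = build_channels(model, pae, hits, cfg.acceptability)
    prob = predict_protein(channels, net)
    return domains_from_probability(prob, model, pae, ss_codes, hits, cfg)


def domains_from_probability(
    prob: PairMatrix,
    model: ChainModel,
    pae: PairMatrix,
    ss_codes: str,
    hits: Sequence[HitAlignment],
    cfg: PipelineConfig = PipelineConfig(),
) -> tuple[DomainSet, dict]:
    """Post-processing entry point when the probability matrix is in hand."""
    if len(ss_codes) != model.L:
        raise ValueError("secondary-structure string length must equal L")
    sses = secondary_structure(ss_codes)
    contacts = residue_contacts(model, cfg.contact)
    accepted = filter_acceptable(hits, cfg.acceptability)
    candidates: set[int] = set()
    for h in accepted:
        candidates |= h.coverage
    return parse_domains(prob, pae, sses, contacts, candidates, cfg.parse)


# ---------------------------------------------------------------------------
# HDF5 feature container: one dataset per named channel group + metadata


def write_features(path: str | Path, channels: np.ndarray, L: int | None = None) -> None:
    """Persist a (24, L, L) channel stack: datasets ``distance``, ``pae``,
    ``position`` (2×), ``evidence_seq`` (10×), ``evidence_struct`` (10×)."""
    channels = np.asarray(channels, dtype=np.float32)
    with h5py.File(path, "w") as f:
        f.attrs["L"] = L if L is not None else channels.shape[1]
        f.create_dataset("distance", data=channels[0])
        f.create_dataset("pae", data=channels[1])
        f.create_dataset("position", data=channels[2:4])
        f.create_dataset("evidence_seq", data=channels[4:14])
        f.create_dataset("evidence_struct", data=channels[14:24])


def read_features(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        parts = [
            f["distance"][()][None],
            f["pae"][()][None],
            f["position"][()],
            f["evidence_seq"][()],
            f["evidence_struct"][()],
        ]
    return np.concatenate(parts).astype(np.float32)


def write_probability(path: str | Path, prob: PairMatrix) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("probability", data=prob.values.astype(np.float32))


def read_probability(path: str | Path) -> PairMatrix:
    with h5py.File(path, "r") as f:
        return PairMatrix("probability", f["probability"][()].astype(np.float64))
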