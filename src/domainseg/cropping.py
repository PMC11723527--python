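"""Mapping L×L channel stacks into fixed 500×500 crops and back.

Proteins shorter than the crop size are padded (left offset x, remainder on
the right, zeros in every channel); longer proteins are covered by crops of
one or two in-sequence segments. Training crops are randomized per epoch;
inference crops tile the protein deterministically so that every residue
pair appears in at least one crop, and per-pair network outputs from
overlapping crops are averaged back into a full probability matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import PairMatrix

CROP_SIZE = 500
#: stride of the deterministic inference tiling
INFERENCE_STRIDE = 250
#: segment length used for discontinuous inference crops
INFERENCE_SEGMENT = 250
#: minimum segment length of a discontinuous training crop
MIN_TRAIN_SEGMENT = 50
#: residue-position channels store resnum/POSITION_SCALE clipped to 1
POSITION_SCALE = 2000.0


@dataclass(frozen=True)
class CropSpec:
    """One or two half-open query segments placed into a 500-wide crop axis.

    ``segments[k] = (start, stop)`` over 1-based residue numbers;
    ``placements[k]`` is the 0-based offset of segment k on the crop axis.
    For padded (short-protein) crops, ``placements[0]`` is the left padding
    ``x``.
    """

    segments: tuple[tuple[int, int], ...]
    placements: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.segments) not in (1, 2) or len(self.placements) != len(self.segments):
            raise ValueError("a crop holds one or two placed segments")
        last_stop = 0
        for (start, stop), plc in zip(self.segments, self.placements):
            if stop <= start or start < 1 or plc < 0:
                raise ValueError(f"bad segment {(start, stop)} at offset {plc}")
            if start < last_stop:
                raise ValueError("segments must be non-overlapping and in sequence order")
            last_stop = stop
        if self.total_length + self.placements[0] > CROP_SIZE:
            raise ValueError("segments plus padding exceed the crop size")

    @property
    def total_length(self) -> int:
        return sum(stop - start for start, stop in self.segments)

    @property
    def pad_left(self) -> int:
        return self.placements[0]

    def axis_residues(self) -> np.ndarray:
        """Residue number at each crop-axis position; -1 marks padding."""
        axis = np.full(CROP_SIZE, -1, dtype=int)
        for (start, stop), plc in zip(self.segments, self.placements):
            n = stop - start
            axis[plc : plc + n] = np.arange(start, stop)
        return axis


@dataclass
class CropBatch:
    """A crop's stacked channels plus the mask of real (non-padding) pixels."""

    spec: CropSpec
    channels: np.ndarray  # (C, 500, 500) float32, zeros on padding
    valid_mask: np.ndarray  # (500, 500) bool


def crop_count(L: int) -> int:
    """Number of training crops for a protein of L residues (L > 500)."""
    if L <= CROP_SIZE:
        raise ValueError(f"L={L} <= {CROP_SIZE}: use the padding path, not cropping")
    if L <= 750:
        return 1
    if L <= 1000:
        return 2
    if L <= 1500:
        return 3
    if L <= 2000:
        return 4
    return 5


def make_training_crops(L: int, rng: np.random.Generator | int) -> list[CropSpec]:
    """Randomized crops for one training epoch.

    Short proteins get a single padded placement with the left pad uniform in
    [0, 500−L]. Long proteins get ``crop_count(L)`` crops, each independently
    a continuous 500-residue window or two in-sequence windows (each ≥50
    residues) totalling 500, with uniformly random bounds. Deterministic for
    a given seed.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if L < CROP_SIZE:
        pad = int(rng.integers(0, CROP_SIZE - L + 1))
        return [CropSpec(((1, L + 1),), (pad,))]
    if L == CROP_SIZE:
        return [CropSpec(((1, L + 1),), (0,))]

    specs: list[CropSpec] = []
    for _ in range(crop_count(L)):
        two_segments = bool(rng.integers(0, 2))
        if not two_segments:
            start = int(rng.integers(1, L - CROP_SIZE + 2))
            specs.append(CropSpec(((start, start + CROP_SIZE),), (0,)))
            continue
        len1 = int(rng.integers(MIN_TRAIN_SEGMENT, CROP_SIZE - MIN_TRAIN_SEGMENT + 1))
        len2 = CROP_SIZE - len1
        s1 = int(rng.integers(1, L - CROP_SIZE + 2))
        s2 = int(rng.integers(s1 + len1, L - len2 + 2))
        specs.append(CropSpec(((s1, s1 + len1), (s2, s2 + len2)), (0, len1)))
    return specs


def _tile_starts(L: int, width: int, stride: int) -> list[int]:
    starts = list(range(1, L - width + 2, stride))
    if starts[-1] != L - width + 1:
        starts.append(L - width + 1)
    return starts


def make_inference_crops(L: int) -> list[CropSpec]:
    """Deterministic crop tiling covering every residue pair (L > 500).

    Continuous 500-residue windows at stride 250 cover near-diagonal pairs;
    two-segment crops pairing every ordered couple of 250-residue tiles cover
    the rest.
    """
    if L <= CROP_SIZE:
        raise ValueError(f"L={L} <= {CROP_SIZE}: use a single padded crop")
    specs = [
        CropSpec(((s, s + CROP_SIZE),), (0,))
        for s in _tile_starts(L, CROP_SIZE, INFERENCE_STRIDE)
    ]
    tiles = _tile_starts(L, INFERENCE_SEGMENT, INFERENCE_SEGMENT)
    for a_idx, a in enumerate(tiles):
        for b in tiles[a_idx + 1 :]:
            if b < a + INFERENCE_SEGMENT:
                continue  # clamped final tile may overlap its predecessor
            specs.append(
                CropSpec(
                    ((a, a + INFERENCE_SEGMENT), (b, b + INFERENCE_SEGMENT)),
                    (0, INFERENCE_SEGMENT),
                )
            )
    return specs


def inference_specs(L: int) -> list[CropSpec]:
    """Crops used at prediction time: one zero-pad placement if L ≤ 500,
    otherwise the deterministic tiling."""
    if L <= CROP_SIZE:
        return [CropSpec(((1, L + 1),), (0,))]
    return make_inference_crops(L)


def position_channels(L: int) -> np.ndarray:
    """The two residue-number channels, scaled by 1/2000 and clipped to 1."""
    pos = np.minimum(np.arange(1, L + 1) / POSITION_SCALE, 1.0)
    pos_i = np.repeat(pos[:, None], L, axis=1)
    pos_j = np.repeat(pos[None, :], L, axis=0)
    return np.stack([pos_i, pos_j])


def extract_crop(channels: np.ndarray, spec: CropSpec) -> CropBatch:
    """Map an (C, L, L) channel stack into one (C, 500, 500) crop.

    Cross-segment blocks of two-segment crops carry the true (i, j) values;
    padding pixels are zero in every channel and False in the mask.
    """
    channels = np.asarray(channels)
    if channels.ndim != 3 or channels.shape[1] != channels.shape[2]:
        raise ValueError("expected a (C, L, L) channel stack")
    L = channels.shape[1]
    if any(stop - 1 > L for _, stop in spec.segments):
        raise ValueError("crop segments exceed the protein length")
    axis = spec.axis_residues()
    valid = axis >= 0
    idx = np.where(valid, axis - 1, 0)
    out = channels[:, idx[:, None], idx[None, :]].astype(np.float32)
    mask = valid[:, None] & valid[None, :]
    out[:, ~mask] = 0.0
    return CropBatch(spec, out, mask)


def assemble_probability(
    outputs: list[np.ndarray], specs: list[CropSpec], L: int
) -> PairMatrix:
    """Average per-crop 500×500 outputs back into an L×L probability matrix.

    Each covered pair's value is the arithmetic mean over the crops covering
    it (padding pixels ignored); the result is symmetrized by averaging with
    its transpose. Raises if any residue pair is covered by no crop.
    """
    if len(outputs) != len(specs):
        raise ValueError("one output per crop spec required")
    acc = np.zeros((L, L))
    cnt = np.zeros((L, L))
    for out, spec in zip(outputs, specs):
        axis = spec.axis_residues()
        valid = np.nonzero(axis >= 0)[0]
        res = axis[valid] - 1
        acc[np.ix_(res, res)] += np.asarray(out, dtype=float)[np.ix_(valid, valid)]
        cnt[np.ix_(res, res)] += 1.0
    if np.any(cnt == 0):
        i, j = np.argwhere(cnt == 0)[0]
        raise ValueError(f"residue pair ({i + 1}, {j + 1}) covered by no crop")
    mean = acc / cnt
    return PairMatrix("probability", (mean + mean.T) / 2.0)
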