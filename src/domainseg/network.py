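"""The residual dilated CNN mapping 24 input channels to same-domain
probabilities, plus its training loop.

The network reads a stack of 500×500 channels — distance, symmetrized PAE,
two residue-position channels, up to 10 sequence-evidence and up to 10
structure-evidence matrices — and emits a per-pixel two-class softmax whose
class-1 map is the probability that the residue pair shares a domain.

Architecture (full preset): a 1×1 projection into 64 filters, 23 residual
blocks of two 3×3 convolutions each, and a 1×1 two-class head — 48
convolutional layers in total — with dilation rates 8/4/2/1 and filter
counts 64/48/32/16 stepping down over block quartiles, and 15 dropout layers
(ratio 0.15) spread evenly across the blocks. Exact schedule, optimizer
(Adam, lr 1e-3) and batch size are configuration, not constants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cropping import (
    CROP_SIZE,
    CropBatch,
    CropSpec,
    assemble_probability,
    extract_crop,
    inference_specs,
    make_training_crops,
)
from .domains import DomainSet
from .nn import Adam, Conv2d, Dropout, ResidualBlock
from .structure import PairMatrix

N_INPUT_CHANNELS = 24


def full_schedule() -> list[tuple[int, int, int]]:
    """(kernel, filters, dilation) per residual block, full preset."""
    return (
        [(3, 64, 8)] * 6 + [(3, 48, 4)] * 6 + [(3, 32, 2)] * 6 + [(3, 16, 1)] * 5
    )


def tiny_schedule() -> list[tuple[int, int, int]]:
    return [(3, 8, 4), (3, 8, 2), (3, 8, 1)]


@dataclass
class NetworkConfig:
    """Layer counts and per-block (kernel, filters, dilation) schedule.

    ``n_conv_layers`` must equal 2 + 2·n_blocks (projection + two convolutions
    per residual block + head); dilations must be non-increasing after the
    initial projection.
    """

    n_conv_layers: int = 48
    n_dropout_layers: int = 15
    dropout_ratio: float = 0.15
    filter_schedule: list[tuple[int, int, int]] = field(default_factory=full_schedule)
    in_channels: int = N_INPUT_CHANNELS
    scale_preset: str = "full"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conv_layers < 2:
            raise ValueError("need at least projection and head layers")
        if not 0 <= self.dropout_ratio < 1:
            raise ValueError("dropout_ratio must be in [0, 1)")
        if self.n_conv_layers != 2 + 2 * len(self.filter_schedule):
            raise ValueError(
                f"n_conv_layers={self.n_conv_layers} inconsistent with "
                f"{len(self.filter_schedule)} residual blocks "
                f"(expected {2 + 2 * len(self.filter_schedule)})"
            )
        dilations = [d for _, _, d in self.filter_schedule]
        if any(d <= 0 for d in dilations):
            raise ValueError("dilations must be positive")
        if any(b > a for a, b in zip(dilations, dilations[1:])):
            raise ValueError("dilations must be non-increasing across blocks")
        if self.n_dropout_layers > len(self.filter_schedule):
            raise ValueError("more dropout layers than residual blocks")

    @classmethod
    def tiny(cls, seed: int = 0) -> "NetworkConfig":
        return cls(
            n_conv_layers=8,
            n_dropout_layers=2,
            dropout_ratio=0.15,
            filter_schedule=tiny_schedule(),
            scale_preset="tiny",
            init_seed=seed,
        )


@dataclass
class TrainConfig:
    epochs: int = 30
    validation_cluster_fraction: float = 0.05
    seed: int = 0
    batch_size: int = 4
    learning_rate: float = 1e-3
    #: early stopping is off by default; set a patience to stop when the
    #: validation loss has not improved for that many epochs
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.validation_cluster_fraction < 1:
            raise ValueError("validation_cluster_fraction must be in (0, 1)")


@dataclass
class ProteinRecord:
    """One training protein: its full channel stack, reference domains and
    redundancy-cluster label."""

    channels: np.ndarray  # (C, L, L)
    truth: DomainSet
    cluster_id: str

    @property
    def L(self) -> int:
        return self.channels.shape[1]


@dataclass
class TrainingExample:
    """A single crop ready for the loss: channels, binary target, mask."""

    batch: CropBatch
    target: np.ndarray  # (500, 500) float32 in {0, 1}
    cluster_id: str


class Network:
    """The CNN as an explicit module list with layer introspection."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.init_seed)
        blocks = cfg.filter_schedule
        self.projection = Conv2d(cfg.in_channels, blocks[0][1], 1, 1, rng)
        self.blocks: list[ResidualBlock] = []
        cin = blocks[0][1]
        for kernel, filters, dilation in blocks:
            self.blocks.append(ResidualBlock(cin, filters, kernel, dilation, rng))
            cin = filters
        self.head = Conv2d(cin, 2, 1, 1, rng)
        drop_at = np.unique(
            np.round(np.linspace(0, len(blocks) - 1, cfg.n_dropout_layers)).astype(int)
        )
        if len(drop_at) != cfg.n_dropout_layers:
            raise ValueError("cannot place the requested number of dropout layers")
        self.dropout_after = {int(i): Dropout(cfg.dropout_ratio) for i in drop_at}

    # -- introspection ------------------------------------------------------
    @property
    def conv_layer_count(self) -> int:
        return 2 + 2 * len(self.blocks)

    @property
    def dropout_layer_count(self) -> int:
        return len(self.dropout_after)

    # -- passes -------------------------------------------------------------
    def forward_logits(
        self,
        channels: np.ndarray,
        valid_mask: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """(C, H, W) → class logits (2, H, W).

        Inputs are multiplied by the validity mask first, so padding pixels
        can never leak information into the loss.
        """
        x = np.asarray(channels, dtype=np.float32)
        if valid_mask is not None:
            x = x * valid_mask.astype(np.float32)
        x = self.projection.forward(x, cache=train)
        for i, block in enumerate(self.blocks):
            x = block.forward(x, cache=train)
            drop = self.dropout_after.get(i)
            if drop is not None:
                x = drop.forward(x, train, rng)
        return self.head.forward(x, cache=train)

    def forward_proba(
        self, channels: np.ndarray, valid_mask: np.ndarray | None = None
    ) -> np.ndarray:
        """Class-1 softmax map: per-pixel same-domain probability."""
        return softmax2(self.forward_logits(channels, valid_mask))[1]

    def backward(self, g_logits: np.ndarray) -> None:
        g = self.head.backward(g_logits)
        for i in range(len(self.blocks) - 1, -1, -1):
            drop = self.dropout_after.get(i)
            if drop is not None:
                g = drop.backward(g)
            g = self.blocks[i].backward(g)
        self.projection.backward(g)

    # -- parameters ---------------------------------------------------------
    def parameters(self):
        params = self.projection.parameters()
        for b in self.blocks:
            params += b.parameters()
        return params + self.head.parameters()

    def zero_grad(self) -> None:
        self.projection.zero_grad()
        for b in self.blocks:
            b.zero_grad()
        self.head.zero_grad()

    def param_arrays(self) -> list[np.ndarray]:
        return [p for p, _ in self.parameters()]


def build_network(cfg: NetworkConfig) -> Network:
    """Instantiate the CNN; introspection reports exact layer counts."""
    return Network(cfg)


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Stable softmax over the leading (2-class) axis."""
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def masked_bce_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Mean binary cross-entropy over masked-in pixels, probabilities clipped
    to [1e-7, 1−1e-7]."""
    if pred.shape != target.shape or pred.shape != mask.shape:
        raise ValueError("pred/target/mask shapes must agree")
    p = np.clip(pred, 1e-7, 1 - 1e-7)
    t = target.astype(np.float64)
    bce = -(t * np.log(p) + (1 - t) * np.log(1 - p))
    m = mask.astype(bool)
    return float(bce[m].mean())


def target_matrix(
    domains: DomainSet, spec: CropSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Binary same-domain target for one crop, plus its validity mask.

    Pixel (u, v) is 1 iff both mapped residues belong to the same reference
    domain; residues in no domain are 0 against everything; padding is
    masked out.
    """
    axis = spec.axis_residues()
    dom_of = domains.domain_of()
    labels = np.array([dom_of.get(int(r), -1) if r > 0 else -2 for r in axis])
    valid = axis >= 0
    tgt = (labels[:, None] == labels[None, :]) & (labels[:, None] >= 0)
    mask = valid[:, None] & valid[None, :]
    return tgt.astype(np.float32), mask


def split_by_cluster(
    examples: Sequence, frac: float, seed: int
) -> tuple[list, list]:
    """Hold out whole redundancy clusters as a validation set.

    Clusters are shuffled deterministically and assigned to validation until
    at least ``frac`` of the clusters are held out; no cluster straddles the
    split.
    """
    clusters = sorted({ex.cluster_id for ex in examples})
    if len(clusters) < 2:
        raise ValueError("need at least two clusters to split")
    rng = np.random.default_rng(seed)
    order = [clusters[i] for i in rng.permutation(len(clusters))]
    n_val = int(np.ceil(frac * len(clusters)))
    val_clusters = set(order[:n_val])
    train = [ex for ex in examples if ex.cluster_id not in val_clusters]
    val = [ex for ex in examples if ex.cluster_id in val_clusters]
    return train, val


def _epoch_seed(run_seed: int, epoch: int) -> int:
    return int(np.random.SeedSequence([run_seed, epoch]).generate_state(1)[0] % (2**31))


def _loss_and_grad(
    net: Network,
    batch: CropBatch,
    target: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """One training crop: forward, masked 2-class CE, backward. Returns loss."""
    mask = batch.valid_mask
    logits = net.forward_logits(batch.channels, mask, train=True, rng=rng)
    p = softmax2(logits)
    p1 = np.clip(p[1], 1e-7, 1 - 1e-7)
    m = mask.astype(np.float64)
    n = m.sum()
    loss = float(
        (-(target * np.log(p1) + (1 - target) * np.log(1 - p1)) * m).sum() / n
    )
    onehot = np.stack([1.0 - target, target]).astype(np.float32)
    g_logits = (p - onehot) * (m / n).astype(np.float32)
    net.backward(g_logits)
    return loss


@dataclass
class TrainResult:
    network: Network
    epoch_log: list[dict]


def train(
    records: Sequence[ProteinRecord],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig,
) -> TrainResult:
    """Train the CNN on per-protein channel stacks.

    Crops are re-sampled every epoch with a fresh seed derived from the run
    seed, whole clusters are held out for validation, and the masked BCE loss
    is minimized with Adam. The per-epoch log records train and validation
    loss; training aborts on a non-finite loss.
    """
    train_recs, val_recs = split_by_cluster(
        records, train_cfg.validation_cluster_fraction, train_cfg.seed
    )
    net = build_network(net_cfg)
    opt = Adam(net.parameters(), lr=train_cfg.learning_rate)
    log: list[dict] = []
    best_val = np.inf
    stale = 0
    for epoch in range(train_cfg.epochs):
        rng = np.random.default_rng(_epoch_seed(train_cfg.seed, epoch))
        losses: list[float] = []
        pending = 0
        net.zero_grad()
        for rec in train_recs:
            for spec in make_training_crops(rec.L, rng):
                batch = extract_crop(rec.channels, spec)
                target, t_mask = target_matrix(rec.truth, spec)
                assert np.array_equal(t_mask, batch.valid_mask)
                loss = _loss_and_grad(net, batch, target, rng)
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite loss at epoch {epoch + 1}")
                losses.append(loss)
                pending += 1
                if pending == train_cfg.batch_size:
                    opt.step()
                    net.zero_grad()
                    pending = 0
        if pending:
            opt.step()
            net.zero_grad()
        entry = {"epoch": epoch + 1, "train_loss": float(np.mean(losses))}
        if val_recs:
            entry["val_loss"] = float(
                np.mean([validation_loss(net, rec) for rec in val_recs])
            )
        log.append(entry)
        if train_cfg.early_stop_patience is not None and "val_loss" in entry:
            if entry["val_loss"] < best_val - 1e-6:
                best_val = entry["val_loss"]
                stale = 0
            else:
                stale += 1
                if stale >= train_cfg.early_stop_patience:
                    break
    return TrainResult(net, log)


def validation_loss(net: Network, rec: ProteinRecord) -> float:
    """Masked BCE of the deterministic inference crops of one protein."""
    losses = []
    for spec in inference_specs(rec.L):
        batch = extract_crop(rec.channels, spec)
        target, _ = target_matrix(rec.truth, spec)
        pred = net.forward_proba(batch.channels, batch.valid_mask)
        losses.append(masked_bce_loss(pred, target, batch.valid_mask))
    return float(np.mean(losses))


def predict_protein(channels: np.ndarray, net: Network) -> PairMatrix:
    """Full-protein same-domain probabilities: deterministic crops → forward
    → per-pair averaging; the result is symmetric and in [0, 1]."""
    L = channels.shape[1]
    if L < 20:
        raise ValueError("prediction requires at least 20 residues")
    specs = inference_specs(L)
    outputs = []
    for spec in specs:
        batch = extract_crop(channels, spec)
        outputs.append(net.forward_proba(batch.channels, batch.valid_mask))
    return assemble_probability(outputs, specs, L)


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(result: TrainResult, path: str | Path) -> None:
    """Single-file checkpoint: config + parameters + loss log (.npz)."""
    cfg = result.network.cfg
    meta = {
        "n_conv_layers": cfg.n_conv_layers,
        "n_dropout_layers": cfg.n_dropout_layers,
        "dropout_ratio": cfg.dropout_ratio,
        "filter_schedule": [list(b) for b in cfg.filter_schedule],
        "in_channels": cfg.in_channels,
        "scale_preset": cfg.scale_preset,
        "init_seed": cfg.init_seed,
        "epoch_log": result.epoch_log,
    }
    arrays = {f"param_{i}": p for i, p in enumerate(result.network.param_arrays())}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainResult:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["meta"]))
    cfg = NetworkConfig(
        n_conv_layers=meta["n_conv_layers"],
        n_dropout_layers=meta["n_dropout_layers"],
        dropout_ratio=meta["dropout_ratio"],
        filter_schedule=[tuple(b) for b in meta["filter_schedule"]],
        in_channels=meta["in_channels"],
        scale_preset=meta["scale_preset"],
        init_seed=meta["init_seed"],
    )
    net = build_network(cfg)
    for i, p in enumerate(net.param_arrays()):
        p[...] = data[f"param_{i}"]
    return TrainResult(net, meta["epoch_log"])
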