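"""DMF-Net: a 26-convolution residual denoiser for grayscale medical images.

The network estimates the noise field of an image rather than the image
itself.  Its structure, kept both as an inspectable ``LayerLedger`` and as a
trainable network:

* **DFEB** (layers 1-16): a fully-convolutional backbone of 64-filter 3x3
  layers; layers 2, 5 and 12 use dilation 2 to widen the receptive field
  without pooling.  Layer 1 is conv+ReLU, the rest are conv+BN+ReLU.
* **CFB / noise taps** (layers 17-19): three 1-filter linear convolutions
  reading the backbone activations of layers 14, 15 and 16, pooling low-,
  mid- and high-level noise evidence.
* **NFB** (layers 20-21): the three tap maps are summed elementwise, passed
  through Tanh, then conv+ReLU and conv+BN+ReLU produce the final noise
  estimate f(N).
* Residual subtraction: ``I_P = I_noisy - f(N)``.
* **PFRB** (layers 22-26): five conv(+BN+ReLU) layers refine the subtracted
  image into the clean output.

Stride is 1 and padding equals the dilation everywhere, so every feature map
— and the output — has the input's spatial size.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import ConvBlock, Tanh

__all__ = [
    "LayerSpec",
    "LayerLedger",
    "canonical_ledger",
    "count_parameters",
    "DMFNet",
]

CHECKPOINT_MAGIC = "dmfnet-checkpoint-v1"


@dataclass(frozen=True)
class LayerSpec:
    """One convolution layer of the ledger (the machine-readable layer table)."""

    index: int  # 1-based
    kind: str  # conv | conv_bn | dilated_conv_bn
    in_channels: int
    filters: int
    dilation: int = 1
    activation: str = "relu"  # relu | none
    block: str = "DFEB"  # DFEB | CFB | NFB | PFRB
    reads_from: int | None = None  # backbone layer index for the CFB taps
    kernel: tuple = (3, 3)
    stride: int = 1

    @property
    def padding(self) -> int:
        # stride-1 same-size convolution: padding matches the dilation
        return self.dilation

    @property
    def has_bn(self) -> bool:
        return self.kind.endswith("_bn") or self.kind == "conv_bn"

    @property
    def has_bias(self) -> bool:
        return not self.has_bn


@dataclass
class LayerLedger:
    layers: list[LayerSpec] = field(default_factory=list)
    tap_sources: tuple = (14, 15, 16)
    fusion: str = "sum_tanh"  # elementwise sum of the tap maps, then Tanh
    structure: dict = field(default_factory=dict)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def n_dilated(self) -> int:
        return sum(1 for l in self.layers if l.dilation > 1)

    @property
    def n_conv_bn_relu(self) -> int:
        """Non-dilated conv+BN+ReLU layers."""
        return sum(
            1 for l in self.layers if l.has_bn and l.dilation == 1 and l.activation == "relu"
        )

    def __getitem__(self, index: int) -> LayerSpec:
        """1-based layer lookup matching the printed table."""
        return self.layers[index - 1]

    def as_table(self) -> str:
        """Plain-text table, one row per layer."""
        buf = io.StringIO()
        header = f"{'idx':>3}  {'block':<5} {'kind':<16} {'in':>3} {'out':>3} {'dil':>3} {'act':<5} reads"
        buf.write(header + "\n")
        buf.write("-" * len(header) + "\n")
        for l in self.layers:
            reads = f"L{l.reads_from}" if l.reads_from else "-"
            buf.write(
                f"{l.index:>3}  {l.block:<5} {l.kind:<16} {l.in_channels:>3} "
                f"{l.filters:>3} {l.dilation:>3} {l.activation:<5} {reads}\n"
            )
        return buf.getvalue()


def canonical_ledger() -> LayerLedger:
    """The fixed 26-layer DMF-Net architecture.

    Backbone: L1 conv(64)+ReLU; L2, L5, L12 dilated (d=2) conv+BN+ReLU;
    remaining backbone layers conv+BN+ReLU; taps L17-19 are 1-filter linear
    convolutions reading backbone layers 14-16; NFB L20 conv(1)+ReLU and
    L21 conv+BN(1)+ReLU give the noise map; PFRB L22-L26 refine the
    noise-subtracted image (64, 64, 64, 64, 1 filters).
    """
    dilated_at = {2, 5, 12}
    layers: list[LayerSpec] = []
    layers.append(LayerSpec(1, "conv", 1, 64, block="DFEB"))
    for i in range(2, 17):
        kind = "dilated_conv_bn" if i in dilated_at else "conv_bn"
        d = 2 if i in dilated_at else 1
        layers.append(LayerSpec(i, kind, 64, 64, dilation=d, block="DFEB"))
    for i, src in zip((17, 18, 19), (14, 15, 16)):
        layers.append(LayerSpec(i, "conv", 64, 1, activation="none", block="CFB", reads_from=src))
    layers.append(LayerSpec(20, "conv", 1, 1, block="NFB"))
    layers.append(LayerSpec(21, "conv_bn", 1, 1, block="NFB"))
    layers.append(LayerSpec(22, "conv_bn", 1, 64, block="PFRB"))
    for i in (23, 24, 25):
        layers.append(LayerSpec(i, "conv_bn", 64, 64, block="PFRB"))
    layers.append(LayerSpec(26, "conv_bn", 64, 1, block="PFRB"))
    structure = {
        "DFEB": tuple(range(1, 17)),
        "CFB": (17, 18, 19),
        "NFB": (20, 21),
        "PFRB": (22, 23, 24, 25, 26),
    }
    return LayerLedger(layers=layers, tap_sources=(14, 15, 16), structure=structure)


def count_parameters(ledger: LayerLedger) -> int:
    """Trainable parameter count implied by a ledger (weights, biases, BN scale/shift)."""
    total = 0
    for l in ledger.layers:
        kh, kw = l.kernel
        total += l.filters * l.in_channels * kh * kw
        if l.has_bias:
            total += l.filters
        if l.has_bn:
            total += 2 * l.filters
    return total


def _block_from_spec(spec: LayerSpec, rng: np.random.Generator, dtype) -> ConvBlock:
    return ConvBlock(
        spec.in_channels,
        spec.filters,
        dilation=spec.dilation,
        bn=spec.has_bn,
        activation=spec.activation,
        rng=rng,
        dtype=dtype,
    )


class DMFNet:
    """The trainable network, built from a :class:`LayerLedger`.

    Fully convolutional: accepts any ``H x W >= 16`` single-channel input and
    returns a noise map and a denoised image of the same size.
    """

    def __init__(
        self,
        ledger: LayerLedger | None = None,
        seed: int | np.random.Generator = 0,
        dtype=np.float32,
    ):
        self.ledger = ledger or canonical_ledger()
        self.dtype = np.dtype(dtype)
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        by_block: dict[str, list[LayerSpec]] = {"DFEB": [], "CFB": [], "NFB": [], "PFRB": []}
        for spec in self.ledger.layers:
            by_block[spec.block].append(spec)
        self.backbone = [_block_from_spec(s, rng, dtype) for s in by_block["DFEB"]]
        self.taps = [_block_from_spec(s, rng, dtype) for s in by_block["CFB"]]
        self.tap_sources = self.ledger.tap_sources
        self.fusion_tanh = Tanh()
        self.nfb = [_block_from_spec(s, rng, dtype) for s in by_block["NFB"]]
        self.pfrb = [_block_from_spec(s, rng, dtype) for s in by_block["PFRB"]]
        # Output-calibrated initialisation.  BatchNorm on the two heads would
        # otherwise emit standardized (zero-mean, unit-scale) values, far from
        # their targets: the noise map is O(sigma/255) and the clean image
        # lives in [0, 1] (mean ~ 0.5).  Starting the head BN scales at those
        # magnitudes makes the residual subtraction near-neutral at step one,
        # which matters at the short training schedules where Adam can move
        # each parameter only by ~ lr * steps.
        if self.nfb and self.nfb[-1].bn is not None:
            self.nfb[-1].bn.gamma[...] = 0.1
        if self.pfrb and self.pfrb[-1].bn is not None:
            self.pfrb[-1].bn.gamma[...] = 0.25
            self.pfrb[-1].bn.beta[...] = 0.5

    # ---- plumbing -------------------------------------------------------

    def _all_blocks(self):
        return self.backbone + self.taps + self.nfb + self.pfrb

    def modules(self):
        out = []
        for blk in self._all_blocks():
            out.extend(blk.modules())
        return out

    def parameters(self):
        """Flat ordered list of (name, array) trainable parameters."""
        out = []
        for k, mod in enumerate(self.modules()):
            for name, arr in mod.parameters():
                out.append((f"m{k:02d}.{name}", arr))
        return out

    def gradients(self):
        out = []
        for k, mod in enumerate(self.modules()):
            for name, arr in mod.gradients():
                out.append((f"m{k:02d}.{name}", arr))
        return out

    def zero_grad(self):
        for _, g in self.gradients():
            g[...] = 0.0

    def release_buffers(self):
        """Free pooled per-layer activation buffers (e.g. after training)."""
        for mod in self.modules():
            mod.release_buffers()

    def n_parameters(self) -> int:
        return sum(arr.size for _, arr in self.parameters())

    # ---- forward / backward --------------------------------------------

    @staticmethod
    def _as_batch(x: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(x)
        if x.ndim == 2:
            return x[None, None], True
        if x.ndim == 4:
            if x.shape[1] != 1:
                raise ValueError(f"multi-channel input not supported (got {x.shape[1]} channels)")
            return x, False
        raise ValueError(f"expected a 2-D image or (N, 1, H, W) batch, got shape {x.shape}")

    def forward(self, noisy: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Run the network; returns ``(noise_map, denoised)``.

        ``noisy`` may be a single 2-D image or an (N, 1, H, W) batch; the
        outputs match the input's layout and spatial size.
        """
        x, squeeze = self._as_batch(noisy)
        if min(x.shape[2], x.shape[3]) < 16:
            raise ValueError(f"input spatial size {x.shape[2:]} too small (min 16)")
        x = x.astype(self.dtype, copy=False)
        h = x
        feats = {}
        for idx, blk in enumerate(self.backbone, start=1):
            h = blk.forward(h, train)
            if idx in self.tap_sources:
                feats[idx] = h
        fused = None
        for tap, src in zip(self.taps, self.tap_sources):
            t = tap.forward(feats[src], train)
            fused = t if fused is None else fused + t
        fused = self.fusion_tanh.forward(fused, train)
        h = fused
        for blk in self.nfb:
            h = blk.forward(h, train)
        noise_map = h
        sub = x - noise_map
        h = sub
        for blk in self.pfrb:
            h = blk.forward(h, train)
        denoised = h
        if not train:
            # detach from the reusable layer buffers
            noise_map = noise_map.copy()
            denoised = denoised.copy()
        if squeeze:
            return noise_map[0, 0], denoised[0, 0]
        return noise_map, denoised

    def backward(self, d_denoised: np.ndarray) -> None:
        """Accumulate parameter gradients given d(loss)/d(denoised)."""
        # private copy: block backward passes reuse gradient buffers in place
        g = np.array(d_denoised, dtype=self.dtype)
        for blk in reversed(self.pfrb):
            g = blk.backward(g)
        # sub = noisy - noise_map: gradient into the noise branch flips sign
        g = -g
        for blk in reversed(self.nfb):
            g = blk.backward(g)
        g = self.fusion_tanh.backward(g)
        # taps feed the fused sum; their input-gradients join the backbone
        tap_in = {src: tap.backward(g) for tap, src in zip(self.taps, self.tap_sources)}
        gb = None
        for idx in range(len(self.backbone), 0, -1):
            if gb is None:
                gb = tap_in.get(idx)  # deepest tapped layer ends the backbone
            elif idx in tap_in:
                gb = gb + tap_in[idx]
            gb = self.backbone[idx - 1].backward(gb, need_dx=(idx > 1))

    def denoise(self, image: np.ndarray) -> np.ndarray:
        """Inference convenience: denoised 2-D image (not clipped)."""
        _, den = self.forward(image, train=False)
        return den

    # ---- checkpointing --------------------------------------------------

    def state_arrays(self) -> dict:
        out = {}
        for k, mod in enumerate(self.modules()):
            for name, arr in mod.parameters():
                out[f"m{k:02d}.{name}"] = arr
            if hasattr(mod, "state"):
                for name, arr in mod.state():
                    out[f"m{k:02d}.{name}"] = arr
        return out

    def save(self, path, extra: dict | None = None) -> None:
        """Serialise parameters + BN running statistics to ``path`` (npz format)."""
        meta = {"magic": CHECKPOINT_MAGIC, "dtype": self.dtype.name}
        if extra:
            meta.update(extra)
        arrays = dict(self.state_arrays())
        arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as fh:
            np.savez(fh, **arrays)

    @classmethod
    def load(cls, path, ledger: LayerLedger | None = None) -> "DMFNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]))
            if meta.get("magic") != CHECKPOINT_MAGIC:
                raise ValueError(f"{path} is not a DMF-Net checkpoint")
            net = cls(ledger=ledger, seed=0, dtype=np.dtype(meta["dtype"]))
            state = net.state_arrays()
            for key, arr in state.items():
                if key not in data:
                    raise ValueError(f"checkpoint missing array {key}")
                arr[...] = data[key]
        return net

    @staticmethod
    def checkpoint_meta(path) -> dict:
        with np.load(path) as data:
            return json.loads(bytes(data["__meta__"]))
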