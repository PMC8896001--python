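"""The convolutional autoencoder for SNP dosage data.

Architecture
------------
The encoder alternates stride-1 "same" 1-D convolutions (elu + batch
normalization) with max-pooling, then a fully-connected funnel down to a
small latent representation.  The decoder mirrors it with
nearest-neighbour upsampling and ends in a kernel-size-1 linear
convolution producing one pre-sigmoid scalar per marker, interpreted
downstream as an allele frequency under Hardy–Weinberg equilibrium.

Two trainable marker-specific variable sets restore positional
information that translation-invariant convolution discards: set A is
concatenated to the input channel stack and to a configured decoder
layer, set B to the second-last decoder layer.  Residual connections
add the output of a source layer to a destination layer's output; when
channel counts differ the source is projected with a kernel-size-1
convolution, and mismatched spatial lengths are a configuration error.

Inputs whose marker count is not a multiple of the total pooling factor
are zero-padded on the right and the final output is cropped back.

In clustering mode the latent layer has k units followed by a softmax,
so the encoding itself is a proportional cluster assignment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _autograd as ag
from .genotype_io import NormalizedBatch

__all__ = [
    "ArchitectureConfig",
    "MarkerVariables",
    "LatentEmbedding",
    "OutputFrequencies",
    "Autoencoder",
    "ConfigurationError",
    "build_autoencoder",
    "encode",
    "decode",
    "forward",
    "hwe_frequencies",
    "save_checkpoint",
    "load_checkpoint",
]


class ConfigurationError(ValueError):
    """An architecture configuration is internally inconsistent."""


@dataclass
class ArchitectureConfig:
    """Declarative description of the autoencoder.

    encoder_spec / decoder_spec entries:
        ("conv", n_kernels, kernel_size) | ("pool", factor) | ("upsample", factor)
    bottleneck_units: fully-connected widths between the flattened
        convolutional output and the latent layer (mirrored on decode).
    residual_connections: (source id, destination id) pairs naming layer
        outputs; the special id "<layer>_in" names a layer's input.
    marker_a_injection / marker_b_injection: decoder conv ids at whose
        *input* marker-variable sets A and B are concatenated.

    The shipped default is the implementation's own compact choice; it
    is sized to recover population structure on data of a few thousand
    markers, not to mirror any published layer table.
    """

    encoder_spec: list = field(
        default_factory=lambda: [("conv", 8, 5), ("pool", 5), ("conv", 8, 5), ("pool", 2)]
    )
    bottleneck_units: list = field(default_factory=lambda: [75])
    latent_dim: int = 2
    decoder_spec: list = field(
        default_factory=lambda: [("upsample", 2), ("conv", 8, 5), ("upsample", 5), ("conv", 8, 5)]
    )
    residual_connections: list = field(
        default_factory=lambda: [
            ("enc_conv0_in", "enc_conv0"),
            ("enc_conv1_in", "enc_conv1"),
            ("dec_conv0_in", "dec_conv0"),
            ("dec_conv1_in", "dec_conv1"),
        ]
    )
    dropout_rate: float = 0.01
    latent_noise_std: float = 0.2
    marker_a_injection: str = "dec_conv1"
    marker_b_injection: str = "final"
    batchnorm_momentum: float = 0.99
    normalize_latent: bool = True
    softmax_latent: bool = False  # clustering mode

    def validate(self):
        pools = [f for kind, *rest in self.encoder_spec if kind == "pool" for f in rest]
        ups = [f for kind, *rest in self.decoder_spec if kind == "upsample" for f in rest]
        if int(np.prod(pools)) != int(np.prod(ups)):
            raise ConfigurationError(
                f"product of pool factors {pools} must equal product of "
                f"upsample factors {ups}"
            )
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        for kind, *rest in list(self.encoder_spec) + list(self.decoder_spec):
            if kind == "conv" and rest[1] % 2 != 1:
                raise ConfigurationError("convolution kernel sizes must be odd")
        return self

    @property
    def total_pool_factor(self) -> int:
        return int(np.prod([f for kind, f in
                            [(k, r[0]) for k, *r in self.encoder_spec if k == "pool"]]))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        d = dict(d)
        for key in ("encoder_spec", "decoder_spec", "residual_connections"):
            if key in d:
                d[key] = [tuple(e) for e in d[key]]
        return cls(**d).validate()


@dataclass
class MarkerVariables:
    """The two trainable per-marker variable sets."""

    set_A: ag.Tensor
    set_B: ag.Tensor

    @classmethod
    def create(cls, n_markers: int, rng: np.random.Generator) -> "MarkerVariables":
        return cls(
            set_A=ag.Tensor(rng.normal(0.0, 0.1, n_markers), requires_grad=True),
            set_B=ag.Tensor(rng.normal(0.0, 0.1, n_markers), requires_grad=True),
        )


@dataclass
class LatentEmbedding:
    """Samples × d latent coordinates."""

    coords: np.ndarray

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass
class OutputFrequencies:
    """Sigmoid-squashed per-site output o and the implied genotype probabilities."""

    o: np.ndarray
    genotype_probs: np.ndarray


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

def _glorot(rng, shape, fan_in, fan_out):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Conv:
    def __init__(self, rng, kernel_size, in_ch, out_ch):
        self.w = ag.Tensor(
            _glorot(rng, (kernel_size, in_ch, out_ch), kernel_size * in_ch, out_ch),
            requires_grad=True,
        )
        self.b = ag.Tensor(np.zeros(out_ch), requires_grad=True)
        self.params = [self.w, self.b]

    def __call__(self, x):
        return ag.conv1d_same(x, self.w, self.b)


class _Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = ag.Tensor(_glorot(rng, (n_in, n_out), n_in, n_out), requires_grad=True)
        self.b = ag.Tensor(np.zeros(n_out), requires_grad=True)
        self.params = [self.w, self.b]

    def __call__(self, x, weight_mask=None):
        w = self.w if weight_mask is None else ag.mul(self.w, weight_mask)
        return ag.dense(x, w, self.b)


class _BatchNorm:
    """Per-channel batch normalization over (batch, length) axes."""

    def __init__(self, n_ch, momentum):
        self.gamma = ag.Tensor(np.ones(n_ch), requires_grad=True)
        self.beta = ag.Tensor(np.zeros(n_ch), requires_grad=True)
        self.running_mean = np.zeros(n_ch)
        self.running_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = 1e-5
        self.params = [self.gamma, self.beta]

    def __call__(self, x, training):
        if training:
            mu = ag.tmean(x, axis=(0, 1), keepdims=True)
            var = ag.tmean(ag.power(x - mu, 2.0), axis=(0, 1), keepdims=True)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
            xn = (x - mu) * ag.power(var + self.eps, -0.5)
        else:
            xn = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xn * self.gamma + self.beta


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class Autoencoder:
    """Handle bundling parameters, running statistics and configuration."""

    def __init__(self, config: ArchitectureConfig, n_markers: int, seed: int = 0):
        config.validate()
        self.config = config
        self.n_markers = n_markers
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._rng = np.random.default_rng(rng.integers(2**31))  # train-time noise

        tpf = config.total_pool_factor
        self.padded_len = int(np.ceil(n_markers / tpf) * tpf)

        self.layers = {}
        self.params = []
        self._shapes = {}  # layer id -> (length, channels) of its output

        # ---- encoder convolutional stack
        length, ch = self.padded_len, 3
        self._shapes["input"] = (length, ch)
        conv_i = 0
        self.enc_plan = []
        for kind, *rest in config.encoder_spec:
            if kind == "conv":
                name = f"enc_conv{conv_i}"
                self._shapes[f"{name}_in"] = (length, ch)
                layer = _Conv(rng, rest[1], ch, rest[0])
                bn = _BatchNorm(rest[0], config.batchnorm_momentum)
                self.layers[name] = (layer, bn)
                self.params += layer.params + bn.params
                ch = rest[0]
                self._shapes[name] = (length, ch)
                self.enc_plan.append(("conv", name))
                conv_i += 1
            elif kind == "pool":
                length //= rest[0]
                self.enc_plan.append(("pool", rest[0]))
            else:
                raise ConfigurationError(f"unknown encoder layer kind {kind!r}")
        self.conv_out_shape = (length, ch)
        flat = length * ch

        # ---- fully-connected funnel (encoder side: elu except latent; the
        # outermost decoder FC is linear)
        widths_enc = [flat] + list(config.bottleneck_units) + [config.latent_dim]
        self.enc_fc = []
        for i, (a, b) in enumerate(zip(widths_enc[:-1], widths_enc[1:])):
            lay = _Dense(rng, a, b)
            self.enc_fc.append(lay)
            self.params += lay.params
        widths_dec = [config.latent_dim] + list(reversed(config.bottleneck_units)) + [flat]
        self.dec_fc = []
        for a, b in zip(widths_dec[:-1], widths_dec[1:]):
            lay = _Dense(rng, a, b)
            self.dec_fc.append(lay)
            self.params += lay.params

        # ---- decoder convolutional stack
        conv_i = 0
        self.dec_plan = []
        for kind, *rest in config.decoder_spec:
            if kind == "conv":
                name = f"dec_conv{conv_i}"
                in_ch = ch
                if config.marker_a_injection == name:
                    in_ch += 1
                self._shapes[f"{name}_in"] = (length, in_ch)
                layer = _Conv(rng, rest[1], in_ch, rest[0])
                bn = _BatchNorm(rest[0], config.batchnorm_momentum)
                self.layers[name] = (layer, bn)
                self.params += layer.params + bn.params
                ch = rest[0]
                self._shapes[name] = (length, ch)
                self.dec_plan.append(("conv", name))
                conv_i += 1
            elif kind == "upsample":
                length *= rest[0]
                self.dec_plan.append(("upsample", rest[0]))
            else:
                raise ConfigurationError(f"unknown decoder layer kind {kind!r}")
        if length != self.padded_len:
            raise ConfigurationError(
                f"decoder ends at spatial length {length}, expected {self.padded_len}"
            )

        # ---- final kernel-size-1 linear convolution (no batch norm)
        in_ch = ch
        if config.marker_b_injection == "final":
            in_ch += 1
        if config.marker_a_injection == "final":
            in_ch += 1
        self.final_conv = _Conv(rng, 1, in_ch, 1)
        self.params += self.final_conv.params
        self._shapes["final_in"] = (length, in_ch)
        self._shapes["final"] = (length, 1)

        # ---- residual projections (kernel-size-1) where channels differ
        self.res_proj = {}
        self.res_by_dst = {}
        for src, dst in config.residual_connections:
            if src not in self._shapes or dst not in self._shapes:
                raise ConfigurationError(f"unknown residual layer id in ({src}, {dst})")
            (ls, cs), (ld, cd) = self._shapes[src], self._shapes[dst]
            if ls != ld:
                raise ConfigurationError(
                    f"residual ({src} -> {dst}): spatial lengths differ ({ls} vs {ld})"
                )
            if cs != cd:
                proj = _Conv(rng, 1, cs, cd)
                self.res_proj[(src, dst)] = proj
                self.params += proj.params
            self.res_by_dst.setdefault(dst, []).append(src)

        # per-unit batch normalization of the latent layer: anchors the
        # latent scale against the additive noise (dimensionality reduction)
        # and prevents saturation into a dead softmax vertex (clustering)
        self.latent_bn = None
        if config.softmax_latent or config.normalize_latent:
            self.latent_bn = _BatchNorm(config.latent_dim, config.batchnorm_momentum)
            self.params += self.latent_bn.params

        self.marker_vars = MarkerVariables.create(n_markers, rng)
        self.params += [self.marker_vars.set_A, self.marker_vars.set_B]

    # -- helpers ---------------------------------------------------------
    def _padded_marker_channel(self, var: ag.Tensor, batch: int) -> ag.Tensor:
        """(n_markers,) trainable vector -> (batch, padded_len, 1) channel."""
        v = ag.reshape(var, (1, self.n_markers, 1))
        v = ag.pad_axis1(v, 0, self.padded_len - self.n_markers)
        return ag.broadcast_to(v, (batch, self.padded_len, 1))

    def _apply_residuals(self, name, out, cache):
        for src in self.res_by_dst.get(name, []):
            s = cache[src]
            proj = self.res_proj.get((src, name))
            if proj is not None:
                s = proj(s)
            out = out + s
        return out

    def _dropout_mask(self, shape, training):
        p = self.config.dropout_rate
        if not training or p <= 0.0:
            return None
        return ag.Tensor(
            (self._rng.random(shape) >= p).astype(float) / (1.0 - p)
        )

    # -- forward passes --------------------------------------------------
    def encode_t(self, batch_values: np.ndarray, training: bool) -> ag.Tensor:
        """Graph-building encoder; batch_values is (B, n_markers, >=2).

        Channel 2 (the marker-specific variable) is rebuilt from the
        trainable set A so gradients reach it; channels 0 and 1 are
        taken from the batch as constants.
        """
        B, L, C = batch_values.shape
        if L != self.n_markers:
            raise ValueError(f"batch has {L} markers, model expects {self.n_markers}")
        geno_mask = ag.Tensor(batch_values[:, :, :2])
        geno_mask = ag.pad_axis1(geno_mask, 0, self.padded_len - L)
        mvar = self._padded_marker_channel(self.marker_vars.set_A, B)
        x = ag.concat([geno_mask, mvar], axis=2)

        cache = {"input": x}
        for kind, arg in self.enc_plan:
            if kind == "conv":
                cache[f"{arg}_in"] = x
                conv, bn = self.layers[arg]
                x = bn(ag.elu(conv(x)), training)
                x = self._apply_residuals(arg, x, cache)
                cache[arg] = x
            else:
                x = ag.maxpool1d(x, arg)

        x = ag.reshape(x, (B, -1))
        # elu on inner FC layers; the latent layer itself is linear.
        # dropout (DropConnect on weights) skips layers adjacent to the latent.
        n_fc = len(self.enc_fc)
        for i, lay in enumerate(self.enc_fc):
            adjacent_latent = i >= n_fc - 1
            mask = None if adjacent_latent else self._dropout_mask(lay.w.shape, training)
            x = lay(x, weight_mask=mask)
            if i < n_fc - 1:
                x = ag.elu(x)
        z = x
        if self.latent_bn is not None:
            z = ag.reshape(
                self.latent_bn(ag.reshape(z, (B, 1, -1)), training), (B, -1)
            )
        if training and self.config.latent_noise_std > 0:
            z = z + ag.Tensor(
                self._rng.normal(0.0, self.config.latent_noise_std, z.data.shape)
            )
        if self.config.softmax_latent:
            z = ag.softmax_lastdim(z)
        return z

    def decode_t(self, z: ag.Tensor, training: bool) -> ag.Tensor:
        """Graph-building decoder; returns pre-sigmoid (B, n_markers)."""
        B = z.data.shape[0]
        x = z
        n_fc = len(self.dec_fc)
        for i, lay in enumerate(self.dec_fc):
            adjacent_latent = i == 0
            outermost = i == n_fc - 1
            mask = None if adjacent_latent else self._dropout_mask(lay.w.shape, training)
            x = lay(x, weight_mask=mask)
            if not outermost:
                x = ag.elu(x)
        length, ch = self.conv_out_shape
        x = ag.reshape(x, (B, length, ch))

        cache = {}
        for kind, arg in self.dec_plan:
            if kind == "conv":
                if self.config.marker_a_injection == arg:
                    x = ag.concat(
                        [x, self._padded_marker_channel(self.marker_vars.set_A, B)],
                        axis=2,
                    )
                cache[f"{arg}_in"] = x
                conv, bn = self.layers[arg]
                x = bn(ag.elu(conv(x)), training)
                x = self._apply_residuals(arg, x, cache)
                cache[arg] = x
            else:
                x = ag.upsample1d(x, arg)

        extra = []
        if self.config.marker_a_injection == "final":
            extra.append(self._padded_marker_channel(self.marker_vars.set_A, B))
        if self.config.marker_b_injection == "final":
            extra.append(self._padded_marker_channel(self.marker_vars.set_B, B))
        if extra:
            x = ag.concat([x] + extra, axis=2)
        cache["final_in"] = x
        x = self.final_conv(x)  # linear, no batch norm
        x = self._apply_residuals("final", x, cache)
        x = ag.crop_axis1(x, 0, self.n_markers)
        return ag.reshape(x, (B, self.n_markers))

    def forward_t(self, batch_values: np.ndarray, training: bool):
        z = self.encode_t(batch_values, training)
        o_raw = self.decode_t(z, training)
        return z, o_raw

    # -- parameter snapshots ---------------------------------------------
    def get_parameters(self) -> list:
        return [p.data.copy() for p in self.params] + [
            self._bn_stats_flat()
        ]

    def _all_batchnorms(self):
        pairs = [(name, self.layers[name][1]) for name in sorted(self.layers)]
        if self.latent_bn is not None:
            pairs.append(("latent", self.latent_bn))
        return pairs

    def _bn_stats_flat(self):
        return [
            (bn.running_mean.copy(), bn.running_var.copy())
            for _, bn in self._all_batchnorms()
        ]

    def set_parameters(self, snapshot):
        *arrays, stats = snapshot
        for p, a in zip(self.params, arrays):
            p.data = a.copy()
        for (_, bn), (m, v) in zip(self._all_batchnorms(), stats):
            bn.running_mean, bn.running_var = m.copy(), v.copy()


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def build_autoencoder(config: ArchitectureConfig, n_markers: int, seed: int = 0) -> Autoencoder:
    """Construct a parameterized autoencoder; deterministic under seed."""
    return Autoencoder(config, n_markers, seed=seed)


def encode(model: Autoencoder, batch: NormalizedBatch, training: bool = False) -> LatentEmbedding:
    z = model.encode_t(batch.values, training)
    return LatentEmbedding(coords=z.data.copy())


def decode(model: Autoencoder, z: LatentEmbedding, training: bool = False) -> np.ndarray:
    out = model.decode_t(ag.Tensor(z.coords), training)
    return out.data.copy()


def hwe_frequencies(o_raw: np.ndarray) -> OutputFrequencies:
    """Map raw decoder output to Hardy–Weinberg genotype probabilities.

    o = sigmoid(o_raw) is the per-site allele frequency; the genotype
    triple is [(1-o)^2, 2(1-o)o, o^2].
    """
    o_raw = np.asarray(o_raw, dtype=float)
    o = 1.0 / (1.0 + np.exp(-o_raw))
    # keep o strictly inside (0, 1) where the sigmoid saturates in float64
    o = np.clip(o, 1e-12, 1.0 - 1e-12)
    probs = np.stack([(1.0 - o) ** 2, 2.0 * (1.0 - o) * o, o**2], axis=-1)
    return OutputFrequencies(o=o, genotype_probs=probs)


def forward(model: Autoencoder, batch: NormalizedBatch, training: bool = False):
    """Full pass: returns (LatentEmbedding, OutputFrequencies)."""
    z, o_raw = model.forward_t(batch.values, training)
    return LatentEmbedding(coords=z.data.copy()), hwe_frequencies(o_raw.data)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Autoencoder, path):
    """Self-describing archive: parameters + config + seed (npz)."""
    path = Path(path)
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.params)}
    for name, bn in model._all_batchnorms():
        arrays[f"bn_mean_{name}"] = bn.running_mean
        arrays[f"bn_var_{name}"] = bn.running_var
    meta = json.dumps(
        {"config": model.config.to_dict(), "n_markers": model.n_markers, "seed": model.seed}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> Autoencoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        config = ArchitectureConfig.from_dict(meta["config"])
        model = Autoencoder(config, meta["n_markers"], seed=meta["seed"])
        for i, p in enumerate(model.params):
            p.data = data[f"param_{i}"].copy()
        for name, bn in model._all_batchnorms():
            bn.running_mean = data[f"bn_mean_{name}"].copy()
            bn.running_var = data[f"bn_var_{name}"].copy()
    return model
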