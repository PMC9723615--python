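"""The two-branch classifier over at-site scores and epigenetic neighborhoods.

The convolutional branch reads the local-marker array (8 channels x 81 bins
at 25-bp resolution) through two 1-D convolutions with leaky-rectifier
activations — 32 kernels of width 4 with padding 1, then 32 kernels of width
5 — each followed by width-2 average pooling, so the length shrinks
81 -> 80 -> 40 -> 36 -> 18 and flattens to 32 x 18 = 576 units.  The at-site
branch is a 400-unit fully connected layer with sigmoid activation.  The
concatenated 976 units feed a 256-unit sigmoid layer and a single sigmoid
output node giving a score in (0, 1).

Training minimizes binary cross-entropy with L2 weight regularization
(weights only, not biases) using Adam at learning rate 1e-4, batch size 128,
for 30 epochs — the configuration under which the classifier was designed to
separate reporter-assay positives from matched genomic background.

Implemented directly on NumPy (see :mod:`.nn`); forward and backward passes
are explicit, which keeps the whole pipeline dependency-light and
deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from . import nn
from .errors import ConfigError


@dataclass
class ModelSpec:
    """Architecture hyperparameters; defaults reproduce the published shapes."""

    l_site: int = 1060
    n_markers: int = 8
    n_bins: int = 81
    conv1_kernels: int = 32
    conv1_width: int = 4
    conv1_pad: int = 1
    conv2_kernels: int = 32
    conv2_width: int = 5
    conv2_pad: int = 0
    pool_width: int = 2
    leaky_slope: float = 0.01
    site_units: int = 400
    joint_units: int = 256
    branches: str = "both"  # "both" | "site" | "neighborhood"

    def conv_lengths(self) -> tuple[int, int, int, int]:
        """(after conv1, pool1, conv2, pool2) sequence lengths."""
        l1 = self.n_bins + 2 * self.conv1_pad - self.conv1_width + 1
        p1 = l1 // self.pool_width
        l2 = p1 + 2 * self.conv2_pad - self.conv2_width + 1
        p2 = l2 // self.pool_width
        if min(l1, p1, l2, p2) <= 0:
            raise ConfigError(
                f"conv/pool stack collapses to non-positive length for n_bins={self.n_bins}"
            )
        return l1, p1, l2, p2

    @property
    def flat_units(self) -> int:
        return self.conv2_kernels * self.conv_lengths()[3]

    @property
    def joint_input(self) -> int:
        if self.branches == "site":
            return self.site_units
        if self.branches == "neighborhood":
            return self.flat_units
        return self.flat_units + self.site_units


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-4
    l2: float = 5e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigError("epochs and batch_size must be >= 1")
        if self.learning_rate <= 0 or self.l2 < 0:
            raise ConfigError("learning_rate must be > 0 and l2 >= 0")


def _fan_in_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class TwoBranchNet:
    """Seeded parameter container with explicit forward/backward passes."""

    WEIGHT_KEYS = ("wc1", "wc2", "ws", "wj", "wo")

    def __init__(self, spec: ModelSpec, seed: int = 0):
        if spec.l_site < 1:
            raise ConfigError("l_site must be >= 1")
        spec.conv_lengths()  # validates the stack
        self.spec = spec
        rng = np.random.default_rng([int(seed), 21])
        s = spec
        p: dict[str, np.ndarray] = {}
        f1 = s.n_markers * s.conv1_width
        p["wc1"] = _fan_in_uniform(rng, (s.conv1_kernels, f1), f1)
        p["bc1"] = _fan_in_uniform(rng, (s.conv1_kernels,), f1)
        f2 = s.conv1_kernels * s.conv2_width
        p["wc2"] = _fan_in_uniform(rng, (s.conv2_kernels, f2), f2)
        p["bc2"] = _fan_in_uniform(rng, (s.conv2_kernels,), f2)
        p["ws"] = _fan_in_uniform(rng, (s.site_units, s.l_site), s.l_site)
        p["bs"] = _fan_in_uniform(rng, (s.site_units,), s.l_site)
        p["wj"] = _fan_in_uniform(rng, (s.joint_units, s.joint_input), s.joint_input)
        p["bj"] = _fan_in_uniform(rng, (s.joint_units,), s.joint_input)
        p["wo"] = _fan_in_uniform(rng, (1, s.joint_units), s.joint_units)
        p["bo"] = _fan_in_uniform(rng, (1,), s.joint_units)
        self.params = p

    # ---------------------------------------------------------------- forward
    def _check_shapes(self, x_site: np.ndarray, x_nbhd: np.ndarray) -> None:
        s = self.spec
        if s.branches != "neighborhood" and x_site.shape[1] != s.l_site:
            raise ConfigError(
                f"site vector length {x_site.shape[1]} != model l_site {s.l_site}"
            )
        if s.branches != "site" and x_nbhd.shape[1:] != (s.n_markers, s.n_bins):
            raise ConfigError(
                f"neighborhood shape {x_nbhd.shape[1:]} != ({s.n_markers}, {s.n_bins})"
            )

    def forward(self, x_site: np.ndarray, x_nbhd: np.ndarray, cache: bool = False):
        s, p = self.spec, self.params
        self._check_shapes(x_site, x_nbhd)
        c: dict = {}
        parts = []
        if s.branches != "site":
            x = np.ascontiguousarray(np.transpose(x_nbhd, (0, 2, 1)))  # (N, bins, markers)
            z1, patches1 = nn.conv1d_forward(x, p["wc1"], p["bc1"], pad=s.conv1_pad)
            a1 = nn.leaky_relu(z1, s.leaky_slope)
            p1 = nn.avgpool_forward(a1, s.pool_width)
            z2, patches2 = nn.conv1d_forward(p1, p["wc2"], p["bc2"], pad=s.conv2_pad)
            a2 = nn.leaky_relu(z2, s.leaky_slope)
            p2 = nn.avgpool_forward(a2, s.pool_width)
            flat = p2.reshape(p2.shape[0], -1)
            parts.append(flat)
            if cache:
                c.update(x=x, z1=z1, patches1=patches1, a1_len=a1.shape[1],
                         p1=p1, z2=z2, patches2=patches2, a2_len=a2.shape[1],
                         p2_shape=p2.shape)
        if s.branches != "neighborhood":
            zs = x_site @ p["ws"].T + p["bs"]
            a_s = nn.sigmoid(zs)
            parts.append(a_s)
            if cache:
                c.update(x_site=x_site, a_s=a_s)
        h = np.concatenate(parts, axis=1)
        zj = h @ p["wj"].T + p["bj"]
        aj = nn.sigmoid(zj)
        zo = aj @ p["wo"].T + p["bo"]
        out = nn.sigmoid(zo)[:, 0]
        if cache:
            c.update(h=h, aj=aj)
            return out, c
        return out

    # --------------------------------------------------------------- backward
    def loss_and_grads(self, x_site, x_nbhd, y, l2: float = 0.0):
        """Mean regularized BCE and gradients of the data term.

        The L2 term (l2/2 * sum of squared weights) is reported in the loss;
        its gradient is applied by the optimizer as weight decay.
        """
        s, p = self.spec, self.params
        out, c = self.forward(x_site, x_nbhd, cache=True)
        n = len(y)
        loss = nn.bce_loss(out, y)
        if l2:
            loss += 0.5 * l2 * sum(float(np.sum(p[k] ** 2)) for k in self.WEIGHT_KEYS)

        g: dict[str, np.ndarray] = {}
        dzo = ((out - y) / n)[:, None]  # sigmoid+BCE shortcut
        g["wo"] = dzo.T @ c["aj"]
        g["bo"] = dzo.sum(axis=0)
        daj = dzo @ p["wo"]
        dzj = daj * c["aj"] * (1 - c["aj"])
        g["wj"] = dzj.T @ c["h"]
        g["bj"] = dzj.sum(axis=0)
        dh = dzj @ p["wj"]

        off = 0
        if s.branches != "site":
            flat_w = s.flat_units
            dflat = dh[:, :flat_w]
            off = flat_w
            dp2 = dflat.reshape(c["p2_shape"])
            da2 = nn.avgpool_backward(dp2, s.pool_width, c["a2_len"])
            dz2 = da2 * nn.leaky_relu_grad(c["z2"], s.leaky_slope)
            dp1, g["wc2"], g["bc2"] = nn.conv1d_backward(
                dz2, c["patches2"], p["wc2"], pad=s.conv2_pad,
                length=c["p1"].shape[1], c_in=s.conv1_kernels)
            da1 = nn.avgpool_backward(dp1, s.pool_width, c["a1_len"])
            dz1 = da1 * nn.leaky_relu_grad(c["z1"], s.leaky_slope)
            _, g["wc1"], g["bc1"] = nn.conv1d_backward(
                dz1, c["patches1"], p["wc1"], pad=s.conv1_pad,
                length=c["x"].shape[1], c_in=s.n_markers)
        else:
            g["wc1"] = np.zeros_like(p["wc1"]); g["bc1"] = np.zeros_like(p["bc1"])
            g["wc2"] = np.zeros_like(p["wc2"]); g["bc2"] = np.zeros_like(p["bc2"])
        if s.branches != "neighborhood":
            da_s = dh[:, off:]
            dzs = da_s * c["a_s"] * (1 - c["a_s"])
            g["ws"] = dzs.T @ c["x_site"]
            g["bs"] = dzs.sum(axis=0)
        else:
            g["ws"] = np.zeros_like(p["ws"]); g["bs"] = np.zeros_like(p["bs"])
        return loss, g

    def parameter_count(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def build_model(spec: ModelSpec, seed: int = 0) -> TwoBranchNet:
    """Initialize a classifier with seeded uniform fan-in weights."""
    return TwoBranchNet(spec, seed=seed)


@dataclass
class TrainResult:
    loss_history: list = field(default_factory=list)


def train(model: TwoBranchNet, x_site, x_nbhd, y, config: TrainConfig) -> TrainResult:
    """Minimize regularized binary cross-entropy on the training split.

    Returns the mean regularized batch loss per epoch.  Shuffling is seeded;
    two identical calls produce identical loss histories and parameters.
    """
    y = np.asarray(y, dtype=float)
    if len(y) == 0:
        raise ConfigError("empty training set")
    if len(np.unique(y)) < 2:
        raise ConfigError("training labels contain a single class")
    x_site = np.asarray(x_site, dtype=float)
    x_nbhd = np.asarray(x_nbhd, dtype=float)

    opt = nn.Adam(
        model.params, lr=config.learning_rate, l2=config.l2,
        decay_params=set(TwoBranchNet.WEIGHT_KEYS),
    )
    rng = np.random.default_rng([int(config.seed), 22])
    n = len(y)
    history = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, grads = model.loss_and_grads(x_site[idx], x_nbhd[idx], y[idx], l2=config.l2)
            opt.step(grads)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainResult(loss_history=history)


def predict(model: TwoBranchNet, x_site, x_nbhd) -> np.ndarray:
    """Raw classifier scores, strictly inside (0, 1)."""
    out = model.forward(np.asarray(x_site, float), np.asarray(x_nbhd, float))
    eps = np.finfo(float).tiny
    return np.clip(out, eps, 1.0 - 1e-16)


def save_checkpoint(model: TwoBranchNet, path) -> None:
    """Versioned .npz checkpoint with the architecture spec embedded."""
    meta = {"format_version": 1, "spec": asdict(model.spec)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.params)


def load_checkpoint(path) -> TwoBranchNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        spec = ModelSpec(**meta["spec"])
        model = TwoBranchNet(spec, seed=0)
        for k in model.params:
            model.params[k] = data[k].copy()
    return model
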