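"""Network construction and layer-wise training.

Each adjacent layer pair is trained as a restricted Boltzmann machine with
k-step contrastive divergence (optionally persistent), under localised
receptive-field masks.  Higher pairs are trained on the activation
probabilities of the trained layer below; the stack is then composed into a
single :class:`~homeodbm.core.LayeredNetwork` with no further joint training.

Exact enumeration helpers (`rbm_free_energy`, `exact_rbm_log_likelihood`,
`exact_rbm_gradient`) provide independent oracles for the learning signal on
tiny networks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp

from .core import LayeredNetwork

__all__ = [
    "TrainConfig",
    "RFSpec",
    "RBM",
    "make_rf_mask",
    "grid_shape",
    "init_network",
    "cd_update",
    "train_rbm",
    "layerwise_pretrain",
    "up_pass",
    "rbm_free_energy",
    "exact_rbm_log_likelihood",
    "exact_rbm_gradient",
]


@dataclass
class TrainConfig:
    """Hyper-parameters for one layer-pair training run.

    Defaults follow standard practice for small binary RBMs; every value is
    overridable per layer.
    """

    epochs: int = 30
    cd_steps: int = 1
    persistent: bool = False
    learning_rate: float = 0.05
    minibatch_size: int = 100
    weight_decay: float = 2e-4
    init_bias: float = -4.0
    weight_init_std: float = 0.01
    rng_seed: int = 0
    # optional activity-target regulariser during training (off by default)
    sparsity_target: float | None = None
    sparsity_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.minibatch_size < 1:
            raise ValueError("minibatch_size must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be non-negative")


@dataclass
class RFSpec:
    """Receptive-field layout: per-hidden-layer square patch sides.

    ``patch_sides[l]`` is the patch side for hidden layer ``l+1`` in units of
    the layer below; ``None`` means a global (all-ones) field.  The topmost
    hidden layer is always global.
    """

    patch_sides: list[int | None]

    def __post_init__(self) -> None:
        if self.patch_sides and self.patch_sides[-1] is not None:
            raise ValueError("topmost hidden layer must have a global field (None)")
        for p in self.patch_sides[:-1]:
            if p is not None and p < 1:
                raise ValueError("patch sides must be >= 1")


def grid_shape(count: int) -> tuple[int, int]:
    """Interpret a layer of ``count`` units as a square 2-D grid."""
    side = int(round(np.sqrt(count)))
    if side * side != count:
        raise ValueError(f"layer of {count} units has no square grid interpretation")
    return side, side


def make_rf_mask(
    lower_grid: tuple[int, int], upper_count: int, patch_side: int
) -> np.ndarray:
    """Binary connectivity mask between a 2-D lower layer and an upper layer.

    Upper units sit on an evenly spaced grid over the lower extent; each
    connects to the square patch of side ``patch_side`` centred at its grid
    position, clipped at the borders.  Returns a (lower, upper) {0,1} matrix.
    """
    lh, lw = lower_grid
    if patch_side > min(lh, lw):
        raise ValueError(f"patch side {patch_side} exceeds lower grid {lower_grid}")
    uh, uw = grid_shape(upper_count)
    # centre coordinates of upper units mapped onto the lower grid
    rows = (np.arange(uh) + 0.5) * lh / uh - 0.5
    cols = (np.arange(uw) + 0.5) * lw / uw - 0.5
    mask = np.zeros((lh * lw, upper_count))
    half = patch_side / 2.0
    for ui in range(uh):
        r0 = int(np.clip(np.round(rows[ui] - half + 0.5), 0, lh - patch_side))
        for uj in range(uw):
            c0 = int(np.clip(np.round(cols[uj] - half + 0.5), 0, lw - patch_side))
            patch = np.zeros((lh, lw))
            patch[r0 : r0 + patch_side, c0 : c0 + patch_side] = 1.0
            mask[:, ui * uw + uj] = patch.ravel()
    return mask


def build_masks(layer_sizes: Sequence[int], rf: RFSpec) -> list[np.ndarray]:
    """Receptive-field masks for every adjacent layer pair."""
    if len(rf.patch_sides) != len(layer_sizes) - 1:
        raise ValueError("need one patch spec per hidden layer")
    masks = []
    for l, patch in enumerate(rf.patch_sides):
        lower, upper = layer_sizes[l], layer_sizes[l + 1]
        if patch is None:
            masks.append(np.ones((lower, upper)))
        else:
            masks.append(make_rf_mask(grid_shape(lower), upper, patch))
    return masks


def init_network(
    layer_sizes: Sequence[int],
    rf: RFSpec,
    cfg: TrainConfig,
    visible_shape: tuple[int, int] | None = None,
) -> LayeredNetwork:
    """Fresh network: small zero-mean masked weights, all biases at ``init_bias``."""
    rng = np.random.default_rng(cfg.rng_seed)
    masks = build_masks(layer_sizes, rf)
    weights = [
        rng.normal(0.0, cfg.weight_init_std, size=m.shape) * m for m in masks
    ]
    biases = [np.full(n, float(cfg.init_bias)) for n in layer_sizes]
    if visible_shape is None:
        try:
            visible_shape = grid_shape(layer_sizes[0])
        except ValueError:
            visible_shape = None
    return LayeredNetwork(list(layer_sizes), weights, biases, masks, visible_shape)


# ---------------------------------------------------------------------------
# RBM view and contrastive divergence
# ---------------------------------------------------------------------------


@dataclass
class RBM:
    """A visible/hidden layer pair with symmetric masked weights.

    ``up_scale``/``down_scale`` multiply the conditional inputs during
    training.  When a pair is destined for the middle of a deeper stack, the
    side that will later receive input from two neighbouring layers is
    trained with its input doubled, so that drive levels match between
    pair-wise training and full-stack inference.  A standalone pair keeps
    both scales at 1.
    """

    w: np.ndarray  # (n_visible, n_hidden)
    vbias: np.ndarray
    hbias: np.ndarray
    mask: np.ndarray
    up_scale: float = 1.0
    down_scale: float = 1.0

    @property
    def n_visible(self) -> int:
        return self.w.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.w.shape[1]

    def hidden_probs(self, v: np.ndarray) -> np.ndarray:
        return expit(self.up_scale * (v @ self.w) + self.hbias)

    def visible_probs(self, h: np.ndarray) -> np.ndarray:
        return expit(self.down_scale * (h @ self.w.T) + self.vbias)

    def copy(self) -> "RBM":
        return RBM(self.w.copy(), self.vbias.copy(), self.hbias.copy(),
                   self.mask.copy(), self.up_scale, self.down_scale)


def cd_update(
    rbm: RBM,
    minibatch: np.ndarray,
    cfg: TrainConfig,
    rng: np.random.Generator,
    chains: np.ndarray | None = None,
) -> np.ndarray | None:
    """One contrastive-divergence parameter update, in place.

    The positive phase uses hidden activation probabilities given the data;
    the negative phase runs ``cfg.cd_steps`` alternating block-Gibbs steps
    starting from the data (CD) or from ``chains`` of persistent hidden
    states (PCD).  Returns the updated chains (hidden samples) for PCD, else
    ``None``.
    """
    v0 = np.asarray(minibatch, dtype=float)
    if v0.ndim != 2 or v0.shape[1] != rbm.n_visible:
        raise ValueError(
            f"minibatch shape {v0.shape} incompatible with {rbm.n_visible} visible units"
        )
    n = v0.shape[0]
    ph0 = rbm.hidden_probs(v0)

    if cfg.persistent and chains is not None:
        h = chains
        if h.shape != (n, rbm.n_hidden):
            raise ValueError("persistent chains do not match minibatch shape")
    else:
        h = (rng.random(ph0.shape) < ph0).astype(float)
    for _ in range(cfg.cd_steps):
        pv = rbm.visible_probs(h)
        vneg = (rng.random(pv.shape) < pv).astype(float)
        phneg = rbm.hidden_probs(vneg)
        h = (rng.random(phneg.shape) < phneg).astype(float)

    lr = cfg.learning_rate
    grad_w = (v0.T @ ph0 - vneg.T @ phneg) / n
    rbm.w += lr * (grad_w - cfg.weight_decay * rbm.w)
    rbm.w *= rbm.mask
    rbm.vbias += lr * (v0 - vneg).mean(axis=0)
    hgrad = (ph0 - phneg).mean(axis=0)
    if cfg.sparsity_target is not None:
        hgrad += cfg.sparsity_rate * (cfg.sparsity_target - ph0.mean(axis=0))
    rbm.hbias += lr * hgrad
    return h if cfg.persistent else None


def train_rbm(
    rbm: RBM, data: np.ndarray, cfg: TrainConfig, rng: np.random.Generator
) -> list[float]:
    """Epoch loop over shuffled minibatches; returns per-epoch reconstruction error.

    Reconstruction error is the mean squared difference between the data and
    its one-step reconstruction, measured at the start of every epoch and
    once more after the final one.
    """
    n = data.shape[0]
    if n == 0:
        raise ValueError("empty training data")
    chains: np.ndarray | None = None

    def recon_error() -> float:
        ph = rbm.hidden_probs(data)
        pv = rbm.visible_probs(ph)
        return float(np.mean((data - pv) ** 2))

    log = [recon_error()]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.minibatch_size):
            batch = data[order[start : start + cfg.minibatch_size]]
            if cfg.persistent and chains is not None and chains.shape[0] != batch.shape[0]:
                chains = None  # ragged final batch: restart those chains from data
            chains = cd_update(rbm, batch, cfg, rng, chains)
        log.append(recon_error())
    return log


def up_pass(net: LayeredNetwork, visible: np.ndarray, to_layer: int | None = None,
            doubled: bool = True) -> np.ndarray:
    """Deterministic bottom-up pass returning activation probabilities.

    With ``doubled=True`` the weights are doubled at every step into an
    intermediate layer, compensating for the missing top-down input; the
    step into the topmost layer, which receives bottom-up input only, is
    never doubled.  This mirrors the decoder's top-down convention.
    """
    if to_layer is None:
        to_layer = net.n_layers - 1
    x = np.asarray(visible, dtype=float)
    for l in range(to_layer):
        scale = 2.0 if doubled and l + 1 < net.n_layers - 1 else 1.0
        x = expit(scale * (x @ net.weights[l]) + net.biases[l + 1])
    return x


def layerwise_pretrain(
    data: np.ndarray,
    layer_sizes: Sequence[int],
    rf: RFSpec,
    cfgs: TrainConfig | Sequence[TrainConfig],
    use_sample_inputs: bool = False,
    dbm_scaling: bool = True,
) -> tuple[LayeredNetwork, list[list[float]]]:
    """Train the stack bottom-up, one adjacent layer pair at a time.

    Each higher pair is trained on the hidden activation probabilities of the
    trained pair below (samples instead if ``use_sample_inputs``).  With
    ``dbm_scaling`` (default) the pair-wise conditionals double the input of
    every layer that later sits between two neighbours, so that activation
    levels carry over from pair training to full-stack inference; without it
    the pairs are composed directly.  Returns the composed network and the
    per-layer reconstruction-error logs.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("empty training data")
    if data.shape[1] != layer_sizes[0]:
        raise ValueError("data width does not match the visible layer size")
    if isinstance(cfgs, TrainConfig):
        cfgs = [replace(cfgs, rng_seed=cfgs.rng_seed + l)
                for l in range(len(layer_sizes) - 1)]
    net = init_network(layer_sizes, rf, cfgs[0])
    logs: list[list[float]] = []
    n_pairs = len(layer_sizes) - 1
    x = data
    for l in range(n_pairs):
        cfg = cfgs[l]
        rng = np.random.default_rng(cfg.rng_seed)
        up = 2.0 if dbm_scaling and l < n_pairs - 1 else 1.0
        down = 2.0 if dbm_scaling and l > 0 else 1.0
        rbm = RBM(net.weights[l], net.biases[l], net.biases[l + 1],
                  net.rf_masks[l], up_scale=up, down_scale=down)
        logs.append(train_rbm(rbm, x, cfg, rng))
        ph = rbm.hidden_probs(x)
        x = (rng.random(ph.shape) < ph).astype(float) if use_sample_inputs else ph
    net.metadata["training"] = {
        "n_images": int(data.shape[0]),
        "epochs": [c.epochs for c in cfgs],
        "cd_steps": [c.cd_steps for c in cfgs],
        "persistent": [c.persistent for c in cfgs],
        "seeds": [c.rng_seed for c in cfgs],
    }
    net.validate()
    return net, logs


# ---------------------------------------------------------------------------
# exact oracles for small RBMs
# ---------------------------------------------------------------------------


def _all_binary(n: int) -> np.ndarray:
    idx = np.arange(1 << n, dtype=np.int64)
    return ((idx[:, None] >> np.arange(n, dtype=np.int64)) & 1).astype(float)


def rbm_free_energy(rbm: RBM, v: np.ndarray) -> np.ndarray:
    """F(v) = -v.b_v - sum_j softplus(hidden input), so p(v) ∝ exp(-F(v))."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    act = v @ rbm.w + rbm.hbias
    return -(v @ rbm.vbias) - np.logaddexp(0.0, act).sum(axis=1)


def exact_rbm_log_likelihood(rbm: RBM, data: np.ndarray) -> float:
    """Mean log-likelihood of ``data`` by full enumeration of visible states."""
    if rbm.n_visible > 20:
        raise ValueError("enumeration limited to 20 visible units")
    log_z = logsumexp(-rbm_free_energy(rbm, _all_binary(rbm.n_visible)))
    return float(np.mean(-rbm_free_energy(rbm, data)) - log_z)


def exact_rbm_gradient(
    rbm: RBM, data: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact mean log-likelihood gradient (dW, dvbias, dhbias) by enumeration."""
    if rbm.n_visible > 20:
        raise ValueError("enumeration limited to 20 visible units")
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ph = rbm.hidden_probs(data)
    pos_w = data.T @ ph / data.shape[0]
    pos_v = data.mean(axis=0)
    pos_h = ph.mean(axis=0)

    allv = _all_binary(rbm.n_visible)
    f = -rbm_free_energy(rbm, allv)
    p = np.exp(f - logsumexp(f))
    ph_all = rbm.hidden_probs(allv)
    neg_w = (allv * p[:, None]).T @ ph_all
    neg_v = p @ allv
    neg_h = p @ ph_all
    return pos_w - neg_w, pos_v - neg_v, pos_h - neg_h
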