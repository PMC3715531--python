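"""Layered Boltzmann machine: architecture, inference and exact oracles.

A :class:`LayeredNetwork` is a stack of binary unit layers connected only
between adjacent layers (no lateral connections), with symmetric weights,
per-unit biases and binary receptive-field masks.  Inference is block Gibbs
sampling (all units of a layer resampled in parallel from their conditional
distribution, valid because layers have no internal connections) or its
deterministic mean-field variant, which propagates activation probabilities
instead of samples.

Intermediate hidden layers can combine their bottom-up and top-down drive
through a balance factor ``lam`` in [0, 1]::

    input = 2*lam * (bottom-up) + 2*(1 - lam) * (top-down) + bias

``lam = 0.5`` reduces exactly to the ordinary conditional input, ``lam > 0.5``
emphasises feedforward (sensory) drive, ``lam < 0.5`` emphasises feedback
(internally generated) drive.  This models the action of a gain neuromodulator
on the feedforward/feedback balance of a processing hierarchy.

:func:`exact_distribution` enumerates the Boltzmann distribution of small
networks and serves as the independent oracle for the sampler.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "CHECKPOINT_FORMAT_VERSION",
    "LayeredNetwork",
    "NetworkState",
    "SamplerConfig",
    "sigmoid",
    "activation_prob",
    "total_input",
    "balanced_input",
    "layer_input",
    "gibbs_sweep",
    "mean_field_sweep",
    "run_trial",
    "energy",
    "exact_distribution",
    "state_index",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_FORMAT_VERSION = 1


def sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    """Logistic function, numerically stable for extreme inputs (saturates)."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


#: alias matching the conditional activation probability of a unit
activation_prob = sigmoid


@dataclass
class LayeredNetwork:
    """Weights, biases and receptive-field masks of an L-layer machine.

    ``weights[l]`` has shape ``(layer_sizes[l], layer_sizes[l+1])`` and is used
    symmetrically; ``rf_masks[l]`` is a congruent {0,1} matrix and masked-out
    weights are exactly zero at all times.
    """

    layer_sizes: list[int]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    rf_masks: list[np.ndarray]
    visible_shape: tuple[int, int] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_layers(self) -> int:
        return len(self.layer_sizes)

    @property
    def n_units(self) -> int:
        return int(sum(self.layer_sizes))

    def validate(self) -> None:
        sizes = self.layer_sizes
        if any(int(s) <= 0 for s in sizes):
            raise ValueError("layer sizes must be positive")
        if len(self.weights) != len(sizes) - 1:
            raise ValueError("need one weight matrix per adjacent layer pair")
        if len(self.biases) != len(sizes):
            raise ValueError("need one bias vector per layer")
        if len(self.rf_masks) != len(self.weights):
            raise ValueError("need one mask per weight matrix")
        for l, (w, m) in enumerate(zip(self.weights, self.rf_masks)):
            if w.shape != (sizes[l], sizes[l + 1]):
                raise ValueError(f"weight {l} has shape {w.shape}")
            if m.shape != w.shape:
                raise ValueError(f"mask {l} incongruent with weight {l}")
            if np.any(w[m == 0] != 0.0):
                raise ValueError(f"weight {l} nonzero outside its mask")
        for l, b in enumerate(self.biases):
            if b.shape != (sizes[l],):
                raise ValueError(f"bias {l} has shape {b.shape}")

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(
            list(self.layer_sizes),
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            [m.copy() for m in self.rf_masks],
            self.visible_shape,
            dict(self.metadata),
        )


@dataclass
class NetworkState:
    """Per-layer unit states with clamping flags.

    Hidden entries are binary in stochastic mode or probabilities in
    mean-field mode; the visible layer may hold grey-scale values in [0, 1]
    when clamped, which sampling treats as expected states.  States may be
    batched: each layer array is ``(n_units,)`` or ``(batch, n_units)``.
    """

    layer_states: list[np.ndarray]
    clamped: list[bool]

    @classmethod
    def from_visible(
        cls, net: LayeredNetwork, visible: np.ndarray, clamp_visible: bool = True
    ) -> "NetworkState":
        """Visible layer set (and by default clamped) to ``visible``; hidden zeros."""
        visible = np.asarray(visible, dtype=float)
        batch = visible.shape[:-1]
        states = [visible.copy()]
        for n in net.layer_sizes[1:]:
            states.append(np.zeros(batch + (n,)))
        clamped = [clamp_visible] + [False] * (net.n_layers - 1)
        return cls(states, clamped)

    def copy(self) -> "NetworkState":
        return NetworkState([s.copy() for s in self.layer_states], list(self.clamped))


@dataclass
class SamplerConfig:
    """Configuration of one inference trial."""

    cycles: int = 50
    mode: str = "stochastic"  # or "mean_field"
    ach_lambda: float | None = None  # None = plain conditional; 0.5 is equivalent
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")
        if self.mode not in ("stochastic", "mean_field"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.ach_lambda is not None and not 0.0 <= self.ach_lambda <= 1.0:
            raise ValueError("ach_lambda must lie in [0, 1]")


# ---------------------------------------------------------------------------
# conditional inputs
# ---------------------------------------------------------------------------


def total_input(
    net: LayeredNetwork, state: NetworkState, layer: int, unit: int
) -> float:
    """Summed weighted input from adjacent layers plus bias, for one unit."""
    if not 0 <= layer < net.n_layers:
        raise IndexError(f"layer {layer} out of range")
    if not 0 <= unit < net.layer_sizes[layer]:
        raise IndexError(f"unit {unit} out of range for layer {layer}")
    total = float(net.biases[layer][unit])
    if layer > 0:
        total += float(state.layer_states[layer - 1] @ net.weights[layer - 1][:, unit])
    if layer < net.n_layers - 1:
        total += float(net.weights[layer][unit] @ state.layer_states[layer + 1])
    return total


def balanced_input(
    net: LayeredNetwork, state: NetworkState, layer: int, lam: float
) -> np.ndarray:
    """Balance-weighted conditional input of an intermediate hidden layer.

    ``2*lam*bottom_up + 2*(1-lam)*top_down + bias``; at ``lam = 0.5`` this is
    bit-identical to the plain conditional input.
    """
    if layer <= 0 or layer >= net.n_layers - 1:
        raise ValueError("balanced_input needs a layer with neighbours on both sides")
    bottom_up = state.layer_states[layer - 1] @ net.weights[layer - 1]
    top_down = state.layer_states[layer + 1] @ net.weights[layer].T
    return (2.0 * lam) * bottom_up + (2.0 * (1.0 - lam)) * top_down + net.biases[layer]


def layer_input(
    net: LayeredNetwork,
    states: Sequence[np.ndarray],
    layer: int,
    lam: float | np.ndarray | None = None,
) -> np.ndarray:
    """Conditional input of a whole layer given current adjacent states.

    ``lam`` applies only to intermediate layers (both neighbours present); it
    may be a scalar or a per-row vector for batched states.  ``None`` selects
    the plain unweighted conditional.
    """
    n_layers = len(states)
    below = states[layer - 1] @ net.weights[layer - 1] if layer > 0 else None
    above = states[layer + 1] @ net.weights[layer].T if layer < n_layers - 1 else None
    b = net.biases[layer]
    if below is None:
        return above + b
    if above is None:
        return below + b
    if lam is None:
        return below + above + b
    lam = np.asarray(lam, dtype=float)
    if lam.ndim == 1:  # per-trial balance values for a batched state
        lam = lam[:, None]
    return (2.0 * lam) * below + (2.0 * (1.0 - lam)) * above + b


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------


def _sweep(
    net: LayeredNetwork,
    states: list[np.ndarray],
    clamped: Sequence[bool],
    lam: float | np.ndarray | None,
    rng: np.random.Generator | None,
    mean_field: bool,
    collect_probs: list[np.ndarray] | None = None,
) -> None:
    """One in-place cycle over all unclamped layers in ascending order.

    The topmost layer and the visible layer always use the plain conditional
    (they have a single neighbour); ``lam`` only reweights intermediate
    layers.  With ``collect_probs`` given, the activation probabilities used
    at each update are appended per hidden layer (index ``layer - 1``).
    """
    n_layers = len(states)
    if all(clamped):
        raise ValueError("cannot sweep: every layer is clamped")
    for layer in range(n_layers):
        if clamped[layer]:
            continue
        p = sigmoid(layer_input(net, states, layer, lam))
        if mean_field:
            states[layer] = p
        else:
            states[layer] = (rng.random(p.shape) < p).astype(float)
        if collect_probs is not None and layer > 0:
            collect_probs[layer - 1] = p


def gibbs_sweep(
    net: LayeredNetwork,
    state: NetworkState,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """One stochastic block-Gibbs cycle; clamped layers are returned unchanged."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = state.copy()
    _sweep(net, out.layer_states, out.clamped, config.ach_lambda, rng, False)
    return out


def mean_field_sweep(
    net: LayeredNetwork,
    state: NetworkState,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> NetworkState:
    """Deterministic cycle setting each layer to its conditional probabilities."""
    out = state.copy()
    _sweep(net, out.layer_states, out.clamped, config.ach_lambda, None, True)
    return out


def run_trial(
    net: LayeredNetwork,
    state: NetworkState,
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
    record_states: bool = False,
) -> tuple[NetworkState, dict]:
    """Run ``config.cycles`` sweeps, accumulating hidden activation probabilities.

    Returns the final state and a dict with ``mean_probs`` (per hidden layer,
    averaged over cycles) and, if requested, the per-cycle layer states.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    out = state.copy()
    mean_field = config.mode == "mean_field"
    sums: list[np.ndarray | None] = [None] * (net.n_layers - 1)
    probs: list[np.ndarray] = [None] * (net.n_layers - 1)  # type: ignore[list-item]
    trace: list[list[np.ndarray]] = []
    for _ in range(config.cycles):
        _sweep(
            net, out.layer_states, out.clamped, config.ach_lambda, rng, mean_field, probs
        )
        for i, p in enumerate(probs):
            if p is None:  # clamped hidden layer: activity is its clamped value
                p = out.layer_states[i + 1]
            sums[i] = p.copy() if sums[i] is None else sums[i] + p
        if record_states:
            trace.append([s.copy() for s in out.layer_states])
    info = {"mean_probs": [s / config.cycles for s in sums]}
    if record_states:
        info["states"] = trace
    return out, info


# ---------------------------------------------------------------------------
# energy and exact oracle
# ---------------------------------------------------------------------------


def energy(net: LayeredNetwork, state: NetworkState | Sequence[np.ndarray]) -> float:
    """Energy ``-sum w*s*s - sum b*s`` over all connected pairs and units."""
    states = state.layer_states if isinstance(state, NetworkState) else list(state)
    total = 0.0
    for l, w in enumerate(net.weights):
        total -= float(np.einsum("...i,ij,...j->...", states[l], w, states[l + 1]))
    for l, b in enumerate(net.biases):
        total -= float(states[l] @ b)
    return total


def _batch_energy(net: LayeredNetwork, layers: list[np.ndarray]) -> np.ndarray:
    e = np.zeros(layers[0].shape[0])
    for l, w in enumerate(net.weights):
        e -= np.einsum("bi,ij,bj->b", layers[l], w, layers[l + 1])
    for l, b in enumerate(net.biases):
        e -= layers[l] @ b
    return e


def state_index(net: LayeredNetwork, states: Sequence[np.ndarray]) -> int:
    """Map a joint binary state to its row in :func:`exact_distribution`.

    Unit ``j`` of layer ``l`` contributes bit ``offset(l) + j`` (LSB first).
    """
    bits = np.concatenate([np.asarray(s).ravel() for s in states])
    return int(np.round(bits) @ (1 << np.arange(bits.size, dtype=np.int64)))


def exact_distribution(net: LayeredNetwork, max_units: int = 20) -> np.ndarray:
    """Boltzmann distribution over all joint binary states, by enumeration.

    Returns probabilities indexed by :func:`state_index`.  Only feasible for
    small networks; this is the independent test oracle for the sampler.
    """
    n = net.n_units
    if n > max_units:
        raise ValueError(
            f"exact enumeration limited to {max_units} units, network has {n}"
        )
    n_states = 1 << n
    offsets = np.cumsum([0] + list(net.layer_sizes))
    energies = np.empty(n_states)
    chunk = 1 << 16
    for start in range(0, n_states, chunk):
        idx = np.arange(start, min(start + chunk, n_states), dtype=np.int64)
        bits = ((idx[:, None] >> np.arange(n, dtype=np.int64)) & 1).astype(float)
        layers = [bits[:, offsets[l] : offsets[l + 1]] for l in range(net.n_layers)]
        energies[start : start + idx.size] = _batch_energy(net, layers)
    logp = -energies
    logp -= logp.max()
    p = np.exp(logp)
    return p / p.sum()


# ---------------------------------------------------------------------------
# checkpoint container
# ---------------------------------------------------------------------------


def save_checkpoint(net: LayeredNetwork, path: str) -> None:
    """Persist a network to a single ``.npz`` container with metadata."""
    meta = dict(net.metadata)
    meta["format_version"] = CHECKPOINT_FORMAT_VERSION
    if net.visible_shape is not None:
        meta["visible_shape"] = list(net.visible_shape)
    arrays = {"layer_sizes": np.array(net.layer_sizes, dtype=np.int64)}
    for l, w in enumerate(net.weights):
        arrays[f"weight_{l}"] = w
        arrays[f"mask_{l}"] = net.rf_masks[l]
    for l, b in enumerate(net.biases):
        arrays[f"bias_{l}"] = b
    arrays["metadata_json"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_checkpoint(path: str) -> LayeredNetwork:
    """Load a network checkpoint, rejecting unknown format versions."""
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["metadata_json"]))
        version = meta.pop("format_version", None)
        if version != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(
                f"checkpoint format version {version!r} not supported "
                f"(expected {CHECKPOINT_FORMAT_VERSION})"
            )
        sizes = [int(s) for s in data["layer_sizes"]]
        weights = [data[f"weight_{l}"] for l in range(len(sizes) - 1)]
        masks = [data[f"mask_{l}"] for l in range(len(sizes) - 1)]
        biases = [data[f"bias_{l}"] for l in range(len(sizes))]
        visible_shape = meta.pop("visible_shape", None)
    return LayeredNetwork(
        sizes,
        weights,
        biases,
        masks,
        tuple(visible_shape) if visible_shape else None,
        meta,
    )
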