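"""Homeostatic regulation of unit excitability.

Each hidden unit carries a target activity — its average activation
probability during inference over the training data, measured after training
— and, during simulated input degradation, a current average activity
measured over repeated inference trials.  Between iterations every hidden
bias is incremented by ``rate * (target - current)``; weights are never
touched.  Parameters are frozen within trials and updated only between them.

Activity is always the activation probability at each update, not the binary
sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import LayeredNetwork, NetworkState, SamplerConfig, run_trial
from .data import Provider
from .decoder import decode_states
from .quality import EMPTY_PERCEPT_PEAK, QualityResult, TemplateBank

__all__ = [
    "HomeostasisConfig",
    "ActivityStats",
    "AdaptationTrace",
    "measure_target_activity",
    "measure_current_activity",
    "homeostatic_step",
    "run_adaptation",
]


@dataclass
class HomeostasisConfig:
    """Protocol parameters for adaptation runs."""

    rate: float = 0.1
    trials_per_iteration: int = 100
    cycles_per_trial: int = 50
    max_iterations: int = 50
    rng_seed: int = 0
    #: balance factor: None (plain conditional), a scalar, or a per-trial array
    lam: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.trials_per_iteration < 1 or self.cycles_per_trial < 1:
            raise ValueError("trials and cycles must be >= 1")


@dataclass
class ActivityStats:
    """Per-hidden-layer target and current average activities, all in [0, 1]."""

    target: list[np.ndarray]
    current: list[np.ndarray]


@dataclass
class AdaptationTrace:
    """Per-iteration record of an adaptation run.

    ``mean_activity[i, l]`` is the grand mean activation of hidden layer
    ``l+1`` at iteration ``i``; ``bias_shift`` is the mean absolute
    difference between current and initial hidden biases; ``records`` holds
    one row per scored trial (quality, matched class, position, balance
    factor, per-layer activity).
    """

    target_mean: np.ndarray
    mean_activity: np.ndarray
    bias_shift: np.ndarray
    mean_quality: np.ndarray
    records: pd.DataFrame
    config: HomeostasisConfig | None = None

    @property
    def n_iterations(self) -> int:
        return len(self.bias_shift)

    def to_csv(self, path: str) -> None:
        self.records.to_csv(path, index=False)


def _measure(
    net: LayeredNetwork,
    visible: np.ndarray,
    cycles: int,
    rng: np.random.Generator,
    lam: float | np.ndarray | None = None,
    clamped_layers: Mapping[int, np.ndarray] | None = None,
    mode: str = "stochastic",
) -> tuple[NetworkState, list[np.ndarray]]:
    """Run one batched trial block; returns final state and per-layer mean probs."""
    state = NetworkState.from_visible(net, visible)
    if clamped_layers:
        batch = visible.shape[:-1]
        for layer, value in clamped_layers.items():
            if layer == 0:
                raise ValueError("visible clamps go through the provider")
            state.layer_states[layer] = np.broadcast_to(
                np.asarray(value, dtype=float), batch + (net.layer_sizes[layer],)
            ).copy()
            state.clamped[layer] = True
    if lam is not None and np.any((np.asarray(lam) < 0) | (np.asarray(lam) > 1)):
        raise ValueError("balance factor must lie in [0, 1]")
    cfg = SamplerConfig(cycles=cycles, mode=mode, ach_lambda=None)
    cfg.ach_lambda = lam  # assigned post-validation: may be a per-trial vector
    final, info = run_trial(net, state, cfg, rng)
    return final, info["mean_probs"]


def measure_target_activity(
    net: LayeredNetwork,
    dataset_images: np.ndarray,
    cycles: int = 50,
    rng: np.random.Generator | int = 0,
) -> list[np.ndarray]:
    """Per-unit target activities: grand mean activation over the training data.

    One trial per image: the image is clamped, hidden layers start at zero,
    and activation probabilities are accumulated over ``cycles`` sweeps.
    """
    images = np.atleast_2d(np.asarray(dataset_images, dtype=float))
    if images.shape[0] == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(rng)
    _, mean_probs = _measure(net, images, cycles, rng)
    return [p.mean(axis=0) for p in mean_probs]


def measure_current_activity(
    net: LayeredNetwork,
    input_provider: Provider,
    config: HomeostasisConfig,
    rng: np.random.Generator | None = None,
    clamped_layers: Mapping[int, np.ndarray] | None = None,
) -> list[np.ndarray]:
    """Per-unit current activities under scenario-provided inputs."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    visible = input_provider(rng, config.trials_per_iteration)
    _, mean_probs = _measure(
        net, visible, config.cycles_per_trial, rng, config.lam, clamped_layers
    )
    return [p.mean(axis=0) for p in mean_probs]


def homeostatic_step(
    net: LayeredNetwork,
    stats: ActivityStats,
    rate: float,
) -> LayeredNetwork:
    """Increment each hidden bias by ``rate * (target - current)``, in place.

    Weights and visible biases are untouched; the (mutated) network is
    returned for convenience.
    """
    if len(stats.target) != net.n_layers - 1 or len(stats.current) != net.n_layers - 1:
        raise ValueError("stats must cover every hidden layer exactly once")
    for l in range(1, net.n_layers):
        net.biases[l] += rate * (stats.target[l - 1] - stats.current[l - 1])
    return net


def run_adaptation(
    net: LayeredNetwork,
    input_provider: Provider,
    targets: Sequence[np.ndarray],
    config: HomeostasisConfig,
    bank: TemplateBank | None = None,
    clamped_layers: Mapping[int, np.ndarray] | None = None,
    score_fn: Callable[[np.ndarray], list[QualityResult]] | None = None,
    classifier=None,
) -> tuple[LayeredNetwork, AdaptationTrace]:
    """Alternate activity measurement and bias adaptation for ``max_iterations``.

    The input network is left untouched; an adapted copy is returned along
    with the trace.  Each iteration runs ``trials_per_iteration`` trials of
    ``cycles_per_trial`` sweeps, decodes the topmost layer's final states and
    scores them (``bank`` for template quality, or an arbitrary ``score_fn``
    over decoded pixel batches).  A label-augmented ``classifier`` adds a
    predicted class per decoded trial; providers returning ``(batch, labels)``
    add the true class, enabling per-iteration classification error.
    """
    net = net.copy()
    master = np.random.default_rng(config.rng_seed)
    b_init = [b.copy() for b in net.biases[1:]]
    n_hidden = net.n_layers - 1
    top = net.n_layers - 1

    if score_fn is None and bank is not None:
        # decoded probability images with no pixel reaching the empty-percept
        # threshold carry no content and score 0
        score_fn = lambda images: bank.score(images, min_peak=EMPTY_PERCEPT_PEAK)

    lam = config.lam
    if isinstance(lam, np.ndarray) and lam.shape != (config.trials_per_iteration,):
        raise ValueError("per-trial lam schedule must have one entry per trial")

    mean_activity = np.zeros((config.max_iterations, n_hidden))
    bias_shift = np.zeros(config.max_iterations)
    mean_quality = np.full(config.max_iterations, np.nan)
    rows: list[dict] = []

    for it in range(config.max_iterations):
        rng = np.random.default_rng(master.integers(2**63))
        provided = input_provider(rng, config.trials_per_iteration)
        if isinstance(provided, tuple):
            visible, labels = provided
        else:
            visible, labels = provided, None
        final, mean_probs = _measure(
            net, visible, config.cycles_per_trial, rng, lam, clamped_layers
        )
        current = [p.mean(axis=0) for p in mean_probs]
        mean_activity[it] = [c.mean() for c in current]
        bias_shift[it] = float(
            np.mean(
                np.concatenate(
                    [np.abs(net.biases[l + 1] - b_init[l]) for l in range(n_hidden)]
                )
            )
        )

        if score_fn is not None:
            decoded = decode_states(net, final.layer_states[top], top)
            results = score_fn(decoded)
            qualities = np.array([r.clamped for r in results])
            mean_quality[it] = float(qualities.mean())
            per_trial_act = [p.mean(axis=-1) for p in mean_probs]
            preds = classifier.predict(decoded) if classifier is not None else None
            for t, r in enumerate(results):
                row = {
                    "iteration": it,
                    "trial": t,
                    "lam": (
                        float(lam[t]) if isinstance(lam, np.ndarray)
                        else (np.nan if lam is None else float(lam))
                    ),
                    "quality": r.clamped,
                    "class_index": -1 if r.class_index is None else r.class_index,
                    "size_class": r.size_class or "",
                    "row": -1 if r.best_position is None else r.best_position[0],
                    "col": -1 if r.best_position is None else r.best_position[1],
                }
                if preds is not None:
                    row["pred_class"] = int(preds[t])
                if labels is not None:
                    row["true_class"] = int(labels[t])
                for l in range(n_hidden):
                    row[f"activity_h{l + 1}"] = float(per_trial_act[l][t])
                rows.append(row)

        homeostatic_step(
            net, ActivityStats(target=list(targets), current=current), config.rate
        )

    trace = AdaptationTrace(
        target_mean=np.array([t.mean() for t in targets]),
        mean_activity=mean_activity,
        bias_shift=bias_shift,
        mean_quality=mean_quality,
        records=pd.DataFrame(rows),
        config=config,
    )
    return net, trace
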