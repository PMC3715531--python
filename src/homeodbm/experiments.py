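"""Scenario orchestration: deprivation experiments on a trained network.

Each scenario degrades the input (or clamps a hidden layer) and runs
homeostatic adaptation, scoring decoded top-layer states at the end of each
trial.  Additional probes examine suppression of an early layer, balance
(ACh) fluctuation, contour completion under mean-field inference, and
realignment of a decoupled model to its true input.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from scipy.special import expit

from .core import LayeredNetwork, NetworkState, SamplerConfig, run_trial
from .data import (
    ShapesDataset,
    blank_provider,
    corrupt_pepper,
    dataset_provider,
    fixed_image_provider,
    half_blank,
    salt_provider,
)
from .decoder import decode_states
from .homeostasis import (
    AdaptationTrace,
    HomeostasisConfig,
    measure_target_activity,
    run_adaptation,
    _measure,
)
from .quality import EMPTY_PERCEPT_PEAK, QualityResult, TemplateBank
from .training import RBM, TrainConfig, train_rbm

__all__ = [
    "SCENARIO_KINDS",
    "Scenario",
    "ExperimentResult",
    "run_scenario",
    "classification_error_series",
    "clean_input_baseline_error",
    "probe_trials",
    "suppression_probe",
    "ach_fluctuation",
    "per_lambda_quality",
    "contour_completion",
    "realign_probe",
    "localization_stats",
    "learning_cessation",
    "save_result",
]

SCENARIO_KINDS = (
    "robustness_pepper",
    "blindness",
    "noise_input",
    "fixed_input",
    "half_field",
    "lesion_h1",
    "ach_fluctuation",
)


@dataclass
class Scenario:
    """A named deprivation condition with its parameters."""

    kind: str
    corruption_fraction: float = 0.65
    noise_fraction: float = 0.10
    half: str = "top"
    lesion_layer: int = 1
    lam_low: float = 0.3
    lam_high: float = 0.7
    fixed_image_index: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(
                f"unknown scenario kind {self.kind!r}; choose from {SCENARIO_KINDS}"
            )


@dataclass
class ExperimentResult:
    """Adapted network plus everything recorded along the way."""

    scenario: Scenario
    adapted_net: LayeredNetwork
    trace: AdaptationTrace
    targets: list[np.ndarray]
    extras: dict = field(default_factory=dict)

    @property
    def quality_table(self) -> pd.DataFrame:
        return self.trace.records


def _scenario_inputs(
    net: LayeredNetwork, dataset: ShapesDataset, scenario: Scenario, n_trials: int
):
    """Provider, hidden clamps, and per-trial balance schedule for a kind."""
    n_pix = net.layer_sizes[0]
    clamps: dict[int, np.ndarray] | None = None
    lam: np.ndarray | None = None
    if scenario.kind == "robustness_pepper":
        provider = dataset_provider(
            dataset,
            lambda im, rng: corrupt_pepper(im, scenario.corruption_fraction, rng),
            with_labels=True,
        )
    elif scenario.kind == "blindness":
        provider = blank_provider(n_pix)
    elif scenario.kind == "noise_input":
        provider = salt_provider(dataset.image_size, scenario.noise_fraction)
    elif scenario.kind == "fixed_input":
        provider = fixed_image_provider(dataset.images[scenario.fixed_image_index])
    elif scenario.kind == "half_field":
        provider = dataset_provider(
            dataset, lambda im, rng: half_blank(im, scenario.half), with_labels=True
        )
    elif scenario.kind == "lesion_h1":
        # early stage blocked: visible content is irrelevant, keep it blank
        provider = blank_provider(n_pix)
        layer = scenario.lesion_layer
        clamps = {layer: np.zeros(net.layer_sizes[layer])}
    elif scenario.kind == "ach_fluctuation":
        provider = blank_provider(n_pix)
        lam = np.where(
            np.arange(n_trials) < n_trials // 2, scenario.lam_low, scenario.lam_high
        ).astype(float)
    else:  # pragma: no cover - guarded by Scenario validation
        raise ValueError(scenario.kind)
    return provider, clamps, lam


def run_scenario(
    net: LayeredNetwork,
    dataset: ShapesDataset,
    scenario: Scenario,
    config: HomeostasisConfig,
    targets: Sequence[np.ndarray] | None = None,
    bank: TemplateBank | None = None,
    classifier=None,
) -> ExperimentResult:
    """Run homeostatic adaptation under one scenario; deterministic given seed."""
    if targets is None:
        targets = measure_target_activity(
            net, dataset.images, config.cycles_per_trial, np.random.default_rng(scenario.seed)
        )
    if bank is None:
        bank = TemplateBank.for_dataset(dataset)
    provider, clamps, lam = _scenario_inputs(
        net, dataset, scenario, config.trials_per_iteration
    )
    cfg = HomeostasisConfig(
        rate=config.rate,
        trials_per_iteration=config.trials_per_iteration,
        cycles_per_trial=config.cycles_per_trial,
        max_iterations=config.max_iterations,
        rng_seed=scenario.seed,
        lam=lam if lam is not None else config.lam,
    )
    adapted, trace = run_adaptation(
        net, provider, list(targets), cfg, bank=bank, clamped_layers=clamps,
        classifier=classifier,
    )
    return ExperimentResult(scenario, adapted, trace, list(targets))


def classification_error_series(trace: AdaptationTrace) -> np.ndarray:
    """Per-iteration error of decoded-state classification vs true labels."""
    rec = trace.records
    if "pred_class" not in rec.columns or "true_class" not in rec.columns:
        raise ValueError("trace lacks classifier predictions or true labels")
    wrong = (rec["pred_class"] != rec["true_class"]).astype(float)
    return wrong.groupby(rec["iteration"]).mean().to_numpy()


def clean_input_baseline_error(
    net: LayeredNetwork,
    dataset: ShapesDataset,
    classifier,
    n_trials: int = 100,
    cycles: int = 50,
    rng: np.random.Generator | int = 0,
) -> float:
    """Classification error of decoded top-layer states on uncorrupted input."""
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, len(dataset), size=n_trials)
    visible = dataset.images[idx]
    top = net.n_layers - 1
    final, _ = _measure(net, visible, cycles, rng)
    pred = classifier.predict(decode_states(net, final.layer_states[top], top))
    return float(np.mean(pred != dataset.class_indices[idx]))


def probe_trials(
    net: LayeredNetwork,
    visible: np.ndarray,
    cycles: int,
    rng: np.random.Generator,
    bank: TemplateBank,
    clamped_layers: Mapping[int, np.ndarray] | None = None,
    lam: float | np.ndarray | None = None,
) -> list[QualityResult]:
    """Run one batch of trials without adaptation and score the decoded top layer."""
    top = net.n_layers - 1
    final, _ = _measure(net, visible, cycles, rng, lam, clamped_layers)
    return bank.score(
        decode_states(net, final.layer_states[top], top),
        min_peak=EMPTY_PERCEPT_PEAK,
    )


def suppression_probe(
    net: LayeredNetwork,
    bank: TemplateBank,
    n_trials: int = 50,
    cycles: int = 50,
    probe_layer: int = 1,
    probe_trials_count: int | None = None,
    rng: np.random.Generator | int = 0,
    visible: np.ndarray | None = None,
) -> dict:
    """Temporarily clamp an early hidden layer to zeros and track quality.

    Runs three blocks of trials — before, during (layer clamped) and after —
    on a fixed network (no adaptation), returning per-phase mean qualities.
    A zero-length probe leaves before/after statistically unchanged.
    """
    rng = np.random.default_rng(rng)
    if visible is None:
        visible = np.zeros((n_trials, net.layer_sizes[0]))
    if probe_trials_count is None:
        probe_trials_count = n_trials
    clamp = {probe_layer: np.zeros(net.layer_sizes[probe_layer])}

    phases: dict[str, list[QualityResult]] = {}
    phases["before"] = probe_trials(net, visible, cycles, rng, bank)
    phases["during"] = (
        probe_trials(net, visible[:probe_trials_count], cycles, rng, bank, clamp)
        if probe_trials_count
        else []
    )
    phases["after"] = probe_trials(net, visible, cycles, rng, bank)
    out = {f"{k}_results": v for k, v in phases.items()}
    for k, v in phases.items():
        out[f"{k}_mean_quality"] = float(np.mean([r.clamped for r in v])) if v else None
    return out


def ach_fluctuation(
    net: LayeredNetwork,
    dataset: ShapesDataset,
    config: HomeostasisConfig,
    lam_low: float = 0.3,
    lam_high: float = 0.7,
    targets: Sequence[np.ndarray] | None = None,
    bank: TemplateBank | None = None,
    seed: int = 0,
) -> ExperimentResult:
    """Blind-input adaptation with half the trials at each balance level."""
    scenario = Scenario(
        "ach_fluctuation", lam_low=lam_low, lam_high=lam_high, seed=seed
    )
    return run_scenario(net, dataset, scenario, config, targets, bank)


def per_lambda_quality(trace: AdaptationTrace) -> pd.DataFrame:
    """Per-iteration mean quality and mean activity grouped by balance factor."""
    rec = trace.records
    cols = {"quality": "mean"}
    cols.update(
        {c: "mean" for c in rec.columns if c.startswith("activity_h")}
    )
    return rec.groupby(["iteration", "lam"]).agg(cols).reset_index()


def contour_completion(
    net: LayeredNetwork,
    image: np.ndarray,
    degraded: np.ndarray,
    lams: Sequence[float] = (0.3, 0.5, 0.7),
    cycles: int = 50,
) -> dict:
    """Mean-field filling-in of blanked object parts, per layer and balance level.

    ``image`` is the intact 2-D object image, ``degraded`` the version with
    parts of the object blanked; the visible layer always remains clamped to
    the degraded image.  The completion score of a layer is the fraction of
    blanked object pixels whose decoded value exceeds 0.5; it is ``None``
    when nothing was blanked.
    """
    image = np.asarray(image, dtype=float)
    degraded = np.asarray(degraded, dtype=float)
    blanked = (image > 0.5) & (degraded <= 0.5)
    n_blanked = int(blanked.sum())
    scores: dict[float, list] = {}
    decoded_images: dict[float, list[np.ndarray]] = {}
    for lam in lams:
        # settle from a bottom-up initialisation: mean-field from all-zero
        # hidden states cannot ignite when the balance favours feedback
        state = NetworkState.from_visible(net, degraded.ravel()[None, :])
        x = state.layer_states[0]
        for l in range(1, net.n_layers):
            scale = 2.0 if l < net.n_layers - 1 else 1.0
            x = expit(scale * (x @ net.weights[l - 1]) + net.biases[l])
            state.layer_states[l] = x
        cfg = SamplerConfig(cycles=cycles, mode="mean_field")
        cfg.ach_lambda = lam
        final, _ = run_trial(net, state, cfg)
        per_layer = []
        images = []
        for layer in range(1, net.n_layers):
            dec = decode_states(net, final.layer_states[layer][0], layer)
            images.append(dec.reshape(image.shape))
            if n_blanked == 0:
                per_layer.append(None)
            else:
                per_layer.append(float((images[-1][blanked] > 0.5).mean()))
        scores[lam] = per_layer
        decoded_images[lam] = images
    return {"scores": scores, "decoded": decoded_images, "n_blanked": n_blanked}


def realign_probe(
    net: LayeredNetwork,
    image: np.ndarray,
    true_spec,
    bank: TemplateBank,
    lam: float = 0.7,
    n_trials: int = 50,
    cycles: int = 50,
    rng: np.random.Generator | int = 0,
    min_quality: float = 0.5,
    position_tolerance: int = 1,
) -> dict:
    """Does raising feedforward impact realign percepts to the clamped input?

    Runs trials with the image clamped and the balance factor at ``lam``;
    among trials whose decoded quality exceeds ``min_quality``, counts those
    whose matched class equals the input's and whose matched position lies
    within ``position_tolerance`` pixels.  ``realigned`` is None when no
    trial produces a scoreable percept (e.g. an untrained network).
    """
    rng = np.random.default_rng(rng)
    visible = np.tile(np.asarray(image, dtype=float).ravel(), (n_trials, 1))
    results = probe_trials(net, visible, cycles, rng, bank, lam=lam)
    scored = [r for r in results if r.clamped > min_quality]
    if not scored:
        return {"realigned": None, "match_fraction": None, "results": results}

    def matches(r: QualityResult) -> bool:
        if r.class_index != true_spec.class_index or r.best_position is None:
            return False
        dr = abs(r.best_position[0] - true_spec.position[0])
        dc = abs(r.best_position[1] - true_spec.position[1])
        return max(dr, dc) <= position_tolerance

    match = float(np.mean([matches(r) for r in scored]))
    return {"realigned": match >= 0.8, "match_fraction": match, "results": results}


def localization_stats(
    records: pd.DataFrame | Sequence[QualityResult],
    image_size: tuple[int, int],
    sides: Mapping[str, int],
    threshold: float = 0.85,
    half: str = "top",
) -> dict:
    """Position histogram and size-class counts of counted hallucinations.

    Only results with quality above ``threshold`` are counted.  A counted
    hallucination lies in the chosen half when its template centre row falls
    there (top half = rows ``0 .. ceil(H/2)-1``).
    """
    if isinstance(records, pd.DataFrame):
        df = records[records["quality"] > threshold]
        rows = df["row"].to_numpy()
        sizes = df["size_class"].to_numpy()
        side_px = np.array([sides[s] for s in sizes]) if len(sizes) else np.array([])
    else:
        kept = [r for r in records if r.clamped > threshold and r.best_position]
        rows = np.array([r.best_position[0] for r in kept])
        sizes = np.array([r.size_class for r in kept])
        side_px = np.array([sides[s] for s in sizes]) if len(sizes) else np.array([])
    h, w = image_size
    split = (h + 1) // 2
    centers = rows + side_px / 2.0
    in_half = centers < split if half == "top" else centers >= split
    histogram = np.zeros(h)
    for c in centers:
        histogram[int(np.clip(round(c), 0, h - 1))] += 1
    n_small = int(np.sum(sizes == "small"))
    n_large = int(np.sum(sizes == "large"))
    return {
        "n_counted": int(len(rows)),
        "fraction_in_half": float(in_half.mean()) if len(rows) else None,
        "n_small": n_small,
        "n_large": n_large,
        "small_large_ratio": (n_small / n_large) if n_large else np.inf,
        "center_row_histogram": histogram,
    }


def learning_cessation(
    net: LayeredNetwork,
    n_images: int = 200,
    epochs: int = 100,
    cfg: TrainConfig | None = None,
    seed: int = 0,
) -> LayeredNetwork:
    """Continue pair-wise CD training on blank input; returns the re-learnt net.

    Models long-term reorganisation: the network learns to generate the empty
    input, losing the capability for hallucinations.  The default uses a
    persistent negative phase, which explores and unlearns the model's
    attractors far faster than data-started chains on blank input.
    """
    if cfg is None:
        cfg = TrainConfig(epochs=epochs, learning_rate=0.2, cd_steps=5,
                          persistent=True, rng_seed=seed)
    net = net.copy()
    rng = np.random.default_rng(cfg.rng_seed)
    x = np.zeros((n_images, net.layer_sizes[0]))
    for l in range(net.n_layers - 1):
        rbm = RBM(net.weights[l], net.biases[l], net.biases[l + 1], net.rf_masks[l])
        train_rbm(rbm, x, cfg, rng)
        x = rbm.hidden_probs(x)
    return net


def save_result(result: ExperimentResult, out_dir: str | Path) -> Path:
    """Persist a run: JSON manifest, CSV tables, and a trace summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trace = result.trace
    manifest = {
        "scenario": result.scenario.__dict__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "iterations": int(trace.n_iterations),
        "config": None if trace.config is None else {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in trace.config.__dict__.items()
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    trace.records.to_csv(out / "quality_table.csv", index=False)
    summary = pd.DataFrame(
        {
            "iteration": np.arange(trace.n_iterations),
            "bias_shift": trace.bias_shift,
            "mean_quality": trace.mean_quality,
            **{
                f"mean_activity_h{l + 1}": trace.mean_activity[:, l]
                for l in range(trace.mean_activity.shape[1])
            },
        }
    )
    summary.to_csv(out / "trace_summary.csv", index=False)
    return out
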