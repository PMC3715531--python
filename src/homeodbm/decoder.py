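"""Decoding hidden states into reconstructed grey-scale images.

A parameter copy of the network is used purely as a decoder: starting from
the states of any hidden layer, a single deterministic top-down pass computes
each lower layer's activation probabilities from the layer above alone, with
the weights doubled to compensate for the missing bottom-up input, down to
the visible layer.  Visible activation probabilities are read as grey-scale
pixel values.  The decoder never mutates the inference network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .core import LayeredNetwork

__all__ = ["DecodedImage", "decode_layer", "decode_states", "decode_trace", "montage"]


@dataclass
class DecodedImage:
    """A reconstructed image with its provenance."""

    pixels: np.ndarray  # (H, W) or (n_pixels,), values in [0, 1]
    source_layer: int
    cycle_index: int = -1


def decode_states(net: LayeredNetwork, states: np.ndarray, layer: int) -> np.ndarray:
    """Top-down pass from ``layer`` to the visible layer; probabilities only.

    ``states`` may be batched ``(batch, n)``; the return value has the same
    leading shape with ``n_visible`` columns.  Weights are doubled at every
    step into a hidden layer, compensating for the bottom-up input those
    layers lack during decoding; the final step into the visible layer is not
    doubled, as the visible layer receives top-down input only in any case.
    """
    if layer <= 0 or layer >= net.n_layers:
        raise ValueError(f"cannot decode layer {layer}")
    x = np.asarray(states, dtype=float)
    if x.shape[-1] != net.layer_sizes[layer]:
        raise ValueError(
            f"states of size {x.shape[-1]} do not match layer {layer} "
            f"({net.layer_sizes[layer]} units)"
        )
    for l in range(layer - 1, -1, -1):
        scale = 2.0 if l > 0 else 1.0
        x = expit(scale * (x @ net.weights[l].T) + net.biases[l])
    return x


def decode_layer(
    net: LayeredNetwork, states: np.ndarray, layer: int, cycle_index: int = -1
) -> DecodedImage:
    """Decode one state vector into a :class:`DecodedImage`."""
    pixels = decode_states(net, states, layer)
    if net.visible_shape is not None and pixels.ndim == 1:
        pixels = pixels.reshape(net.visible_shape)
    return DecodedImage(pixels, layer, cycle_index)


def decode_trace(
    net: LayeredNetwork, recorded_states: list[list[np.ndarray]]
) -> list[DecodedImage]:
    """Decode every hidden layer at every recorded cycle of a trial.

    ``recorded_states[c][l]`` is the state of layer ``l`` after cycle ``c``
    (as produced by ``run_trial(..., record_states=True)``).  Returns
    ``cycles * n_hidden_layers`` images, cycle-major.
    """
    images = []
    for c, layers in enumerate(recorded_states):
        for l in range(1, net.n_layers):
            images.append(decode_layer(net, layers[l], l, cycle_index=c))
    return images


def montage(images: list[np.ndarray], n_cols: int = 10, pad: int = 1) -> np.ndarray:
    """Tile equally sized 2-D images into one array for figure-style panels."""
    if not images:
        raise ValueError("no images to tile")
    h, w = images[0].shape
    n = len(images)
    n_rows = (n + n_cols - 1) // n_cols
    out = np.full((n_rows * (h + pad) + pad, n_cols * (w + pad) + pad), 0.5)
    for i, im in enumerate(images):
        r, c = divmod(i, n_cols)
        out[
            pad + r * (h + pad) : pad + r * (h + pad) + h,
            pad + c * (w + pad) : pad + c * (w + pad) + w,
        ] = im
    return out
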