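"""Scoring of decoded internal representations.

Two measures are provided.  Template matching scores an image by its maximum
normalized cross-correlation against the training shape templates, evaluated
at every valid placement: both the image and each rendered template are
mean-subtracted and scaled to unit Euclidean norm, so a perfect match scores
exactly 1 and no score can exceed 1 (Cauchy-Schwarz).  The classifier-based
measure attaches a one-of-K label group to the topmost layer pair of a
network instance and reads quality as the maximum of the label posterior,
again bounded by 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, softmax

from .core import LayeredNetwork
from .data import CLASS_NAMES, ShapesDataset, enumerate_instances
from .training import RBM, TrainConfig, cd_update, up_pass

__all__ = [
    "QualityResult",
    "TemplateBank",
    "template_quality",
    "LabelAugmentedClassifier",
    "train_classifier",
    "classifier_quality",
    "classification_error",
]

_EPS = 1e-12

#: grey level a decoded image must reach somewhere to count as a percept;
#: below it every unit is more likely off than on and the decode is empty
EMPTY_PERCEPT_PEAK = 0.5


@dataclass
class QualityResult:
    """Outcome of a quality evaluation for one image."""

    quality: float  # raw normalized correlation in [-1, 1]
    class_index: int | None  # None for degenerate (zero-variance) images
    best_position: tuple[int, int] | None = None
    size_class: str | None = None

    @property
    def category(self) -> str | None:
        return None if self.class_index is None else CLASS_NAMES[self.class_index]

    @property
    def clamped(self) -> float:
        """Quality on the reported [0, 1] scale (negative correlations -> 0)."""
        return max(0.0, self.quality)


class TemplateBank:
    """All template placements, pre-normalized for fast batch scoring.

    Row ``i`` of ``rows`` is the mean-subtracted, unit-norm rendering of one
    (category, size, position) instance; scoring an image is a single matrix
    product, with ties broken by canonical class order then row-major
    position (the enumeration order).
    """

    def __init__(
        self, image_size: tuple[int, int], sides: dict[str, int] | None = None
    ) -> None:
        full = enumerate_instances(image_size, sides)
        self.image_size = image_size
        self.sides = full.sides
        self.labels = full.labels
        rows = full.images - full.images.mean(axis=1, keepdims=True)
        rows /= np.linalg.norm(rows, axis=1, keepdims=True)
        self.rows = rows
        self.class_indices = full.class_indices

    @classmethod
    def for_dataset(cls, dataset: ShapesDataset) -> "TemplateBank":
        return cls(dataset.image_size, dataset.sides)

    def _normalize(self, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.atleast_2d(np.asarray(images, dtype=float).reshape(-1, self.rows.shape[1]))
        x = x - x.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(x, axis=1, keepdims=True)
        ok = norms[:, 0] > _EPS
        x = np.divide(x, norms, out=np.zeros_like(x), where=norms > _EPS)
        return x, ok

    def score(
        self, images: np.ndarray, min_peak: float = 0.0
    ) -> list[QualityResult]:
        """Score a batch of images (2-D single image or (batch, n_pixels)).

        ``min_peak`` extends the degenerate-image convention to decoded
        probability images: when no pixel reaches that grey level, the image
        represents an empty percept (every unit more likely off than on) and
        scores 0 with an undefined category.  The default 0.0 disables the
        gate, keeping the raw measure affine-invariant.
        """
        x, ok = self._normalize(images)
        if min_peak > 0.0:
            flat = np.atleast_2d(
                np.asarray(images, dtype=float).reshape(-1, self.rows.shape[1])
            )
            ok &= flat.max(axis=1) >= min_peak
        corr = x @ self.rows.T
        best = np.argmax(corr, axis=1)  # argmax keeps first = canonical tie-break
        results = []
        for i, j in enumerate(best):
            if not ok[i]:
                results.append(QualityResult(0.0, None))
                continue
            spec = self.labels[j]
            results.append(
                QualityResult(
                    float(corr[i, j]), spec.class_index, spec.position, spec.size_class
                )
            )
        return results


def template_quality(
    image: np.ndarray, bank: TemplateBank | tuple[int, int]
) -> QualityResult:
    """Template-matching hallucination quality of one image.

    ``bank`` may be a prepared :class:`TemplateBank` or an image size (the
    bank is then built with default shape sides).  Degenerate zero-variance
    images score 0 with an undefined category.
    """
    if not isinstance(bank, TemplateBank):
        bank = TemplateBank(bank)
    return bank.score(np.asarray(image).ravel())[0]


# ---------------------------------------------------------------------------
# label-augmented classifier
# ---------------------------------------------------------------------------


@dataclass
class LabelAugmentedClassifier:
    """A network instance with a one-of-K label group on its topmost pair.

    Classification of an image is the posterior over the K labels given the
    representation inferred by a deterministic bottom-up pass, computed
    exactly by summing out the top hidden layer analytically.
    """

    net: LayeredNetwork  # frozen copy; not subject to homeostasis
    label_weights: np.ndarray  # (K, n_top_hidden)
    label_bias: np.ndarray  # (K,)
    n_classes: int

    def features(self, images: np.ndarray) -> np.ndarray:
        """Bottom-up activation probabilities of the pair's visible side."""
        x = np.atleast_2d(np.asarray(images, dtype=float))
        return up_pass(self.net, x, to_layer=self.net.n_layers - 2)

    def posterior_from_features(self, feats: np.ndarray) -> np.ndarray:
        w = self.net.weights[-1]  # (n_feats, n_hidden)
        c = self.net.biases[-1]
        base = feats @ w + c  # (B, n_hidden)
        # log-score of class y: d_y + sum_j softplus(base_j + U_yj)
        scores = np.stack(
            [
                np.logaddexp(0.0, base + self.label_weights[y]).sum(axis=1)
                for y in range(self.n_classes)
            ],
            axis=1,
        )
        return softmax(scores + self.label_bias, axis=1)

    def posterior(self, images: np.ndarray) -> np.ndarray:
        """Label posterior for a batch of images; rows sum to 1."""
        return self.posterior_from_features(self.features(images))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.posterior(images), axis=1)


def train_classifier(
    dataset: ShapesDataset | tuple[np.ndarray, np.ndarray],
    net: LayeredNetwork,
    cfg: TrainConfig | None = None,
    n_classes: int | None = None,
    generative_weight: float = 0.0,
) -> LabelAugmentedClassifier:
    """Attach and train a label group on the topmost layer pair.

    The pair is trained jointly with the labels via the exact gradient of the
    label posterior, optionally mixed with a generative CD term over the
    augmented pair (``generative_weight``).  The underlying network copy is
    frozen apart from its top pair.
    """
    if isinstance(dataset, ShapesDataset):
        images, labels = dataset.images, dataset.class_indices
    else:
        images, labels = dataset
    labels = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(labels.max()) + 1
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes to train a classifier")
    if cfg is None:
        cfg = TrainConfig(epochs=500, learning_rate=0.3, minibatch_size=50,
                          init_bias=0.0)

    net = net.copy()
    rng = np.random.default_rng(cfg.rng_seed)
    clf = LabelAugmentedClassifier(
        net,
        rng.normal(0.0, cfg.weight_init_std, size=(n_classes, net.layer_sizes[-1])),
        np.zeros(n_classes),
        n_classes,
    )
    feats = clf.features(images)
    onehot = np.eye(n_classes)[labels]
    n_feats = feats.shape[1]

    # the augmented pair as one RBM: visible = [features ; labels]
    aug_w = np.vstack([net.weights[-1], clf.label_weights])
    aug_mask = np.vstack([net.rf_masks[-1], np.ones_like(clf.label_weights)])
    aug_vbias = np.concatenate([net.biases[-2], clf.label_bias])
    rbm = RBM(aug_w, aug_vbias, net.biases[-1], aug_mask)

    n = feats.shape[0]
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.minibatch_size):
            idx = order[start : start + cfg.minibatch_size]
            fb, yb, ob = feats[idx], labels[idx], onehot[idx]
            if generative_weight > 0.0:
                gen_cfg = TrainConfig(
                    epochs=1,
                    cd_steps=cfg.cd_steps,
                    learning_rate=cfg.learning_rate * generative_weight,
                    minibatch_size=cfg.minibatch_size,
                    weight_decay=cfg.weight_decay,
                    init_bias=cfg.init_bias,
                )
                cd_update(rbm, np.hstack([fb, ob]), gen_cfg, rng)
            # exact discriminative gradient of mean log p(y | features)
            w, u = rbm.w[:n_feats], rbm.w[n_feats:]  # u: (K, n_hidden)
            c, d = rbm.hbias, rbm.vbias[n_feats:]
            base = fb @ w + c  # (B, n_hidden)
            o = base[:, None, :] + u[None, :, :]  # (B, K, n_hidden)
            scores = np.logaddexp(0.0, o).sum(axis=2) + d
            post = softmax(scores, axis=1)
            sig = expit(o)
            resid = ob - post  # (B, K)
            sig_true = sig[np.arange(len(yb)), yb]  # (B, n_hidden)
            sig_mean = np.einsum("bk,bkj->bj", post, sig)
            b = fb.shape[0]
            lr = cfg.learning_rate
            rbm.w[:n_feats] += lr * (fb.T @ (sig_true - sig_mean)) / b
            rbm.w[n_feats:] += lr * np.einsum("bkj,bk->kj", sig, resid) / b
            rbm.vbias[n_feats:] += lr * resid.mean(axis=0)
            rbm.hbias += lr * (sig_true - sig_mean).mean(axis=0)
            rbm.w *= rbm.mask

    net.weights[-1][...] = rbm.w[:n_feats]
    net.biases[-2][...] = rbm.vbias[:n_feats]
    net.biases[-1][...] = rbm.hbias
    clf.label_weights = rbm.w[n_feats:]
    clf.label_bias = rbm.vbias[n_feats:]
    return clf


def classifier_quality(
    images: np.ndarray, classifier: LabelAugmentedClassifier
) -> list[QualityResult]:
    """Quality = maximum of the label posterior; class = its argmax."""
    post = classifier.posterior(images)
    return [
        QualityResult(float(post[i].max()), int(post[i].argmax()))
        for i in range(post.shape[0])
    ]


def classification_error(
    images: np.ndarray, labels: np.ndarray, classifier: LabelAugmentedClassifier
) -> float:
    """Fraction of images whose posterior argmax differs from the label."""
    pred = classifier.predict(images)
    return float(np.mean(pred != np.asarray(labels, dtype=int)))
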