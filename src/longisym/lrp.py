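"""Epsilon layer-wise relevance propagation through the Siamese network.

The pre-softmax score of a target class (the progressor class by default)
is redistributed backward layer by layer.  At every linear layer the
incoming relevance is divided by the epsilon-stabilized pre-activation and
propagated along the weights, then multiplied by the layer's input; max
pooling routes relevance winner-take-all; the ``|a - b|`` merge splits
relevance onto both branches via its local linearization, so each input
session receives its own per-voxel relevance map.

For bias-free networks with strictly positive pre-activations this reduces
exactly to gradient x input as epsilon goes to zero; with biases present a
small fraction of relevance leaks into the bias terms, so conservation of
the target score holds only approximately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, UnsupportedLayerError
from .nn.layers import Layer
from .nn.model import DeepSymNetModel

__all__ = ["LRPConfig", "RelevanceMap", "relevance"]


@dataclass(frozen=True)
class LRPConfig:
    """epsilon: denominator stabilizer; target: class whose score is decomposed."""

    epsilon: float = 1e-9
    target: int = DeepSymNetModel.PROGRESSOR_CLASS

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")


@dataclass
class RelevanceMap:
    """Per-voxel relevance for both sessions of one subject."""

    subject_id: str
    session1_relevance: np.ndarray
    session2_relevance: np.ndarray
    target_score: float

    def __post_init__(self) -> None:
        if self.session1_relevance.shape != self.session2_relevance.shape:
            raise ConfigurationError("relevance maps must share the input shape")
        if not (
            np.all(np.isfinite(self.session1_relevance))
            and np.all(np.isfinite(self.session2_relevance))
        ):
            raise ConfigurationError("relevance maps must be finite")

    @property
    def total_relevance(self) -> float:
        return float(self.session1_relevance.sum() + self.session2_relevance.sum())


def _check_supported(layer: object) -> Layer:
    if not isinstance(layer, Layer) or not hasattr(layer, "lrp"):
        raise UnsupportedLayerError(
            f"no relevance rule for layer type {type(layer).__name__}"
        )
    return layer


def relevance(
    model: DeepSymNetModel,
    pair: tuple[np.ndarray, np.ndarray],
    cfg: LRPConfig = LRPConfig(),
    subject_id: str = "",
) -> RelevanceMap:
    """Decompose the target class's pre-softmax score over both input sessions."""
    x1, x2 = pair
    z, cache = model.forward_logits(x1, x2)
    caches_a, caches_b, cm, caches_post, cg, ch = cache
    if not 0 <= cfg.target < z.shape[1]:
        raise ConfigurationError(f"target class {cfg.target} out of range")
    target_score = float(z[0, cfg.target])
    R = np.zeros_like(z)
    R[:, cfg.target] = z[:, cfg.target]

    eps = cfg.epsilon
    R = _check_supported(model.head).lrp(R, ch, eps)
    R = _check_supported(model.gpool).lrp(R, cg, eps)
    for mod, cp in zip(reversed(model.post), reversed(caches_post)):
        R = _check_supported(mod).lrp(R, cp, eps)
    Ra, Rb = _check_supported(model.merge).lrp(R, cm, eps)
    for mod, ca in zip(reversed(model.branch), reversed(caches_a)):
        Ra = _check_supported(mod).lrp(Ra, ca, eps)
    for mod, cb in zip(reversed(model.branch), reversed(caches_b)):
        Rb = _check_supported(mod).lrp(Rb, cb, eps)

    return RelevanceMap(
        subject_id=subject_id,
        session1_relevance=np.asarray(Ra[0, 0], dtype=np.float64),
        session2_relevance=np.asarray(Rb[0, 0], dtype=np.float64),
        target_score=target_score,
    )
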