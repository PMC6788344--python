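"""The weight-shared 3-D Inception Siamese network.

Two identical stacks of 3-D Inception modules (shared weight storage, not
copies) encode the two imaging sessions; an elementwise L-1 merge
``|a - b|`` turns the pair of feature maps into a change representation;
further Inception modules, global max pooling, and a 2-unit softmax head
turn it into a progression probability.

Architectural reading choices (both configurable):

* "64 filters" is applied per parallel branch of each Inception module, so
  a module's concatenated width is ``3 * filters_per_branch``.
* Each Inception module max-pools (2x2x2, stride 2) after concatenation.
* The final spatial pooling is a global max pool, keeping the head's
  parameter count independent of the input grid.

The merge is the elementwise absolute difference: it is symmetric in the
two sessions and collapses to exactly zero on identical inputs, which makes
the network's output on ``(x, x)`` a bias-driven constant.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from ..errors import ConfigurationError, InputError
from .layers import (
    AbsDiffMerge,
    Concat,
    Conv3d,
    Dense,
    GlobalMaxPool,
    Layer,
    MaxPool3d,
    ReLU,
)

__all__ = ["InceptionSpec", "DeepSymNetConfig", "InceptionModule", "DeepSymNetModel", "build"]


@dataclass(frozen=True)
class InceptionSpec:
    """One Inception module: parallel 1/3/5 convolutions, concat, max pool."""

    branch_kernels: tuple[int, ...] = (1, 3, 5)
    filters_per_branch: int = 64
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.filters_per_branch < 1:
            raise ConfigurationError("filters_per_branch must be >= 1")
        if any(k % 2 == 0 or k < 1 for k in self.branch_kernels):
            raise ConfigurationError("branch kernels must be odd positive integers")

    @property
    def width(self) -> int:
        return self.filters_per_branch * len(self.branch_kernels)


@dataclass(frozen=True)
class DeepSymNetConfig:
    """Architecture configuration.

    ``resolution_fraction`` records the isotropic downsampling applied
    upstream; it does not change the graph.
    """

    input_shape: tuple[int, int, int] = (16, 16, 16)
    modules_before: int = 1
    modules_after: int = 1
    inception: InceptionSpec = field(default_factory=InceptionSpec)
    n_classes: int = 2
    resolution_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.modules_before not in (1, 2, 3) or self.modules_after not in (1, 2, 3):
            raise ConfigurationError("modules_before/after must be in {1, 2, 3}")
        if self.n_classes != 2:
            raise ConfigurationError("the head is a 2-class softmax")
        depth = self.modules_before + self.modules_after
        if any(n < 2**depth for n in self.input_shape):
            raise ConfigurationError(
                f"input shape {self.input_shape} too small for {depth} pooling stages"
            )

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "DeepSymNetConfig":
        d = json.loads(s)
        d["input_shape"] = tuple(d["input_shape"])
        inc = d.pop("inception")
        inc["branch_kernels"] = tuple(inc["branch_kernels"])
        return cls(inception=InceptionSpec(**inc), **d)


class InceptionModule(Layer):
    """Parallel multi-scale convolutions + ReLU, concatenated, max-pooled."""

    def __init__(self, in_channels: int, spec: InceptionSpec, rng: np.random.Generator):
        self.spec = spec
        self.convs = [
            Conv3d(in_channels, spec.filters_per_branch, k, rng) for k in spec.branch_kernels
        ]
        self.relus = [ReLU() for _ in spec.branch_kernels]
        self.concat = Concat()
        self.pool = MaxPool3d(spec.pool_size)
        self.out_channels = spec.width

    @property
    def params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, conv in enumerate(self.convs):
            for name, arr in conv.params.items():
                out[f"conv{self.spec.branch_kernels[i]}.{name}"] = arr
        return out

    @property
    def grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, conv in enumerate(self.convs):
            for name, arr in conv.grads.items():
                out[f"conv{self.spec.branch_kernels[i]}.{name}"] = arr
        return out

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, Any]:
        acts, caches = [], []
        for conv, relu in zip(self.convs, self.relus):
            z, cz = conv.forward(x)
            a, ca = relu.forward(z)
            acts.append(a)
            caches.append((cz, ca))
        cat, ccat = self.concat.forward(acts)
        y, cpool = self.pool.forward(cat)
        return y, (caches, ccat, cpool)

    def backward(self, gy: np.ndarray, cache: Any) -> np.ndarray:
        caches, ccat, cpool = cache
        gcat = self.pool.backward(gy, cpool)
        parts = self.concat.backward(gcat, ccat)
        gx = None
        for (cz, ca), relu, conv, g in zip(caches, self.relus, self.convs, parts):
            gi = conv.backward(relu.backward(g, ca), cz)
            gx = gi if gx is None else gx + gi
        return gx

    def lrp(self, R: np.ndarray, cache: Any, epsilon: float) -> np.ndarray:
        caches, ccat, cpool = cache
        Rcat = self.pool.lrp(R, cpool, epsilon)
        parts = self.concat.lrp(Rcat, ccat, epsilon)
        Rx = None
        for (cz, ca), relu, conv, r in zip(caches, self.relus, self.convs, parts):
            ri = conv.lrp(relu.lrp(r, ca, epsilon), cz, epsilon)
            Rx = ri if Rx is None else Rx + ri
        return Rx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DeepSymNetModel:
    """Built network: shared branch, merge, post-merge stack, softmax head.

    The Siamese branch is a single list of modules applied to both inputs,
    so the weight-sharing contract is structural: there is exactly one copy
    of the pre-merge weights.
    """

    PROGRESSOR_CLASS = 1

    def __init__(self, config: DeepSymNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng([seed, 7])
        spec = config.inception
        self.branch: list[InceptionModule] = []
        ch = 1
        for _ in range(config.modules_before):
            mod = InceptionModule(ch, spec, rng)
            self.branch.append(mod)
            ch = mod.out_channels
        self.merge = AbsDiffMerge()
        self.post: list[InceptionModule] = []
        for _ in range(config.modules_after):
            mod = InceptionModule(ch, spec, rng)
            self.post.append(mod)
            ch = mod.out_channels
        self.gpool = GlobalMaxPool()
        self.head = Dense(ch, config.n_classes, rng)
        self.training_history: list[dict[str, float]] = []

    # ---- parameter plumbing ---------------------------------------------

    def named_params(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, mod in enumerate(self.branch):
            for name, arr in mod.params.items():
                out[f"branch.{i}.{name}"] = arr
        for i, mod in enumerate(self.post):
            for name, arr in mod.params.items():
                out[f"post.{i}.{name}"] = arr
        for name, arr in self.head.params.items():
            out[f"head.{name}"] = arr
        return out

    def named_grads(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, mod in enumerate(self.branch):
            for name, arr in mod.grads.items():
                out[f"branch.{i}.{name}"] = arr
        for i, mod in enumerate(self.post):
            for name, arr in mod.grads.items():
                out[f"post.{i}.{name}"] = arr
        for name, arr in self.head.grads.items():
            out[f"head.{name}"] = arr
        return out

    @property
    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.named_params().values()))

    def zero_grads(self) -> None:
        for g in self.named_grads().values():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_params()
        if set(params) != set(state):
            raise ConfigurationError("state dict does not match the architecture")
        for k, v in state.items():
            params[k][...] = v

    # ---- forward / backward ---------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None, None]
        elif x.ndim == 4:
            x = x[:, None]
        if x.shape[2:] != tuple(self.config.input_shape):
            raise InputError(
                f"input spatial shape {x.shape[2:]} != configured {self.config.input_shape}"
            )
        return x

    def forward_logits(self, x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, Any]:
        a, b = self._check_input(x1), self._check_input(x2)
        if a.shape != b.shape:
            raise InputError("the two sessions must share a shape")
        caches_a, caches_b = [], []
        for mod in self.branch:
            a, ca = mod.forward(a)
            caches_a.append(ca)
        for mod in self.branch:
            b, cb = mod.forward(b)
            caches_b.append(cb)
        m, cm = self.merge.forward((a, b))
        caches_post = []
        for mod in self.post:
            m, cp = mod.forward(m)
            caches_post.append(cp)
        p, cg = self.gpool.forward(m)
        z, ch = self.head.forward(p)
        return z, (caches_a, caches_b, cm, caches_post, cg, ch)

    def backward(self, gz: np.ndarray, cache: Any) -> None:
        caches_a, caches_b, cm, caches_post, cg, ch = cache
        g = self.head.backward(gz, ch)
        g = self.gpool.backward(g, cg)
        for mod, cp in zip(reversed(self.post), reversed(caches_post)):
            g = mod.backward(g, cp)
        ga, gb = self.merge.backward(g, cm)
        for mod, ca in zip(reversed(self.branch), reversed(caches_a)):
            ga = mod.backward(ga, ca)
        for mod, cb in zip(reversed(self.branch), reversed(caches_b)):
            gb = mod.backward(gb, cb)

    def predict_proba(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        """Progressor-class probability for a batch (or single pair)."""
        z, _ = self.forward_logits(x1, x2)
        return _softmax(z)[:, self.PROGRESSOR_CLASS]

    def forward(self, pair: tuple[np.ndarray, np.ndarray]) -> float:
        """Progression probability for one preprocessed pair."""
        return float(self.predict_proba(pair[0], pair[1])[0])

    # ---- serialization ---------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Portable zip archive: config JSON + one array per unique parameter."""
        path = Path(path)
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("config.json", self.config.to_json())
            zf.writestr("history.json", json.dumps(self.training_history))
            buf = io.BytesIO()
            np.savez(buf, **self.named_params())
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "DeepSymNetModel":
        with zipfile.ZipFile(Path(path)) as zf:
            config = DeepSymNetConfig.from_json(zf.read("config.json").decode())
            model = cls(config, seed=seed)
            with zf.open("weights.npz") as f:
                state = dict(np.load(io.BytesIO(f.read())))
            model.load_state_dict(state)
            model.training_history = json.loads(zf.read("history.json").decode())
        return model


def build(config: DeepSymNetConfig, seed: int = 0) -> DeepSymNetModel:
    """Construct an untrained model from a configuration."""
    return DeepSymNetModel(config, seed=seed)
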