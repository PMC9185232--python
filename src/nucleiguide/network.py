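"""Two-branch nuclei-guided grading network.

Architecture (configurable depth ``M``, VGG-style): two parameter-independent
convolutional branches of identical layout — the *main* branch reads the
raw H&E tile, the *guide* branch reads the nuclei-only tile.  Each stage is
``convs_per_stage`` 3x3 same-convolutions with ReLU followed by 2x2 max
pooling; after every stage a nuclei-guided attention (NGA) gate lets guide
features reweight main features.  At the deepest stage both maps are
flattened to token sequences and merged by the nuclei-guided fusion (NGF)
cross-attention stack (depth ``L``); the fused sequence is flattened and a
two-layer MLP head produces class logits.

Six variants cover the ablation lattice: ``full``, ``no_nga``, ``no_ngf``
(NGF replaced by token-wise concatenation — "simple fusion"),
``no_nga_no_ngf``, and the single-branch ``image_only`` / ``nuclei_only``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .attention import flatten_to_tokens, nga_forward, ngf_forward
from .autodiff import Tensor, concat, conv2d_3x3, maxpool2x2

__all__ = [
    "ModelConfig",
    "GradingPrediction",
    "VARIANTS",
    "init_params",
    "forward",
    "cross_entropy_loss",
]

VARIANTS = ("full", "no_nga", "no_ngf", "no_nga_no_ngf", "image_only", "nuclei_only")

#: Variants using a single convolutional branch.
SINGLE_BRANCH = {"image_only", "nuclei_only"}


@dataclasses.dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the grading network.

    The default is a desk-scale backbone (three stages, 8/16/32 channels)
    that trains in minutes on one CPU; :meth:`paper_like` returns the
    VGG16-width five-stage configuration.
    """

    input_size: int = 64
    channels_per_stage: tuple[int, ...] = (8, 16, 32)
    convs_per_stage: int = 1
    fusion_depth: int = 3  # NGF layers L
    n_classes: int = 3
    head_hidden: int = 64
    variant: str = "full"
    attention_axis: str = "spatial"  # NGA softmax normalisation axis

    @property
    def n_stages(self) -> int:
        return len(self.channels_per_stage)

    def __post_init__(self):
        if self.n_stages < 1 or self.fusion_depth < 1 or self.n_classes < 2:
            raise ValueError("need M >= 1, L >= 1, n_classes >= 2")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.input_size % (2**self.n_stages) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.n_stages}"
            )

    @classmethod
    def paper_like(cls, **overrides) -> "ModelConfig":
        """Five-stage VGG16-width configuration (64..512 channels)."""
        kw = dict(
            input_size=64,
            channels_per_stage=(64, 128, 256, 512, 512),
            convs_per_stage=2,
            fusion_depth=3,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def token_grid(self) -> int:
        return self.input_size // (2**self.n_stages)

    @property
    def n_tokens(self) -> int:
        return self.token_grid**2

    @property
    def head_in_dim(self) -> int:
        d = self.channels_per_stage[-1]
        if self.variant in ("no_ngf", "no_nga_no_ngf"):
            return self.n_tokens * 2 * d  # token-wise concatenation
        return self.n_tokens * d


@dataclasses.dataclass
class GradingPrediction:
    """Per-image output: logits, softmax probabilities and 1-based grade."""

    logits: np.ndarray
    probabilities: np.ndarray
    predicted_grade: int


def _branches(config: ModelConfig) -> tuple[str, ...]:
    return ("main",) if config.variant in SINGLE_BRANCH else ("main", "guide")


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, Tensor]:
    """He-initialised convolutions, small-uniform attention projections.

    Main and guide branches share architecture but are initialised and
    trained independently (disjoint parameter tensors).
    """
    rng = np.random.default_rng(seed)
    params: dict[str, Tensor] = {}

    def add(name, data):
        params[name] = Tensor(data, requires_grad=True)

    for branch in _branches(config):
        c_in = 3
        for m, c_out in enumerate(config.channels_per_stage):
            for j in range(config.convs_per_stage):
                fan_in = c_in * 9
                add(
                    f"{branch}_s{m}_c{j}_w",
                    rng.normal(0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, 3, 3)),
                )
                add(f"{branch}_s{m}_c{j}_b", np.zeros(c_out))
                c_in = c_out

    use_nga = config.variant in ("full", "no_ngf")
    if use_nga:
        for m, c in enumerate(config.channels_per_stage):
            add(f"nga_s{m}_w", rng.uniform(-0.05, 0.05, size=(c, c)))
            add(f"nga_s{m}_b", np.zeros(c))

    if config.variant in ("full", "no_nga"):
        d = config.channels_per_stage[-1]
        # dimension-aware scale keeps pre-softmax attention logits O(1)
        s = 0.05 / np.sqrt(d)
        for l in range(config.fusion_depth):
            add(f"ngf_l{l}_wq", rng.uniform(-s, s, size=(d, d)))
            add(f"ngf_l{l}_wk", rng.uniform(-s, s, size=(d, d)))

    h = config.head_hidden
    # the residual fusion stack roughly doubles token magnitude per layer;
    # shrink the head fan-in init accordingly so hidden pre-activations
    # stay O(1) for every variant
    gain = 2.0**config.fusion_depth if config.variant in ("full", "no_nga") else 1.0
    add(
        "head_w1",
        rng.normal(
            0, np.sqrt(2.0 / config.head_in_dim) / gain, size=(config.head_in_dim, h)
        ),
    )
    add("head_b1", np.zeros(h))
    # small output layer keeps initial predictions near uniform, so the
    # first cross-entropy sits at ~ln(k) and RMSProp steps are well scaled
    add("head_w2", rng.normal(0, 0.01 * np.sqrt(1.0 / h), size=(h, config.n_classes)))
    add("head_b2", np.zeros(config.n_classes))
    return params


def _branch_stage(x: Tensor, params, branch: str, m: int, config: ModelConfig) -> Tensor:
    for j in range(config.convs_per_stage):
        x = conv2d_3x3(
            x, params[f"{branch}_s{m}_c{j}_w"], params[f"{branch}_s{m}_c{j}_b"]
        ).relu()
    return x


def forward(
    params: dict[str, Tensor],
    x_main: np.ndarray | Tensor,
    x_nuclei: np.ndarray | Tensor | None,
    config: ModelConfig,
) -> tuple[Tensor, dict[str, Tensor]]:
    """Batched forward pass.

    ``x_main``/``x_nuclei``: (N, 3, H, W) in [0, 1].  Returns the logits
    tensor (N, k) and a cache of intermediate tensors; the cache entry
    ``fused_s{m}`` holds the post-NGA (or plain main, if NGA is off)
    feature map of stage ``m``, which Grad-CAM differentiates against.
    """
    x_main = x_main if isinstance(x_main, Tensor) else Tensor(x_main)
    if x_main.ndim != 4 or x_main.shape[1] != 3:
        raise ValueError(f"expected (N,3,H,W) input, got {x_main.shape}")
    # rescale [0,1] pixels to [-1,1]: centred inputs keep activation
    # variance seed-stable through the ReLU stack
    x_main = x_main * 2.0 - 1.0
    variant = config.variant
    two_branch = variant not in SINGLE_BRANCH
    if two_branch:
        if x_nuclei is None:
            raise ValueError(f"variant {variant!r} needs the nuclei-only input")
        x_nuclei = x_nuclei if isinstance(x_nuclei, Tensor) else Tensor(x_nuclei)
        x_nuclei = x_nuclei * 2.0 - 1.0
        if x_nuclei.shape != x_main.shape:
            raise ValueError(
                f"shape mismatch: main {x_main.shape} vs nuclei {x_nuclei.shape}"
            )

    use_nga = variant in ("full", "no_ngf")
    use_ngf = variant in ("full", "no_nga")
    cache: dict[str, Tensor] = {}

    if variant == "nuclei_only":
        if x_nuclei is None:
            raise ValueError("nuclei_only variant needs the nuclei-only input")
        x_nuclei = x_nuclei if isinstance(x_nuclei, Tensor) else Tensor(x_nuclei)
        h = x_nuclei * 2.0 - 1.0
    else:
        h = x_main
    g = x_nuclei if two_branch else None

    for m in range(config.n_stages):
        h = _branch_stage(h, params, "main", m, config)
        cache[f"main_s{m}"] = h
        if two_branch:
            g = _branch_stage(g, params, "guide", m, config)
            cache[f"guide_s{m}"] = g
            if use_nga:
                h = nga_forward(
                    h, g, params[f"nga_s{m}_w"], params[f"nga_s{m}_b"],
                    axis=config.attention_axis,
                )
        cache[f"fused_s{m}"] = h
        h = maxpool2x2(h)
        if two_branch:
            g = maxpool2x2(g)

    main_tokens = flatten_to_tokens(h)
    cache["main_tokens"] = main_tokens
    if two_branch:
        guide_tokens = flatten_to_tokens(g)
        cache["guide_tokens"] = guide_tokens
        if use_ngf:
            w_q = [params[f"ngf_l{l}_wq"] for l in range(config.fusion_depth)]
            w_k = [params[f"ngf_l{l}_wk"] for l in range(config.fusion_depth)]
            fused = ngf_forward(main_tokens, guide_tokens, w_q, w_k)
        else:
            fused = concat([main_tokens, guide_tokens], axis=-1)  # simple fusion
    else:
        fused = main_tokens
    cache["fused_tokens"] = fused

    n = fused.shape[0]
    flat = fused.reshape(n, int(np.prod(fused.shape[1:])))
    hidden = (flat @ params["head_w1"] + params["head_b1"]).relu()
    logits = hidden @ params["head_w2"] + params["head_b2"]
    cache["logits"] = logits
    return logits, cache


def predict(params, x_main, x_nuclei, config) -> list[GradingPrediction]:
    """Run the network and wrap each row in a :class:`GradingPrediction`."""
    logits, _ = forward(params, x_main, x_nuclei, config)
    probs = logits.softmax(axis=-1).data
    return [
        GradingPrediction(
            logits=logits.data[i],
            probabilities=probs[i],
            predicted_grade=int(np.argmax(probs[i])) + 1,
        )
        for i in range(probs.shape[0])
    ]


def cross_entropy_loss(probabilities, labels_onehot) -> Tensor:
    """Batch-mean categorical cross entropy ``-mean_z sum_k q log p``.

    ``probabilities``: (N, k) simplex rows (clipped to [1e-7, 1] before the
    log); ``labels_onehot``: (N, k) strict one-hot rows.
    """
    p = probabilities if isinstance(probabilities, Tensor) else Tensor(probabilities)
    q = np.asarray(
        labels_onehot.data if isinstance(labels_onehot, Tensor) else labels_onehot
    )
    if q.ndim != 2 or p.shape != q.shape:
        raise ValueError(f"probabilities {p.shape} and labels {q.shape} must match")
    if not (np.isin(q, (0, 1)).all() and (q.sum(axis=1) == 1).all()):
        raise ValueError("labels must be one-hot rows")
    logp = p.clamp(1e-7, 1.0).log()
    return -(Tensor(q) * logp).sum() * (1.0 / p.shape[0])


def one_hot(grades: np.ndarray, n_classes: int) -> np.ndarray:
    """1-based integer grades -> one-hot matrix."""
    grades = np.asarray(grades, dtype=int)
    out = np.zeros((grades.size, n_classes))
    out[np.arange(grades.size), grades - 1] = 1.0
    return out
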