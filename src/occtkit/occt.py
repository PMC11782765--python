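"""Compact convolutional-transformer classifier (OCCT).

Architecture: two-stage convolutional tokenizer (conv -> ReLU -> 3x3
stride-2 pool, channels 3 -> 64 -> embed_dim), a stack of pre-norm
transformer encoder blocks, a final layer norm, learnable sequence
pooling (softmax-weighted token average) and a dense softmax head.
There is no positional embedding anywhere: the token sequence is
processed permutation-equivariantly up to the pooling stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import functional as F
from .nn.tensor import Tensor

ACTIVATION_CHOICES = ("relu", "elu", "tanh", "softplus", "softsign",
                      "leaky_relu", "gelu", "sigmoid")


@dataclass(frozen=True)
class OCCTConfig:
    """Every hyperparameter varied by the ablation grid, plus model widths."""

    n_blocks: int = 1
    tokenizer_kernel: int = 3
    tokenizer_channels: tuple[int, int] = (64, 128)
    conv_stride: int = 1
    pool: str = "max"
    embed_dim: int = 128
    n_heads: int = 2
    mlp_hidden: int = 384
    dropout: float = 0.1
    activation: str = "elu"
    n_classes: int = 4
    input_size: int = 32

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")
        if not 1 <= self.tokenizer_kernel <= 5:
            raise ValueError("tokenizer_kernel must lie in 1..5")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.pool not in ("max", "average"):
            raise ValueError("pool must be 'max' or 'average'")
        act = self.activation.lower().replace("-", "_")
        if act not in ACTIVATION_CHOICES:
            raise ValueError(f"activation must be one of {ACTIVATION_CHOICES}")


class Tokenizer(nn.Module):
    """Conv tokenizer: two (conv -> ReLU -> pool) stages, then flatten to tokens."""

    def __init__(self, rng, cfg: OCCTConfig):
        super().__init__()
        c1, c2 = cfg.tokenizer_channels[0], cfg.embed_dim
        k = cfg.tokenizer_kernel
        self.conv1 = nn.Conv2d(rng, 3, c1, k, stride=cfg.conv_stride,
                               padding="same" if cfg.conv_stride == 1 else (k // 2))
        self.conv2 = nn.Conv2d(rng, c1, c2, k, stride=cfg.conv_stride,
                               padding="same" if cfg.conv_stride == 1 else (k // 2))
        self.pool_fn = F.max_pool2d if cfg.pool == "max" else F.avg_pool2d

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool_fn(self.conv1(x).relu())
        x = self.pool_fn(self.conv2(x).relu())
        n, e, h, w = x.shape
        return x.reshape(n, e, h * w).transpose(0, 2, 1)  # (N, tokens, embed)


class EncoderBlock(nn.Module):
    """Pre-norm residual block: x += MSA(LN(x)); x += MLP(LN(x))."""

    def __init__(self, rng, cfg: OCCTConfig):
        super().__init__()
        e = cfg.embed_dim
        self.ln1 = nn.LayerNorm(e)
        self.attn = nn.MultiHeadSelfAttention(rng, e, cfg.n_heads, cfg.dropout)
        self.ln2 = nn.LayerNorm(e)
        self.fc1 = nn.Dense(rng, e, cfg.mlp_hidden)
        self.act = nn.Activation(cfg.activation)
        self.drop1 = nn.Dropout(rng, cfg.dropout)
        self.fc2 = nn.Dense(rng, cfg.mlp_hidden, e)
        self.drop2 = nn.Dropout(rng, cfg.dropout)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        h = self.drop2(self.fc2(self.drop1(self.act(self.fc1(self.ln2(x))))))
        return x + h


def sequence_pool(tokens: Tensor, scorer: nn.Dense) -> Tensor:
    """Softmax-weighted token average using a learnable scalar scoring map.

    ``tokens``: (N, g, e); returns (N, e).
    """
    if tokens.shape[1] < 1:
        raise ValueError("empty token sequence")
    logits = scorer(tokens)                       # (N, g, 1)
    weights = F.softmax(logits.transpose(0, 2, 1), axis=-1)  # (N, 1, g)
    pooled = weights @ tokens                     # (N, 1, e)
    n, _, e = pooled.shape
    return pooled.reshape(n, e)


class OCCT(nn.Module):
    """Full classifier; ``forward`` returns class probabilities."""

    def __init__(self, cfg: OCCTConfig = OCCTConfig(), seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.tokenizer = Tokenizer(rng, cfg)
        self.blocks = nn.Sequential(
            *[EncoderBlock(rng, cfg) for _ in range(cfg.n_blocks)])
        self.final_ln = nn.LayerNorm(cfg.embed_dim)
        self.scorer = nn.Dense(rng, cfg.embed_dim, 1)
        self.head = nn.Dense(rng, cfg.embed_dim, cfg.n_classes)

    def logits(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        tokens = self.tokenizer(x)
        tokens = self.blocks(tokens)
        tokens = self.final_ln(tokens)
        pooled = sequence_pool(tokens, self.scorer)
        return self.head(pooled)

    def forward(self, x) -> Tensor:
        return F.softmax(self.logits(x), axis=-1)

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        """Argmax class indices, computed in eval mode."""
        was_training = self.training
        self.eval()
        x = np.asarray(x, dtype=np.float32)
        preds = []
        for i in range(0, len(x), batch_size):
            preds.append(self.forward(x[i:i + batch_size]).data.argmax(axis=1))
        if was_training:
            self.train()
        return np.concatenate(preds)


def build_tokenizer(cfg: OCCTConfig = OCCTConfig(), seed: int = 0) -> Tokenizer:
    return Tokenizer(np.random.default_rng(seed), cfg)


def build_encoder_block(cfg: OCCTConfig = OCCTConfig(), seed: int = 0) -> EncoderBlock:
    return EncoderBlock(np.random.default_rng(seed), cfg)


def build_occt(cfg: OCCTConfig = OCCTConfig(), seed: int = 0) -> OCCT:
    return OCCT(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Total number of elements across all trainable tensors."""
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# Sequential ablation grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AblationEntry:
    study: int
    config_number: int
    axis: str
    value: object
    config: OCCTConfig
    optimizer: str
    learning_rate: float
    loss: str


# Axis values per study, in table order; the bolded winner of each study is
# carried into all later studies.
_STUDIES = [
    (1, "n_blocks", [1, 2, 3], 1),
    (2, "tokenizer_kernel", [1, 2, 3, 4, 5], 3),
    (3, "activation", ["relu", "elu", "tanh", "softplus", "softsign",
                       "leaky_relu", "gelu", "sigmoid"], "elu"),
    (4, "pool", ["max", "average"], "max"),
    (5, "optimizer", ["adam", "adamax", "nadam", "sgd", "rmsprop"], "adam"),
    (6, "learning_rate", [0.01, 0.001, 0.006, 0.0008], 0.001),
    (7, "loss", ["categorical_crossentropy", "binary_crossentropy",
                 "mean_squared_error", "mean_squared_logarithmic_error",
                 "mean_absolute_error"], "categorical_crossentropy"),
]

# Values each axis takes before its own study has selected a winner.
_PRESELECTION = {
    "n_blocks": 1,
    "tokenizer_kernel": 3,
    "activation": "relu",
    "pool": "max",
    "optimizer": "adam",
    "learning_rate": 0.001,
    "loss": "categorical_crossentropy",
}


def ablation_grid() -> list[AblationEntry]:
    """All 32 sequential-ablation configurations (studies 1-7).

    Each study varies one axis; axes from earlier studies are pinned to
    their winners, later axes to the pre-selection defaults. The chain of
    winners terminates at the final proposed configuration.
    """
    entries = []
    state = dict(_PRESELECTION)
    for study, axis, values, winner in _STUDIES:
        for i, value in enumerate(values, start=1):
            setting = dict(state)
            setting[axis] = value
            cfg = OCCTConfig(
                n_blocks=setting["n_blocks"],
                tokenizer_kernel=setting["tokenizer_kernel"],
                activation=setting["activation"],
                pool=setting["pool"],
            )
            entries.append(AblationEntry(
                study=study, config_number=i, axis=axis, value=value,
                config=cfg, optimizer=setting["optimizer"],
                learning_rate=setting["learning_rate"], loss=setting["loss"]))
        state[axis] = winner
    return entries


def final_configuration() -> AblationEntry:
    """The winners' chain endpoint (proposed model configuration)."""
    state = dict(_PRESELECTION)
    for study, axis, values, winner in _STUDIES:
        state[axis] = winner
    cfg = OCCTConfig(n_blocks=state["n_blocks"],
                     tokenizer_kernel=state["tokenizer_kernel"],
                     activation=state["activation"], pool=state["pool"])
    return AblationEntry(study=7, config_number=0, axis="final", value="final",
                         config=cfg, optimizer=state["optimizer"],
                         learning_rate=state["learning_rate"],
                         loss=state["loss"])
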