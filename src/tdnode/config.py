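"""Architecture and training configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

__all__ = ["ModelDims", "TrainConfig"]


@dataclass(frozen=True)
class ModelDims:
    """Layer dimensionalities of the four network modules.

    Defaults are the full-scale configuration: 4-dimensional latent state
    (``c``), 2-dimensional kinetic encoding (``k``), GRU hidden 10,
    LSTM/attention width 100, vector-field hidden width 21.
    ``reduced()`` is the desk-scale profile used by the test-suite fixtures
    and the shipped end-to-end experiments.
    """

    c: int = 4  # latent state dimension
    k: int = 2  # kinetic metric dimension
    gru_hidden: int = 10
    gru_layers: int = 2
    pre_width: int = 4  # parameter-encoder preprocessor width
    lstm_hidden: int = 100
    attn_dim: int = 100
    post_width: int = 100
    post_blocks: int = 3
    vf_width: int = 21
    vf_blocks: int = 3
    reducer_width: int = 16

    @classmethod
    def reduced(cls) -> "ModelDims":
        return cls(
            gru_hidden=8,
            gru_layers=2,
            lstm_hidden=24,
            attn_dim=24,
            post_width=32,
            post_blocks=2,
            vf_width=16,
            vf_blocks=2,
            reducer_width=8,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrainConfig:
    """End-to-end training hyperparameters.

    The defaults mirror the reference configuration (150 epochs, Adam at
    learning rate 5e-5, L2 weight decay 1e-3, batch size 8, ODE tolerance
    1e-4, 32-week observation window). ``desk()`` is the scaled-down
    profile exercised in tests and shipped experiments: fewer epochs, a
    larger learning rate suited to the smaller reduced-width network, and a
    bigger batch.
    """

    epochs: int = 150
    lr: float = 5e-5
    weight_decay: float = 1e-3
    batch_size: int = 8
    ode_tol: float = 1e-4
    window: float = 32.0
    seed: int = 0
    pad_mode: str = "pack"
    dims: ModelDims = field(default_factory=ModelDims)
    # discretize-then-optimize integration grid (normalized time units)
    train_dtau: float = 0.25
    train_min_steps: int = 8
    train_max_steps: int = 64

    def __post_init__(self):
        if self.epochs <= 0 or self.lr <= 0 or self.batch_size <= 0:
            raise ValueError("epochs, lr and batch_size must be positive")
        if self.window <= 0 or self.ode_tol <= 0:
            raise ValueError("window and ode_tol must be positive")

    @classmethod
    def desk(cls, epochs: int = 20, seed: int = 0, **kw) -> "TrainConfig":
        return cls(
            epochs=epochs,
            lr=3e-3,
            batch_size=16,
            seed=seed,
            dims=ModelDims.reduced(),
            **kw,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dims"] = self.dims.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["dims"] = ModelDims(**d["dims"])
        return cls(**d)
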