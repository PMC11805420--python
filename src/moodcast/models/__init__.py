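"""Forecast model families of the factorial benchmark."""

from .base import (
    DEFAULT_ORDINAL_THRESHOLDS,
    ModelConfig,
    OrdinalThresholds,
    PredictionSet,
    tune_binary_threshold,
    tune_thresholds,
)
from .gbt import FittedGBT, train_gbt_binary, train_gbt_ordinal
from .recurrent import (
    FittedRNN,
    LSTMCore,
    classes_from_exceedance,
    corn_exceedance,
    train_rnn_binary,
    train_rnn_ordinal,
)

_TRAINERS = {
    ("gbt", "ordinal"): train_gbt_ordinal,
    ("gbt", "binary"): train_gbt_binary,
    ("rnn", "ordinal"): train_rnn_ordinal,
    ("rnn", "binary"): train_rnn_binary,
}


def train(split, config: ModelConfig):
    """Dispatch to the (algorithm, task) trainer of the config."""
    return _TRAINERS[(config.algorithm, config.task)](split, config)


__all__ = [
    "DEFAULT_ORDINAL_THRESHOLDS",
    "ModelConfig",
    "OrdinalThresholds",
    "PredictionSet",
    "FittedGBT",
    "FittedRNN",
    "LSTMCore",
    "classes_from_exceedance",
    "corn_exceedance",
    "train",
    "train_gbt_binary",
    "train_gbt_ordinal",
    "train_rnn_binary",
    "train_rnn_ordinal",
    "tune_binary_threshold",
    "tune_thresholds",
]
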