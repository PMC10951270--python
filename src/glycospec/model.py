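"""High-level modelling interface: a Model fitted to data yielding Results.

:class:`GlycoSpectrumModel` bundles a training/validation/holdout split of
annotated spectra with the network and training hyperparameters; ``fit()``
runs multi-task training and returns :class:`GlycoSpectrumResults`, which
carries the fitted network, the loss history and evaluation utilities
(``predict``, ``evaluate``, ``summary``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fragments import FragmentIndex, GlycopeptidePrecursor
from .network import GlycoSpectrumNetwork, ModelConfig, PredictedSpectrum
from .spectra import AnnotatedSpectrum
from .training import (
    TrainConfig,
    evaluate_spectra,
    finetune,
    split_dataset,
    train,
    train_b_model,
)

__all__ = ["GlycoSpectrumModel", "GlycoSpectrumResults"]


class GlycoSpectrumModel:
    """A spectrum-prediction model specification bound to a dataset."""

    def __init__(
        self,
        train_set: Sequence[AnnotatedSpectrum],
        val_set: Sequence[AnnotatedSpectrum] = (),
        holdout_set: Sequence[AnnotatedSpectrum] = (),
        config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
    ):
        self.train_set = list(train_set)
        self.val_set = list(val_set)
        self.holdout_set = list(holdout_set)
        self.config = config
        self.train_config = train_config

    @classmethod
    def from_dataset(
        cls,
        records: Sequence[AnnotatedSpectrum],
        config: ModelConfig = ModelConfig(),
        train_config: TrainConfig = TrainConfig(),
    ) -> "GlycoSpectrumModel":
        """Split records 3/5-1/5-1/5 (seeded by the train config) and bind."""
        tr, va, ho = split_dataset(records, train_config.seed)
        return cls(tr, va, ho, config=config, train_config=train_config)

    def fit(
        self,
        pretrained: GlycoSpectrumNetwork | None = None,
        freeze_peptide_encoder: bool = False,
        mode: str = "train",
    ) -> "GlycoSpectrumResults":
        """Train the network and return a results object.

        ``mode``: ``train`` (warmup + cosine restarts), ``finetune``
        (plateau decay from a pretrained network) or ``train_b`` (B head on
        top of a trained base model).
        """
        net = GlycoSpectrumNetwork(self.config, seed=self.train_config.seed)
        frozen: set[str] = set()
        if pretrained is not None:
            state = net.state_dict()
            state.update(
                {
                    k: v
                    for k, v in pretrained.state_dict().items()
                    if k in state and state[k].shape == v.shape
                }
            )
            net.load_state_dict(state)
        if freeze_peptide_encoder:
            frozen |= net.peptide_encoder_param_names()
        if mode == "train":
            history = train(
                net, self.train_set, self.val_set, self.train_config, frozen
            )
        elif mode == "finetune":
            if pretrained is None:
                raise ValueError("finetune mode requires a pretrained network")
            history = finetune(
                net, self.train_set, self.val_set, self.train_config, frozen
            )
        elif mode == "train_b":
            if pretrained is None:
                raise ValueError("train_b mode requires a pretrained network")
            history = train_b_model(
                net, self.train_set, self.val_set, self.train_config
            )
        else:
            raise ValueError(f"unknown fit mode {mode!r}")
        return GlycoSpectrumResults(self, net, history)


@dataclass
class GlycoSpectrumResults:
    """Fitted model: the trained network plus training diagnostics."""

    model: GlycoSpectrumModel
    network: GlycoSpectrumNetwork
    history: pd.DataFrame
    _holdout_metrics: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, precursor: GlycopeptidePrecursor) -> PredictedSpectrum:
        return self.network.predict_precursor(precursor)

    def evaluate(
        self, records: Sequence[AnnotatedSpectrum] | None = None
    ) -> pd.DataFrame:
        """Per-spectrum SA/DP metrics (default: the holdout set)."""
        if records is None:
            records = self.model.holdout_set
        return evaluate_spectra(self.network, records)

    @property
    def holdout_metrics(self) -> pd.DataFrame:
        if self._holdout_metrics is None:
            self._holdout_metrics = self.evaluate()
        return self._holdout_metrics

    def save(self, path: str) -> None:
        self.network.save(path)

    def summary(self) -> str:
        """Plain-text summary of the fit, statsmodels-style."""
        cfg = self.network.config
        tc = self.model.train_config
        lines = [
            "Glycopeptide fragment-spectrum prediction results",
            "=" * 58,
            f"{'hidden size':<28}{cfg.hidden_size:>10}",
            f"{'dropout':<28}{cfg.dropout:>10}",
            f"{'B-ion head':<28}{str(cfg.with_B):>10}",
            f"{'parameters':<28}{self.network.n_parameters:>10,}",
            f"{'train / val / holdout':<28}"
            f"{len(self.model.train_set):>4} /{len(self.model.val_set):>4} /"
            f"{len(self.model.holdout_set):>4}",
            f"{'epochs':<28}{len(self.history):>10}",
            f"{'batch size':<28}{tc.batch_size:>10}",
            f"{'seed':<28}{tc.seed:>10}",
        ]
        if len(self.history):
            best = self.history["val_loss"].min()
            lines.append(f"{'best validation loss':<28}{best:>10.4f}")
        hm = self.holdout_metrics
        lines.append("-" * 58)
        lines.append("holdout medians")
        for col in ("sa_total", "sa_pep", "sa_gly", "sa_B", "dp_total"):
            if col in hm.columns and hm[col].notna().any():
                lines.append(
                    f"{'  median ' + col:<28}{hm[col].median():>10.4f}"
                )
        if "ratio_error" in hm.columns and len(hm):
            lines.append(
                f"{'  median |ratio error|':<28}"
                f"{hm['ratio_error'].abs().median():>10.4f}"
            )
        return "\n".join(lines)
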