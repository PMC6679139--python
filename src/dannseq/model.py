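"""Model / Results interface over the adversarial network.

``DannBindingModel`` is built from labeled sequence data (target cell type,
optional source cell types), a training regime, and a config; ``fit()`` runs
the adversarial training loop and returns a ``DannResults`` carrying the
learned parameters, the per-epoch training log, and prediction/evaluation
helpers.

Example
-------
>>> from dannseq import simulate, DannBindingModel
>>> task = simulate.generate_transfer_task(n_domains=3, shift=1.0, seed=0)
>>> model = DannBindingModel(task.target, task.sources, regime="cross_cell_type")
>>> res = model.fit()
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import asdict
from typing import Sequence

import numpy as np

from . import network as nn
from .network import DannConfig
from .sequences import LabeledSequence, encode_dataset, read_tsv
from .training import TrainingRegime, regime_from_mode, train


class DannBindingModel:
    """A domain-adversarial TF binding-site classifier, pre-fit.

    Parameters
    ----------
    target : list of LabeledSequence
        Data of the target cell type.  How its binding labels are used is
        governed by the regime (fully, a seeded fraction, or not at all).
    sources : list of LabeledSequence, optional
        Pooled labeled data of the source cell types (a single "source"
        domain for the binary domain classifier).
    regime : TrainingRegime or str
        One of data_augmentation / semi_supervised / cross_cell_type /
        supervised_baseline, or a TrainingRegime for full control.
    config : DannConfig, optional
    val_data : list of LabeledSequence, optional
        Labeled target validation set for early stopping; if omitted, a
        seeded tenth of the target data is held out.
    """

    def __init__(
        self,
        target: Sequence[LabeledSequence],
        sources: Sequence[LabeledSequence] | None = None,
        regime: TrainingRegime | str = "data_augmentation",
        config: DannConfig | None = None,
        val_data: Sequence[LabeledSequence] | None = None,
        labeled_fraction: float | None = None,
    ):
        if isinstance(regime, str):
            regime = regime_from_mode(regime, labeled_fraction)
        self.target = list(target)
        self.sources = list(sources) if sources else []
        self.regime = regime
        self.config = config or DannConfig()
        self.val_data = list(val_data) if val_data else None

    @classmethod
    def from_tsv(cls, target_tsv, source_tsvs: Sequence = (), **kwargs) -> "DannBindingModel":
        """Build from the 3-column dataset TSVs (sequence, binding_label,
        domain_label) written by the dataset builders."""
        target = read_tsv(target_tsv)
        sources: list[LabeledSequence] = []
        for path in source_tsvs:
            sources.extend(read_tsv(path))
        return cls(target, sources, **kwargs)

    def fit(self) -> "DannResults":
        params, log = train(self.target, self.sources, self.regime, self.config,
                            val_data=self.val_data)
        return DannResults(params, self.config, self.regime, log)


class DannResults:
    """Fitted parameters, training history, and prediction interface."""

    def __init__(self, params: dict, config: DannConfig, regime: TrainingRegime | None,
                 training_log: list[dict]):
        nn.check_param_shapes(params, config)
        self.params = params
        self.config = config
        self.regime = regime
        self.training_log = training_log

    # component views -------------------------------------------------------
    @property
    def theta_f(self) -> dict:
        return {k: self.params[k] for k in nn.THETA_F}

    @property
    def theta_l(self) -> dict:
        return {k: self.params[k] for k in nn.THETA_L}

    @property
    def theta_d(self) -> dict:
        return {k: self.params[k] for k in nn.THETA_D}

    # prediction ------------------------------------------------------------
    def _encode(self, data) -> np.ndarray:
        if isinstance(data, np.ndarray):
            return data.astype(self.config.np_dtype, copy=False)
        if data and isinstance(data[0], str):
            data = [LabeledSequence(s) for s in data]
        X, _, _ = encode_dataset(data, self.config.np_dtype)
        return X

    def score(self, data) -> np.ndarray:
        """Binding scores in [0, 1] (TFBS-class probability, dropout off).

        Accepts LabeledSequence lists, raw 101-mer strings, or encoded
        (B, 4, 101) arrays.
        """
        X = self._encode(data)
        out = [nn.score(X[i:i + 512], self.params, self.config) for i in range(0, len(X), 512)]
        return np.concatenate(out) if out else np.zeros(0)

    def predict(self, data, threshold: float = 0.5) -> np.ndarray:
        """Hard binding calls at the given score threshold."""
        return (self.score(data) >= threshold).astype(int)

    def evaluate(self, data: Sequence[LabeledSequence], threshold: float = 0.5) -> dict:
        from .evaluate import compute_auc, compute_f1

        X, binding, _ = encode_dataset(data, self.config.np_dtype)
        if (binding < 0).any():
            raise ValueError("evaluation data must be fully labeled")
        s = self.score(X)
        y = (binding == 0).astype(int)
        return {"auc": compute_auc(s, y), "f1": compute_f1(s, y, threshold),
                "n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum())}

    # reporting -------------------------------------------------------------
    @property
    def best_epoch(self) -> int:
        aucs = [e["val_auc"] for e in self.training_log]
        return int(np.argmax(aucs)) if aucs else -1

    def summary(self) -> str:
        cfg = self.config
        n_params = sum(int(np.prod(v.shape)) for v in self.params.values())
        lines = [
            "Domain-Adversarial Binding-Site Model Results",
            "=" * 54,
            f"{'regime:':<24}{self.regime.mode if self.regime else 'unknown'}",
            f"{'labeled fraction:':<24}{self.regime.labeled_fraction if self.regime else float('nan'):g}",
            f"{'adversary:':<24}{'on' if self.regime and self.regime.use_adversary else 'off'}",
            f"{'kernels (conv1/conv2):':<24}{cfg.n_kernels_1}/{cfg.n_kernels_2}",
            f"{'feature width:':<24}{cfg.feature_width}",
            f"{'alpha:':<24}{cfg.alpha:g}",
            f"{'learning rate:':<24}{cfg.learning_rate:g}  (momentum {cfg.momentum:g})",
            f"{'parameters:':<24}{n_params}",
            f"{'epochs run:':<24}{len(self.training_log)}",
            f"{'best epoch (val AUC):':<24}{self.best_epoch}"
            + (f"  ({self.training_log[self.best_epoch]['val_auc']:.4f})" if self.training_log else ""),
            "-" * 54,
            f"{'epoch':>5} {'pred_loss':>10} {'dom_loss':>10} {'val_auc':>9} {'lambda':>8}",
        ]
        for e in self.training_log:
            lines.append(
                f"{e['epoch']:>5} {e['pred_loss']:>10.4f} {e['dom_loss']:>10.4f} "
                f"{e['val_auc']:>9.4f} {e['lambda']:>8.4f}"
            )
        return "\n".join(lines)

    # persistence -----------------------------------------------------------
    def save(self, path) -> None:
        nn.save_checkpoint(path, self.params, self.config, self.training_log)

    @classmethod
    def load(cls, path) -> "DannResults":
        params, config, log = nn.load_checkpoint(path)
        return cls(params, config, None, log)
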