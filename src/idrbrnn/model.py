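"""High-level modelling interface.

``DisorderBRNN`` is built from a labelled corpus and a variant choice;
``fit()`` runs the cross-validated training protocol and returns a
``DisorderResults`` object carrying the per-fold ensembles, the pooled
out-of-fold predictions, the FPR-anchored decision threshold and the full
evaluation battery, with a ``summary()`` table.

    >>> from idrbrnn import DisorderBRNN, SyntheticConfig, generate_corpus
    >>> corpus = generate_corpus(SyntheticConfig(n_chains=20, seed=1))
    >>> model = DisorderBRNN(corpus, variant="MSA")
    >>> res = model.fit()            # doctest: +SKIP
    >>> print(res.summary())         # doctest: +SKIP
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import make_folds
from .encoders import assemble_inputs
from .evaluation import (
    ChainScores,
    EvalReport,
    evaluate_scores,
    pool_chains,
    threshold_at_fpr,
    trim_termini,
)
from .network import FilterGeometry
from .records import FoldSplit, ProteinRecord
from .training import (
    EnsembleModel,
    TrainConfig,
    crossvalidate,
    ensemble_predict,
    load_ensemble,
    merge_ensembles,
    save_ensemble,
)


class DisorderBRNN:
    """Two-stage BRNN disorder predictor over a labelled corpus.

    Parameters
    ----------
    corpus:
        Labelled, annotated protein records.
    variant:
        Input-encoding variant: ``MSA``, ``MSA-SS-SA``, ``MSA-Templ`` or
        ``MSA-SS-SA-Templ``.
    geometry:
        Second-stage filter geometry (defaults w=7, p=10).
    hidden_chain, subnet_hidden, span:
        Network widths and shortcut span.
    train_config:
        Schedule; defaults to the full-scale protocol.
    """

    def __init__(
        self,
        corpus: list[ProteinRecord],
        variant: str = "MSA",
        geometry: FilterGeometry | None = None,
        hidden_chain: int = 11,
        subnet_hidden: int = 11,
        span: int = 2,
        train_config: TrainConfig | None = None,
    ) -> None:
        if not corpus:
            raise ValueError("empty corpus")
        self.corpus = corpus
        self.variant = variant
        self.geometry = geometry or FilterGeometry()
        self.hidden_chain = hidden_chain
        self.subnet_hidden = subnet_hidden
        self.span = span
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "DisorderBRNN":
        from .corpus_io import read_corpus

        return cls(read_corpus(path), **kwargs)

    def fit(
        self,
        folds: FoldSplit | None = None,
        k: int = 5,
        target_fpr: float = 0.05,
    ) -> "DisorderResults":
        """Cross-validated training; the decision threshold is selected at
        the target FPR on the pooled out-of-fold scores."""
        if folds is None:
            folds = make_folds(self.corpus, k=k, seed=self.train_config.seed)
        ensembles, pooled, histories = crossvalidate(
            self.corpus,
            folds,
            self.variant,
            self.train_config,
            geometry=self.geometry,
            hidden_chain=self.hidden_chain,
            subnet_hidden=self.subnet_hidden,
            span=self.span,
        )
        chains = [
            ChainScores(
                r.id,
                pooled[r.id],
                np.frombuffer(r.labels.encode(), dtype=np.int8) - ord("0"),
            )
            for r in self.corpus
        ]
        scores, labels = pool_chains(chains)
        threshold = threshold_at_fpr(scores, labels, target_fpr)
        return DisorderResults(
            model=self,
            folds=folds,
            ensembles=ensembles,
            chains=chains,
            histories=histories,
            threshold=threshold,
            target_fpr=target_fpr,
        )


@dataclass
class DisorderResults:
    """Fitted predictor: ensembles, out-of-fold scores and diagnostics."""

    model: DisorderBRNN
    folds: FoldSplit
    ensembles: list[EnsembleModel]
    chains: list[ChainScores]
    histories: list[pd.DataFrame]
    threshold: float
    target_fpr: float
    _merged: EnsembleModel | None = field(default=None, repr=False)

    @property
    def merged_ensemble(self) -> EnsembleModel:
        if self._merged is None:
            self._merged = merge_ensembles(self.ensembles)
        return self._merged

    def predict(self, record: ProteinRecord) -> np.ndarray:
        """Per-residue disorder probability from the merged ensemble."""
        X = assemble_inputs(self.model.variant, record)
        return ensemble_predict(self.merged_ensemble, X)[:, 1]

    def predict_proba(self, record: ProteinRecord) -> np.ndarray:
        X = assemble_inputs(self.model.variant, record)
        return ensemble_predict(self.merged_ensemble, X)

    def report(self, n_trim: int = 0) -> EvalReport:
        """Out-of-fold evaluation battery, optionally trimming chain termini."""
        chains = trim_termini(self.chains, n_trim)
        scores, labels = pool_chains(chains)
        return evaluate_scores(scores, labels, self.threshold)

    def summary(self) -> str:
        rep = self.report()
        scores, labels = pool_chains(self.chains)
        lines = [
            "Disorder prediction: two-stage BRNN, out-of-fold results",
            "=" * 58,
            f"variant:              {self.model.variant}",
            f"chains / residues:    {len(self.chains)} / {scores.size}",
            f"disorder prevalence:  {labels.mean():.4f}",
            f"folds / members:      {self.folds.n_folds} / "
            f"{len(self.merged_ensemble.members)}",
            f"threshold (FPR<={self.target_fpr:.0%}): {self.threshold:.4f}",
            "-" * 58,
            f"sensitivity (SE):     {rep.metrics.sensitivity:.3f}",
            f"specificity (SP):     {rep.metrics.specificity:.3f}",
            f"precision (Prec):     {rep.metrics.precision:.3f}",
            f"balanced acc (Acc):   {rep.metrics.balanced_accuracy:.3f}",
            f"MCC:                  {rep.metrics.mcc:.3f}",
            f"AUC-ROC:              {rep.auc_roc:.3f}",
            f"AUC-PR:               {rep.auc_pr:.3f}",
        ]
        return "\n".join(lines)

    def plot_curves(self, path: str | Path | None = None):
        """ROC and PR curves of the pooled out-of-fold predictions.

        Returns the matplotlib figure; saves it when ``path`` is given.
        """
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        from .evaluation import pr_curve, roc_curve

        scores, labels = pool_chains(self.chains)
        roc = roc_curve(scores, labels)
        pr = pr_curve(scores, labels)
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
        ax1.plot(roc.points[:, 0], roc.points[:, 1])
        ax1.plot([0, 1], [0, 1], ls=":", c="grey")
        ax1.set(xlabel="FPR", ylabel="TPR",
                title=f"ROC (AUC = {roc.area:.3f})")
        ax2.plot(pr.points[:, 0], pr.points[:, 1])
        ax2.axhline(labels.mean(), ls=":", c="grey")
        ax2.set(xlabel="recall", ylabel="precision",
                title=f"PR (AUC = {pr.area:.3f})")
        fig.suptitle(self.model.variant)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
        return fig

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for i, ens in enumerate(self.ensembles):
            save_ensemble(ens, out / f"ensemble_fold{i}.npz")
        save_ensemble(self.merged_ensemble, out / "ensemble_merged.npz")
        for i, h in enumerate(self.histories):
            h.to_csv(out / f"history_fold{i}.csv", index=False)
        meta = dict(
            variant=self.model.variant,
            threshold=self.threshold,
            target_fpr=self.target_fpr,
            n_folds=self.folds.n_folds,
            seed=self.model.train_config.seed,
        )
        (out / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
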