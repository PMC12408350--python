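"""Scikit-learn style estimator for latent Langevin inference.

``LatentLangevinEstimator`` wraps the full pipeline — two-split ADAM
fitting, feature-consistency model selection and Viterbi decoding — as a
BaseEstimator with ``fit`` / ``predict`` / ``score`` and fitted
attributes carrying trailing underscores, so it composes with sklearn
model-selection utilities.  The functional API in ``optimize`` and
``selection`` remains the underlying implementation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import SpikeData, Trial
from .likelihood import dataset_loglik
from .optimize import FitConfig, two_split_fit
from .selection import classify_outcome, select, selected_barrier_counts
from .validation import orient_to_choices, predict_choice

__all__ = ["LatentLangevinEstimator"]


class LatentLangevinEstimator(BaseEstimator):
    """Joint inference of latent dynamics and tuning from spike trains.

    Parameters mirror :class:`~latentspike.optimize.FitConfig`.  ``fit``
    expects a :class:`SpikeData` (or list of :class:`Trial`); it runs two
    independent fits on the even/odd trial split and selects the
    highest-complexity consistent model pair.

    Attributes (after fit)
    ----------------------
    model_ : the selected model from split 1 (potential, D, p0, tuning).
    model2_ : the matched model from split 2.
    selection_ : full :class:`SelectionResult` (M*, D_JS curve, outcome).
    traces_ : the two :class:`FitTrace` objects.
    outcome_ : fit-outcome label (good / overfit / underfit_*).
    barriers_ : barrier count per condition from the selected pair.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        beta1: float = 0.9,
        beta2: float = 0.99,
        epsilon: float = 1e-8,
        n_batches: int = 20,
        n_epochs: int = 5000,
        n_line_searches: int = 30,
        seed: int = 0,
        grid_size: int = 256,
        djs_threshold: float = 0.0015,
        D_init: float = 0.1,
        n_snapshots: int = 40,
    ):
        self.alpha = alpha
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.n_batches = n_batches
        self.n_epochs = n_epochs
        self.n_line_searches = n_line_searches
        self.seed = seed
        self.grid_size = grid_size
        self.djs_threshold = djs_threshold
        self.D_init = D_init
        self.n_snapshots = n_snapshots

    # ------------------------------------------------------------------

    def _as_data(self, X) -> SpikeData:
        if isinstance(X, SpikeData):
            return X
        if isinstance(X, (list, tuple)) and all(isinstance(t, Trial) for t in X):
            n = 1 + max((int(t.neuron_ids.max()) for t in X if t.n_spikes), default=0)
            return SpikeData(list(X), n)
        raise TypeError("X must be SpikeData or a list of Trial")

    def _config(self) -> FitConfig:
        return FitConfig(
            alpha=self.alpha,
            beta1=self.beta1,
            beta2=self.beta2,
            epsilon=self.epsilon,
            n_batches=self.n_batches,
            n_epochs=self.n_epochs,
            n_line_searches=self.n_line_searches,
            seed=self.seed,
            grid_size=self.grid_size,
            djs_threshold=self.djs_threshold,
            D_init=self.D_init,
            n_snapshots=self.n_snapshots,
        )

    def fit(self, X, y=None):
        data = self._as_data(X)
        if len(data) < 2:
            raise ValueError("need at least two trials")
        t1, t2 = two_split_fit(data, self._config())
        sel = select(t1, t2, threshold=self.djs_threshold)
        classify_outcome(sel)
        # fix the reflection gauge from choice labels where available
        m1, flipped = orient_to_choices(sel.model1, data)
        m2 = sel.model2.mirror() if flipped else sel.model2
        self.traces_ = (t1, t2)
        self.selection_ = sel
        self.gauge_flipped_ = flipped
        self.model_ = m1
        self.model2_ = m2
        self.outcome_ = sel.outcome
        self.barriers_ = selected_barrier_counts(sel)
        self.n_conditions_ = sel.model1.n_conditions
        self.n_neurons_ = sel.model1.n_neurons
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted choice (-1 / +1) per trial from the decoded path."""
        self._check_fitted()
        data = self._as_data(X)
        return np.array(
            [predict_choice(self.model_, tr, tr.condition) for tr in data]
        )

    def score(self, X, y=None) -> float:
        """Mean per-trial normalized log-likelihood under the selected model."""
        self._check_fitted()
        data = self._as_data(X)
        return dataset_loglik(self.model_, data, which="normalized") / len(data)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
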