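"""scikit-learn style estimator façades over the two denoisers.

Both estimators consume paired window matrices shaped ``(n_windows, L)``
(rows are z-scored signal windows) and learn the noisy-to-clean mapping;
``predict`` reconstructs windows and ``denoise_signal`` runs the full
embed / reconstruct / diagonal-average pipeline on a whole signal.  They
compose with sklearn model selection through ``get_params``/``set_params``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import dbn_core, baseline_cnn
from .dbn_core import (DBNModel, LossConfig, TrainConfig, pretrain,
                       fine_tune, forward, denoise)
from .signal_prep import TimeSeries
from .baseline_cnn import (CNNSpec, build_default_cnn, cnn_forward,
                           train_cnn)

__all__ = ["DBNDenoiser", "CNNDenoiser"]


def _check_pair(X, y):
    X = check_array(X, dtype=float)
    y = check_array(y, dtype=float)
    if X.shape != y.shape:
        raise ValueError(
            f"noisy and clean batches must share a shape: {X.shape} vs "
            f"{y.shape}")
    return X, y


class DBNDenoiser(RegressorMixin, BaseEstimator):
    """Gauss-Bernoulli deep-belief-network window denoiser.

    Parameters
    ----------
    hidden_dims : widths of the three stacked RBM hidden layers.
    pretrain_epochs, finetune_epochs, batch_size, cd_steps : training
        schedule; pre-training is unsupervised CD with plain SGD, the
        fine-tuning stage backpropagates the joint time/frequency loss with
        Adam.
    lr_schedule : ``((epoch, rate), ...)`` breakpoints, default halves
        5e-3 to 2.5e-3 at epoch 90.
    lambda1, lambda2 : joint-loss weights (time MSE / spectral L1).
    random_state : seed controlling initialization, CD sampling, batching
        and the validation split.

    Attributes
    ----------
    model_ : trained :class:`~piezodenoise.dbn_core.DBNModel`.
    history_ : per-epoch dicts of train/validation loss and learning rate.
    """

    def __init__(self, hidden_dims=(256, 128, 64), pretrain_epochs=10,
                 finetune_epochs=100, batch_size=32, cd_steps=1,
                 pretrain_rate=1e-3, lr_schedule=((1, 5e-3), (90, 2.5e-3)),
                 lambda1=0.7, lambda2=0.3, validation_fraction=0.2,
                 random_state=0):
        self.hidden_dims = hidden_dims
        self.pretrain_epochs = pretrain_epochs
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.cd_steps = cd_steps
        self.pretrain_rate = pretrain_rate
        self.lr_schedule = lr_schedule
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def _configs(self) -> tuple[TrainConfig, LossConfig]:
        return (TrainConfig(pretrain_epochs=self.pretrain_epochs,
                            finetune_epochs=self.finetune_epochs,
                            batch_size=self.batch_size,
                            cd_steps=self.cd_steps,
                            pretrain_rate=self.pretrain_rate,
                            lr_schedule=tuple(self.lr_schedule),
                            validation_fraction=self.validation_fraction,
                            seed=self.random_state),
                LossConfig(lambda1=self.lambda1, lambda2=self.lambda2))

    def fit(self, X, y):
        """Pre-train on the noisy windows, then fine-tune on (X, y) pairs."""
        X, y = _check_pair(X, y)
        cfg, loss_cfg = self._configs()
        model = DBNModel.initialize(input_dim=X.shape[1],
                                    hidden_dims=tuple(self.hidden_dims),
                                    seed=self.random_state)
        model = pretrain(model, X, cfg)
        self.model_, self.history_ = fine_tune(model, X, y, cfg, loss_cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = check_array(X, dtype=float)
        return forward(self.model_, X)

    def denoise_signal(self, x: TimeSeries | np.ndarray) -> TimeSeries:
        """Denoise a whole 1-D signal via the trajectory-matrix pipeline."""
        check_is_fitted(self, "model_")
        return denoise(self.model_, x)


class CNNDenoiser(RegressorMixin, BaseEstimator):
    """Convolutional encoder-decoder comparator with the same training
    loop, loss and optimizer settings as :class:`DBNDenoiser`."""

    def __init__(self, spec: CNNSpec | None = None, finetune_epochs=100,
                 batch_size=32, lr_schedule=((1, 5e-3), (90, 2.5e-3)),
                 lambda1=0.7, lambda2=0.3, validation_fraction=0.2,
                 random_state=0):
        self.spec = spec
        self.finetune_epochs = finetune_epochs
        self.batch_size = batch_size
        self.lr_schedule = lr_schedule
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _check_pair(X, y)
        spec = build_default_cnn() if self.spec is None else self.spec
        cfg = TrainConfig(finetune_epochs=self.finetune_epochs,
                          batch_size=self.batch_size,
                          lr_schedule=tuple(self.lr_schedule),
                          validation_fraction=self.validation_fraction,
                          seed=self.random_state)
        loss_cfg = LossConfig(lambda1=self.lambda1, lambda2=self.lambda2)
        self.spec_ = spec
        self.weights_, self.history_ = train_cnn(spec, X, y, cfg, loss_cfg)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        return cnn_forward(self.spec_, self.weights_, X)

    def denoise_signal(self, x: TimeSeries | np.ndarray,
                       chunk_size: int = 256) -> TimeSeries:
        """Window the signal, reconstruct each window, diagonal-average.

        Windows are processed in chunks: the im2col convolution buffers
        grow with batch x length x (channels x kernel), so an unchunked
        pass over a long signal would be needlessly memory-hungry.
        """
        check_is_fitted(self, "weights_")
        from .signal_prep import (build_trajectory_matrix, normalize_columns,
                                  denormalize_columns, diagonal_average,
                                  TrajectoryMatrix)
        X = normalize_columns(build_trajectory_matrix(x, self.n_features_in_))
        windows = X.values.T
        rec = np.vstack([self.predict(windows[i:i + chunk_size])
                         for i in range(0, windows.shape[0],
                                        chunk_size)]).T
        out = denormalize_columns(TrajectoryMatrix(
            values=rec, rate=X.rate, normalized=True,
            column_means=X.column_means, column_stds=X.column_stds))
        return diagonal_average(out)
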