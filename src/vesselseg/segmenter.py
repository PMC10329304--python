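"""scikit-learn-style estimator facade over the segmentation toolkit.

:class:`VesselSegmenter` wraps network construction, the training loop and
sliding-window inference behind the familiar ``fit`` / ``predict`` API so it
composes with sklearn model selection; the functional modules underneath
remain the primary library surface.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import RunConfig, load_config
from .inference import build_sliding_plan, postprocess, sliding_window_infer
from .io import CTVolume, LabelVolume
from .metrics import voxel_metrics
from .network import IBSwinUNet3D
from .training import train


class VesselSegmenter(BaseEstimator):
    """Trainable 3D vessel segmenter.

    Parameters mirror the run configuration; ``config_overrides`` takes
    dotted keys (e.g. ``{"loss.beta": 6}``).  After ``fit`` the trained
    network is available as ``model_`` and the loss trajectory as
    ``loss_history_``.
    """

    def __init__(self, base_channels: int = 128, depths: tuple = (2, 2, 2),
                 window_size: tuple = (4, 4, 4), beta: float = 6.0,
                 learning_rate: float = 3e-5, steps: int | None = None,
                 seed: int = 0, config_overrides: dict | None = None):
        self.base_channels = base_channels
        self.depths = depths
        self.window_size = window_size
        self.beta = beta
        self.learning_rate = learning_rate
        self.steps = steps
        self.seed = seed
        self.config_overrides = config_overrides

    def _config(self) -> RunConfig:
        overrides = {
            "model.base_channels": self.base_channels,
            "model.depths": list(self.depths),
            "model.window_size": list(self.window_size),
            "loss.beta": self.beta,
            "training.learning_rate": self.learning_rate,
            "training.seed": self.seed,
        }
        overrides.update(self.config_overrides or {})
        return load_config(overrides=overrides)

    def fit(self, X, y):
        """Train on paired volumes: ``X`` and ``y`` are sequences of images
        and binary vessel masks on matching grids."""
        cfg = self._config()
        self.config_ = cfg
        self.model_ = IBSwinUNet3D(
            base_channels=cfg.model.base_channels, depths=cfg.model.depths,
            window_size=cfg.model.window_size, position_mode=cfg.model.position_mode,
            downsample_mode=cfg.model.downsample_mode,
            upsample_mode=cfg.model.upsample_mode, local_path=cfg.model.local_path,
            mlp_ratio=cfg.model.mlp_ratio, seed=self.seed)
        state = train(self.model_, list(zip(X, y)), cfg, steps=self.steps, log_every=0)
        self.loss_history_ = state.loss_history
        self.n_steps_ = state.step
        return self

    def predict_proba(self, volume) -> np.ndarray:
        """Foreground-probability volume via sliding-window inference."""
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")
        vol = volume if isinstance(volume, CTVolume) else CTVolume(np.asarray(volume))
        cfg = self.config_
        plan = build_sliding_plan(vol.shape, cfg.inference.patch_size,
                                  cfg.inference.overlap, cfg.inference.overlap_is_step)
        return sliding_window_infer(vol, lambda p: self.model_.forward(p).foreground,
                                    plan, cfg.inference.aggregation)

    def predict(self, volume) -> LabelVolume:
        """Binary vessel mask with post-processing applied."""
        vol = volume if isinstance(volume, CTVolume) else CTVolume(np.asarray(volume))
        prob = self.predict_proba(vol)
        cfg = self.config_
        return postprocess(prob, vol.spacing, cfg.inference.threshold,
                           cfg.postprocess.min_component_mm3,
                           cfg.postprocess.morphological_close)

    def score(self, X, y) -> float:
        """Mean foreground Dice over the given cases."""
        dices = [voxel_metrics(self.predict(v).data, getattr(g, "data", g))[0]
                 for v, g in zip(X, y)]
        return float(np.mean(dices))
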