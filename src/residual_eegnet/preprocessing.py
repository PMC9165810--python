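"""Per-trial normalization and two-scale additive-noise augmentation.

Normalization standardizes every trial to mean 0 / sd 1 (per channel by
default), compensating impedance and noise-level differences between
electrodes and participants.  Augmentation — applied to *training* trials
only — adds one Gaussian offset per trial (sd 0.10) and one per channel
(sd 0.03), the "10% trial-scale / 3% channel-scale" noise expansion.
An i.i.d.-per-sample reading of the same sigmas is available behind
``mode="iid_samples"``; the default scalar-offset reading is recorded in
output metadata by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from residual_eegnet.data_model import EEGEpoch


class DegenerateEpochError(ValueError):
    pass


@dataclass
class AugmentParams:
    sigma_trial: float = 0.10
    sigma_channel: float = 0.03
    enabled: bool = True
    mode: str = "scalar_offsets"  # or "iid_samples"

    def __post_init__(self):
        if self.sigma_trial < 0 or self.sigma_channel < 0:
            raise ValueError("augmentation sigmas must be non-negative")
        if self.mode not in ("scalar_offsets", "iid_samples"):
            raise ValueError(f"unknown augmentation mode {self.mode!r}")


def zscore_array(data: np.ndarray, scope: str = "per_channel") -> np.ndarray:
    """Standardize a (channels, samples) array to mean 0 / sd 1.

    ``scope="per_channel"`` standardizes each channel row separately (the
    default); ``"per_trial_pooled"`` uses one mean/sd over the whole trial.
    """
    if scope == "per_channel":
        mean = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        bad = np.flatnonzero(sd[:, 0] == 0)
        if bad.size:
            raise DegenerateEpochError(
                f"zero-variance channel(s) {bad.tolist()}: cannot standardize"
            )
    elif scope == "per_trial_pooled":
        mean = data.mean()
        sd = data.std()
        if sd == 0:
            raise DegenerateEpochError("zero-variance trial: cannot standardize")
    else:
        raise ValueError(f"unknown zscore scope {scope!r}")
    return (data - mean) / sd


def zscore_epoch(epoch: EEGEpoch, scope: str = "per_channel") -> EEGEpoch:
    """Return a standardized copy of ``epoch`` (metadata preserved)."""
    return replace(epoch, data=zscore_array(epoch.data, scope=scope))


def augment_array(data: np.ndarray, params: AugmentParams,
                  rng: np.random.Generator) -> np.ndarray:
    """Add two-scale noise to one or a batch of (channels, samples) arrays.

    ``data`` may be (C, T) or (N, C, T); offsets are drawn per trial and
    per trial-channel, fresh on every call.
    """
    if not params.enabled:
        return data
    single = data.ndim == 2
    x = data[None] if single else data
    n, c, t = x.shape
    if params.mode == "scalar_offsets":
        trial = params.sigma_trial * rng.standard_normal((n, 1, 1))
        chan = params.sigma_channel * rng.standard_normal((n, c, 1))
        out = x + trial + chan
    else:  # iid_samples
        out = (
            x
            + params.sigma_trial * rng.standard_normal((n, 1, t))
            + params.sigma_channel * rng.standard_normal((n, c, t))
        )
    return out[0] if single else out


def augment_epoch(epoch: EEGEpoch, params: AugmentParams,
                  rng: np.random.Generator) -> EEGEpoch:
    """Noise-augmented copy of an (already normalized) epoch."""
    return replace(epoch, data=augment_array(epoch.data, params, rng))
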