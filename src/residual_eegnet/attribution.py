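"""Grad-CAM attribution over channels and time.

For a trained model and a trial, the class score y^c (by default the
pre-softmax logit for class c; the log-softmax output is available via
``score="log_softmax"``) is differentiated with respect to the
feature maps A^k of a chosen block — by default the output of the tenth
temporal-residual block, which still has full 64 x 720 resolution, so no
upsampling is needed.  The map weights are the global average of those
gradients, alpha_k = (1/Z) sum_ij dy^c/dA^k_ij, and the heatmap is
L^c = ReLU(sum_k alpha_k A^k).

Group analysis follows the correct-trial protocol: only trials the model
classifies correctly contribute, maps are averaged per participant and
task, and each channel's time-averaged score is compared against the
participant's cross-channel baseline (the mean of all 64 channel scores)
with Welch's t-test, Benjamini-Hochberg corrected per task over the 64
channels (or over the 64 x T channel-time family for time-resolved maps,
with a per-time-point baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from residual_eegnet import nn
from residual_eegnet.data_model import EEGEpoch, TaskLabel
from residual_eegnet.evaluation import bh_fdr, welch_t_test
from residual_eegnet.training import prepare_arrays

log = logging.getLogger(__name__)

DEFAULT_LAYER = "conv2dtype1.10"
#: differentiate the pre-softmax logit: on confident correct trials the
#: log-softmax output saturates at 0 and its gradients vanish, which would
#: null exactly the trials the correct-trial protocol aggregates.
DEFAULT_SCORE = "logit"


@dataclass
class FeatureMapStack:
    """Activations A and gradients dy^c/dA of one block for one trial."""

    maps: np.ndarray   # (K, channels, time)
    grads: np.ndarray  # same geometry
    class_index: int
    layer: str

    def __post_init__(self):
        if self.maps.shape != self.grads.shape:
            raise ValueError("maps and grads must share geometry")

    @property
    def Z(self) -> int:
        return self.maps.shape[1] * self.maps.shape[2]


@dataclass
class AttributionMap:
    heatmap: np.ndarray  # (channels, time), non-negative
    class_index: int
    subject_id: int
    layer: str

    def __post_init__(self):
        if np.any(self.heatmap < 0):
            raise ValueError("heatmap must be non-negative (ReLU output)")


@dataclass
class ChannelScoreTable:
    """Per-participant per-channel time-averaged scores, one task at a time.

    ``mean_maps[task][participant]`` keeps the time-resolved (channels x
    time) participant mean for the time-point tests; ``scores[task]`` is
    the participants x channels table; the baseline is each participant's
    mean over the 64 channels.
    """

    scores: dict[TaskLabel, pd.DataFrame] = field(default_factory=dict)
    mean_maps: dict[TaskLabel, dict[int, np.ndarray]] = field(default_factory=dict)

    def baseline(self, task: TaskLabel) -> pd.Series:
        return self.scores[task].mean(axis=1)


def capture_layer(model: nn.Model, epoch, class_index: int,
                  layer: str = DEFAULT_LAYER,
                  score: str = DEFAULT_SCORE) -> FeatureMapStack:
    """Forward + backward one trial, returning A and dy^c/dA at ``layer``.

    ``score`` selects the differentiated quantity: the pre-softmax
    ``"logit"`` (default) or the ``"log_softmax"`` class output.
    """
    if score not in ("log_softmax", "logit"):
        raise ValueError(f"unknown score type {score!r}")
    x = _as_batch(epoch, model)
    out = model.forward(x, train=False, capture=(layer,))
    seed = np.zeros_like(out)
    seed[:, class_index] = 1.0
    if score == "logit":
        # differentiate the pre-softmax class score: walk backward skipping
        # the head's final log-softmax layer
        head = model.block("classifier")
        if not (isinstance(head, nn.Sequential)
                and isinstance(head.layers[-1], nn.LogSoftmax)):
            raise ValueError("logit score requires a log-softmax classifier head")
        model._grads = {}
        g = seed
        for name, block in reversed(model.blocks):
            if name == "classifier":
                for sub in reversed(block.layers[:-1]):
                    g = sub.backward(g)
            else:
                if name == layer:
                    model._grads[name] = nn.from_internal(g)
                g = block.backward(g)
    else:
        model.backward(seed, capture=(layer,))
    maps = model.captured_activation(layer)[0]
    grads = model.captured_gradient(layer)[0]
    return FeatureMapStack(maps=maps.copy(), grads=grads.copy(),
                           class_index=int(class_index), layer=layer)


def _as_batch(epoch, model) -> np.ndarray:
    dtype = model.parameters()[0].value.dtype
    if isinstance(epoch, EEGEpoch):
        return epoch.data.astype(dtype)[None, None]
    arr = np.asarray(epoch, dtype=dtype)
    if arr.ndim == 2:
        arr = arr[None, None]
    return arr


def alpha_weights(stack: FeatureMapStack) -> np.ndarray:
    """Global-average-pooled gradient weight per feature map."""
    return stack.grads.reshape(stack.grads.shape[0], -1).mean(axis=1)


def cam_heatmap(stack: FeatureMapStack, alphas: np.ndarray) -> AttributionMap:
    """Rectified alpha-weighted map combination at native resolution."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape[0] != stack.maps.shape[0]:
        raise ValueError("one alpha per feature map required")
    combined = np.tensordot(alphas, stack.maps, axes=(0, 0))
    return AttributionMap(heatmap=np.maximum(combined, 0.0),
                          class_index=stack.class_index, subject_id=-1,
                          layer=stack.layer)


def gradcam_trial(model: nn.Model, epoch, class_index: int,
                  layer: str = DEFAULT_LAYER,
                  score: str = DEFAULT_SCORE) -> AttributionMap:
    stack = capture_layer(model, epoch, class_index, layer, score)
    return cam_heatmap(stack, alpha_weights(stack))


def gradcam_for_correct_trials(model: nn.Model, epochs: list[EEGEpoch],
                               layer: str = DEFAULT_LAYER,
                               score: str = DEFAULT_SCORE,
                               zscore_scope: str = "per_channel"
                               ) -> dict[tuple[int, TaskLabel], list[AttributionMap]]:
    """Grad-CAM w.r.t. the true class on correctly classified trials only.

    Epochs are normalized, predicted in a batch, filtered to prediction ==
    label, and each kept trial's map is grouped by (participant, task).
    """
    from residual_eegnet.evaluation import predict

    x, y, subj = prepare_arrays(epochs, zscore_scope,
                                model.parameters()[0].value.dtype)
    preds, _ = predict(model, x)
    groups: dict[tuple[int, TaskLabel], list[AttributionMap]] = {}
    n_correct = 0
    for i in range(x.shape[0]):
        if preds[i] != y[i]:
            continue
        n_correct += 1
        amap = gradcam_trial(model, x[i : i + 1], int(y[i]), layer, score)
        amap.subject_id = int(subj[i])
        groups.setdefault((int(subj[i]), TaskLabel(int(y[i]))), []).append(amap)
    if n_correct == 0:
        log.warning("no correctly classified trials; attribution set is empty")
    return groups


def channel_scores(groups: dict[tuple[int, TaskLabel], list[AttributionMap]]
                   ) -> ChannelScoreTable:
    """Per-participant trial-mean maps and time-averaged channel scores."""
    if not groups:
        raise ValueError("no attribution maps to aggregate")
    table = ChannelScoreTable()
    for (subject, task), maps in sorted(groups.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        if not maps:
            continue
        mean_map = np.mean([m.heatmap for m in maps], axis=0)
        table.mean_maps.setdefault(task, {})[subject] = mean_map
        row = mean_map.mean(axis=1)
        df = table.scores.setdefault(
            task, pd.DataFrame(columns=pd.RangeIndex(row.size, name="channel"))
        )
        table.scores[task].loc[subject] = row
    return table


def significance_vs_baseline(table: ChannelScoreTable, q: float = 0.05,
                             axis: str = "channel") -> dict[TaskLabel, pd.DataFrame]:
    """Welch-test channel scores against the cross-channel baseline.

    ``axis="channel"``: per task, 64 unpaired tests of the participants'
    channel scores vs their baselines, BH over the 64.  ``axis=
    "timepoint"``: the same per channel and time point, with the baseline
    recomputed per time point (mean over channels), BH over the 64 x T
    family per task.
    """
    if axis not in ("channel", "timepoint"):
        raise ValueError(f"unknown axis {axis!r}")
    out: dict[TaskLabel, pd.DataFrame] = {}
    for task, df in table.scores.items():
        if df.shape[0] < 2:
            raise ValueError(
                f"need >= 2 participants for task {task.name}, got {df.shape[0]}"
            )
        if axis == "channel":
            base = table.baseline(task).to_numpy()
            rows = []
            for ch in df.columns:
                r = welch_t_test(df[ch].to_numpy(), base, q=q)
                rows.append({"channel": ch, "t": r.t, "df": r.df, "p": r.p})
            res = pd.DataFrame(rows).set_index("channel")
            res["rejected"] = bh_fdr(res["p"].to_numpy(), q=q)
            out[task] = res
        else:
            subjects = sorted(table.mean_maps[task])
            S = np.stack([table.mean_maps[task][s] for s in subjects])  # (P, C, T)
            B = S.mean(axis=1)  # (P, T) per-time-point baseline
            t, dfree, p = _welch_arrays(S, B[:, None, :])
            res = pd.DataFrame({
                "channel": np.repeat(np.arange(S.shape[1]), S.shape[2]),
                "time": np.tile(np.arange(S.shape[2]), S.shape[1]),
                "t": t.ravel(), "df": dfree.ravel(), "p": p.ravel(),
            })
            res["rejected"] = bh_fdr(res["p"].to_numpy(), q=q)
            out[task] = res
    return out


def _welch_arrays(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch test along axis 0 with broadcasting (two-tailed)."""
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1) / na
    vb = np.broadcast_to(b.var(axis=0, ddof=1) / nb, ma.shape)
    denom = va + vb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (ma - mb) / np.sqrt(np.where(denom > 0, denom, 1.0)), 0.0)
        dfree = np.where(
            denom > 0,
            denom**2 / (va**2 / (na - 1) + vb**2 / (nb - 1) + 1e-300),
            float(na + nb - 2),
        )
    p = np.where(denom > 0, 2.0 * stats.t.sf(np.abs(t), dfree), 1.0)
    return t, dfree, p


def significant_channels(results: dict[TaskLabel, pd.DataFrame],
                         task: TaskLabel) -> list[int]:
    """Channels flagged (BH-rejected with score above baseline) for a task."""
    res = results[task]
    mask = res["rejected"] & (res["t"] > 0)
    return sorted(res.index[mask].tolist())
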