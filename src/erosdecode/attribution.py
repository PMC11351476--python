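"""DeepLIFT (Rescale rule) feature attribution on the voxel x time input grid.

Relevance is propagated from the sigmoid output back to the model input
against an all-zero reference (the natural rest point of a baseline-corrected,
max-abs-scaled optical trial): positive values support a right-response
prediction, negative values a left one.  The attribution satisfies
summation-to-delta: the relevance values sum to f(trial) - f(reference).

Trials are grouped by response type and by prediction confidence — high when
the output probability is below 0.20 or above 0.80, low in between — and
group-averaged heatmaps are rendered over space-time or as spatial slices at
chosen post-response latencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import Network

_LEFT, _RIGHT = "left", "right"
_HIGH, _LOW = "high", "low"


@dataclass
class AttributionConfig:
    reference_input: np.ndarray | None = None   # default: all zeros
    low_conf: float = 0.20
    high_conf: float = 0.80
    slice_times_ms: tuple[float, ...] = (179.0, 410.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.low_conf < self.high_conf < 1.0):
            raise ValueError("need 0 < low_conf < high_conf < 1")


@dataclass
class AttributionMap:
    relevance: np.ndarray             # (C, T) signed
    prediction: float
    label: int | None = None
    group: tuple[str, str] | None = None   # (response, confidence)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.relevance)):
            raise ValueError("relevance contains non-finite values")


def deeplift_rescale(net: Network, trial: np.ndarray,
                     reference: np.ndarray | None = None,
                     label: int | None = None) -> AttributionMap:
    """Input relevance for one trial with respect to the right-response output.

    Linear layers propagate multipliers exactly; the ELU and sigmoid
    nonlinearities use the Rescale rule (delta-output over delta-input, with
    a gradient fallback where the input delta vanishes).  The returned map
    sums to f(trial) - f(reference).
    """
    from .nn import deeplift_rescale_pass

    trial = np.asarray(trial, dtype=float)
    if trial.shape != (net.cfg.C, net.cfg.T):
        raise ValueError(f"trial shape {trial.shape} does not match model "
                         f"({net.cfg.C}, {net.cfg.T})")
    if reference is None:
        reference = np.zeros_like(trial)
    reference = np.asarray(reference, dtype=float)
    if reference.shape != trial.shape:
        raise ValueError("reference shape must match the trial")
    x = trial[None, None, :, :]
    ref = reference[None, None, :, :]
    m, fx, fref = deeplift_rescale_pass(net.seq, x, ref)
    relevance = (m * (x - ref))[0, 0]
    return AttributionMap(relevance=relevance, prediction=float(fx.ravel()[0]),
                          label=label)


def completeness_residual(net: Network, trial: np.ndarray,
                          reference: np.ndarray | None = None) -> float:
    """|sum(relevance) - (f(trial) - f(reference))| — the summation-to-delta
    property the Rescale rule guarantees."""
    amap = deeplift_rescale(net, trial, reference)
    ref = np.zeros_like(trial) if reference is None else reference
    f_ref = float(net.predict_proba(np.asarray(ref, dtype=float))[0])
    return abs(float(amap.relevance.sum()) - (amap.prediction - f_ref))


def group_by_confidence(predictions: np.ndarray, labels: np.ndarray,
                        acfg: AttributionConfig | None = None
                        ) -> dict[tuple[str, str], np.ndarray]:
    """Partition trial indices into {left, right} x {high, low} confidence.

    High confidence: prediction < low_conf or > high_conf; the boundary
    values belong to the low-confidence group.  Every trial lands in exactly
    one of the four groups.
    """
    acfg = acfg or AttributionConfig()
    predictions = np.asarray(predictions, dtype=float)
    labels = np.asarray(labels).astype(int)
    if np.any((predictions < 0) | (predictions > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    high = (predictions < acfg.low_conf) | (predictions > acfg.high_conf)
    out: dict[tuple[str, str], np.ndarray] = {}
    for resp, lab in ((_LEFT, 0), (_RIGHT, 1)):
        for conf, mask in ((_HIGH, high), (_LOW, ~high)):
            out[(resp, conf)] = np.where((labels == lab) & mask)[0]
    return out


def mean_heatmap(maps: list[AttributionMap]) -> AttributionMap:
    """Element-wise mean of a non-empty group of attribution maps."""
    if not maps:
        raise ValueError("cannot average an empty attribution group")
    rel = np.mean([m.relevance for m in maps], axis=0)
    return AttributionMap(relevance=rel,
                          prediction=float(np.mean([m.prediction for m in maps])),
                          group=maps[0].group)


def time_slice(amap: AttributionMap, t_ms: float, fs: float,
               hemi_shape: tuple[int, int] = (3, 7)) -> np.ndarray:
    """Spatial relevance at one post-response latency, as a (2, rows, cols)
    two-hemisphere grid; nearest-sample lookup with the response at T // 2."""
    C, T = amap.relevance.shape
    idx = T // 2 + int(round(t_ms / 1000.0 * fs))
    if not (0 <= idx < T):
        raise ValueError(f"latency {t_ms} ms falls outside the epoch")
    nr, nc = hemi_shape
    if C != 2 * nr * nc:
        raise ValueError("hemisphere grid does not match the voxel count")
    return amap.relevance[:, idx].reshape(2, nr, nc)


def attribute_group_means(net: Network, trials: np.ndarray, labels: np.ndarray,
                          acfg: AttributionConfig | None = None
                          ) -> dict[tuple[str, str], AttributionMap]:
    """Per-trial DeepLIFT maps, grouped by response x confidence and averaged.

    Groups with no trials are omitted (an explicit empty result, never a NaN
    map)."""
    acfg = acfg or AttributionConfig()
    preds = net.predict_proba(trials)
    groups = group_by_confidence(preds, labels, acfg)
    ref = acfg.reference_input
    out: dict[tuple[str, str], AttributionMap] = {}
    for key, idx in groups.items():
        if len(idx) == 0:
            continue
        maps = [deeplift_rescale(net, trials[i], ref, label=int(labels[i]))
                for i in idx]
        for m in maps:
            m.group = key
        out[key] = mean_heatmap(maps)
    return out


def plot_heatmap(amap: AttributionMap, fs: float, out_path=None, ax=None):
    """Space x time relevance heatmap (diverging colormap, response at t=0)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    C, T = amap.relevance.shape
    t_ms = (np.arange(T) - T // 2) / fs * 1000.0
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    vmax = np.abs(amap.relevance).max() or 1.0
    im = ax.imshow(amap.relevance, aspect="auto", cmap="PiYG",
                   vmin=-vmax, vmax=vmax,
                   extent=[t_ms[0], t_ms[-1], C, 0])
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel("time after response (ms)")
    ax.set_ylabel("flattened voxel")
    fig.colorbar(im, ax=ax, label="relevance")
    if out_path is not None:
        fig.savefig(out_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
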