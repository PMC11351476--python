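"""Synthetic event-related optical signal (EROS) data generation.

Fast optical signals measured over motor cortex have a very low single-trial
SNR: a hand-lateralized event-related deflection of roughly the same order as
the background noise, buried under 1/f instrumental drift and a quasi-periodic
cardiac pulse artifact.  This module emulates that structure at the voxel
level so the full decoding pipeline (preprocessing -> CNN -> attribution) can
be exercised end to end without access to any recording hardware.

The simulated geometry is a two-hemisphere region of interest over motor
cortex, flattened to ``C`` voxels (default 42, split 21/21 across
hemispheres on a 3 x 7 grid each).  A response-locked effect template (two
Gaussian bumps at configurable post-response latencies) is planted at a
"hand" voxel in the right hemisphere, with a weaker mirror in the left
hemisphere; its sign flips with the responding hand.  Montage placement
quality is modelled by a viable-voxel mask and a channels-per-voxel count,
with per-voxel noise scaled by 1/sqrt(k) for k averaged channels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace

import h5py
import numpy as np

logger = logging.getLogger(__name__)

MONTAGE_LABELS = ("A", "B", "C", "D")
MODALITIES = ("phase", "intensity")
LABEL_NAMES = ("left", "right")  # label 0 = left, 1 = right


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Conditions of the simulated experiment.

    Amplitudes are in the (arbitrary) units of the optical signal before
    per-trial max-abs scaling; latencies are milliseconds after the response.
    """

    n_subjects: int = 12
    n_montages_per_subject: int = 4
    n_blocks: int = 20
    trials_per_block: int = 24
    manual_fraction: float = 0.5
    fs: float = 39.0625
    epoch_half_ms: float = 716.0           # epoch extent either side of response

    effect_amplitude: float = 0.5
    effect_latencies_ms: tuple[float, ...] = (179.0, 410.0)
    effect_sigma_ms: float = 50.0
    effect_voxel: tuple[int, int, int] = (1, 1, 3)   # (hemisphere, row, col)
    hemi_shape: tuple[int, int] = (3, 7)
    contra_ratio: float = 1.5              # right- vs left-hemisphere amplitude
    spatial_sigma_vox: float = 0.75

    noise_sd: float = 1.0
    pink_exponent: float = 1.0
    pink_fraction: float = 0.5
    pulse_freq: float = 1.2
    pulse_amplitude: float = 0.3
    intensity_noise_factor: float = 1.5    # extra low-frequency noise on DC intensity
    intensity_effect_factor: float = 0.6

    voxel_dropout_range: tuple[float, float] = (0.10, 0.35)
    channels_per_voxel_range: tuple[int, int] = (1, 6)
    montage_jitter_ms: float = 0.0         # SD of per-montage effect-latency offset

    iti_s: float = 4.0                     # event spacing in continuous blocks
    margin_s: float = 1.5                  # silent margin at block edges
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived geometry ---------------------------------------------------
    @property
    def n_voxels(self) -> int:
        return 2 * self.hemi_shape[0] * self.hemi_shape[1]

    @property
    def n_epoch_samples(self) -> int:
        return 2 * int(round(self.epoch_half_ms / 1000.0 * self.fs))

    @property
    def manual_trials_per_block(self) -> int:
        return int(round(self.trials_per_block * self.manual_fraction))

    def voxel_index(self, hemi: int, row: int, col: int) -> int:
        nr, nc = self.hemi_shape
        if not (0 <= hemi < 2 and 0 <= row < nr and 0 <= col < nc):
            raise ValueError(f"voxel ({hemi},{row},{col}) outside 2x{nr}x{nc} grid")
        return hemi * nr * nc + row * nc + col

    def validate(self) -> None:
        if min(self.n_subjects, self.n_montages_per_subject, self.n_blocks,
               self.trials_per_block) < 1:
            raise ValueError("all counts must be positive")
        if self.n_montages_per_subject > len(MONTAGE_LABELS):
            raise ValueError("at most 4 montages (labels A-D) per subject")
        if not (0.0 < self.manual_fraction <= 1.0):
            raise ValueError("manual_fraction must lie in (0, 1]")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for lat in self.effect_latencies_ms:
            if not (-self.epoch_half_ms < lat < self.epoch_half_ms):
                raise ValueError(f"effect latency {lat} ms outside epoch window")
        lo, hi = self.voxel_dropout_range
        if not (0.0 <= lo <= hi < 1.0):
            raise ValueError("voxel_dropout_range must satisfy 0 <= lo <= hi < 1")
        lo, hi = self.channels_per_voxel_range
        if not (1 <= lo <= hi):
            raise ValueError("channels_per_voxel_range must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0 or self.pulse_amplitude < 0:
            raise ValueError("noise_sd and pulse_amplitude must be non-negative")
        if not (0.0 <= self.pink_fraction <= 1.0):
            raise ValueError("pink_fraction must lie in [0, 1]")


@dataclass
class MontageSpec:
    """Placement quality of one recording montage.

    ``viable_voxel_mask`` marks region-of-interest voxels reached by at least
    one quality-passing channel; ``channels_per_voxel`` is zero exactly where
    the mask is false.  ``spatial_offset_ms`` shifts the effect latencies for
    this montage, modelling imperfect inter-montage alignment.
    """

    montage_id: str
    viable_voxel_mask: np.ndarray      # (C,) bool
    channels_per_voxel: np.ndarray     # (C,) int
    spatial_offset_ms: float = 0.0

    def __post_init__(self) -> None:
        self.viable_voxel_mask = np.asarray(self.viable_voxel_mask, dtype=bool)
        self.channels_per_voxel = np.asarray(self.channels_per_voxel, dtype=int)
        if self.channels_per_voxel.shape != self.viable_voxel_mask.shape:
            raise ValueError("mask and channel counts must have the same shape")
        if np.any(self.channels_per_voxel < 0):
            raise ValueError("channel counts must be non-negative")
        if np.any((self.channels_per_voxel > 0) != self.viable_voxel_mask):
            raise ValueError("channels_per_voxel must be 0 exactly off the viable mask")

    @property
    def viable_count(self) -> int:
        return int(self.viable_voxel_mask.sum())

    def viable_count_hemi(self, hemi: int, hemi_shape: tuple[int, int]) -> int:
        n = hemi_shape[0] * hemi_shape[1]
        return int(self.viable_voxel_mask[hemi * n:(hemi + 1) * n].sum())

    @property
    def mean_channels_per_viable_voxel(self) -> float:
        if self.viable_count == 0:
            return 0.0
        return float(self.channels_per_voxel[self.viable_voxel_mask].mean())


@dataclass
class BlockRecording:
    """One continuous multi-voxel recording block with response events."""

    data: np.ndarray          # (C, n_samples)
    events: np.ndarray        # (n_events,) sample index of each response
    labels: np.ndarray        # (n_events,) 0 = left, 1 = right
    block_index: int
    modality: str
    fs: float


@dataclass
class TrialSet:
    """Labeled single-trial tensors: the pipeline's central currency."""

    data: np.ndarray          # (n_trials, C, T)
    labels: np.ndarray        # (n_trials,) 0 = left, 1 = right
    blocks: np.ndarray        # (n_trials,) recording-block index
    modality: str
    subject_id: int
    montage_id: str
    fs: float
    montage_spec: MontageSpec | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.data) or len(self.blocks) != len(self.data):
            raise ValueError("labels/blocks length must equal trial count")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial data contain non-finite values")

    @property
    def n_trials(self) -> int:
        return len(self.data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]


# ---------------------------------------------------------------------------
# random-stream plumbing: every (seed, subject, montage, modality) combination
# maps to its own independent, reproducible generator
# ---------------------------------------------------------------------------

def _rng(cfg: SimConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed) & 0x7FFFFFFF, *keys]))


def _montage_index(montage_id: str) -> int:
    try:
        return MONTAGE_LABELS.index(montage_id)
    except ValueError:
        raise ValueError(f"unknown montage id {montage_id!r}; expected one of {MONTAGE_LABELS}")


# ---------------------------------------------------------------------------
# montage specification
# ---------------------------------------------------------------------------

def make_montage_spec(cfg: SimConfig, montage_id: str,
                      rng: np.random.Generator | None = None) -> MontageSpec:
    """Draw a montage quality structure from the configured ranges.

    Deterministic given ``(cfg.seed, montage_id)`` when no generator is
    passed; callers that need per-subject variation pass their own stream.
    """
    m_idx = _montage_index(montage_id)
    if rng is None:
        rng = _rng(cfg, 101, m_idx)
    C = cfg.n_voxels
    dropout = rng.uniform(*cfg.voxel_dropout_range)
    viable = rng.random(C) >= dropout
    if not viable.any():
        raise ValueError("voxel dropout produced zero viable voxels")
    lo, hi = cfg.channels_per_voxel_range
    counts = np.where(viable, rng.integers(lo, hi + 1, size=C), 0)
    offset = float(rng.normal(0.0, cfg.montage_jitter_ms)) if cfg.montage_jitter_ms > 0 else 0.0
    return MontageSpec(montage_id, viable, counts, offset)


# ---------------------------------------------------------------------------
# deterministic effect template
# ---------------------------------------------------------------------------

def _spatial_profile(cfg: SimConfig) -> np.ndarray:
    """Per-voxel effect amplitude: Gaussian falloff around the effect voxel
    and its left-hemisphere mirror, right hemisphere stronger by contra_ratio."""
    nr, nc = cfg.hemi_shape
    e_hemi, e_row, e_col = cfg.effect_voxel
    prof = np.zeros(cfg.n_voxels)
    for hemi in range(2):
        amp = cfg.effect_amplitude if hemi == e_hemi else cfg.effect_amplitude / cfg.contra_ratio
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        d2 = (rows - e_row) ** 2 + (cols - e_col) ** 2
        g = amp * np.exp(-d2 / (2.0 * cfg.spatial_sigma_vox ** 2))
        n = nr * nc
        prof[hemi * n:(hemi + 1) * n] = g.ravel()
    return prof


def _temporal_bumps(t_ms: np.ndarray, cfg: SimConfig, offset_ms: float = 0.0) -> np.ndarray:
    out = np.zeros_like(t_ms, dtype=float)
    for lat in cfg.effect_latencies_ms:
        out += np.exp(-((t_ms - (lat + offset_ms)) ** 2) / (2.0 * cfg.effect_sigma_ms ** 2))
    return out


def trial_template(label: int | str, mspec: MontageSpec, cfg: SimConfig,
                   modality: str = "phase") -> np.ndarray:
    """Noise-free single-trial template, (C, T).

    The sign of the planted deflection flips with the responding hand
    (left -> negative, right -> positive); non-viable voxels carry no signal.
    """
    label = _label_code(label)
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    T = cfg.n_epoch_samples
    t_ms = (np.arange(T) - T // 2) / cfg.fs * 1000.0
    temporal = _temporal_bumps(t_ms, cfg, mspec.spatial_offset_ms)
    spatial = _spatial_profile(cfg) * mspec.viable_voxel_mask
    sign = 1.0 if label == 1 else -1.0
    scale = cfg.intensity_effect_factor if modality == "intensity" else 1.0
    return sign * scale * np.outer(spatial, temporal)


def _label_code(label: int | str) -> int:
    if isinstance(label, str):
        if label not in LABEL_NAMES:
            raise ValueError(f"unknown label {label!r}; expected 'left' or 'right'")
        return LABEL_NAMES.index(label)
    if label not in (0, 1):
        raise ValueError("label must be 0 (left) or 1 (right)")
    return int(label)


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def pink_noise(n: int, exponent: float, rng: np.random.Generator,
               size: int = 1) -> np.ndarray:
    """(size, n) spectrally shaped 1/f^exponent noise, unit sample SD."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    weight = np.zeros_like(f)
    weight[1:] = f[1:] ** (-exponent / 2.0)
    shaped = np.fft.irfft(spec * weight, n=n, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


def _voxel_noise(cfg: SimConfig, mspec: MontageSpec, modality: str, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """(C, n) mixed pink + white noise, per-voxel SD ~ noise_sd / sqrt(k)."""
    C = cfg.n_voxels
    pf = cfg.pink_fraction
    total_sd = cfg.noise_sd
    if modality == "intensity":
        # DC intensity is dominated by low-frequency contamination
        total_sd *= cfg.intensity_noise_factor
        pf = min(1.0, pf * 1.5)
    if total_sd == 0:
        return np.zeros((C, n))
    pink = pink_noise(n, cfg.pink_exponent, rng, size=C)
    white = rng.standard_normal((C, n))
    noise = total_sd * (np.sqrt(pf) * pink + np.sqrt(1.0 - pf) * white)
    k = np.maximum(mspec.channels_per_voxel, 1)
    return noise / np.sqrt(k)[:, None]


# ---------------------------------------------------------------------------
# trial- and block-level generation
# ---------------------------------------------------------------------------

def generate_trial(label: int | str, mspec: MontageSpec, cfg: SimConfig,
                   modality: str, rng: np.random.Generator,
                   pulse_phase: float | None = None) -> np.ndarray:
    """One epoched synthetic trial (C, T): template + noise + pulse artifact."""
    label = _label_code(label)
    trial = trial_template(label, mspec, cfg, modality)
    T = cfg.n_epoch_samples
    trial = trial + _voxel_noise(cfg, mspec, modality, T, rng)
    if cfg.pulse_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi) if pulse_phase is None else pulse_phase
        t = np.arange(T) / cfg.fs
        trial = trial + cfg.pulse_amplitude * np.sin(2 * np.pi * cfg.pulse_freq * t + phase)
    return trial


def generate_block(cfg: SimConfig, mspec: MontageSpec, modality: str,
                   labels: np.ndarray, block_index: int,
                   rng: np.random.Generator) -> BlockRecording:
    """Continuous block recording with one response event per labeled trial."""
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    labels = np.asarray(labels, dtype=int)
    n_ev = len(labels)
    n = int(round((2 * cfg.margin_s + n_ev * cfg.iti_s) * cfg.fs))
    base = cfg.margin_s + cfg.iti_s / 2.0 + cfg.iti_s * np.arange(n_ev)
    jitter = rng.uniform(-0.2, 0.2, size=n_ev)
    events = np.round((base + jitter) * cfg.fs).astype(int)

    data = _voxel_noise(cfg, mspec, modality, n, rng)
    if cfg.pulse_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / cfg.fs
        data = data + cfg.pulse_amplitude * np.sin(2 * np.pi * cfg.pulse_freq * t + phase)

    # plant the response-locked effect at each event
    spatial = _spatial_profile(cfg) * mspec.viable_voxel_mask
    scale = cfg.intensity_effect_factor if modality == "intensity" else 1.0
    half = cfg.n_epoch_samples // 2
    rel = np.arange(-half, half + 1)
    t_ms = rel / cfg.fs * 1000.0
    temporal = _temporal_bumps(t_ms, cfg, mspec.spatial_offset_ms)
    for e, lab in zip(events, labels):
        sign = 1.0 if lab == 1 else -1.0
        lo, hi = e - half, e + half + 1
        data[:, lo:hi] += sign * scale * np.outer(spatial, temporal)
    return BlockRecording(data.astype(np.float32), events, labels,
                          block_index, modality, cfg.fs)


def _block_labels(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Balanced left/right assignment within a block (|#L - #R| <= 1)."""
    k = cfg.manual_trials_per_block
    labels = np.arange(k) % 2
    rng.shuffle(labels)
    return labels


def generate_subject_blocks(cfg: SimConfig, subject_id: int
                            ) -> dict[str, dict[str, list[BlockRecording]]]:
    """Continuous raw recordings for one subject: montage -> modality -> blocks.

    Both modalities of a montage share event times and labels (they are
    co-recorded) but carry independent noise.
    """
    out: dict[str, dict[str, list[BlockRecording]]] = {}
    for m_idx in range(cfg.n_montages_per_subject):
        montage_id = MONTAGE_LABELS[m_idx]
        mspec = make_montage_spec(cfg, montage_id, _rng(cfg, int(subject_id), m_idx, 0))
        label_rng = _rng(cfg, int(subject_id), m_idx, 1)
        block_labels = [_block_labels(cfg, label_rng) for _ in range(cfg.n_blocks)]
        out[montage_id] = {}
        for mod_idx, modality in enumerate(MODALITIES):
            rng = _rng(cfg, int(subject_id), m_idx, 2 + mod_idx)
            blocks = [generate_block(cfg, mspec, modality, block_labels[b], b, rng)
                      for b in range(cfg.n_blocks)]
            out[montage_id][modality] = blocks
        out[montage_id]["_spec"] = mspec  # type: ignore[assignment]
    return out


def generate_subject_dataset(cfg: SimConfig, subject_id: int,
                             pcfg=None) -> dict[str, dict[str, TrialSet]]:
    """Model-ready trial sets for one subject: montage -> modality -> TrialSet.

    Runs the continuous synthetic blocks through the standard preprocessing
    chain (per-block centering, band-pass, epoching, baseline correction,
    crop, per-trial max-abs scaling).  At the defaults (20 blocks x 24 trials,
    half manual) this yields 240 trials per montage and modality.
    """
    from . import preprocessing as pp  # deferred: preprocessing is downstream

    if pcfg is None:
        pcfg = pp.PreprocessConfig(fs=cfg.fs)
    raw = generate_subject_blocks(cfg, subject_id)
    out: dict[str, dict[str, TrialSet]] = {}
    for montage_id, per_mod in raw.items():
        mspec: MontageSpec = per_mod.pop("_spec")  # type: ignore[assignment]
        out[montage_id] = {}
        for modality, blocks in per_mod.items():
            epochs, labels, block_ix = [], [], []
            for blk in blocks:
                for ep in pp.preprocess_block(blk.data, blk.events, pcfg,
                                              labels=blk.labels,
                                              block_index=blk.block_index,
                                              modality=modality):
                    epochs.append(pp.scale_maxabs(ep.data))
                    labels.append(ep.label)
                    block_ix.append(ep.block_index)
            out[montage_id][modality] = TrialSet(
                data=np.stack(epochs).astype(np.float32),
                labels=np.asarray(labels, dtype=int),
                blocks=np.asarray(block_ix, dtype=int),
                modality=modality, subject_id=int(subject_id),
                montage_id=montage_id, fs=cfg.fs, montage_spec=mspec)
    return out


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def _cfg_to_json(cfg: SimConfig) -> str:
    return json.dumps(asdict(cfg))


def save_trialsets(path, datasets: dict[int, dict[str, dict[str, TrialSet]]],
                   cfg: SimConfig) -> None:
    """Write /s{subject}/{montage}/{modality}/{trials,labels,blocks} plus
    montage quality arrays and the generating config as attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cfg.fs
        f.attrs["seed"] = cfg.seed
        f.attrs["config"] = _cfg_to_json(cfg)
        for subject_id, per_montage in datasets.items():
            gs = f.create_group(f"s{subject_id}")
            for montage_id, per_mod in per_montage.items():
                gm = gs.create_group(montage_id)
                any_ts = next(iter(per_mod.values()))
                if any_ts.montage_spec is not None:
                    gm.create_dataset("viable_voxel_mask",
                                      data=any_ts.montage_spec.viable_voxel_mask)
                    gm.create_dataset("channels_per_voxel",
                                      data=any_ts.montage_spec.channels_per_voxel)
                    gm.attrs["spatial_offset_ms"] = any_ts.montage_spec.spatial_offset_ms
                for modality, ts in per_mod.items():
                    gd = gm.create_group(modality)
                    gd.create_dataset("trials", data=ts.data)
                    gd.create_dataset("labels", data=ts.labels)
                    gd.create_dataset("blocks", data=ts.blocks)


def load_trialsets(path) -> tuple[dict[int, dict[str, dict[str, TrialSet]]], SimConfig]:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        for key in ("effect_latencies_ms", "effect_voxel", "hemi_shape",
                    "voxel_dropout_range", "channels_per_voxel_range"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = SimConfig(**cfg_d)
        out: dict[int, dict[str, dict[str, TrialSet]]] = {}
        for sname, gs in f.items():
            subject_id = int(sname[1:])
            out[subject_id] = {}
            for montage_id, gm in gs.items():
                mspec = None
                if "viable_voxel_mask" in gm:
                    mspec = MontageSpec(
                        montage_id, gm["viable_voxel_mask"][:],
                        gm["channels_per_voxel"][:],
                        float(gm.attrs.get("spatial_offset_ms", 0.0)))
                out[subject_id][montage_id] = {}
                for modality in MODALITIES:
                    if modality not in gm:
                        continue
                    gd = gm[modality]
                    out[subject_id][montage_id][modality] = TrialSet(
                        data=gd["trials"][:], labels=gd["labels"][:],
                        blocks=gd["blocks"][:], modality=modality,
                        subject_id=subject_id, montage_id=montage_id,
                        fs=float(f.attrs["fs"]), montage_spec=mspec)
    return out, cfg


def save_blocks(path, per_subject: dict[int, dict[str, dict[str, list[BlockRecording]]]],
                cfg: SimConfig) -> None:
    """Raw continuous-block layout (pre-preprocessing)."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = cfg.fs
        f.attrs["seed"] = cfg.seed
        f.attrs["config"] = _cfg_to_json(cfg)
        for subject_id, per_montage in per_subject.items():
            gs = f.create_group(f"s{subject_id}")
            for montage_id, per_mod in per_montage.items():
                gm = gs.create_group(montage_id)
                mspec = per_mod.get("_spec")
                if isinstance(mspec, MontageSpec):
                    gm.create_dataset("viable_voxel_mask", data=mspec.viable_voxel_mask)
                    gm.create_dataset("channels_per_voxel", data=mspec.channels_per_voxel)
                    gm.attrs["spatial_offset_ms"] = mspec.spatial_offset_ms
                for modality in MODALITIES:
                    blocks = per_mod.get(modality)
                    if not blocks:
                        continue
                    gd = gm.create_group(modality)
                    for blk in blocks:
                        gb = gd.create_group(f"block{blk.block_index}")
                        gb.create_dataset("data", data=blk.data)
                        gb.create_dataset("events", data=blk.events)
                        gb.create_dataset("labels", data=blk.labels)


def load_blocks(path) -> tuple[dict[int, dict[str, dict[str, list[BlockRecording]]]], SimConfig]:
    with h5py.File(path, "r") as f:
        cfg_d = json.loads(f.attrs["config"])
        for key in ("effect_latencies_ms", "effect_voxel", "hemi_shape",
                    "voxel_dropout_range", "channels_per_voxel_range"):
            cfg_d[key] = tuple(cfg_d[key])
        cfg = SimConfig(**cfg_d)
        out: dict[int, dict[str, dict[str, list[BlockRecording]]]] = {}
        for sname, gs in f.items():
            subject_id = int(sname[1:])
            out[subject_id] = {}
            for montage_id, gm in gs.items():
                per_mod: dict = {}
                if "viable_voxel_mask" in gm:
                    per_mod["_spec"] = MontageSpec(
                        montage_id, gm["viable_voxel_mask"][:],
                        gm["channels_per_voxel"][:],
                        float(gm.attrs.get("spatial_offset_ms", 0.0)))
                for modality in MODALITIES:
                    if modality not in gm:
                        continue
                    blocks = []
                    gd = gm[modality]
                    for bname in sorted(gd, key=lambda s: int(s[5:])):
                        gb = gd[bname]
                        blocks.append(BlockRecording(
                            gb["data"][:], gb["events"][:], gb["labels"][:],
                            int(bname[5:]), modality, float(f.attrs["fs"])))
                    per_mod[modality] = blocks
                out[subject_id][montage_id] = per_mod
    return out, cfg
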