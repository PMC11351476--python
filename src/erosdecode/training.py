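"""Model fitting, data splitting, hyperparameter search, training paradigms.

Splits: a 20% held-out test set stratified by response label (and by montage
when trials from several montages are pooled), with the remaining 80% divided
into 5 stratified cross-validation folds.  Models train for up to 300 passes
minimizing binary cross-entropy, with early stopping on a validation metric,
best-weight restoration, and max-norm projection after every optimizer step.

Three subject-specific paradigms:
  * montage-specific — train and test within one montage; across montages the
    reporting montage is chosen by validation accuracy alone;
  * cross-montage — one model on the pooled montages with montage-and-label
    stratified splits;
  * pre-train + fine-tune — warm-start from the other montages, then
    fine-tune every weight on the target montage's training split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

from . import nn
from .model import ModelConfig, Network, DualNetwork, constrain_weights
from .evaluation import Metrics, accuracy_score, auroc

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    max_epochs: int = 300
    optimizer_name: str = "adam"          # "adam" | "sgd"
    learning_rate: float = 1e-3
    weight_decay: float = 1e-5
    early_stop_metric: str = "val_accuracy"   # | "val_auroc" | "val_loss"
    patience: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if 1 < self.max_epochs <= self.patience:
            self.patience = self.max_epochs - 1
        if self.early_stop_metric not in ("val_accuracy", "val_auroc", "val_loss"):
            raise ValueError(f"unknown early-stop metric {self.early_stop_metric!r}")


@dataclass
class SplitSpec:
    test_indices: np.ndarray
    cv_folds: list[tuple[np.ndarray, np.ndarray]]   # (train, val) over the 80%

    def validate_disjoint(self) -> None:
        test = set(self.test_indices.tolist())
        covered: list[int] = []
        for tr, va in self.cv_folds:
            if test & set(tr.tolist()) or test & set(va.tolist()):
                raise ValueError("test set leaks into a CV fold")
            if set(tr.tolist()) & set(va.tolist()):
                raise ValueError("train/val overlap within a fold")
            covered.extend(va.tolist())
        if sorted(covered) != sorted(set(covered)):
            raise ValueError("validation folds overlap")


@dataclass
class SearchSpace:
    """Random-search candidate sets / distributions."""

    f1: tuple[int, ...] = (4, 8, 16)
    d: tuple[int, ...] = (1, 2, 4)
    f2: tuple[int, ...] = (8, 16, 32)
    optimizer: tuple[str, ...] = ("adam", "sgd")
    lr_range: tuple[float, float] = (1e-4, 1e-2)        # log-uniform
    weight_decay_range: tuple[float, float] = (1e-6, 1e-3)  # log-uniform
    early_stop_metric: tuple[str, ...] = ("val_accuracy", "val_auroc", "val_loss")
    n_configs: int = 50
    n_iterations: int = 3

    def __post_init__(self) -> None:
        if self.n_configs < 1 or self.n_iterations < 1:
            raise ValueError("n_configs and n_iterations must be >= 1")

    def sample(self, rng: np.random.Generator, base_model: ModelConfig,
               base_train: TrainConfig) -> list[tuple[ModelConfig, TrainConfig]]:
        out = []
        for _ in range(self.n_configs):
            mcfg = replace(base_model,
                           F1=int(rng.choice(self.f1)),
                           D=int(rng.choice(self.d)),
                           F2=int(rng.choice(self.f2)))
            lr = float(np.exp(rng.uniform(np.log(self.lr_range[0]),
                                          np.log(self.lr_range[1]))))
            wd = float(np.exp(rng.uniform(np.log(self.weight_decay_range[0]),
                                          np.log(self.weight_decay_range[1]))))
            tcfg = replace(base_train,
                           optimizer_name=str(rng.choice(self.optimizer)),
                           learning_rate=lr, weight_decay=wd,
                           early_stop_metric=str(rng.choice(self.early_stop_metric)))
            out.append((mcfg, tcfg))
        return out


@dataclass
class TrainRun:
    """One fitted model with its provenance and metric traces."""

    config: TrainConfig
    fold: int
    seed: int
    train_loss: list[float]
    val_loss: list[float]
    val_accuracy: list[float]
    val_auroc: list[float]
    best_epoch: int
    stopped_epoch: int
    best_val_metric: float
    test_metrics: Metrics | None = None

    @property
    def best_val_accuracy(self) -> float:
        return self.val_accuracy[self.best_epoch]


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def make_splits(labels: np.ndarray, seed: int,
                montages: np.ndarray | None = None,
                n_folds: int = 5, test_fraction: float = 0.2) -> SplitSpec:
    """Stratified 20% test split plus stratified k-fold partition of the rest.

    Stratification is by label, and jointly by (label, montage) when a
    montage vector is given, keeping montage proportions within +/-1 trial.
    Deterministic given the seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both response classes must be present")
    if counts.min() < n_folds:
        raise ValueError("too few trials per class for the requested folds")
    strata = labels.astype(str)
    if montages is not None:
        strata = np.char.add(strata, np.asarray(montages).astype(str))
    idx = np.arange(len(labels))
    pool, test = train_test_split(idx, test_size=test_fraction,
                                  stratify=strata, random_state=int(seed) % (2**32))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                          random_state=(int(seed) + 1) % (2**32))
    folds = [(pool[tr], pool[va]) for tr, va in skf.split(pool, strata[pool])]
    spec = SplitSpec(np.sort(test), folds)
    spec.validate_disjoint()
    return spec


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _subset(X, idx):
    if isinstance(X, tuple):
        return tuple(x[idx] for x in X)
    return X[idx]


def _n_of(X) -> int:
    return len(X[0]) if isinstance(X, tuple) else len(X)


def _val_metrics(net, X, y) -> tuple[float, float, float]:
    prob = net.predict_proba(X)
    z = np.clip(prob, 1e-12, 1 - 1e-12)
    loss = float(np.mean(-(y * np.log(z) + (1 - y) * np.log(1 - z))))
    acc = accuracy_score(prob > net.cfg.decision_threshold, y)
    try:
        auc = auroc(prob, y)
    except ValueError:
        auc = np.nan
    return loss, acc, auc


def fit(net: Network | DualNetwork, X_train, y_train, X_val, y_val,
        tcfg: TrainConfig, fold: int = 0) -> TrainRun:
    """Train with BCE + early stopping; restores the best-epoch weights.

    Max-norm constraints are projected after every optimizer step.  The
    validation metric trace and the train-loss trace are recorded in full.
    """
    y_train = np.asarray(y_train, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    rng = np.random.default_rng(np.random.SeedSequence([int(tcfg.seed) & 0x7FFFFFFF, fold, 0xF1]))
    opt = nn.make_optimizer(tcfg.optimizer_name, tcfg.learning_rate, tcfg.weight_decay)
    params = net.params()
    constrain_weights(net)

    sign = -1.0 if tcfg.early_stop_metric == "val_loss" else 1.0
    best_metric = -np.inf
    best_epoch = 0
    best_weights = net.get_weights()
    tr_loss_trace: list[float] = []
    va_loss_trace: list[float] = []
    va_acc_trace: list[float] = []
    va_auc_trace: list[float] = []

    n = _n_of(X_train)
    stopped = tcfg.max_epochs - 1
    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, tcfg.batch_size):
            bidx = order[start:start + tcfg.batch_size]
            z = net.forward_logits(_subset(X_train, bidx), training=True)
            loss, gz = nn.bce_with_logits(z, y_train[bidx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={tcfg.learning_rate}, optimizer={tcfg.optimizer_name}")
            epoch_loss += loss * len(bidx)
            opt.zero_grad(params)
            net.backward(gz, from_logits=True)
            opt.step(params)
            constrain_weights(net)
        tr_loss_trace.append(epoch_loss / n)

        vl, va, vauc = _val_metrics(net, X_val, y_val)
        va_loss_trace.append(vl)
        va_acc_trace.append(va)
        va_auc_trace.append(vauc)
        metric = {"val_accuracy": va, "val_auroc": vauc, "val_loss": vl}[tcfg.early_stop_metric]
        if sign * metric > best_metric:
            best_metric = sign * metric
            best_epoch = epoch
            best_weights = net.get_weights()
        if epoch - best_epoch >= tcfg.patience:
            stopped = epoch
            break
        stopped = epoch

    net.set_weights(best_weights)
    return TrainRun(config=tcfg, fold=fold, seed=tcfg.seed,
                    train_loss=tr_loss_trace, val_loss=va_loss_trace,
                    val_accuracy=va_acc_trace, val_auroc=va_auc_trace,
                    best_epoch=best_epoch, stopped_epoch=stopped,
                    best_val_metric=sign * best_metric)


def evaluate_on(net, X, y) -> Metrics:
    prob = net.predict_proba(X)
    pred = prob > net.cfg.decision_threshold
    try:
        auc = auroc(prob, y)
    except ValueError:
        auc = np.nan
    return Metrics(accuracy=accuracy_score(pred, y), auroc=auc, n_test=_n_of(X),
                   predictions=prob, labels=np.asarray(y))


# ---------------------------------------------------------------------------
# random hyperparameter search
# ---------------------------------------------------------------------------

def random_search(space: SearchSpace, X, y, splits: SplitSpec,
                  base_model: ModelConfig, base_train: TrainConfig,
                  seed: int = 0, search_folds: tuple[int, ...] = (0,),
                  build=Network) -> tuple[int, list[dict]]:
    """Sample configurations, train each with several random initializations,
    and select by mean validation metric across iterations (ties broken by
    lower config index).  Returns (best config index, full runs table)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5E]))
    candidates = space.sample(rng, base_model, base_train)
    runs: list[dict] = []
    for ci, (mcfg, tcfg) in enumerate(candidates):
        for it in range(space.n_iterations):
            vals = []
            for f in search_folds:
                tr, va = splits.cv_folds[f]
                init_seed = int(rng.integers(0, 2**31 - 1))
                net = build(mcfg, seed=init_seed)
                run = fit(net, _subset(X, tr), y[tr], _subset(X, va), y[va],
                          replace(tcfg, seed=init_seed), fold=f)
                vals.append(run.best_val_accuracy)
            runs.append({"config_index": ci, "iteration": it,
                         "model_config": mcfg, "train_config": tcfg,
                         "val_accuracy": float(np.mean(vals))})
    means = np.full(len(candidates), -np.inf)
    for ci in range(len(candidates)):
        vals = [r["val_accuracy"] for r in runs if r["config_index"] == ci]
        means[ci] = float(np.mean(vals))
    best = int(np.argmax(means))   # argmax takes the lowest index on ties
    return best, runs


def select_best_config(runs: list[dict]) -> int:
    """Brute-force argmax over a runs table (audit companion to random_search)."""
    import collections
    acc = collections.defaultdict(list)
    for r in runs:
        acc[r["config_index"]].append(r["val_accuracy"])
    best, best_val = None, -np.inf
    for ci in sorted(acc):
        v = float(np.mean(acc[ci]))
        if v > best_val:
            best, best_val = ci, v
    return best


# ---------------------------------------------------------------------------
# training paradigms
# ---------------------------------------------------------------------------

@dataclass
class MontageResult:
    montage_id: str
    splits: SplitSpec
    fold_runs: list[TrainRun]
    fold_test_metrics: list[Metrics]
    mean_val_accuracy: float


def _fit_folds(X, y, splits: SplitSpec, mcfg: ModelConfig, tcfg: TrainConfig,
               seed: int, build=Network, init_weights=None,
               montage_id: str = "") -> MontageResult:
    fold_runs, fold_metrics = [], []
    test = splits.test_indices
    for f, (tr, va) in enumerate(splits.cv_folds):
        net = build(mcfg, seed=int(seed) + 1000 * f)
        if init_weights is not None:
            net.set_weights(init_weights)
        run = fit(net, _subset(X, tr), y[tr], _subset(X, va), y[va],
                  replace(tcfg, seed=int(seed) + 1000 * f), fold=f)
        run.test_metrics = evaluate_on(net, _subset(X, test), y[test])
        fold_runs.append(run)
        fold_metrics.append(run.test_metrics)
    mean_val = float(np.mean([r.best_val_accuracy for r in fold_runs]))
    return MontageResult(montage_id, splits, fold_runs, fold_metrics, mean_val)


def run_montage_specific(subject_data: dict, mcfg: ModelConfig, tcfg: TrainConfig,
                         seed: int = 0, modality: str = "phase",
                         search: SearchSpace | None = None) -> dict:
    """Train one model per montage; report the montage with the highest mean
    validation accuracy (test metrics never influence the choice)."""
    per_montage: dict[str, MontageResult] = {}
    for montage_id in sorted(subject_data):
        ts = subject_data[montage_id][modality]
        splits = make_splits(ts.labels, seed)
        m, t = mcfg, tcfg
        if search is not None:
            best, runs = random_search(search, ts.data, ts.labels, splits,
                                       mcfg, tcfg, seed=seed)
            m = runs[[r["config_index"] for r in runs].index(best)]["model_config"]
            t = runs[[r["config_index"] for r in runs].index(best)]["train_config"]
        per_montage[montage_id] = _fit_folds(ts.data, ts.labels, splits, m, t,
                                             seed, montage_id=montage_id)
    best_montage = max(sorted(per_montage),
                       key=lambda k: per_montage[k].mean_val_accuracy)
    return {"per_montage": per_montage, "best_montage": best_montage,
            "best_result": per_montage[best_montage]}


def _pool_montages(subject_data: dict, modality: str, exclude: str | None = None):
    Xs, ys, ms = [], [], []
    for montage_id in sorted(subject_data):
        if montage_id == exclude:
            continue
        ts = subject_data[montage_id][modality]
        Xs.append(ts.data)
        ys.append(ts.labels)
        ms.append(np.full(len(ts.labels), montage_id))
    if not Xs:
        raise ValueError("no montages available after exclusion")
    return np.concatenate(Xs), np.concatenate(ys), np.concatenate(ms)


def run_cross_montage(subject_data: dict, mcfg: ModelConfig, tcfg: TrainConfig,
                      seed: int = 0, modality: str = "phase") -> MontageResult:
    """Single model on pooled montages with montage-and-label stratified splits."""
    if len(subject_data) < 2:
        raise ValueError("cross-montage training needs at least 2 montages")
    X, y, m = _pool_montages(subject_data, modality)
    splits = make_splits(y, seed, montages=m)
    res = _fit_folds(X, y, splits, mcfg, tcfg, seed, montage_id="pooled")
    return res


def run_pretrain_finetune(subject_data: dict, target_montage: str,
                          mcfg: ModelConfig, tcfg: TrainConfig, seed: int = 0,
                          modality: str = "phase",
                          finetune_cfg: TrainConfig | None = None) -> dict:
    """Pre-train on the non-target montages, fine-tune every weight on the
    target montage's training split, evaluate on the target's held-out test."""
    others = [k for k in subject_data if k != target_montage]
    if not others:
        raise ValueError("pre-training requires at least one non-target montage")
    Xp, yp, mp = _pool_montages(subject_data, modality, exclude=target_montage)
    pre_splits = make_splits(yp, seed, montages=mp)
    tr, va = pre_splits.cv_folds[0]
    pre_net = Network(mcfg, seed=int(seed))
    pre_run = fit(pre_net, _subset(Xp, tr), yp[tr], _subset(Xp, va), yp[va],
                  replace(tcfg, seed=int(seed)), fold=0)
    init = pre_net.get_weights()

    ts = subject_data[target_montage][modality]
    splits = make_splits(ts.labels, seed)
    ft_cfg = finetune_cfg or tcfg
    if ft_cfg.max_epochs == 0:
        # degenerate case: evaluate the pre-trained model directly
        metrics = [evaluate_on(pre_net, ts.data[splits.test_indices],
                               ts.labels[splits.test_indices])
                   for _ in splits.cv_folds]
        result = MontageResult(target_montage, splits, [], metrics,
                               mean_val_accuracy=np.nan)
    else:
        result = _fit_folds(ts.data, ts.labels, splits, mcfg, ft_cfg, seed,
                            init_weights=init, montage_id=target_montage)
    return {"pretrain_run": pre_run, "pretrain_montages": sorted(others),
            "result": result}
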