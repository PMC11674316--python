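"""Multimodal brain-age model: assembly, training protocol, results.

The user-facing surface follows the familiar model/results pattern:
:class:`BrainAgeModel` is built from cohort data plus a
:class:`TrainConfig`; ``fit()`` runs the training protocol (MAE loss,
Adam with the stated learning rate and weight decay, best-on-validation
checkpoint selection, 80/10/10 split) and returns a
:class:`BrainAgeResults` carrying per-subject predictions, the brain-age
bias correction fitted on the training split, per-split metrics and a
``summary()`` table.

All randomness (split, weight init, shuffling, dropout) fans out
deterministically from ``TrainConfig.seed``, so a seeded end-to-end run
is reproducible in single-threaded mode.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import nn
from .nn.autograd import Tensor
from .extractors import (FEATURE_DIM, MEGEncoder, MEGEncoderConfig, SFCN,
                         SFCNConfig)
from .fusion import LowRankFusionLayer
from .evaluation import (apply_bias_correction, fit_bias_correction,
                         metrics_by_split, report_to_markdown)

__all__ = [
    "TrainConfig", "SplitAssignment", "TrainHistory", "split_dataset",
    "MultimodalNet", "build_network", "train_network", "predict_network",
    "save_checkpoint", "load_checkpoint", "predict_from_checkpoint",
    "BrainAgeModel", "BrainAgeResults", "MODALITY_ORDER",
]

MODALITY_ORDER = ("smri", "dti", "meg")
FUSION_KINDS = ("lowrank", "add", "concat", "none")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol parameters (defaults follow the full-scale protocol)."""

    learning_rate: float = 1e-4
    weight_decay: float = 1e-8
    batch_size: int = 12
    epochs: int = 300
    loss: str = "mae"
    seed: int = 0
    modalities: tuple = MODALITY_ORDER
    fusion: str = "lowrank"
    rank: int = 4
    drop_rate: float = 0.1
    d_out: int = FEATURE_DIM

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mae":
            raise ValueError(f"unsupported loss {self.loss!r}")
        mods = tuple(self.modalities)
        if not mods:
            raise ValueError("at least one modality is required")
        unknown = set(mods) - set(MODALITY_ORDER)
        if unknown:
            raise ValueError(f"unknown modalities {sorted(unknown)}")
        # canonical ordering for reproducibility
        object.__setattr__(self, "modalities",
                           tuple(m for m in MODALITY_ORDER if m in mods))
        if self.fusion not in FUSION_KINDS:
            raise ValueError(f"fusion must be one of {FUSION_KINDS}")
        if self.fusion == "none" and len(mods) != 1:
            raise ValueError("fusion 'none' requires exactly one modality")
        if self.fusion != "none" and len(mods) < 2:
            raise ValueError(f"fusion {self.fusion!r} needs >= 2 modalities")
        if self.fusion == "lowrank" and self.rank < 1:
            raise ValueError("rank must be >= 1")


@dataclass(frozen=True)
class SplitAssignment:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    @property
    def sizes(self) -> tuple:
        return (len(self.train), len(self.val), len(self.test))


def split_dataset(n: int, seed: int) -> SplitAssignment:
    """Random 80/10/10 split: sizes (floor(0.8n), floor(0.1n), remainder).

    For the 521-subject cohort this reproduces the 416/52/53 protocol split.
    """
    if n < 3:
        raise ValueError(f"cannot split fewer than 3 subjects, got {n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(0.8 * n))
    n_val = int(np.floor(0.1 * n))
    return SplitAssignment(train=np.sort(perm[:n_train]),
                           val=np.sort(perm[n_train:n_train + n_val]),
                           test=np.sort(perm[n_train + n_val:]))


@dataclass
class TrainHistory:
    train_loss: list = field(default_factory=list)   # years, per epoch
    val_mae: list = field(default_factory=list)      # years, per epoch
    best_epoch: int = -1
    checkpoint_path: str | None = None


class MultimodalNet(nn.Module):
    """Branches -> fusion -> linear head mapping to one scalar age."""

    def __init__(self, config: TrainConfig, sfcn_config: SFCNConfig,
                 meg_config: MEGEncoderConfig, n_bins: int,
                 rng: np.random.Generator,
                 share_structural_weights: bool = False):
        super().__init__()
        self.modalities = config.modalities
        self.fusion_kind = config.fusion
        self.n_bins = n_bins
        self.share_structural_weights = share_structural_weights

        if "smri" in self.modalities:
            self.branch_smri = SFCN(sfcn_config, rng)
        if "dti" in self.modalities:
            if share_structural_weights and "smri" in self.modalities:
                self.branch_dti = self.branch_smri
            else:
                self.branch_dti = SFCN(sfcn_config, rng)
        if "meg" in self.modalities:
            self.branch_meg = MEGEncoder(meg_config, n_bins, rng)

        M = len(self.modalities)
        if config.fusion == "lowrank":
            self.fusion_layer = LowRankFusionLayer(
                [FEATURE_DIM] * M, config.d_out, config.rank, rng,
                drop_rate=config.drop_rate)
            head_in = config.d_out
        elif config.fusion == "concat":
            head_in = FEATURE_DIM * M
        else:  # add / none
            head_in = FEATURE_DIM
        self.head = nn.Linear(head_in, 1, rng)

    def _branch(self, modality: str):
        return getattr(self, f"branch_{modality}")

    def features(self, batch: dict) -> list:
        feats = []
        for m in self.modalities:
            x = batch[m]
            if m in ("smri", "dti"):
                x = np.asarray(x, dtype=np.float32)
                if x.ndim == 4:
                    x = x[:, None]
            feats.append(self._branch(m)(x))
        return feats

    def forward(self, batch: dict) -> Tensor:
        feats = self.features(batch)
        if self.fusion_kind == "lowrank":
            fused = self.fusion_layer(feats)
        elif self.fusion_kind == "add":
            fused = feats[0]
            for f in feats[1:]:
                fused = fused + f
        elif self.fusion_kind == "concat":
            fused = nn.concatenate(feats, axis=1)
        else:
            fused = feats[0]
        return self.head(fused)


def build_network(config: TrainConfig,
                  sfcn_config: SFCNConfig | None = None,
                  meg_config: MEGEncoderConfig | None = None,
                  n_bins: int = 64,
                  init_seed: int | np.random.SeedSequence = 0,
                  share_structural_weights: bool = False) -> MultimodalNet:
    sfcn_config = sfcn_config or SFCNConfig()
    meg_config = meg_config or MEGEncoderConfig()
    rng = np.random.default_rng(init_seed)
    return MultimodalNet(config, sfcn_config, meg_config, n_bins, rng,
                         share_structural_weights)


def _mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    return (pred.reshape(-1) - Tensor(target.astype(np.float32))).abs().mean()


def predict_network(net: MultimodalNet, data: dict, indices=None,
                    batch_size: int = 12) -> np.ndarray:
    """Deterministic inference (dropout off, batch-norm frozen)."""
    n = len(next(iter(data.values())))
    indices = np.arange(n) if indices is None else np.asarray(indices)
    net.eval()
    out = np.empty(len(indices), dtype=np.float64)
    with nn.no_grad():
        for start in range(0, len(indices), batch_size):
            idx = indices[start:start + batch_size]
            batch = {m: data[m][idx] for m in net.modalities}
            pred = net(batch)
            out[start:start + len(idx)] = pred.data.reshape(-1)
    return out


def train_network(net: MultimodalNet, data: dict, ages: np.ndarray,
                  split: SplitAssignment, config: TrainConfig,
                  checkpoint_path=None, shuffle_seed=None,
                  verbose: bool = False, log_fn=None,
                  resume_from=None) -> TrainHistory:
    """Run the training protocol and keep the best-on-validation weights.

    On return ``net`` holds the best weights; if ``checkpoint_path`` is
    given the best model (plus config and optimizer state) is saved there.
    """
    if len(split.train) == 0:
        raise ValueError("training split is empty")
    ages = np.asarray(ages, dtype=np.float64)
    opt = nn.Adam(net.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(
        shuffle_seed if shuffle_seed is not None else config.seed)
    start_epoch = 0
    history = TrainHistory()
    if resume_from is not None:
        meta = _load_into(net, opt, resume_from)
        start_epoch = meta.get("epoch", 0)
        history.train_loss = list(meta.get("train_loss", []))
        history.val_mae = list(meta.get("val_mae", []))
        history.best_epoch = meta.get("best_epoch", -1)

    best_val = min(history.val_mae) if history.val_mae else np.inf
    best_state = net.state_dict()
    use_val = len(split.val) > 0   # fall back to train loss for tiny cohorts

    for epoch in range(start_epoch, config.epochs):
        net.train()
        perm = shuffle_rng.permutation(split.train)
        total = 0.0
        for bi, start in enumerate(range(0, len(perm), config.batch_size)):
            idx = perm[start:start + config.batch_size]
            batch = {m: data[m][idx] for m in net.modalities}
            pred = net(batch)
            loss = _mae_loss(pred, ages[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {bi} "
                    f"(subjects {idx.tolist()})")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        train_loss = total / len(split.train)
        if use_val:
            val_pred = predict_network(net, data, split.val, config.batch_size)
            val_mae = float(np.mean(np.abs(val_pred - ages[split.val])))
        else:
            val_mae = train_loss
        history.train_loss.append(train_loss)
        history.val_mae.append(val_mae)
        if val_mae < best_val:
            best_val = val_mae
            history.best_epoch = epoch
            best_state = net.state_dict()
        msg = (f"epoch {epoch + 1}/{config.epochs} "
               f"train_mae={train_loss:.3f} val_mae={val_mae:.3f}")
        if log_fn is not None:
            log_fn(msg)
        elif verbose:
            print(msg)

    net.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(checkpoint_path, net, config,
                        extra={"epoch": config.epochs,
                               "best_epoch": history.best_epoch,
                               "train_loss": history.train_loss,
                               "val_mae": history.val_mae},
                        optimizer=opt)
        history.checkpoint_path = str(checkpoint_path)
    return history


# ---------------------------------------------------------------------------
# checkpoints: single .npz archive holding weights + embedded JSON config
# ---------------------------------------------------------------------------

def _net_meta(net: MultimodalNet, config: TrainConfig) -> dict:
    sfcn_cfg = None
    for m in ("smri", "dti"):
        if m in net.modalities:
            sfcn_cfg = asdict(net._branch(m).config)
            break
    meg_cfg = (asdict(net.branch_meg.config)
               if "meg" in net.modalities else None)
    return {
        "train_config": asdict(config),
        "sfcn_config": sfcn_cfg,
        "meg_config": meg_cfg,
        "n_bins": net.n_bins,
        "share_structural_weights": net.share_structural_weights,
    }


def save_checkpoint(path, net: MultimodalNet, config: TrainConfig,
                    extra: dict | None = None, optimizer=None):
    meta = _net_meta(net, config)
    if extra:
        meta.update(extra)
    arrays = {f"state/{k}": v for k, v in net.state_dict().items()}
    if optimizer is not None:
        opt_state = optimizer.state_dict()
        meta["optimizer_t"] = opt_state["t"]
        for i, (m, v) in enumerate(zip(opt_state["m"], opt_state["v"])):
            arrays[f"opt_m/{i}"] = m
            arrays[f"opt_v/{i}"] = v
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def _read_checkpoint(path):
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    return meta, arrays


def load_checkpoint(path) -> tuple:
    """Rebuild the network stored at ``path``; returns (net, meta)."""
    meta, arrays = _read_checkpoint(path)
    config = TrainConfig(**{k: tuple(v) if isinstance(v, list) else v
                            for k, v in meta["train_config"].items()})
    sfcn_cfg = meta["sfcn_config"]
    if sfcn_cfg is not None:
        sfcn_cfg = SFCNConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in sfcn_cfg.items()})
    meg_cfg = meta["meg_config"]
    if meg_cfg is not None:
        meg_cfg = MEGEncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                                      for k, v in meg_cfg.items()})
    net = build_network(config, sfcn_cfg, meg_cfg, n_bins=meta["n_bins"],
                        share_structural_weights=meta["share_structural_weights"])
    net.load_state_dict({k[len("state/"):]: v for k, v in arrays.items()
                         if k.startswith("state/")})
    return net, meta


def _load_into(net: MultimodalNet, optimizer, path) -> dict:
    meta, arrays = _read_checkpoint(path)
    net.load_state_dict({k[len("state/"):]: v for k, v in arrays.items()
                         if k.startswith("state/")})
    if optimizer is not None and "optimizer_t" in meta:
        n = len([k for k in arrays if k.startswith("opt_m/")])
        optimizer.load_state_dict({
            "t": meta["optimizer_t"],
            "m": [arrays[f"opt_m/{i}"] for i in range(n)],
            "v": [arrays[f"opt_v/{i}"] for i in range(n)],
        })
    return meta


def predict_from_checkpoint(path, data: dict, subject_ids=None,
                            batch_size: int = 12) -> np.ndarray:
    """One finite scalar age per subject, from a saved checkpoint."""
    net, _ = load_checkpoint(path)
    for m in net.modalities:
        if m not in data:
            raise KeyError(f"checkpoint expects modality {m!r} "
                           f"missing from the provided data")
    return predict_network(net, data, batch_size=batch_size)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class BrainAgeModel:
    """Brain-age regression from multimodal imaging.

    Parameters
    ----------
    data
        Mapping from modality name (``smri``, ``dti``, ``meg``) to a stacked
        array: volumes ``(n, D, H, W)``, PSD ``(n, regions, bins)``.
    ages
        Chronological ages in years, length n.
    config, sfcn_config, meg_config
        Protocol and branch configurations.
    """

    def __init__(self, data: dict, ages, subject_ids=None,
                 config: TrainConfig | None = None,
                 sfcn_config: SFCNConfig | None = None,
                 meg_config: MEGEncoderConfig | None = None,
                 share_structural_weights: bool = False):
        self.config = config or TrainConfig()
        missing = [m for m in self.config.modalities if m not in data]
        if missing:
            raise KeyError(f"config requires modalities {missing} not in data")
        self.data = {m: np.asarray(data[m]) for m in self.config.modalities}
        self.ages = np.asarray(ages, dtype=np.float64)
        n = len(self.ages)
        for m, arr in self.data.items():
            if len(arr) != n:
                raise ValueError(f"modality {m!r} has {len(arr)} subjects, "
                                 f"expected {n}")
        self.subject_ids = (list(subject_ids) if subject_ids is not None
                            else [f"sub-{i:04d}" for i in range(n)])
        self.sfcn_config = sfcn_config or SFCNConfig()
        self.meg_config = meg_config or MEGEncoderConfig()
        self.share_structural_weights = share_structural_weights
        self.net: MultimodalNet | None = None

    # -- constructors ---------------------------------------------------------
    @classmethod
    def from_cohort(cls, subjects, **kwargs) -> "BrainAgeModel":
        """Build from a list of in-memory subjects (e.g. the synthetic
        generator's output)."""
        data = {
            "smri": np.stack([s.smri_map.data for s in subjects]),
            "dti": np.stack([s.dti_map.data for s in subjects]),
            "meg": np.stack([s.psd.values for s in subjects]),
        }
        ages = [s.age for s in subjects]
        ids = [s.subject_id for s in subjects]
        return cls(data, ages, subject_ids=ids, **kwargs)

    @classmethod
    def from_manifest(cls, manifest_path, **kwargs) -> "BrainAgeModel":
        from .io import load_cohort_arrays
        data, ages, ids, split = load_cohort_arrays(manifest_path)
        model = cls(data, ages, subject_ids=ids, **kwargs)
        model._manifest_split = split
        return model

    # -- fitting ----------------------------------------------------------------
    def fit(self, split: SplitAssignment | None = None,
            checkpoint_path=None, verbose: bool = False,
            log_fn=None) -> "BrainAgeResults":
        n = len(self.ages)
        ss = np.random.SeedSequence(self.config.seed)
        split_ss, init_ss, shuffle_ss = ss.spawn(3)
        if split is None:
            split = getattr(self, "_manifest_split", None)
        if split is None:
            split = split_dataset(n, split_ss)
        n_bins = (self.data["meg"].shape[-1]
                  if "meg" in self.config.modalities else 64)
        self.net = build_network(self.config, self.sfcn_config,
                                 self.meg_config, n_bins=n_bins,
                                 init_seed=init_ss,
                                 share_structural_weights=self.share_structural_weights)
        # anchoring the head bias at the mean training age shortens the
        # initial transient of the MAE loss
        self.net.head.bias.data = np.full(
            1, self.ages[split.train].mean(), dtype=np.float32)
        history = train_network(self.net, self.data, self.ages, split,
                                self.config, checkpoint_path=checkpoint_path,
                                shuffle_seed=shuffle_ss, verbose=verbose,
                                log_fn=log_fn)
        predicted = predict_network(self.net, self.data,
                                    batch_size=self.config.batch_size)
        labels = np.empty(n, dtype=object)
        labels[split.train] = "train"
        labels[split.val] = "val"
        labels[split.test] = "test"
        predictions = pd.DataFrame({
            "subject_id": self.subject_ids,
            "split": labels,
            "age": self.ages,
            "predicted": predicted,
        })
        bias = fit_bias_correction(predictions[predictions["split"] == "train"])
        predictions = apply_bias_correction(predictions, bias)
        return BrainAgeResults(model=self, split=split, history=history,
                               predictions=predictions, bias_correction=bias)

    def num_parameters(self) -> int:
        if self.net is None:
            raise RuntimeError("call fit() first")
        return self.net.num_parameters()


@dataclass
class BrainAgeResults:
    """Fitted-model artifacts: predictions, bias correction, diagnostics."""

    model: BrainAgeModel
    split: SplitAssignment
    history: TrainHistory
    predictions: pd.DataFrame
    bias_correction: "BiasCorrectionModel"

    def metrics(self, corrected: bool = True) -> pd.DataFrame:
        col = "corrected" if corrected else "predicted"
        return metrics_by_split(self.predictions, predicted_col=col)

    def summary(self) -> str:
        cfg = self.model.config
        buf = _io.StringIO()
        buf.write("Brain age estimation results\n")
        buf.write("=" * 60 + "\n")
        buf.write(f"modalities:      {', '.join(cfg.modalities)}\n")
        buf.write(f"fusion:          {cfg.fusion}"
                  + (f" (rank={cfg.rank})" if cfg.fusion == "lowrank" else "")
                  + "\n")
        buf.write(f"parameters:      {self.model.num_parameters():,}\n")
        buf.write(f"epochs trained:  {len(self.history.train_loss)} "
                  f"(best on validation: {self.history.best_epoch + 1})\n")
        buf.write(f"bias correction: gap = {self.bias_correction.alpha:+.4f}"
                  f" * age {self.bias_correction.beta:+.3f}\n")
        buf.write("-" * 60 + "\n")
        buf.write("metrics on bias-corrected predictions (years):\n")
        buf.write(report_to_markdown(self.metrics(corrected=True)))
        return buf.getvalue()

    def save_predictions(self, path):
        self.predictions.to_csv(path, sep="\t", index=False)

    def plot_predictions(self, path=None, corrected: bool = True):
        """Scatter of predicted vs chronological age, one panel per split."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        col = "corrected" if corrected else "predicted"
        splits = [s for s in ("train", "val", "test")
                  if s in set(self.predictions["split"])]
        fig, axes = plt.subplots(1, len(splits), figsize=(4 * len(splits), 4),
                                 squeeze=False)
        for ax, split in zip(axes[0], splits):
            sub = self.predictions[self.predictions["split"] == split]
            ax.scatter(sub["age"], sub[col], s=12, alpha=0.7)
            lims = [self.predictions["age"].min(), self.predictions["age"].max()]
            ax.plot(lims, lims, "k--", lw=1)
            ax.set_title(split)
            ax.set_xlabel("chronological age (y)")
            ax.set_ylabel("predicted age (y)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return None
        return fig
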