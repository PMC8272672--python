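"""End-to-end orchestration: phantom -> backbone -> head -> fusion -> metrics.

One model is trained per (task, plane) combination.  Feature scaling, batch
normalization statistics and the RBM are all fitted on the training split
only; the test split is transformed with the frozen training-set statistics
(no leakage).  Everything is driven by a single seed, so a run is
bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from . import backbone as bb
from . import energy_fusion as ef
from . import head
from . import metrics as mx
from .errors import ConfigurationError
from .phantom import LabeledImage, PLANES

logger = logging.getLogger(__name__)

TASKS = ("acl_tear", "meniscus_tear")


@dataclass(frozen=True)
class TaskSpec:
    task: str = "acl_tear"
    plane: str = "sagittal"

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ConfigurationError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.plane not in PLANES:
            raise ConfigurationError(f"plane must be one of {PLANES}, got {self.plane!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """All knobs of one experiment; reduced desk-scale profile by default."""

    backbone: bb.BackboneConfig = field(default_factory=bb.BackboneConfig)
    pool_size: int = 8
    deep_dim: int = 64
    train: ef.TrainConfig = field(default_factory=lambda: ef.TrainConfig(
        epochs=30, n_hidden=24, log_exact_likelihood=False))
    seed: int = 0


@dataclass
class EvaluationReport:
    task: TaskSpec
    accuracy: float
    recall: float
    auc: float
    confusion: mx.ConfusionMatrix
    n_train: int | None  # None when evaluating a stored model
    n_test: int
    seed: int
    config_hash: str

    def to_dict(self) -> dict:
        return {
            "task": self.task.task, "plane": self.task.plane,
            "accuracy": self.accuracy, "recall": self.recall, "auc": self.auc,
            "confusion": {"tp": self.confusion.tp, "fp": self.confusion.fp,
                          "tn": self.confusion.tn, "fn": self.confusion.fn},
            "n_train": self.n_train, "n_test": self.n_test,
            "seed": self.seed, "config_hash": self.config_hash,
        }


@dataclass
class MinMaxScaler:
    """Per-column min-max scaling to [0,1], fitted on the training set only.

    Constant columns map to 0; transformed values are clipped to [0,1] so
    out-of-range test values remain valid RBM inputs.
    """

    lo: np.ndarray = None  # type: ignore[assignment]
    hi: np.ndarray = None  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "MinMaxScaler":
        self.lo = X.min(axis=0)
        self.hi = X.max(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.hi - self.lo
        span = np.where(span > 0, span, 1.0)
        return np.clip((X - self.lo) / span, 0.0, 1.0)


@dataclass
class FittedModel:
    """Everything needed to score new slices for one (task, plane)."""

    task: TaskSpec
    config: ExperimentConfig
    backbone_weights: bb.BackboneWeights
    fusion_weights: bb.FusionWeights
    bn_params: head.BNParams
    projection: head.ProjectionParams
    trad_scaler: MinMaxScaler
    deep_scaler: MinMaxScaler
    rbm: ef.RBMParams


def _config_hash(config: ExperimentConfig) -> str:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    blob = json.dumps(asdict(config), sort_keys=True, default=default)
    return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _fused_stack(images, config: ExperimentConfig,
                 weights: bb.BackboneWeights,
                 fusion: bb.FusionWeights) -> np.ndarray:
    """Bottom fused map of each image, stacked to (N, C, H, W)."""
    maps = []
    for im in images:
        pyr = bb.extract_pyramid(im, config.backbone, weights)
        bb.fuse_pyramid(pyr, fusion)
        maps.append(pyr.bottom_fused().values)
    return np.stack(maps)


def _deep_features(stack: np.ndarray, config: ExperimentConfig,
                   bn: head.BNParams, projection: head.ProjectionParams,
                   mode: str) -> np.ndarray:
    normed = head.relu(head.batch_normalize(stack, bn, mode=mode))
    rows = []
    for i in range(normed.shape[0]):
        pooled = head.adaptive_max_pool(normed[i], config.pool_size)
        rows.append(head.project_deep_features(pooled, projection))
    return np.vstack(rows)


def _traditional_matrix(images) -> np.ndarray:
    return np.vstack([head.extract_traditional_features(im).values for im in images])


def fit_model(train_images, task_spec: TaskSpec, config: ExperimentConfig) -> FittedModel:
    """Fit all trainable state (scalers, BN stats, RBM) on the training set."""
    labels = np.array([im.label(task_spec.task) for im in train_images])
    if set(labels.tolist()) != {0, 1}:
        raise ConfigurationError("training set must contain both classes")
    weights = bb.init_backbone_weights(config.backbone)
    fusion = bb.init_fusion_weights(config.backbone)
    stack = _fused_stack(train_images, config, weights, fusion)
    bn = head.BNParams.identity(stack.shape[1])
    # single full-batch pass: adopt the training-set statistics exactly so
    # eval mode normalizes test images with the same moments
    bn.momentum = 1.0
    projection = head.init_projection(
        stack.shape[1] * config.pool_size ** 2, config.deep_dim, seed=config.seed)
    deep = _deep_features(stack, config, bn, projection, mode="train")
    trad = _traditional_matrix(train_images)
    trad_scaler = MinMaxScaler().fit(trad)
    deep_scaler = MinMaxScaler().fit(deep)
    M = np.hstack([trad_scaler.transform(trad), deep_scaler.transform(deep)])
    samples = [ef.FusedSample(m=row, label=int(lab)) for row, lab in zip(M, labels)]
    rbm = ef.train(samples, config.train)
    return FittedModel(task=task_spec, config=config, backbone_weights=weights,
                       fusion_weights=fusion, bn_params=bn, projection=projection,
                       trad_scaler=trad_scaler, deep_scaler=deep_scaler, rbm=rbm)


def featurize(images, model: FittedModel, mode: str = "eval") -> np.ndarray:
    """Multimodal matrix m = (c, o) for a set of images, in [0,1]."""
    stack = _fused_stack(images, model.config, model.backbone_weights,
                         model.fusion_weights)
    deep = _deep_features(stack, model.config, model.bn_params,
                          model.projection, mode=mode)
    trad = _traditional_matrix(images)
    return np.hstack([model.trad_scaler.transform(trad),
                      model.deep_scaler.transform(deep)])


def score(images, model: FittedModel) -> tuple[np.ndarray, np.ndarray]:
    """Tear probabilities and binary calls (threshold 0.5) for images."""
    M = featurize(images, model)
    return ef.predict_batch(M, model.rbm)


def evaluate(test_images, model: FittedModel) -> EvaluationReport:
    labels = np.array([im.label(model.task.task) for im in test_images])
    probs, calls = score(test_images, model)
    cm = mx.confusion(calls, labels)
    _, auc = mx.roc_auc(probs, labels)
    return EvaluationReport(
        task=model.task, accuracy=mx.accuracy(cm), recall=mx.recall(cm),
        auc=auc, confusion=cm, n_train=None, n_test=len(test_images),
        seed=model.config.seed, config_hash=_config_hash(model.config))


def run_experiment(train_images, test_images, task_spec: TaskSpec,
                   config: ExperimentConfig,
                   shuffle_labels: bool = False) -> EvaluationReport:
    """Train on one split, evaluate on the other.

    ``shuffle_labels=True`` permutes the training labels (seeded) as a
    negative control: held-out performance should then collapse to chance.
    """
    train_images = list(train_images)
    test_images = list(test_images)
    if not train_images or not test_images:
        raise ConfigurationError("both splits must be nonempty")
    if shuffle_labels:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))
        labels = np.array([im.label(task_spec.task) for im in train_images])
        labels = labels[rng.permutation(len(labels))]
        train_images = [
            LabeledImage(
                pixels=im.pixels, plane=im.plane,
                acl_tear=int(lab) if task_spec.task == "acl_tear" else im.acl_tear,
                meniscus_tear=int(lab) if task_spec.task == "meniscus_tear"
                else im.meniscus_tear,
                meta=im.meta)
            for im, lab in zip(train_images, labels)
        ]
    model = fit_model(train_images, task_spec, config)
    report = evaluate(test_images, model)
    report.n_train = len(train_images)
    logger.info("experiment %s/%s: accuracy=%.3f recall=%.3f auc=%.3f",
                task_spec.task, task_spec.plane, report.accuracy,
                report.recall, report.auc)
    return report


# ---------------------------------------------------------------------------
# Model checkpoints: one .npz with every parameter array plus a JSON header
# ---------------------------------------------------------------------------

def save_model(model: FittedModel, path: str) -> None:
    arrays: dict[str, np.ndarray] = {}
    for g, layers in enumerate(model.backbone_weights.blocks, start=1):
        for i, (w, b) in enumerate(layers):
            arrays[f"bb_block{g}_conv{i}_w"] = w
            arrays[f"bb_block{g}_conv{i}_b"] = b
    for g, (w, b) in model.fusion_weights.lateral.items():
        arrays[f"fw_lateral{g}_w"], arrays[f"fw_lateral{g}_b"] = w, b
    for g, (w, b) in model.fusion_weights.smooth.items():
        arrays[f"fw_smooth{g}_w"], arrays[f"fw_smooth{g}_b"] = w, b
    bn = model.bn_params
    arrays.update(bn_scale=bn.scale, bn_shift=bn.shift,
                  bn_running_mean=bn.running_mean, bn_running_var=bn.running_var,
                  proj_w=model.projection.weight, proj_b=model.projection.bias,
                  trad_lo=model.trad_scaler.lo, trad_hi=model.trad_scaler.hi,
                  deep_lo=model.deep_scaler.lo, deep_hi=model.deep_scaler.hi,
                  rbm_t=model.rbm.visible_bias, rbm_beta=model.rbm.hidden_bias,
                  rbm_w=model.rbm.weights, rbm_out_w=model.rbm.output_weights,
                  rbm_out_b=np.array([model.rbm.output_bias]))
    header = {
        "task": asdict(model.task),
        "config": json.loads(json.dumps(asdict(model.config), default=list)),
        "bn": {"eps": bn.eps, "momentum": bn.momentum},
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path: str) -> FittedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        cfg_d = header["config"]
        bcfg = dict(cfg_d["backbone"])
        bcfg["block_range"] = tuple(bcfg["block_range"])
        bcfg["channels"] = tuple(bcfg["channels"])
        config = ExperimentConfig(
            backbone=bb.BackboneConfig(**bcfg),
            pool_size=cfg_d["pool_size"], deep_dim=cfg_d["deep_dim"],
            train=ef.TrainConfig(**cfg_d["train"]), seed=cfg_d["seed"])
        blocks = []
        for g in range(1, 6):
            layers = []
            i = 0
            while f"bb_block{g}_conv{i}_w" in data:
                layers.append((data[f"bb_block{g}_conv{i}_w"],
                               data[f"bb_block{g}_conv{i}_b"]))
                i += 1
            blocks.append(layers)
        lateral = {g: (data[f"fw_lateral{g}_w"], data[f"fw_lateral{g}_b"])
                   for g in config.backbone.blocks if f"fw_lateral{g}_w" in data}
        smooth = {g: (data[f"fw_smooth{g}_w"], data[f"fw_smooth{g}_b"])
                  for g in config.backbone.blocks if f"fw_smooth{g}_w" in data}
        bn = head.BNParams(scale=data["bn_scale"], shift=data["bn_shift"],
                           eps=header["bn"]["eps"], momentum=header["bn"]["momentum"],
                           running_mean=data["bn_running_mean"],
                           running_var=data["bn_running_var"])
        rbm = ef.RBMParams(visible_bias=data["rbm_t"], hidden_bias=data["rbm_beta"],
                           weights=data["rbm_w"], output_weights=data["rbm_out_w"],
                           output_bias=float(data["rbm_out_b"][0]), trained=True)
        return FittedModel(
            task=TaskSpec(**header["task"]), config=config,
            backbone_weights=bb.BackboneWeights(blocks),
            fusion_weights=bb.FusionWeights(lateral, smooth),
            bn_params=bn,
            projection=head.ProjectionParams(weight=data["proj_w"], bias=data["proj_b"]),
            trad_scaler=MinMaxScaler(lo=data["trad_lo"], hi=data["trad_hi"]),
            deep_scaler=MinMaxScaler(lo=data["deep_lo"], hi=data["deep_hi"]),
            rbm=rbm)
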