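"""The Panoptes architecture family and its single-resolution baselines.

Panoptes consumes a *tile set* — three co-registered 299x299 tiles at 10x,
5x and 2.5x equivalent magnification — through three parallel
inception-resnet-style branch extractors that stay separate until their
final feature maps are concatenated on the channel axis, followed by an
optional 1x1 feature-pooling convolution (Panoptes3/4), global average
pooling, an optional clinical-feature embedding (age + BMI), dropout and
the final fully connected classifier.  Each branch additionally carries an
auxiliary classifier head whose loss regularizes training.  Baselines are
the corresponding single-branch networks fed the 10x tile only.

Branch extractors here follow the inception / inception-resnet block
structure (parallel 1x1 / 3x3 paths, scaled residual shortcuts, stride-2
reductions) at reduced depth so the family trains on a CPU; per-family
channel plans differ so the nine names remain genuinely distinct networks.
``width_multiplier`` scales every channel count uniformly (floor of 4) and
``input_px`` may be reduced to 75 for desk-scale runs; defaults are the
full-size 299-pixel models.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import WiringError
from .nn import (
    BatchNorm2d,
    Conv2d,
    Dense,
    Dropout,
    GlobalAvgPool,
    Module,
    ParallelConcat,
    ReLU,
    Residual,
    Sequential,
    softmax,
)

PANOPTES_FAMILIES = ("panoptes1", "panoptes2", "panoptes3", "panoptes4")
BASELINE_FAMILIES = (
    "inception_v1",
    "inception_v2",
    "inception_v3",
    "inception_resnet_v1",
    "inception_resnet_v2",
)
CLINICAL_DIM = 16

#: per-family branch plan: stem (channels, stride), block type, counts, widths
_BRANCH_PLANS = {
    "inception_resnet_v1": dict(
        stem=[(32, 2), (32, 1), (64, 2)], residual=True,
        stage_a=(2, 64, 32, 0.17), reduce_to=128, stage_b=(2, 128, 48, 0.10),
    ),
    "inception_resnet_v2": dict(
        stem=[(32, 2), (64, 1), (96, 2)], residual=True,
        stage_a=(3, 96, 48, 0.17), reduce_to=160, stage_b=(2, 160, 64, 0.10),
    ),
    "inception_v1": dict(
        stem=[(32, 2), (64, 2)], residual=False,
        stage_a=(2, 64, 32, None), reduce_to=128, stage_b=(1, 128, 64, None),
    ),
    "inception_v2": dict(
        stem=[(32, 2), (64, 2)], residual=False,
        stage_a=(3, 64, 32, None), reduce_to=128, stage_b=(2, 128, 64, None),
    ),
    "inception_v3": dict(
        stem=[(32, 2), (48, 1), (64, 2)], residual=False,
        stage_a=(3, 64, 32, None), reduce_to=160, stage_b=(2, 160, 80, None),
    ),
}


@dataclass(frozen=True)
class ArchitectureConfig:
    family: str = "panoptes2"
    use_clinical: bool = False
    feature_pool_channels: int = 1024
    dropout_keep: float = 0.3
    aux_weight: float = 0.4
    width_multiplier: float = 1.0
    input_px: int = 299
    n_classes: int = 2

    def __post_init__(self):
        if self.family not in PANOPTES_FAMILIES + BASELINE_FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not (0 < self.width_multiplier <= 1):
            raise ValueError("width_multiplier must be in (0, 1]")
        if self.input_px < 75:
            raise ValueError("input_px below 75 is not supported")
        if not (0 < self.dropout_keep <= 1):
            raise ValueError("dropout_keep must be in (0, 1]")

    @property
    def is_panoptes(self) -> bool:
        return self.family in PANOPTES_FAMILIES

    @property
    def branch_family(self) -> str:
        return {
            "panoptes1": "inception_resnet_v1",
            "panoptes3": "inception_resnet_v1",
            "panoptes2": "inception_resnet_v2",
            "panoptes4": "inception_resnet_v2",
        }.get(self.family, self.family)

    @property
    def has_feature_pool(self) -> bool:
        return self.family in ("panoptes3", "panoptes4")

    def fingerprint(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()


def _ch(base: int, wm: float) -> int:
    return max(4, int(round(base * wm)))


def _conv_relu(rng, c_in, c_out, k=3, stride=1):
    # conv -> batchnorm -> relu, the inception lineage's standard unit
    return Sequential(Conv2d(rng, c_in, c_out, k, stride), BatchNorm2d(c_out), ReLU())


def _block(rng, channels: int, branch_ch: int, residual: bool, scale: Optional[float]):
    mix = ParallelConcat(
        _conv_relu(rng, channels, branch_ch, k=1),
        Sequential(
            _conv_relu(rng, channels, branch_ch, k=1),
            _conv_relu(rng, branch_ch, branch_ch, k=3),
        ),
    )
    if residual:
        # linear 1x1 projection back to the trunk width, scaled shortcut
        proj = Conv2d(rng, 2 * branch_ch, channels, 1)
        return Sequential(Residual(Sequential(mix, proj), scale=scale), ReLU())
    # plain inception: concat paths then 1x1 to the stage width
    return Sequential(mix, _conv_relu(rng, 2 * branch_ch, channels, k=1))


def build_branch(rng, family: str, wm: float, c_in: int = 3) -> tuple[Module, int]:
    """One feature-extractor branch truncated before pooling/classifier."""
    plan = _BRANCH_PLANS[family]
    layers: list[Module] = []
    c = c_in
    for c_out, stride in plan["stem"]:
        co = _ch(c_out, wm)
        layers.append(_conv_relu(rng, c, co, 3, stride))
        c = co
    n_a, ch_a, bc_a, scale_a = plan["stage_a"]
    assert _ch(ch_a, wm) == c or True
    for _ in range(n_a):
        layers.append(_block(rng, c, _ch(bc_a, wm), plan["residual"], scale_a))
    red = _ch(plan["reduce_to"], wm)
    layers.append(_conv_relu(rng, c, red, 3, 2))
    c = red
    n_b, ch_b, bc_b, scale_b = plan["stage_b"]
    for _ in range(n_b):
        layers.append(_block(rng, c, _ch(bc_b, wm), plan["residual"], scale_b))
    return Sequential(*layers), c


class AuxHead(Module):
    """Auxiliary classifier on a branch's final feature map (GAP + FC)."""

    def __init__(self, rng, c_in: int, n_classes: int):
        self.gap = GlobalAvgPool()
        self.fc = Dense(rng, c_in, n_classes)

    def forward(self, x, train=False):
        return self.fc.forward(self.gap.forward(x, train), train)

    def backward(self, dout):
        return self.gap.backward(self.fc.backward(dout))


class ClinicalBranch(Module):
    """MLP embedding of standardized age/BMI plus missingness flags.

    Standardization constants must be fitted on the training partition via
    :meth:`fit_standardizer` before use.
    """

    def __init__(self, rng, n_inputs: int = 4, hidden: int = CLINICAL_DIM):
        self.mean = np.zeros(n_inputs)
        self.std = np.ones(n_inputs)
        self.fitted = False
        self.net = Sequential(
            Dense(rng, n_inputs, hidden), ReLU(), Dense(rng, hidden, hidden), ReLU()
        )

    def fit_standardizer(self, clinical: np.ndarray) -> None:
        self.mean = clinical.mean(axis=0)
        std = clinical.std(axis=0)
        self.std = np.where(std < 1e-8, 1.0, std)
        self.fitted = True

    def forward(self, x, train=False):
        return self.net.forward((x - self.mean) / self.std, train)

    def backward(self, dout):
        return self.net.backward(dout) / self.std


class PanoptesNetwork(Module):
    """Three-branch multi-resolution classifier with auxiliary heads."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        if not cfg.is_panoptes:
            raise ValueError(f"{cfg.family} is not a Panoptes family")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.magnifications = (10.0, 5.0, 2.5)
        self.branches = []
        self.aux_heads = []
        c_out = None
        for _ in self.magnifications:
            branch, c = build_branch(rng, cfg.branch_family, cfg.width_multiplier)
            self.branches.append(branch)
            self.aux_heads.append(AuxHead(rng, c, cfg.n_classes))
            c_out = c
        concat_ch = 3 * c_out
        self.feature_pool = None
        feat_ch = concat_ch
        if cfg.has_feature_pool:
            feat_ch = _ch(cfg.feature_pool_channels, cfg.width_multiplier)
            self.feature_pool = Sequential(
                Conv2d(rng, concat_ch, feat_ch, 1), BatchNorm2d(feat_ch), ReLU()
            )
        self.gap = GlobalAvgPool()
        self.clinical = ClinicalBranch(rng) if cfg.use_clinical else None
        self.feature_dim = feat_ch + (CLINICAL_DIM if cfg.use_clinical else 0)
        self.dropout = Dropout(np.random.default_rng(seed + 1), cfg.dropout_keep)
        self.fc = Dense(rng, self.feature_dim, cfg.n_classes)
        self._concat_ch = concat_ch

    # -- forward/backward --------------------------------------------------

    def _check_inputs(self, inputs: dict) -> None:
        missing = [m for m in self.magnifications if m not in inputs]
        if missing:
            raise WiringError(f"missing tile inputs for magnifications {missing}")
        if self.clinical is not None and inputs.get("clinical") is None:
            raise WiringError("clinical branch enabled but no clinical inputs given")

    def forward_full(self, inputs: dict, train: bool = False):
        """Returns (logits, aux_logits list, pooled feature vectors)."""
        self._check_inputs(inputs)
        maps = []
        aux = []
        for branch, head, mag in zip(self.branches, self.aux_heads, self.magnifications):
            f = branch.forward(inputs[mag], train)
            maps.append(f)
            aux.append(head.forward(f, train))
        shapes = {f.shape[2:] for f in maps}
        if len(shapes) != 1:
            raise WiringError(f"branch spatial grids differ: {shapes}")
        x = np.concatenate(maps, axis=1)
        self._splits = np.cumsum([f.shape[1] for f in maps])[:-1]
        if self.feature_pool is not None:
            x = self.feature_pool.forward(x, train)
        g = self.gap.forward(x, train)
        if self.clinical is not None:
            e = self.clinical.forward(inputs["clinical"], train)
            g = np.concatenate([g, e], axis=1)
        self._feat = g
        d = self.dropout.forward(g, train)
        return self.fc.forward(d, train), aux, g

    def backward_full(self, dlogits, daux: Optional[Sequence[np.ndarray]] = None):
        dg = self.dropout.backward(self.fc.backward(dlogits))
        if self.clinical is not None:
            dg, de = dg[:, : -CLINICAL_DIM], dg[:, -CLINICAL_DIM:]
            self.clinical.backward(de)
        dx = self.gap.backward(dg)
        if self.feature_pool is not None:
            dx = self.feature_pool.backward(dx)
        parts = np.split(dx, self._splits, axis=1)
        for i, (branch, head) in enumerate(zip(self.branches, self.aux_heads)):
            d = np.ascontiguousarray(parts[i])
            if daux is not None:
                d = d + head.backward(daux[i])
            branch.backward(d)

    def forward(self, inputs, train=False):
        logits, _, _ = self.forward_full(inputs, train)
        return logits

    def predict_proba(self, inputs) -> np.ndarray:
        return softmax(self.forward(inputs, train=False))


class BaselineNetwork(Module):
    """Single-resolution classifier; consumes only the 10x member tile."""

    def __init__(self, cfg: ArchitectureConfig, seed: int = 0):
        if cfg.is_panoptes:
            raise ValueError(f"{cfg.family} is not a baseline family")
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.magnification = 10.0
        self.branch, c = build_branch(rng, cfg.family, cfg.width_multiplier)
        self.aux_head = AuxHead(rng, c, cfg.n_classes)
        self.gap = GlobalAvgPool()
        self.feature_dim = c
        self.dropout = Dropout(np.random.default_rng(seed + 1), cfg.dropout_keep)
        self.fc = Dense(rng, c, cfg.n_classes)
        self.clinical = None

    def forward_full(self, inputs, train: bool = False):
        x = inputs[self.magnification] if isinstance(inputs, dict) else inputs
        f = self.branch.forward(x, train)
        aux = [self.aux_head.forward(f, train)]
        g = self.gap.forward(f, train)
        self._feat = g
        d = self.dropout.forward(g, train)
        return self.fc.forward(d, train), aux, g

    def backward_full(self, dlogits, daux: Optional[Sequence[np.ndarray]] = None):
        dg = self.dropout.backward(self.fc.backward(dlogits))
        d = self.gap.backward(dg)
        if daux is not None:
            d = d + self.aux_head.backward(daux[0])
        self.branch.backward(d)

    def forward(self, inputs, train=False):
        logits, _, _ = self.forward_full(inputs, train)
        return logits

    def predict_proba(self, inputs) -> np.ndarray:
        return softmax(self.forward(inputs, train=False))


def build_model(cfg: ArchitectureConfig, seed: int = 0):
    """Construct the network named by the configuration."""
    if cfg.is_panoptes:
        return PanoptesNetwork(cfg, seed)
    return BaselineNetwork(cfg, seed)


def forward_features(model, inputs) -> np.ndarray:
    """Per-sample feature vector before the final fully connected layer.

    The post-pooling (and post-clinical-concatenation, when enabled) vector
    used for tSNE feature visualization; evaluation mode, deterministic.
    """
    _, _, feats = model.forward_full(inputs, train=False)
    return feats


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(path: str, model, cfg: ArchitectureConfig) -> None:
    state = model.get_state()
    np.savez_compressed(
        path,
        _fingerprint=np.frombuffer(cfg.fingerprint().encode(), dtype=np.uint8),
        _config=np.frombuffer(json.dumps(asdict(cfg)).encode(), dtype=np.uint8),
        **{f"p{i}": v for i, v in enumerate(state)},
    )


def load_checkpoint(path: str, cfg: ArchitectureConfig, seed: int = 0):
    with np.load(path) as z:
        fp = bytes(z["_fingerprint"]).decode()
        if fp != cfg.fingerprint():
            raise WiringError(
                f"checkpoint fingerprint {fp[:12]} does not match config "
                f"{cfg.fingerprint()[:12]}"
            )
        state = [z[f"p{i}"] for i in range(sum(1 for k in z.files if k.startswith("p")))]
    model = build_model(cfg, seed)
    model.set_state(state)
    return model
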