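"""Attention-based multiple-instance learning over tile feature bags.

A slide is a bag of tile embeddings H (N x 512) carrying a single
slide-level label. The attention layer scores each tile,

    a_k = softmax_k( w^T tanh(V h_k) ),

pools the bag into z = sum_k a_k h_k, and a two-logit softmax head maps
z to the slide-level likelihood of the biomarker. Attention weights are
non-negative, sum to one, and are equivariant under tile permutation;
they double as the per-tile interpretability heatmap.

Training minimizes class-weighted cross-entropy, one slide-bag per
optimization step, with dropout on the pooled embedding, decoupled
weight decay and Adam. Gradients are derived analytically (the backbone
is frozen), so the whole loop is plain NumPy and deterministic given
the config seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureBag, HandcraftedBackbone, extract_features
from .qc import DEFAULT_QC_CONFIG, TileRef, filter_tiles, qc_slide
from .slideio import read_slide
from .errors import DeviceError


@dataclass(frozen=True)
class MILConfig:
    """Training hyperparameters.

    Defaults follow the production recipe (learning rate 1e-5, weight
    decay 1e-4, dropout 0.5); desk-scale runs with the handcrafted
    backbone typically pass a larger learning rate and fewer epochs.
    """

    tile_size: int = 224
    magnification: str = "10x"
    learning_rate: float = 1e-5
    weight_decay: float = 1e-4
    dropout: float = 0.5
    epochs: int = 20
    hidden_dim: int = 128
    seed: int = 0
    backbone_name: str = "handcrafted-v1"

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


@dataclass
class AttentionParams:
    """Attention layer parameters: V (hidden x 512) and w (hidden)."""

    V: np.ndarray
    w: np.ndarray

    def __post_init__(self):
        self.V = np.asarray(self.V, dtype=np.float64)
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.V.ndim != 2 or self.w.shape != (self.V.shape[0],):
            raise ValueError("inconsistent attention shapes")
        if not (np.isfinite(self.V).all() and np.isfinite(self.w).all()):
            raise ValueError("attention parameters must be finite")

    @property
    def hidden_dim(self) -> int:
        return self.V.shape[0]


@dataclass
class SlidePrediction:
    """Slide likelihood plus per-tile attention weights."""

    likelihood: float
    attention_weights: np.ndarray
    tiles: list[TileRef]


def _softmax(x: np.ndarray) -> np.ndarray:
    e = np.exp(x - x.max())
    return e / e.sum()


def attention_pool(bag: FeatureBag | np.ndarray, params: AttentionParams):
    """Pool a bag into (bag_embedding, attention weights)."""
    H = bag.features if isinstance(bag, FeatureBag) else np.asarray(bag, dtype=np.float64)
    if H.ndim != 2 or H.shape[1] != params.V.shape[1]:
        raise ValueError("bag / attention shape mismatch")
    scores = np.tanh(H @ params.V.T) @ params.w
    weights = _softmax(scores)
    return weights @ H, weights


class MILModel:
    """Attention MIL head over a frozen feature backbone.

    Holds the attention parameters, the two-logit classifier head, the
    feature standardization learned from the training bags, and the
    operating threshold chosen at model selection.
    """

    def __init__(self, config: MILConfig, rng: np.random.Generator | None = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        d, h = 512, config.hidden_dim
        self.attention = AttentionParams(
            V=rng.normal(0.0, 0.1, size=(h, d)), w=rng.normal(0.0, 0.1, size=h)
        )
        self.U = rng.normal(0.0, 0.01, size=(2, d))
        self.b = np.zeros(2)
        self.feat_mean = np.zeros(d)
        self.feat_scale = np.ones(d)
        self.threshold: float = 0.5

    # -- inference ----------------------------------------------------------

    def _standardize(self, H: np.ndarray) -> np.ndarray:
        return (H - self.feat_mean) / self.feat_scale

    def predict_bag(self, bag: FeatureBag) -> SlidePrediction:
        H = self._standardize(bag.features)
        z, weights = attention_pool(H, self.attention)
        p = _softmax(self.U @ z + self.b)
        return SlidePrediction(
            likelihood=float(p[1]), attention_weights=weights, tiles=list(bag.tiles)
        )

    # -- persistence --------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "config": asdict(self.config),
            "threshold": self.threshold,
            "V": self.attention.V.tolist(),
            "w": self.attention.w.tolist(),
            "U": self.U.tolist(),
            "b": self.b.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_scale": self.feat_scale.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "MILModel":
        payload = json.loads(Path(path).read_text())
        model = cls(MILConfig(**payload["config"]))
        model.attention = AttentionParams(
            V=np.array(payload["V"]), w=np.array(payload["w"])
        )
        model.U = np.array(payload["U"])
        model.b = np.array(payload["b"])
        model.feat_mean = np.array(payload["feat_mean"])
        model.feat_scale = np.array(payload["feat_scale"])
        model.threshold = float(payload["threshold"])
        return model


def predict_slide(bag: FeatureBag, model: MILModel) -> SlidePrediction:
    """Slide likelihood = positive-class probability of the pooled bag."""
    return model.predict_bag(bag)


# ---------------------------------------------------------------------------
# training


def class_weights(labels) -> dict:
    """Inverse-frequency loss weights, normalized to mean 1."""
    labels = list(labels)
    n_pos = sum(1 for l in labels if l == "positive")
    n_neg = sum(1 for l in labels if l == "negative")
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute class weights")
    w = np.array([1.0 / n_neg, 1.0 / n_pos])
    w = w / w.mean()
    return {"negative": float(w[0]), "positive": float(w[1])}


class _Adam:
    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


def fit_mil(bags: list[FeatureBag], labels: list[str], config: MILConfig) -> tuple[MILModel, pd.DataFrame]:
    """Train the attention head on in-memory bags.

    One bag per optimization step; class-weighted cross-entropy; dropout
    on the pooled embedding; Adam with decoupled weight decay. Returns
    the model and a per-epoch mean-loss log.
    """
    if len(bags) != len(labels) or not bags:
        raise ValueError("bags and labels must be non-empty and aligned")
    rng = np.random.default_rng(config.seed)
    model = MILModel(config, rng=rng)

    all_feats = np.vstack([b.features for b in bags])
    model.feat_mean = all_feats.mean(axis=0)
    model.feat_scale = all_feats.std(axis=0) + 1e-8

    cw = class_weights(labels)
    y = np.array([1 if l == "positive" else 0 for l in labels])
    V, w, U, b = model.attention.V, model.attention.w, model.U, model.b
    opt = _Adam([V.shape, w.shape, U.shape, b.shape], config.learning_rate)
    p_drop = config.dropout
    wd = config.weight_decay

    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(bags))
        losses = []
        for i in order:
            H = (bags[i].features - model.feat_mean) / model.feat_scale
            yi = y[i]
            weight = cw["positive"] if yi == 1 else cw["negative"]

            # forward
            pre = H @ V.T            # N x h
            s = np.tanh(pre)
            att_logit = s @ w        # N
            a = _softmax(att_logit)
            z = a @ H                # 512
            if p_drop > 0:
                mask = (rng.random(z.shape[0]) >= p_drop) / (1.0 - p_drop)
            else:
                mask = np.ones_like(z)
            zd = z * mask
            logits = U @ zd + b
            p = _softmax(logits)
            losses.append(-weight * np.log(max(p[yi], 1e-300)))

            # backward (analytic; backbone frozen)
            dlogits = weight * (p - np.eye(2)[yi])
            dU = np.outer(dlogits, zd)
            db = dlogits
            dz = (U.T @ dlogits) * mask
            da = H @ dz
            ds_logit = a * (da - a @ da)
            dw = s.T @ ds_logit
            dV = ((ds_logit[:, None] * w[None, :]) * (1.0 - s**2)).T @ H

            # decoupled weight decay on matrices
            V_, w_, U_, b_ = opt.step([V, w, U, b], [dV, dw, dU, db])
            V = V_ * (1.0 - config.learning_rate * wd)
            U = U_ * (1.0 - config.learning_rate * wd)
            w, b = w_, b_
        history.append({"epoch": epoch, "loss": float(np.mean(losses))})

    model.attention = AttentionParams(V=V, w=w)
    model.U, model.b = U, b
    return model, pd.DataFrame(history)


def bag_from_slide(path_or_slide, backbone, qc_config=DEFAULT_QC_CONFIG, allow_resample: bool = False) -> FeatureBag:
    """Read -> QC -> filter -> embed one slide into a feature bag."""
    slide = path_or_slide if not isinstance(path_or_slide, (str, Path)) else read_slide(
        path_or_slide, allow_resample=allow_resample
    )
    records = qc_slide(slide, qc_config)
    kept = filter_tiles(records, qc_config.score_threshold)
    tiles = [slide.region(r.tile.x, r.tile.y, r.tile.size, r.tile.size) for r in kept]
    return extract_features(tiles, backbone, tile_refs=[r.tile for r in kept])


def train_mil(
    manifest: pd.DataFrame,
    config: MILConfig,
    backbone=None,
    qc_config=DEFAULT_QC_CONFIG,
) -> tuple[MILModel, pd.DataFrame]:
    """Train from a cohort manifest (slide_id, file_path, label).

    Slides whose tiles all fail QC are skipped with a warning.
    """
    backbone = backbone or HandcraftedBackbone()
    bags, labels = [], []
    for row in manifest.itertuples():
        try:
            bags.append(bag_from_slide(row.file_path, backbone, qc_config))
            labels.append(row.label)
        except DeviceError as exc:
            warnings.warn(f"skipping slide {row.slide_id}: {exc.message}", stacklevel=2)
    if not bags:
        raise ValueError("no slide in the manifest survived QC")
    return fit_mil(bags, labels, config)


# ---------------------------------------------------------------------------
# splitting and model selection


def stratified_splits(
    manifest: pd.DataFrame,
    holdout_fraction: float = 0.15,
    n_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Holdout + K-fold assignment stratified by (label, cohort_name).

    Within every label x cohort stratum the holdout receives
    ``round(fraction * n)`` slides and the remainder is dealt round-robin
    into folds, so partition counts deviate from their targets by at most
    one slide per stratum. Returns a copy of the manifest with
    ``partition`` ("train"/"holdout") and ``fold`` (-1 for holdout).
    """
    rng = np.random.default_rng(seed)
    out = manifest.copy().reset_index(drop=True)
    out["partition"] = "train"
    out["fold"] = -1
    for _, idx in out.groupby(["label", "cohort_name"]).groups.items():
        idx = np.array(sorted(idx))
        if len(idx) < n_folds:
            warnings.warn(
                f"stratum smaller than n_folds ({len(idx)} < {n_folds}); degenerate fold assignment",
                stacklevel=2,
            )
        perm = idx[rng.permutation(len(idx))]
        n_hold = round(holdout_fraction * len(idx))
        hold, train = perm[:n_hold], perm[n_hold:]
        out.loc[hold, "partition"] = "holdout"
        for j, i in enumerate(train):
            out.loc[i, "fold"] = j % n_folds
    return out


def _op_at_threshold(scores: np.ndarray, labels: np.ndarray, t: float):
    pred = scores >= t
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    tn = int((~pred & (labels == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else 0.0
    return sens, spec, ppv


@dataclass
class SelectionResult:
    model: object
    index: int
    threshold: float
    ppv: float
    sensitivity: float
    specificity: float
    flagged: bool = False
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def select_model(candidates, target_sensitivity: float = 0.9) -> SelectionResult:
    """Pick the candidate with the highest PPV at the target sensitivity.

    Each candidate is ``(model, validation_scores, validation_labels)``
    with binary labels (1 = positive). For every candidate the threshold
    is the *largest* score value achieving sensitivity >= target; PPV is
    evaluated there. Ties break toward higher specificity, then lower
    candidate index. Candidates that never reach the target sensitivity
    are scored at their maximal-sensitivity threshold and flagged.
    """
    rows = []
    for i, (model, scores, labels) in enumerate(candidates):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=int)
        thresholds = np.unique(scores)
        best = None
        flagged = False
        feasible = [
            t for t in thresholds if _op_at_threshold(scores, labels, t)[0] >= target_sensitivity
        ]
        if feasible:
            t = max(feasible)
        else:
            flagged = True
            t = max(thresholds, key=lambda t: (_op_at_threshold(scores, labels, t)[0], t))
        sens, spec, ppv = _op_at_threshold(scores, labels, t)
        best = (t, sens, spec, ppv)
        rows.append(
            {
                "index": i,
                "model": model,
                "threshold": best[0],
                "sensitivity": best[1],
                "specificity": best[2],
                "ppv": best[3],
                "flagged": flagged,
            }
        )
    table = pd.DataFrame(rows)
    ranked = sorted(rows, key=lambda r: (-r["ppv"], -r["specificity"], r["index"]))
    top = ranked[0]
    if isinstance(top["model"], MILModel):
        top["model"].threshold = float(top["threshold"])
    return SelectionResult(
        model=top["model"],
        index=top["index"],
        threshold=float(top["threshold"]),
        ppv=float(top["ppv"]),
        sensitivity=float(top["sensitivity"]),
        specificity=float(top["specificity"]),
        flagged=bool(top["flagged"]),
        table=table.drop(columns="model"),
    )


# ---------------------------------------------------------------------------
# heatmaps


def attention_heatmap(prediction: SlidePrediction, slide_shape: tuple[int, int]) -> np.ndarray:
    """Raster of max-normalized attention weights over tile footprints.

    ``slide_shape`` is (height, width). Each tile footprint is filled
    with weight / max(weights); area outside any tile stays 0.
    """
    h, w = slide_shape
    canvas = np.zeros((h, w), dtype=np.float64)
    wmax = float(prediction.attention_weights.max())
    for ref, a in zip(prediction.tiles, prediction.attention_weights):
        canvas[ref.y : ref.y + ref.size, ref.x : ref.x + ref.size] = a / wmax
    return canvas


def save_heatmap_png(heatmap: np.ndarray, path) -> None:
    from PIL import Image

    img = Image.fromarray(np.clip(np.round(heatmap * 255), 0, 255).astype(np.uint8), mode="L")
    img.save(path)
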