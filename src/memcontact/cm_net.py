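"""MCP-augmented residual contact-map network at configurable scale.

Per-residue (1-D) features — PSSM, SS3, SA and the predicted MCP — pass
through a small 1-D convolutional residual stack (kernel 17), are lifted
to residue pairs by concatenating the feature vectors at i, j and the
midpoint ⌊(i+j)/2⌋, joined with the 2-D pair channels (coevolution
scores, averaged pairwise potential, mutual information), and fed to a
stack of 2-D residual blocks (5×5 kernels, two convolutions and two
activations per block with an identity shortcut).  A sigmoid keeps the
output in [0, 1]; the final map is symmetrized as (M + Mᵀ)/2 with a zero
diagonal.

Depth is a parameter: the default desk scale uses 6 blocks (12 conv
layers); the full-scale architecture (60 layers) is the same code with a
larger block count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, concat, parameter, zeros_param
from .contacts import map_pcc, topk_precision
from .types import BANDS, ContactMap, MemcontactError, RangeBand

#: all evaluable separations (the near-diagonal |i-j| < 6 is excluded
#: everywhere: from the loss, the training curve, and evaluation)
ALL_RANGE = RangeBand("all", 6, 10 ** 9)
MIN_SEPARATION = 6


@dataclass
class PairFeatureTensor:
    """1-D features, 2-D channels, and the manifest describing them."""

    f1d: np.ndarray  # (L, C1)
    f2d: np.ndarray  # (L, L, C2)
    manifest_1d: list
    manifest_2d: list

    def __post_init__(self):
        self.f1d = np.asarray(self.f1d, dtype=float)
        self.f2d = np.asarray(self.f2d, dtype=float)
        L = self.f1d.shape[0]
        if self.f2d.shape[:2] != (L, L):
            raise MemcontactError("2D channels must be L×L")
        if len(self.manifest_1d) != self.f1d.shape[1]:
            raise MemcontactError("1D manifest does not match channel count")
        if len(self.manifest_2d) != self.f2d.shape[2]:
            raise MemcontactError("2D manifest does not match channel count")
        for c in range(self.f2d.shape[2]):
            if not np.allclose(self.f2d[:, :, c], self.f2d[:, :, c].T):
                raise MemcontactError(f"2D channel {self.manifest_2d[c]} not symmetric")

    @property
    def length(self) -> int:
        return self.f1d.shape[0]

    @property
    def n_channels(self) -> int:
        """Channel count of the lifted pair tensor: 3·C1 + C2."""
        return 3 * self.f1d.shape[1] + self.f2d.shape[2]

    @property
    def tensor(self) -> np.ndarray:
        """Materialized L×L×C pair tensor (i, j, midpoint lifting + 2D)."""
        L = self.length
        i_idx = np.repeat(np.arange(L), L)
        j_idx = np.tile(np.arange(L), L)
        m_idx = (i_idx + j_idx) // 2
        lifted = np.concatenate(
            [self.f1d[i_idx], self.f1d[j_idx], self.f1d[m_idx]], axis=1
        ).reshape(L, L, -1)
        return np.concatenate([lifted, self.f2d], axis=2)

    def drop_1d_channel(self, name: str) -> "PairFeatureTensor":
        """Ablate a 1-D channel by manifest name (e.g. the MCP column)."""
        keep = [i for i, n in enumerate(self.manifest_1d) if n != name]
        if len(keep) == len(self.manifest_1d):
            raise MemcontactError(f"no 1D channel named {name!r}")
        return PairFeatureTensor(
            f1d=self.f1d[:, keep], f2d=self.f2d,
            manifest_1d=[self.manifest_1d[i] for i in keep],
            manifest_2d=list(self.manifest_2d),
        )

    def manifest(self) -> dict:
        return {"1d": list(self.manifest_1d), "2d": list(self.manifest_2d)}


def assemble_pair_features(
    f1d: np.ndarray,
    f2d: Sequence[np.ndarray],
    manifest_1d: Optional[Sequence[str]] = None,
    manifest_2d: Optional[Sequence[str]] = None,
) -> PairFeatureTensor:
    """Bundle per-residue features and L×L channels into a pair tensor."""
    f1d = np.asarray(f1d, dtype=float)
    L = f1d.shape[0]
    channels = []
    for c, ch in enumerate(f2d):
        ch = np.asarray(ch, dtype=float)
        if ch.shape != (L, L):
            raise MemcontactError(f"2D channel {c} has shape {ch.shape}, need ({L},{L})")
        channels.append(ch)
    stack = np.stack(channels, axis=2) if channels else np.zeros((L, L, 0))
    if manifest_1d is None:
        manifest_1d = [f"f1d_{i}" for i in range(f1d.shape[1])]
    if manifest_2d is None:
        manifest_2d = [f"f2d_{i}" for i in range(stack.shape[2])]
    return PairFeatureTensor(
        f1d=f1d, f2d=stack,
        manifest_1d=list(manifest_1d), manifest_2d=list(manifest_2d),
    )


@dataclass
class ResNetConfig:
    n_1d_layers: int = 2
    kernel_1d: int = 17
    hidden_1d: int = 16
    n_2d_blocks: int = 6  # two conv layers per block; 30 blocks = full scale
    kernel_2d: int = 5
    hidden_2d: int = 16
    instance_norm: bool = True
    learning_rate: float = 3e-3
    epochs: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.kernel_1d % 2 == 0 or self.kernel_2d % 2 == 0:
            raise MemcontactError("kernels must be odd")
        if min(self.n_1d_layers, self.n_2d_blocks) < 1:
            raise MemcontactError("layer counts must be >= 1")


def init_cm_params(config: ResNetConfig, c1_in: int, c2_in: int) -> dict:
    rng = np.random.default_rng(config.seed)
    params = {}
    k1, h1 = config.kernel_1d, config.hidden_1d
    params["c1d_0_W"] = parameter(rng, (k1 * c1_in, h1))
    params["c1d_0_b"] = zeros_param((h1,))
    for layer in range(1, config.n_1d_layers):
        params[f"c1d_{layer}_W"] = parameter(rng, (k1 * h1, h1))
        params[f"c1d_{layer}_b"] = zeros_param((h1,))
    k2, h2 = config.kernel_2d, config.hidden_2d
    d_in = 3 * h1 + c2_in
    params["proj_W"] = parameter(rng, (k2 * k2 * d_in, h2))
    params["proj_b"] = zeros_param((h2,))
    for blk in range(config.n_2d_blocks):
        for sub in (0, 1):
            params[f"blk{blk}_{sub}_W"] = parameter(rng, (k2 * k2 * h2, h2))
            params[f"blk{blk}_{sub}_b"] = zeros_param((h2,))
    params["head_W"] = parameter(rng, (h2, 1))
    params["head_b"] = zeros_param((1,))
    return params


def _unfold_1d(t: Tensor, k: int) -> Tensor:
    """(L, C) → (L, k·C) same-padded windows, differentiable."""
    L, C = t.shape
    zero = Tensor(np.zeros((1, C)))
    padded = concat([t, zero], axis=0)  # row L is the zero pad
    half = k // 2
    pos = np.arange(L)[:, None] + np.arange(-half, half + 1)[None, :]
    idx = np.where((pos < 0) | (pos >= L), L, pos)  # OOB → zero row
    return padded.gather_rows(idx.ravel()).reshape(L, k * C)


def _unfold_2d_indices(L: int, k: int) -> np.ndarray:
    """Flat neighbor indices for a k×k window on an L×L grid; OOB → L²."""
    half = k // 2
    ii = np.repeat(np.arange(L), L)
    jj = np.tile(np.arange(L), L)
    offsets = [(di, dj) for di in range(-half, half + 1)
               for dj in range(-half, half + 1)]
    cols = []
    for di, dj in offsets:
        ni, nj = ii + di, jj + dj
        flat = ni * L + nj
        flat = np.where((ni < 0) | (ni >= L) | (nj < 0) | (nj >= L), L * L, flat)
        cols.append(flat)
    return np.stack(cols, axis=1)  # (L², k²)


def _conv2d(t: Tensor, idx: np.ndarray, W: Tensor, b: Tensor, k: int) -> Tensor:
    """5×5 (or k×k) convolution on (L², C) rows via gather + matmul."""
    n, C = t.shape
    zero = Tensor(np.zeros((1, C)))
    padded = concat([t, zero], axis=0)
    cols = padded.gather_rows(idx.ravel()).reshape(n, k * k * C)
    return cols @ W + b


def _instance_norm(t: Tensor, eps: float = 1e-5) -> Tensor:
    m = t.mean(axis=0, keepdims=True)
    d = t - m
    v = d.pow(2.0).mean(axis=0, keepdims=True)
    return d * (v + eps).pow(-0.5)


def resnet_forward(
    pft: PairFeatureTensor,
    params: dict,
    config: ResNetConfig,
    return_tensor: bool = False,
):
    """Forward pass; returns a symmetric, zero-diagonal ContactMap.

    With ``return_tensor=True`` the per-pair symmetrized probability
    Tensor over the strict upper triangle is returned alongside, for
    training.
    """
    L = pft.length
    # 1-D residual stack
    y = (_unfold_1d(Tensor(pft.f1d), config.kernel_1d) @ params["c1d_0_W"]
         + params["c1d_0_b"]).relu()
    for layer in range(1, config.n_1d_layers):
        t = (_unfold_1d(y, config.kernel_1d) @ params[f"c1d_{layer}_W"]
             + params[f"c1d_{layer}_b"]).relu()
        y = y + t
    # lift to pairs: concat features at i, j, midpoint; append 2D channels
    i_idx = np.repeat(np.arange(L), L)
    j_idx = np.tile(np.arange(L), L)
    m_idx = (i_idx + j_idx) // 2
    pair = concat(
        [y.gather_rows(i_idx), y.gather_rows(j_idx), y.gather_rows(m_idx),
         Tensor(pft.f2d.reshape(L * L, -1))],
        axis=1,
    )
    idx = _unfold_2d_indices(L, config.kernel_2d)
    z = _conv2d(pair, idx, params["proj_W"], params["proj_b"], config.kernel_2d).relu()
    for blk in range(config.n_2d_blocks):
        t = z.relu()
        if config.instance_norm:
            t = _instance_norm(t)
        t = _conv2d(t, idx, params[f"blk{blk}_0_W"], params[f"blk{blk}_0_b"],
                    config.kernel_2d).relu()
        t = _conv2d(t, idx, params[f"blk{blk}_1_W"], params[f"blk{blk}_1_b"],
                    config.kernel_2d)
        z = z + t
    logits = z @ params["head_W"] + params["head_b"]  # (L², 1)
    probs = logits.sigmoid()

    iu, ju = np.triu_indices(L, k=1)
    upper = probs.gather_rows(iu * L + ju)
    lower = probs.gather_rows(ju * L + iu)
    sym_upper = (upper + lower) * 0.5  # (n_pairs, 1)

    values = np.zeros((L, L))
    values[iu, ju] = sym_upper.data.ravel()
    values = values + values.T
    cm = ContactMap(values=values, kind="predicted")
    if return_tensor:
        return cm, sym_upper
    return cm


def bce_loss_upper(sym_upper: Tensor, native: ContactMap,
                   min_sep: int = MIN_SEPARATION, eps: float = 1e-7) -> Tensor:
    """Binary cross-entropy over upper-triangle pairs with |i-j| >= min_sep."""
    L = native.size
    iu, ju = np.triu_indices(L, k=1)
    keep = (ju - iu) >= min_sep
    if not keep.any():
        raise MemcontactError("no pairs at or beyond the minimum separation")
    p = sym_upper.gather_rows(np.flatnonzero(keep))
    t = Tensor(native.values[iu[keep], ju[keep]][:, None])
    one = Tensor(np.ones_like(t.data))
    loss = -(t * (p + eps).log() + (one - t) * (one - p + eps).log())
    return loss.mean()


def train_cm(dataset: Sequence, config: ResNetConfig) -> tuple:
    """Train on (PairFeatureTensor, native ContactMap) pairs.

    Adam, batch size 1, seeded.  Returns (params, history) where history
    holds the per-epoch mean training top-L/10 precision (separation >= 6).
    """
    if not dataset:
        raise MemcontactError("empty contact-map training set")
    c1_in = dataset[0][0].f1d.shape[1]
    c2_in = dataset[0][0].f2d.shape[2]
    params = init_cm_params(config, c1_in, c2_in)
    opt = Adam(params, lr=config.learning_rate)
    history = {"train_top_l10": [], "train_loss": []}
    for _epoch in range(config.epochs):
        precs, losses = [], []
        for pft, native in dataset:
            opt.zero_grad()
            cm, sym_upper = resnet_forward(pft, params, config, return_tensor=True)
            obj = bce_loss_upper(sym_upper, native)
            obj.backward()
            opt.step()
            losses.append(float(obj.data))
            prec = topk_precision(cm, native, k=10, band=ALL_RANGE)
            if prec is not None:
                precs.append(prec)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_top_l10"].append(float(np.mean(precs)) if precs else None)
    return params, history


def predict_cm(pft: PairFeatureTensor, params: dict, config: ResNetConfig) -> ContactMap:
    return resnet_forward(pft, params, config)


def evaluate_cm(
    preds: Sequence[ContactMap],
    natives: Sequence[ContactMap],
    ks: tuple = (10, 5, 2, 1),
    bands: tuple = ("short", "medium", "long"),
) -> dict:
    """Mean top-L/k precision per (band, k) plus mean whole-map PCC."""
    if len(preds) != len(natives):
        raise MemcontactError("prediction and native lists differ in length")
    report = {}
    for band in bands:
        for k in ks:
            vals = [
                topk_precision(p, n, k=k, band=band) for p, n in zip(preds, natives)
            ]
            vals = [v for v in vals if v is not None]
            report[(band, k)] = float(np.mean(vals)) if vals else None
    pccs = [map_pcc(p, n) for p, n in zip(preds, natives)]
    pccs = [v for v in pccs if v is not None]
    report["map_pcc"] = float(np.mean(pccs)) if pccs else None
    return report


def report_to_tsv(report: dict) -> str:
    lines = ["band\tk\tprecision"]
    for key, val in report.items():
        if key == "map_pcc":
            continue
        band, k = key
        cell = "" if val is None else f"{val:.4f}"
        lines.append(f"{band}\tL/{k}\t{cell}")
    pcc = report.get("map_pcc")
    cell = "" if pcc is None else f"{pcc:.4f}"
    lines.append(f"map_pcc\t\t{cell}")
    return "\n".join(lines) + "\n"
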