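"""Sequence-based MCP prediction: a small convolutional-recurrent network.

Per-residue features (3-state secondary structure, 3-state solvent
accessibility, 20-column PSSM → 26 columns) pass through three parallel
1-D convolutions (kernels 3/7/9) for local context, a bidirectional GRU
for global context, and a per-position affine head squashed by a sigmoid
so predictions stay in [0, 1].  Training minimizes the masked residual
sum of squares plus an L2 penalty on the parameters, with Adam at batch
size 1.

The recurrence runs over the true (masked) sequence length, never over
padding, which is what makes predictions exactly padding-invariant.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Adam, Tensor, concat, l2_penalty, parameter, zeros_param
from .types import MemcontactError, UNDEFINED

logger = logging.getLogger(__name__)

N_FEATURES = 26  # 3 SS3 + 3 SA3 + 20 PSSM
DEFAULT_PAD_LEN = 700


@dataclass
class FeatureMatrix1D:
    """pad_len × 26 feature block with a validity mask.

    Column order is fixed: [SS3 | SA3 | PSSM].  Rows beyond the sequence
    length are zero and masked off.
    """

    matrix: np.ndarray
    mask: np.ndarray
    pad_len: int = DEFAULT_PAD_LEN

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.matrix.shape != (self.pad_len, N_FEATURES):
            raise MemcontactError(
                f"feature matrix must be {self.pad_len}×{N_FEATURES}"
            )
        if self.mask.shape != (self.pad_len,):
            raise MemcontactError("mask length must equal pad_len")
        if np.any(self.matrix[~self.mask] != 0):
            raise MemcontactError("padded rows must be zero")

    @property
    def length(self) -> int:
        return int(self.mask.sum())

    @property
    def valid(self) -> np.ndarray:
        return self.matrix[: self.length]


def build_features(ss3: np.ndarray, sa3: np.ndarray, pssm: np.ndarray,
                   pad_len: int = DEFAULT_PAD_LEN) -> FeatureMatrix1D:
    """Concatenate [SS3 | SA3 | PSSM] per residue and zero-pad to pad_len."""
    ss3, sa3, pssm = (np.asarray(a, dtype=float) for a in (ss3, sa3, pssm))
    L = len(ss3)
    if len(sa3) != L or len(pssm) != L:
        raise MemcontactError("feature blocks disagree on residue count")
    if ss3.shape[1] != 3 or sa3.shape[1] != 3 or pssm.shape[1] != 20:
        raise MemcontactError("feature blocks must be L×3, L×3, L×20")
    if L > pad_len:
        raise MemcontactError(f"sequence length {L} exceeds pad_len {pad_len}")
    mat = np.zeros((pad_len, N_FEATURES))
    mat[:L] = np.hstack([ss3, sa3, pssm])
    mask = np.zeros(pad_len, dtype=bool)
    mask[:L] = True
    return FeatureMatrix1D(matrix=mat, mask=mask, pad_len=pad_len)


@dataclass
class DCRNNConfig:
    conv_kernels: tuple = (3, 7, 9)
    conv_channels: int = 64
    rnn_hidden: int = 64
    l2_weight: float = 1e-5
    learning_rate: float = 1e-3
    epochs: int = 50
    batch_size: int = 1
    seed: int = 0
    pad_len: int = DEFAULT_PAD_LEN
    output_squash: str = "sigmoid"  # or "clamp"

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.conv_kernels):
            raise MemcontactError("conv kernels must be odd")
        if self.conv_channels <= 0 or self.rnn_hidden <= 0:
            raise MemcontactError("channels and hidden size must be positive")
        if self.l2_weight < 0:
            raise MemcontactError("l2 weight must be non-negative")


def init_params(config: DCRNNConfig) -> dict:
    """Seeded Glorot-initialized parameter dict for the DCRNN."""
    rng = np.random.default_rng(config.seed)
    params = {}
    for k in config.conv_kernels:
        params[f"conv{k}_W"] = parameter(rng, (k * N_FEATURES, config.conv_channels))
        params[f"conv{k}_b"] = zeros_param((config.conv_channels,))
    d_in = len(config.conv_kernels) * config.conv_channels
    H = config.rnn_hidden
    for direction in ("f", "b"):
        for gate in ("z", "r", "n"):
            params[f"gru_{direction}_W{gate}"] = parameter(rng, (d_in, H))
            params[f"gru_{direction}_U{gate}"] = parameter(rng, (H, H))
            params[f"gru_{direction}_b{gate}"] = zeros_param((H,))
    params["head_W"] = parameter(rng, (2 * H, 1))
    params["head_b"] = zeros_param((1,))
    return params


def _im2col_1d(x: np.ndarray, k: int) -> np.ndarray:
    """Unfold a zero same-padded (L, C) array into (L, k*C) windows."""
    L, C = x.shape
    half = k // 2
    padded = np.zeros((L + 2 * half, C))
    padded[half: half + L] = x
    return np.concatenate([padded[i: i + L] for i in range(k)], axis=1)


def _gru_direction(xs: Tensor, params: dict, prefix: str, H: int) -> Tensor:
    """Run a GRU over the rows of xs (L, D); returns (L, H) hidden states."""
    L = xs.shape[0]
    Wz, Uz, bz = params[f"{prefix}_Wz"], params[f"{prefix}_Uz"], params[f"{prefix}_bz"]
    Wr, Ur, br = params[f"{prefix}_Wr"], params[f"{prefix}_Ur"], params[f"{prefix}_br"]
    Wn, Un, bn = params[f"{prefix}_Wn"], params[f"{prefix}_Un"], params[f"{prefix}_bn"]
    h = Tensor(np.zeros((1, H)))
    out = []
    for t in range(L):
        x_t = xs[t: t + 1]
        z = (x_t @ Wz + h @ Uz + bz).sigmoid()
        r = (x_t @ Wr + h @ Ur + br).sigmoid()
        n = (x_t @ Wn + (r * h) @ Un + bn).tanh()
        h = (1.0 - z) * n + z * h
        out.append(h)
    return concat(out, axis=0)


def forward_graph(features: FeatureMatrix1D, params: dict, config: DCRNNConfig) -> Tensor:
    """Differentiable forward pass over the unpadded length; output (L, 1)."""
    x = features.valid
    conv_outs = []
    for k in config.conv_kernels:
        cols = Tensor(_im2col_1d(x, k))
        conv_outs.append((cols @ params[f"conv{k}_W"] + params[f"conv{k}_b"]).relu())
    h_in = concat(conv_outs, axis=1)
    hf = _gru_direction(h_in, params, "gru_f", config.rnn_hidden)
    # backward direction: reverse rows, run, reverse back
    L = features.length
    rev = np.arange(L - 1, -1, -1)
    hb = _gru_direction(h_in.gather_rows(rev), params, "gru_b",
                        config.rnn_hidden).gather_rows(rev)
    h = concat([hf, hb], axis=1)
    y = h @ params["head_W"] + params["head_b"]
    if config.output_squash == "sigmoid":
        return y.sigmoid()
    # clamp alternative: y - relu(y-1) + relu(-y) pins the output to [0, 1]
    return y - (y - 1.0).relu() + (-y).relu()


def predict(features: FeatureMatrix1D, params: dict, config: DCRNNConfig) -> np.ndarray:
    """Per-residue MCP prediction in [0, 1], length = true sequence length."""
    return forward_graph(features, params, config).data.ravel().copy()


def loss(pred, obs, mask=None, params: Optional[dict] = None, l2_weight: float = 0.0):
    """Masked residual sum of squares + λ·Σ params².

    Accepts numpy arrays (returns float) or Tensors (returns a Tensor node
    for backpropagation).
    """
    if isinstance(pred, Tensor):
        diff = pred.reshape(-1) - Tensor(np.asarray(obs, dtype=float).ravel())
        if mask is not None:
            diff = diff * Tensor(np.asarray(mask, dtype=float).ravel())
        total = diff.pow(2.0).sum()
        if params is not None and l2_weight > 0:
            total = total + l2_weight * l2_penalty(params)
        return total
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    sq = (pred - obs) ** 2
    if mask is not None:
        sq = sq[np.asarray(mask, dtype=bool).ravel()]
    total = float(sq.sum())
    if params is not None and l2_weight > 0:
        total += l2_weight * float(sum((p.data ** 2).sum() for p in params.values()))
    return total


def records_to_dataset(records: Sequence, pad_len: int = DEFAULT_PAD_LEN) -> list:
    """TrainingRecords → (FeatureMatrix1D, target) pairs."""
    return [
        (build_features(r.ss3, r.sa3, r.pssm, pad_len=pad_len), r.target)
        for r in records
    ]


def train(
    dataset: Sequence,
    config: DCRNNConfig,
    val: Optional[Sequence] = None,
) -> tuple:
    """Train the DCRNN; returns (params, history).

    ``dataset`` holds (FeatureMatrix1D, target) pairs.  history has
    per-epoch mean train MSE (and val MSE when a validation set is given).
    """
    if not dataset:
        raise MemcontactError("empty training set")
    params = init_params(config)
    opt = Adam(params, lr=config.learning_rate)
    history = {"train_mse": [], "val_mse": []}
    for _epoch in range(config.epochs):
        sq_sum, n_res = 0.0, 0
        for feats, target in dataset:
            opt.zero_grad()
            pred = forward_graph(feats, params, config)
            obj = loss(pred, target, params=params, l2_weight=config.l2_weight)
            obj.backward()
            opt.step()
            sq_sum += loss(pred.data.ravel(), target)
            n_res += len(target)
        history["train_mse"].append(sq_sum / n_res)
        if val:
            v_sq, v_n = 0.0, 0
            for feats, target in val:
                p = predict(feats, params, config)
                v_sq += loss(p, target)
                v_n += len(target)
            history["val_mse"].append(v_sq / v_n)
    return params, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _pcc(a: np.ndarray, b: np.ndarray):
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return UNDEFINED
    return float(np.corrcoef(a, b)[0, 1])


def evaluate(
    pred_profiles: Sequence[np.ndarray],
    obs_profiles: Sequence[np.ndarray],
    ss_labels: Sequence[str],
    per_protein: bool = False,
) -> dict:
    """MSE and PCC overall and per secondary-structure class (H/E/C).

    Default pools residues across proteins; ``per_protein=True`` instead
    averages per-protein PCCs (both conventions are defensible, so both
    are available).  Undefined correlations (zero variance, <2 residues)
    are reported as None, never as NaN.
    """
    preds = [np.asarray(p, dtype=float) for p in pred_profiles]
    obss = [np.asarray(o, dtype=float) for o in obs_profiles]
    for p, o, s in zip(preds, obss, ss_labels):
        if not (len(p) == len(o) == len(s)):
            raise MemcontactError("profile/label length mismatch")

    table = {}
    scopes = {"overall": None, "H": "H", "E": "E", "C": "C"}
    for scope, label in scopes.items():
        if per_protein and scope == "overall":
            pccs = [
                _pcc(p, o) for p, o in zip(preds, obss)
            ]
            pccs = [x for x in pccs if x is not UNDEFINED]
            mse_all = np.concatenate([(p - o) ** 2 for p, o in zip(preds, obss)])
            table[scope] = {
                "mse": float(mse_all.mean()),
                "pcc": float(np.mean(pccs)) if pccs else UNDEFINED,
                "n": int(sum(len(p) for p in preds)),
            }
            continue
        sel_p, sel_o = [], []
        for p, o, s in zip(preds, obss, ss_labels):
            keep = np.ones(len(p), dtype=bool) if label is None else \
                np.array([c == label for c in s])
            sel_p.append(p[keep])
            sel_o.append(o[keep])
        cat_p = np.concatenate(sel_p) if sel_p else np.array([])
        cat_o = np.concatenate(sel_o) if sel_o else np.array([])
        table[scope] = {
            "mse": float(((cat_p - cat_o) ** 2).mean()) if len(cat_p) else UNDEFINED,
            "pcc": _pcc(cat_p, cat_o),
            "n": int(len(cat_p)),
        }
    return table


def kfold(records: Sequence, k: int = 10, config: DCRNNConfig = None,
          seed: int = 0) -> dict:
    """Seeded k-fold cross-validation over TrainingRecords.

    Returns per-fold metric tables plus the mean/SD of the overall PCC
    and MSE across folds.
    """
    if config is None:
        config = DCRNNConfig()
    if k > len(records):
        raise MemcontactError("k exceeds dataset size")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(records))
    folds = np.array_split(perm, k)
    tables = []
    for f, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_recs = [records[i] for i in perm if i not in test_set]
        test_recs = [records[i] for i in test_idx]
        params, _ = train(records_to_dataset(train_recs), config)
        preds = [
            predict(build_features(r.ss3, r.sa3, r.pssm, pad_len=config.pad_len),
                    params, config)
            for r in test_recs
        ]
        tables.append(evaluate(preds, [r.target for r in test_recs],
                               [r.ss_labels for r in test_recs]))
    pccs = [t["overall"]["pcc"] for t in tables if t["overall"]["pcc"] is not UNDEFINED]
    mses = [t["overall"]["mse"] for t in tables]
    return {
        "folds": tables,
        "mean_pcc": float(np.mean(pccs)) if pccs else UNDEFINED,
        "sd_pcc": float(np.std(pccs)) if pccs else UNDEFINED,
        "mean_mse": float(np.mean(mses)),
        "sd_mse": float(np.std(mses)),
    }


# ---------------------------------------------------------------------------
# per-protein feature tables (TSV: residue rows, 26 feature columns + SS)
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = (
    ["ss3_H", "ss3_E", "ss3_C", "sa3_B", "sa3_M", "sa3_E"]
    + [f"pssm_{a}" for a in "ACDEFGHIKLMNPQRSTVWY"]
)


def features_to_tsv(ss3, sa3, pssm, ss_labels: str) -> str:
    block = np.hstack([np.asarray(ss3, float), np.asarray(sa3, float),
                       np.asarray(pssm, float)])
    lines = ["resid\tss\t" + "\t".join(_FEATURE_COLUMNS)]
    for i, row in enumerate(block):
        cells = "\t".join(f"{v:.6f}" for v in row)
        lines.append(f"{i + 1}\t{ss_labels[i]}\t{cells}")
    return "\n".join(lines) + "\n"


def features_from_tsv(text: str) -> tuple:
    """Returns (FeatureMatrix1D, ss_labels)."""
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    ss_labels = "".join(r[1] for r in rows)
    block = np.array([[float(v) for v in r[2:]] for r in rows])
    return build_features(block[:, :3], block[:, 3:6], block[:, 6:]), ss_labels


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar of config and seed
# ---------------------------------------------------------------------------

def save_checkpoint(params: dict, config: DCRNNConfig, path: str) -> None:
    np.savez(path, **{k: p.data for k, p in params.items()})
    sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"config": config.__dict__ | {
            "conv_kernels": list(config.conv_kernels)}}, fh, indent=2)


def load_checkpoint(path: str) -> tuple:
    archive = np.load(path if path.endswith(".npz") else path + ".npz")
    params = {k: Tensor(archive[k], requires_grad=True) for k in archive.files}
    sidecar = (path[:-4] if path.endswith(".npz") else path) + ".json"
    with open(sidecar) as fh:
        raw = json.load(fh)["config"]
    raw["conv_kernels"] = tuple(raw["conv_kernels"])
    return params, DCRNNConfig(**raw)
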