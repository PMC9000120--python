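"""Contact-map construction, evaluation statistics, and MSA 2-D features.

Native contacts: two residues are in contact when their Cβ atoms (Cα for
glycine) are within 8 Å.  Predicted maps hold per-pair probabilities.
Evaluation follows the standard protocol: precision of the top L/k
predicted pairs (k = 10, 5, 2, 1), stratified by sequence separation into
short [6, 11], medium [12, 23] and long (>= 24) range; whole-map Pearson
correlation; and threshold classification metrics (normalized confusion
matrix, accuracy, AUC) at a 0.5 cutoff.

The two MSA-derived pair features the contact network consumes are also
implemented here: column mutual information (21 symbols, add-one
pseudocount, optional APC correction) and the averaged pairwise contact
potential across alignment columns.
"""

from __future__ import annotations

import io
import logging
import math
from typing import Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .types import (
    BANDS,
    ContactMap,
    LengthMismatchError,
    LONG_RANGE,
    MSA,
    MemcontactError,
    RangeBand,
    StructureCoords,
    UNDEFINED,
)

logger = logging.getLogger(__name__)


def _values(cm: Union[ContactMap, np.ndarray]) -> np.ndarray:
    return cm.values if isinstance(cm, ContactMap) else np.asarray(cm, dtype=float)


def native_contact_map(structure: StructureCoords, cutoff: float = 8.0) -> ContactMap:
    """Binary contact map at a Cβ distance cutoff (Cα fallback for glycine)."""
    pts = structure.contact_atoms()
    d = cdist(pts, pts)
    values = (d <= cutoff).astype(float)
    np.fill_diagonal(values, 0.0)
    return ContactMap(values=values, kind="native")


def _band_pairs(L: int, band: RangeBand):
    iu, ju = np.triu_indices(L, k=1)
    keep = band.contains(ju - iu)
    return iu[keep], ju[keep]


def topk_precision(
    pred: Union[ContactMap, np.ndarray],
    native: Union[ContactMap, np.ndarray],
    k: int,
    band: Union[str, RangeBand] = LONG_RANGE,
):
    """Fraction of native contacts among the top floor(L/k) predicted pairs.

    Pairs are restricted to the separation band, ranked by predicted
    probability (ties broken lexicographically by (i, j) for determinism).
    Returns None when the band holds no pairs at this length.
    """
    if isinstance(band, str):
        band = BANDS[band]
    p = _values(pred)
    n = _values(native)
    if p.shape != n.shape:
        raise LengthMismatchError("prediction and native map sizes differ")
    L = p.shape[0]
    iu, ju = _band_pairs(L, band)
    if len(iu) == 0:
        return UNDEFINED
    take = L // k
    if take < 1:
        return UNDEFINED
    order = np.lexsort((ju, iu, -p[iu, ju]))[:take]
    return float(n[iu[order], ju[order]].sum() / len(order))


def map_pcc(
    pred: Union[ContactMap, np.ndarray],
    native: Union[ContactMap, np.ndarray],
    min_sep: int = 6,
):
    """Pearson correlation between maps over upper-triangle pairs.

    Near-diagonal pairs with separation below ``min_sep`` are excluded by
    default so trivially-correct neighbors don't inflate the correlation;
    pass min_sep=1 to include every off-diagonal pair.
    """
    p = _values(pred)
    n = _values(native)
    if p.shape != n.shape:
        raise LengthMismatchError("prediction and native map sizes differ")
    iu, ju = np.triu_indices(p.shape[0], k=max(min_sep, 1))
    a, b = p[iu, ju], n[iu, ju]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return UNDEFINED
    return float(np.corrcoef(a, b)[0, 1])


def relative_improvement(base: float, new: float) -> float:
    """Percent improvement 100·(new − base)/base."""
    if base == 0:
        raise MemcontactError("relative improvement undefined for base 0")
    return 100.0 * (new - base) / base


def classification_metrics(
    pred: Union[ContactMap, np.ndarray],
    native: Union[ContactMap, np.ndarray],
    cutoff: float = 0.5,
) -> dict:
    """Confusion matrix (rows normalized by true class), accuracy, and AUC.

    Computed over all upper-triangle pairs; predicted positive means
    probability >= cutoff.  AUC uses the rank statistic over all pairs and
    is None when the natives contain a single class.
    """
    p = _values(pred)
    n = _values(native)
    if p.shape != n.shape:
        raise LengthMismatchError("prediction and native map sizes differ")
    iu, ju = np.triu_indices(p.shape[0], k=1)
    scores, truth = p[iu, ju], n[iu, ju].astype(int)
    called = (scores >= cutoff).astype(int)

    cm = np.zeros((2, 2))
    for t in (0, 1):
        row_mask = truth == t
        total = row_mask.sum()
        for c in (0, 1):
            cm[t, c] = ((called == c) & row_mask).sum() / total if total else np.nan
    accuracy = float((called == truth).mean())
    auc = UNDEFINED if len(set(truth.tolist())) < 2 else float(
        roc_auc_score(truth, scores)
    )
    return {"confusion": cm, "accuracy": accuracy, "auc": auc}


# ---------------------------------------------------------------------------
# MSA-derived pair features
# ---------------------------------------------------------------------------

N_SYMBOLS = 21  # 20 amino acids + gap


def msa_mutual_information(msa: MSA, apc: bool = False) -> np.ndarray:
    """Column-pair mutual information with an add-one pseudocount.

    MI(i,j) = Σ_ab f_ab ln(f_ab / (f_a f_b)) over the 21-symbol alphabet,
    with joint frequencies smoothed by one pseudo-observation per cell and
    marginals taken from the smoothed joint.  Symmetric with a zero
    diagonal.  ``apc=True`` applies the average-product correction.
    Alignments with fewer than two rows return all zeros.
    """
    L = msa.length
    mi = np.zeros((L, L))
    if msa.depth < 2:
        return mi
    idx = msa.to_indices()
    N = msa.depth
    denom = N + N_SYMBOLS * N_SYMBOLS
    for i in range(L):
        for j in range(i + 1, L):
            joint = np.ones((N_SYMBOLS, N_SYMBOLS))
            np.add.at(joint, (idx[:, i], idx[:, j]), 1.0)
            f = joint / denom
            fa = f.sum(axis=1, keepdims=True)
            fb = f.sum(axis=0, keepdims=True)
            mi[i, j] = mi[j, i] = float((f * np.log(f / (fa * fb))).sum())
    if apc:
        off = ~np.eye(L, dtype=bool)
        col_mean = mi.sum(axis=0) / max(L - 1, 1)
        overall = mi[off].mean() if L > 1 else 0.0
        if overall != 0:
            mi = mi - np.outer(col_mean, col_mean) / overall
            np.fill_diagonal(mi, 0.0)
    return mi


def msa_pairwise_potential(
    msa: MSA,
    potential: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Average contact-potential term across two alignment columns.

    P(i,j) = mean over alignment rows of potential[a_ri, a_rj], skipping
    rows where either column is gapped.  Entries where every row is
    gapped are NaN (the undefined marker for matrix entries).
    """
    if potential is None:
        from .potentials import default_contact_potential

        potential = default_contact_potential()
    potential = np.asarray(potential, dtype=float)
    if potential.shape != (20, 20) or not np.allclose(potential, potential.T):
        raise MemcontactError("potential must be a symmetric 20×20 table")
    idx = msa.to_indices()
    L = msa.length
    out = np.full((L, L), np.nan)
    for i in range(L):
        for j in range(i, L):
            ai, aj = idx[:, i], idx[:, j]
            ok = (ai < 20) & (aj < 20)
            if ok.any():
                val = float(potential[ai[ok], aj[ok]].mean())
                out[i, j] = out[j, i] = val
    return out


# ---------------------------------------------------------------------------
# text I/O: score matrices and CASP RR contact files
# ---------------------------------------------------------------------------

def read_score_matrix(text: str, symmetrize: bool = True) -> np.ndarray:
    """Parse a whitespace-separated square matrix (coevolution-tool output)."""
    rows = [line.split() for line in text.strip().splitlines() if line.strip()]
    if not rows:
        raise MemcontactError("empty score matrix")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise MemcontactError("ragged rows in score matrix")
    mat = np.array([[float(v) for v in r] for r in rows])
    if mat.shape[0] != mat.shape[1]:
        raise MemcontactError(
            f"score matrix is not square: {mat.shape[0]}×{mat.shape[1]}"
        )
    if symmetrize and not np.allclose(mat, mat.T):
        logger.warning("asymmetric score matrix; symmetrizing by averaging")
        mat = (mat + mat.T) / 2.0
    return mat


def write_score_matrix(mat: np.ndarray, precision: int = 6) -> str:
    return "\n".join(
        " ".join(f"{v:.{precision}f}" for v in row) for row in np.asarray(mat)
    ) + "\n"


def write_rr(
    cm: Union[ContactMap, np.ndarray],
    sequence: Optional[str] = None,
    target: str = "T0000",
    min_prob: float = 0.0,
    d_min: float = 0.0,
    d_max: float = 8.0,
) -> str:
    """CASP RR export: header, optional sequence, 'i j d1 d2 p' (1-based)."""
    p = _values(cm)
    lines = ["PFRMAT RR", f"TARGET {target}", "MODEL 1"]
    if sequence:
        for s in range(0, len(sequence), 50):
            lines.append(sequence[s: s + 50])
    iu, ju = np.triu_indices(p.shape[0], k=1)
    order = np.lexsort((ju, iu, -p[iu, ju]))
    for o in order:
        prob = p[iu[o], ju[o]]
        if prob > min_prob:
            lines.append(f"{iu[o] + 1} {ju[o] + 1} {d_min:g} {d_max:g} {prob:.6f}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_rr(text: str, L: Optional[int] = None) -> ContactMap:
    """Parse a CASP RR file into a predicted contact map.

    When L is not given it is inferred from the embedded sequence lines
    or, failing that, the largest residue index.
    """
    seq_chars = []
    records = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.split()[0] in {"PFRMAT", "TARGET", "MODEL", "END",
                                           "REMARK", "AUTHOR", "METHOD"}:
            continue
        parts = line.split()
        if len(parts) >= 5:
            i, j = int(parts[0]), int(parts[1])
            records.append((i - 1, j - 1, float(parts[4])))
        elif len(parts) == 1 and parts[0].isalpha():
            seq_chars.append(parts[0])
    if L is None:
        L = len("".join(seq_chars)) or (max(j for _, j, _ in records) + 1)
    values = np.zeros((L, L))
    for i, j, prob in records:
        values[i, j] = values[j, i] = prob
    return ContactMap(values=values, kind="predicted")
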