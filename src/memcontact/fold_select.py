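"""Contact-driven structure model selection.

From a predicted contact map, the pipeline takes the top-xL pairs for
x = 0.1, 0.2, …, 4.0 as bounded distance restraints (3.5–8 Å), asks a
pluggable folding backend for 20 models per x, keeps the 5 best by the
backend's contact energy (lower is better) giving 200 models, ranks those
by the satisfaction score — the fraction of the top L/5 long-range
predicted contacts realized in the model — keeps the top 50, clusters
them by pairwise TM-score into 5 clusters, and returns each cluster's
medoid.  Quality against a reference is measured by Kabsch RMSD.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .contacts import topk_precision
from .types import (
    BackendError,
    ContactMap,
    LONG_RANGE,
    MemcontactError,
    ModelCandidate,
    RestraintSet,
    SelectionConfig,
    UNDEFINED,
    tm_d0,
)

logger = logging.getLogger(__name__)

MIN_SEPARATION = 6
RESTRAINT_D_MIN = 3.5
RESTRAINT_D_MAX = 8.0

_BACKENDS: dict = {}


def register_backend(name: str, fn: Callable) -> None:
    """Register a folding backend: fn(restraints, n, seed, length) -> models."""
    _BACKENDS[name] = fn


def select_top_xL_contacts(cm: ContactMap, x: float) -> list:
    """Top floor(x·L) upper-triangle pairs (|i−j| >= 6) by probability.

    Ties break lexicographically by (i, j); if x·L exceeds the available
    pairs, all of them are returned.
    """
    if x <= 0:
        raise MemcontactError("x must be positive")
    L = cm.size
    iu, ju = np.triu_indices(L, k=1)
    keep = (ju - iu) >= MIN_SEPARATION
    iu, ju = iu[keep], ju[keep]
    order = np.lexsort((ju, iu, -cm.values[iu, ju]))
    take = min(int(x * L), len(order))
    return [(int(iu[o]), int(ju[o])) for o in order[:take]]


def contacts_to_restraints(pairs: Sequence[tuple]) -> RestraintSet:
    """Each contact becomes a bounded-distance restraint (3.5, 8.0 Å)."""
    return RestraintSet(
        contacts=[(i, j, RESTRAINT_D_MIN, RESTRAINT_D_MAX) for (i, j) in pairs]
    )


def restraints_to_tsv(restraints: RestraintSet) -> str:
    lines = ["i\tj\td_min\td_max"]
    for (i, j, dmin, dmax) in restraints.contacts:
        lines.append(f"{i}\t{j}\t{dmin:g}\t{dmax:g}")
    return "\n".join(lines) + "\n"


def restraints_from_tsv(text: str) -> RestraintSet:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    return RestraintSet(
        contacts=[(int(r[0]), int(r[1]), float(r[2]), float(r[3])) for r in rows]
    )


def run_backend(
    restraints: RestraintSet,
    backend: str,
    n: int,
    seed: int = 0,
    length: Optional[int] = None,
) -> list:
    """Produce n scored model candidates from a registered backend."""
    if backend not in _BACKENDS:
        raise BackendError(backend, "backend not registered")
    try:
        models = _BACKENDS[backend](restraints, n, seed=seed, length=length)
    except MemcontactError:
        raise
    except Exception as exc:  # backend internals are opaque
        raise BackendError(backend, str(exc)) from exc
    for m in models:
        if not np.isfinite(m.backend_score):
            raise BackendError(backend, "non-finite backend score")
    return models


def per_x_select(groups: dict, keep: int = 5) -> list:
    """Per x group, keep the ``keep`` lowest-energy models.

    Lower backend_score = better (contact energy).  Ties break by
    provenance (replicate index) for determinism.
    """
    retained = []
    for x in sorted(groups):
        models = groups[x]
        if not models:
            raise MemcontactError(f"empty model group for x={x}")
        ranked = sorted(models, key=lambda m: (m.backend_score, m.provenance))
        retained.extend(ranked[: keep])
    return retained


def satisfaction_score(
    model: ModelCandidate,
    cm: ContactMap,
    k: int = 5,
    band=LONG_RANGE,
    cutoff: float = 8.0,
):
    """Fraction of the top L/k long-range predicted contacts realized in the
    model (Cβ distance <= cutoff, Cα for glycine).  None when the map has
    no long-range predictions at this length."""
    if len(model) != cm.size:
        raise MemcontactError("model length does not match contact map")
    model_native = _model_contact_values(model, cutoff)
    return topk_precision(cm.values, model_native, k=k, band=band)


def _model_contact_values(model: ModelCandidate, cutoff: float) -> np.ndarray:
    from .contacts import native_contact_map

    return native_contact_map(model.structure(), cutoff=cutoff).values


# ---------------------------------------------------------------------------
# superposition-based scores
# ---------------------------------------------------------------------------

def _kabsch_rotation(P: np.ndarray, Q: np.ndarray):
    """Optimal proper rotation R and translation mapping P onto Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return R, qc - R @ pc


def kabsch_rmsd(model: Union[ModelCandidate, np.ndarray],
                reference: Union[ModelCandidate, np.ndarray]) -> float:
    """Minimal least-squares Cα RMSD after optimal rigid superposition."""
    P = model.coords if isinstance(model, ModelCandidate) else np.asarray(model, float)
    Q = (reference.coords if isinstance(reference, ModelCandidate)
         else np.asarray(reference, float))
    if P.shape != Q.shape:
        raise MemcontactError("structures differ in length")
    if len(P) < 3:
        raise MemcontactError("need at least 3 residues")
    R, t = _kabsch_rotation(P, Q)
    moved = P @ R.T + t
    return float(np.sqrt(((moved - Q) ** 2).sum() / len(P)))


def tm_score(a: Union[ModelCandidate, np.ndarray],
             b: Union[ModelCandidate, np.ndarray]) -> float:
    """TM-score between two equal-length Cα traces (fixed correspondence).

    d0 = max(0.5, 1.24·(L−15)^(1/3) − 1.8); normalization uses the common
    length, so the score is symmetric.  Superposition starts from the
    full-length least-squares fit and iteratively refits on the residues
    currently within d0 of their counterparts until the included set is
    stable; the maximum score over iterations is returned.
    """
    P = a.coords if isinstance(a, ModelCandidate) else np.asarray(a, float)
    Q = b.coords if isinstance(b, ModelCandidate) else np.asarray(b, float)
    if P.shape != Q.shape:
        raise MemcontactError("structures differ in length")
    L = len(P)
    if L < 3:
        raise MemcontactError("need at least 3 residues")
    d0 = tm_d0(L)

    def score_for(subset: np.ndarray):
        R, t = _kabsch_rotation(P[subset], Q[subset])
        d = np.linalg.norm(P @ R.T + t - Q, axis=1)
        return float((1.0 / (1.0 + (d / d0) ** 2)).mean()), d

    subset = np.arange(L)
    best, d = score_for(subset)
    seen = {subset.tobytes()}
    for _ in range(50):
        new = np.flatnonzero(d < max(d0, 3.0))
        if len(new) < 3 or new.tobytes() in seen:
            break
        seen.add(new.tobytes())
        s, d = score_for(new)
        best = max(best, s)
        subset = new
    return best


def cluster_models(models: Sequence[ModelCandidate], k: int = 5) -> list:
    """Average-linkage clustering on (1 − TM-score), cut at k clusters.

    Returns a list of (member indices, medoid index) per cluster, ordered
    by smallest member index.  The medoid maximizes the mean TM-score to
    its cluster mates (ties: smaller index).  Deterministic given input
    order.
    """
    n = len(models)
    if n < k:
        raise MemcontactError(f"cannot make {k} clusters from {n} models")
    tm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            tm[i, j] = tm[j, i] = tm_score(models[i], models[j])
    dist = 1.0 - tm
    np.fill_diagonal(dist, 0.0)
    if n == k:
        assignments = np.arange(1, n + 1)
    else:
        Z = linkage(squareform(dist, checks=False), method="average")
        assignments = fcluster(Z, t=k, criterion="maxclust")
    clusters = []
    for label in sorted(set(assignments.tolist())):
        members = np.flatnonzero(assignments == label)
        if len(members) == 1:
            medoid = int(members[0])
        else:
            sub = tm[np.ix_(members, members)]
            mean_tm = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
            medoid = int(members[int(np.argmax(mean_tm))])
        clusters.append((members.tolist(), medoid))
    clusters.sort(key=lambda c: c[0][0])
    return clusters


def select_models(
    cm: ContactMap,
    backend: str = "stub",
    config: Optional[SelectionConfig] = None,
    seed: int = 0,
    reference: Optional[np.ndarray] = None,
) -> dict:
    """Run the full selection pipeline on one predicted contact map.

    Returns a report with the retained models at each stage (200 → 50 →
    5 under the default configuration), per-stage provenance, and — when
    a reference structure is given — the Kabsch RMSD of each final model.
    """
    if config is None:
        config = SelectionConfig()
    L = cm.size
    groups = {}
    rng = np.random.default_rng(seed)
    for x in config.x_grid:
        pairs = select_top_xL_contacts(cm, x)
        restraints = contacts_to_restraints(pairs)
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        models = run_backend(restraints, backend, config.models_per_x,
                             seed=sub_seed, length=L)
        for m in models:
            m.provenance = (x, m.provenance[1] if len(m.provenance) > 1 else None)
        groups[x] = models
    pool = per_x_select(groups, keep=config.per_x_keep)

    scored = []
    for m in pool:
        s = satisfaction_score(m, cm)
        scored.append((0.0 if s is None else s, m))
    scored.sort(key=lambda sm: (-sm[0], sm[1].provenance))
    ranked = [m for _, m in scored[: config.rank_pool]]

    clusters = cluster_models(ranked, k=config.n_clusters)
    finals = [ranked[medoid] for _, medoid in clusters]
    report = {
        "n_after_per_x": len(pool),
        "n_after_ranking": len(ranked),
        "n_final": len(finals),
        "final_models": finals,
        "final_provenance": [m.provenance for m in finals],
        "clusters": clusters,
    }
    if reference is not None:
        report["final_rmsd"] = [kabsch_rmsd(m, reference) for m in finals]
    return report


# register the stub backend shipped with the synthetic fixtures
from .synthetic import stub_fold_backend as _stub  # noqa: E402

register_backend("stub", _stub)
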