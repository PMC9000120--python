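"""Training-corpus assembly for the MCP predictor.

Mirrors the construction of the two corpora used to train the predictor:
a large one (membrane chains plus soluble chains whose MCP labels are all
zero, since soluble residues never touch an acyl chain) and a small
redundancy-reduced one filtered at 40% pairwise identity and split
roughly 8:1:1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align

from .types import (
    AMINO_ACIDS,
    InsufficientPoolError,
    MemcontactError,
    SeqRecord,
)

logger = logging.getLogger(__name__)

STANDARD_AA = set(AMINO_ACIDS)


@dataclass
class SplitSpec:
    """Sizes for the large-corpus assembly (counts, not fractions)."""

    n_train_membrane: int = 5000
    n_train_soluble: int = 5000
    n_val: int = 400
    n_test: int = 500
    seed: int = 0


def split_chains(structures: Iterable[tuple], klass: str = "membrane") -> list:
    """One SeqRecord per chain, exact duplicate sequences collapsed.

    ``structures`` yields (pdb_id, chains) where chains maps chain_id to
    (sequence, labels-or-None).  Duplicate collapse uses exact string
    equality on the sequence; the first occurrence wins.
    """
    seen = {}
    out = []
    for pdb_id, chains in structures:
        for chain_id, payload in chains.items():
            sequence, labels = payload
            if sequence in seen:
                continue
            rec = SeqRecord(
                record_id=f"{pdb_id}_{chain_id}", sequence=sequence,
                labels=labels, klass=klass,
            )
            seen[sequence] = rec
            out.append(rec)
    return out


def filter_sequences(
    records: Sequence[SeqRecord],
    min_len: int = 26,
    max_len: int = 700,
    standard_only: bool = True,
) -> list:
    """Keep records with min_len <= L <= max_len (inclusive) and, when
    standard_only, only the 20 canonical letters."""
    kept = []
    for rec in records:
        if not (min_len <= len(rec) <= max_len):
            continue
        if standard_only and not set(rec.sequence) <= STANDARD_AA:
            continue
        kept.append(rec)
    return kept


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment sequence identity in [0, 1].

    Needleman-Wunsch with affine gaps (match +1, mismatch 0, open -10,
    extend -0.5); identity = identical aligned pairs / min(len(a), len(b)).
    Among co-optimal alignments the one maximizing the identity count is
    used, which also makes the function exactly symmetric.
    """
    if not a or not b:
        raise MemcontactError("empty sequence in identity computation")
    matches = _max_identities_affine(a, b)
    return matches / min(len(a), len(b))


def _max_identities_affine(a: str, b: str) -> int:
    """Max #identities among score-optimal affine-gap global alignments.

    Gotoh dynamic programming over lexicographic (score, matches) values.
    Scores lie on a 0.5 grid, so (2*score, matches) is encoded as a single
    integer 2*score*K + matches with K > max possible matches.
    """
    n, m = len(a), len(b)
    K = min(n, m) + 1
    open_, ext = -10.0, -0.5
    NEG = -(10 ** 12)

    def enc(score2: int, matches: int) -> int:
        return score2 * K + matches

    # M: a[i-1] aligned to b[j-1]; X: gap in b (a consumed); Y: gap in a
    M = np.full(m + 1, NEG, dtype=np.int64)
    X = np.full(m + 1, NEG, dtype=np.int64)
    Y = np.full(m + 1, NEG, dtype=np.int64)
    M[0] = enc(0, 0)
    for j in range(1, m + 1):
        Y[j] = enc(int(2 * (open_ + (j - 1) * ext)), 0)
    for i in range(1, n + 1):
        Mp, Xp, Yp = M.copy(), X.copy(), Y.copy()
        M[0] = NEG
        X[0] = enc(int(2 * (open_ + (i - 1) * ext)), 0)
        Y[0] = NEG
        for j in range(1, m + 1):
            best_prev = max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            if best_prev <= NEG:
                M[j] = NEG
            else:
                sc = 2 if a[i - 1] == b[j - 1] else 0
                mt = 1 if a[i - 1] == b[j - 1] else 0
                M[j] = best_prev + enc(sc, mt)
            X[j] = max(
                Mp[j] + enc(int(2 * open_), 0) if Mp[j] > NEG else NEG,
                Xp[j] + enc(int(2 * ext), 0) if Xp[j] > NEG else NEG,
                Yp[j] + enc(int(2 * open_), 0) if Yp[j] > NEG else NEG,
            )
            Y[j] = max(
                M[j - 1] + enc(int(2 * open_), 0) if M[j - 1] > NEG else NEG,
                Y[j - 1] + enc(int(2 * ext), 0) if Y[j - 1] > NEG else NEG,
                X[j - 1] + enc(int(2 * open_), 0) if X[j - 1] > NEG else NEG,
            )
    best = int(max(M[m], X[m], Y[m]))
    # enc() keeps matches in [0, K); Python floor-modulo recovers it even
    # when the score part is negative
    return best % K


def alignment_score(a: str, b: str) -> float:
    """Optimal global affine-gap alignment score (same scoring as identity)."""
    return float(_make_aligner().score(a, b))


def redundancy_reduce(records: Sequence[SeqRecord], threshold: float = 0.40) -> list:
    """Greedy incremental redundancy filter.

    Records are visited sorted by (descending length, record_id); a record
    is kept iff its identity to every already-kept record is strictly
    below ``threshold``.  Deterministic.
    """
    if not (0 < threshold <= 1):
        raise MemcontactError("threshold must be in (0, 1]")
    order = sorted(records, key=lambda r: (-len(r), r.record_id))
    kept = []
    for rec in order:
        if all(pairwise_identity(rec.sequence, k.sequence) < threshold for k in kept):
            kept.append(rec)
    return kept


def assemble_mcp_large(
    membrane_pool: Sequence[SeqRecord],
    soluble_pool: Sequence[SeqRecord],
    spec: Optional[SplitSpec] = None,
) -> dict:
    """Assemble the large corpus: mixed train set, membrane-only val/test.

    Soluble records get all-zero labels.  Train/val/test are disjoint by
    record_id; sampling is seeded.  Defaults: 5000 membrane + 5000 soluble
    training chains, 400 validation and 500 test membrane chains.
    """
    if spec is None:
        spec = SplitSpec()
    need_mem = spec.n_train_membrane + spec.n_val + spec.n_test
    if len(membrane_pool) < need_mem:
        raise InsufficientPoolError("membrane", need_mem, len(membrane_pool))
    if len(soluble_pool) < spec.n_train_soluble:
        raise InsufficientPoolError("soluble", spec.n_train_soluble, len(soluble_pool))

    rng = np.random.default_rng(spec.seed)
    mem_idx = rng.permutation(len(membrane_pool))
    sol_idx = rng.permutation(len(soluble_pool))

    mem_train = [membrane_pool[i] for i in mem_idx[: spec.n_train_membrane]]
    val = [membrane_pool[i] for i in
           mem_idx[spec.n_train_membrane: spec.n_train_membrane + spec.n_val]]
    test = [membrane_pool[i] for i in
            mem_idx[spec.n_train_membrane + spec.n_val: need_mem]]
    sol_train = [
        SeqRecord(record_id=r.record_id, sequence=r.sequence,
                  labels=np.zeros(len(r)), klass="soluble")
        for r in (soluble_pool[i] for i in sol_idx[: spec.n_train_soluble])
    ]
    return {"train": mem_train + sol_train, "val": val, "test": test}


def split_ratio(
    records: Sequence[SeqRecord],
    fractions: tuple = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> tuple:
    """Seeded shuffle, then a contiguous split with largest-remainder sizes.

    Returns (train, val, test); the three parts are disjoint and their
    union is the input set.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise MemcontactError("fractions must sum to 1")
    n = len(records)
    quotas = [f * n for f in fractions]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    # distribute leftovers to the largest fractional parts (ties: earlier part)
    frac_order = sorted(range(len(fractions)),
                        key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in range(rem):
        sizes[frac_order[i]] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [records[i] for i in perm]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0]: sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1]:]
    return train, val, test


# ---------------------------------------------------------------------------
# FASTA / manifest I/O
# ---------------------------------------------------------------------------

def records_to_fasta(records: Sequence[SeqRecord]) -> str:
    return "".join(f">{r.record_id}\n{r.sequence}\n" for r in records)


def records_from_fasta(text: str, klass: str = "membrane") -> list:
    from io import StringIO

    from Bio import SeqIO

    return [
        SeqRecord(record_id=rec.id, sequence=str(rec.seq), klass=klass)
        for rec in SeqIO.parse(StringIO(text), "fasta")
    ]


def dataset_manifest(splits: dict) -> dict:
    """JSON-serializable manifest listing record_ids per split."""
    return {name: [r.record_id for r in recs] for name, recs in splits.items()}
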