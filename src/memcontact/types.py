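"""Shared domain types for the membrane-contact toolkit.

The central quantity is the membrane contact probability (MCP): for each
residue, the fraction of trajectory frames in which its Cα lies within a
distance cutoff of any lipid acyl-chain carbon.  Everything else in the
package either computes this quantity, predicts it from sequence features,
or consumes it downstream (surface characterization, contact maps, model
selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

#: canonical one-letter amino-acid alphabet, fixed column order for PSSMs
#: and pairwise potential tables
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: MSA alphabet: 20 amino acids plus the gap symbol
GAP = "-"
MSA_ALPHABET = AMINO_ACIDS + GAP


class MemcontactError(Exception):
    """Base class for structured errors raised by this package."""


class EmptySelectionError(MemcontactError):
    """An atom or frame selection matched nothing."""


class LengthMismatchError(MemcontactError):
    """Two per-residue arrays that must align have different lengths."""


class DegenerateGeometryError(MemcontactError):
    """Coordinates are collinear/coincident where a 3-D shape is required."""


class InsufficientPoolError(MemcontactError):
    """A dataset assembly step asked for more records than available."""

    def __init__(self, pool_name: str, requested: int, available: int):
        self.pool_name = pool_name
        self.requested = requested
        self.available = available
        super().__init__(
            f"pool '{pool_name}' has {available} records, {requested} requested"
        )


class BackendError(MemcontactError):
    """A folding backend failed; carries the backend's diagnostics."""

    def __init__(self, backend: str, diagnostics: str):
        self.backend = backend
        self.diagnostics = diagnostics
        super().__init__(f"backend '{backend}' failed: {diagnostics}")


#: marker returned where a statistic is undefined (e.g. zero variance)
UNDEFINED = None


@dataclass
class FrameSet:
    """Trajectory frames with role-tagged atoms.

    coords has shape (n_frames, n_atoms, 3) in Å.  Roles identify the two
    groups the contact definition cares about: protein Cα atoms and lipid
    acyl-chain carbons; everything else is 'other'.
    """

    coords: np.ndarray
    roles: np.ndarray  # str array: protein_ca | lipid_tail_carbon | other
    chain_ids: np.ndarray
    residue_indices: np.ndarray
    residue_names: np.ndarray
    times: Optional[np.ndarray] = None  # ns

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise MemcontactError("coords must have shape (frames, atoms, 3)")
        if self.coords.shape[0] < 1:
            raise MemcontactError("FrameSet needs at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise MemcontactError("non-finite coordinates in FrameSet")
        n_atoms = self.coords.shape[1]
        for name in ("roles", "chain_ids", "residue_indices", "residue_names"):
            arr = np.asarray(getattr(self, name))
            setattr(self, name, arr)
            if arr.shape != (n_atoms,):
                raise MemcontactError(f"{name} must have one entry per atom")
        ca = self.roles == "protein_ca"
        keys = list(zip(self.chain_ids[ca], self.residue_indices[ca]))
        if len(set(keys)) != len(keys):
            raise MemcontactError("duplicate (chain, residue) among protein_ca atoms")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(self, selector: Union[str, np.ndarray, callable]) -> np.ndarray:
        """Resolve a selector (role name, boolean mask, or predicate) to a mask."""
        if isinstance(selector, str):
            return self.roles == selector
        if callable(selector):
            return np.asarray(selector(self), dtype=bool)
        mask = np.asarray(selector, dtype=bool)
        if mask.shape != (self.n_atoms,):
            raise MemcontactError("selector mask length does not match atom count")
        return mask


@dataclass
class MCPProfile:
    """Per-residue membrane contact probability with its sequence."""

    chain_id: str
    sequence: str
    values: np.ndarray
    source: str  # md | annotated_pdb | predicted

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.sequence):
            raise LengthMismatchError(
                f"{len(self.values)} values for {len(self.sequence)} residues"
            )
        if len(self.values) and (self.values.min() < 0 or self.values.max() > 1):
            raise MemcontactError("MCP values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactConfig:
    """Settings for occupancy extraction.

    frame_window: either a trailing fraction in (0, 1] (averaging is done
    over the last ``fraction`` of frames, the production tail of a
    trajectory) or an inclusive (start, end) frame index range.
    """

    cutoff_A: float = 6.0
    frame_window: Union[float, tuple] = 0.8
    tail_selector: str = r"C[0-9]+[AB]?"

    def __post_init__(self):
        if self.cutoff_A <= 0:
            raise MemcontactError("cutoff must be positive")

    def frame_indices(self, n_frames: int) -> np.ndarray:
        if isinstance(self.frame_window, tuple):
            start, end = self.frame_window
            if not (0 <= start <= end < n_frames):
                raise MemcontactError("frame_window out of range")
            return np.arange(start, end + 1)
        frac = float(self.frame_window)
        if not (0 < frac <= 1):
            raise MemcontactError("frame_window fraction must be in (0, 1]")
        n_sel = max(1, int(round(frac * n_frames)))
        return np.arange(n_frames - n_sel, n_frames)


@dataclass
class StructureCoords:
    """Per-residue Cα (and optional Cβ) coordinates with the sequence.

    Glycine has no Cβ; where ``cb`` rows are NaN the Cα position is the
    fallback (standard CASP convention).
    """

    ca: np.ndarray  # (L, 3)
    cb: Optional[np.ndarray] = None  # (L, 3), NaN rows allowed
    sequence: Optional[str] = None

    def __post_init__(self):
        self.ca = np.asarray(self.ca, dtype=float)
        if self.cb is not None:
            self.cb = np.asarray(self.cb, dtype=float)
            if self.cb.shape != self.ca.shape:
                raise LengthMismatchError("cb shape differs from ca")

    def __len__(self) -> int:
        return len(self.ca)

    def contact_atoms(self) -> np.ndarray:
        """Cβ positions with Cα substituted where Cβ is missing."""
        if self.cb is None:
            return self.ca.copy()
        out = self.cb.copy()
        missing = ~np.all(np.isfinite(out), axis=1)
        out[missing] = self.ca[missing]
        if not np.all(np.isfinite(out)):
            bad = int(np.flatnonzero(~np.all(np.isfinite(out), axis=1))[0])
            raise MemcontactError(f"residue {bad} lacks both Cβ and Cα")
        return out


@dataclass
class SeqRecord:
    """A single-chain sequence with optional per-residue MCP labels."""

    record_id: str
    sequence: str
    labels: Optional[np.ndarray] = None
    klass: str = "membrane"  # membrane | soluble

    def __post_init__(self):
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=float)
            if len(self.labels) != len(self.sequence):
                raise LengthMismatchError(
                    f"labels ({len(self.labels)}) vs sequence ({len(self.sequence)})"
                )
            if len(self.labels) and (self.labels.min() < 0 or self.labels.max() > 1):
                raise MemcontactError("labels must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactMap:
    """L×L residue contact map: native binary contacts or predicted probabilities."""

    values: np.ndarray
    kind: str = "predicted"  # predicted | native

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise MemcontactError("contact map must be square")
        if not np.allclose(self.values, self.values.T):
            raise MemcontactError("contact map must be symmetric")
        if np.any(np.diagonal(self.values) != 0):
            raise MemcontactError("contact map diagonal must be zero")
        if self.kind == "predicted" and len(self.values):
            if self.values.min() < 0 or self.values.max() > 1:
                raise MemcontactError("predicted contact probabilities must be in [0,1]")

    @property
    def size(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class RangeBand:
    """Sequence-separation band for contact evaluation (bounds inclusive)."""

    name: str
    lo: int
    hi: int  # use a large sentinel for open-ended

    def contains(self, sep: np.ndarray) -> np.ndarray:
        return (sep >= self.lo) & (sep <= self.hi)


SHORT_RANGE = RangeBand("short", 6, 11)
MEDIUM_RANGE = RangeBand("medium", 12, 23)
LONG_RANGE = RangeBand("long", 24, 10 ** 9)
BANDS = {b.name: b for b in (SHORT_RANGE, MEDIUM_RANGE, LONG_RANGE)}


@dataclass
class MSA:
    """Aligned sequences over the 20 amino acids plus gap."""

    rows: Sequence[str]

    def __post_init__(self):
        self.rows = list(self.rows)
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise MemcontactError("MSA rows must have equal length")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def to_indices(self) -> np.ndarray:
        """Integer encoding: 0..19 amino acids, 20 gap/unknown."""
        idx = np.full((self.depth, self.length), 20, dtype=np.int8)
        for r, row in enumerate(self.rows):
            for c, ch in enumerate(row):
                idx[r, c] = AA_INDEX.get(ch.upper(), 20)
        return idx


@dataclass
class RestraintSet:
    """Bounded-distance contact restraints plus opaque SS records."""

    contacts: list  # of (i, j, d_min, d_max), i < j
    ss_records: list = field(default_factory=list)

    def __post_init__(self):
        for (i, j, dmin, dmax) in self.contacts:
            if not (i < j):
                raise MemcontactError(f"restraint pair must satisfy i < j: ({i},{j})")
            if not (dmin < dmax):
                raise MemcontactError("restraint needs d_min < d_max")

    def __len__(self) -> int:
        return len(self.contacts)


@dataclass
class ModelCandidate:
    """A structure model produced by a folding backend."""

    coords: np.ndarray  # (L, 3) Cα
    backend_score: float  # contact energy; lower = better
    provenance: tuple = ()  # (x value, replicate index)
    cb: Optional[np.ndarray] = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise MemcontactError("non-finite model coordinates")

    def __len__(self) -> int:
        return len(self.coords)

    def structure(self) -> StructureCoords:
        return StructureCoords(ca=self.coords, cb=self.cb)


@dataclass
class SelectionConfig:
    """Bookkeeping constants of the contact-driven selection pipeline."""

    x_grid: tuple = tuple(np.round(np.arange(0.1, 4.01, 0.1), 10))
    models_per_x: int = 20
    per_x_keep: int = 5
    rank_pool: int = 50
    n_clusters: int = 5

    def __post_init__(self):
        if self.per_x_keep > self.models_per_x:
            raise MemcontactError("per_x_keep must not exceed models_per_x")
        if self.n_clusters > self.rank_pool:
            raise MemcontactError("n_clusters must not exceed rank_pool")


def tm_d0(L: int) -> float:
    """TM-score distance scale d0(L) = 1.24 (L-15)^(1/3) - 1.8, floored at 0.5."""
    if L <= 15:
        return 0.5
    return max(0.5, 1.24 * (L - 15) ** (1.0 / 3.0) - 1.8)
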