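"""Synthetic inputs with known ground truth.

Every generator here is a pure function of (spec, seed) and produces the
same file formats and containers the real pipeline consumes: membrane
systems whose exact lipid-contact occupancy is computed by an embedded
brute-force loop, per-residue feature/target sets with a planted,
learnable membrane-anchoring signal, toy MSAs with planted covariation,
toy helical structures, and a stub folding backend that stands in for a
restraint-based model builder.

None of this emulates lipid physics; it gives the analysis code inputs
whose correct answers are known by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .types import (
    AMINO_ACIDS,
    ContactConfig,
    FrameSet,
    MCPProfile,
    MSA,
    ModelCandidate,
    RestraintSet,
    StructureCoords,
)
from .lipid_contact import _AA1TO3

# Kyte-Doolittle hydropathy, used to rank residue hydrophobicity
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}
_HYD_ORDER = sorted(KYTE_DOOLITTLE, key=KYTE_DOOLITTLE.get)
#: hydrophobicity rank normalized to (0, 1]; 1 = most hydrophobic (Ile)
HYDROPHOBICITY_RANK = {a: (i + 1) / 20.0 for i, a in enumerate(_HYD_ORDER)}
HYDROPHOBIC_SET = "IVLFCMA"

# canonical alpha-helix trace geometry
HELIX_RISE = 1.5  # Å per residue
HELIX_RADIUS = 2.3  # Å
HELIX_TURN = 100.0  # degrees per residue


@dataclass
class MembraneSystemSpec:
    """A helical peptide crossing a lipid-slab region.

    The 'membrane' is a slab |z| <= slab_half_thickness filled with lipid
    tail pseudo-atoms; the helix runs along z through it, so residues near
    the slab get high contact occupancy and the termini get zero.
    """

    n_residues: int = 40
    slab_half_thickness: float = 15.0
    n_lipid_tail_atoms: int = 60
    n_frames: int = 20
    jitter_sigma: float = 0.5
    seed: int = 0
    lipid_xy_halfwidth: float = 12.0
    lipid_offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if min(self.n_residues, self.n_lipid_tail_atoms, self.n_frames) <= 0:
            raise ValueError("all counts must be positive")
        if self.jitter_sigma < 0:
            raise ValueError("jitter sigma must be non-negative")


def helix_trace(n: int, rise: float = HELIX_RISE, radius: float = HELIX_RADIUS,
                turn: float = HELIX_TURN) -> np.ndarray:
    """Ideal helical Cα trace along z, centered at the origin."""
    i = np.arange(n)
    theta = np.radians(turn * i)
    z = (i - (n - 1) / 2.0) * rise
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


def make_membrane_system(spec: MembraneSystemSpec,
                         config: Optional[ContactConfig] = None):
    """Build a membrane system and its exact occupancy ground truth.

    Returns (FrameSet, MCPProfile).  The ground truth is computed by an
    embedded brute-force per-frame double loop over residues and lipid
    atoms — deliberately independent of the vectorized occupancy kernel it
    is used to test.
    """
    if config is None:
        config = ContactConfig()
    rng = np.random.default_rng(spec.seed)

    ca = helix_trace(spec.n_residues)
    lip = np.column_stack([
        rng.uniform(-spec.lipid_xy_halfwidth, spec.lipid_xy_halfwidth,
                    spec.n_lipid_tail_atoms),
        rng.uniform(-spec.lipid_xy_halfwidth, spec.lipid_xy_halfwidth,
                    spec.n_lipid_tail_atoms),
        rng.uniform(-spec.slab_half_thickness, spec.slab_half_thickness,
                    spec.n_lipid_tail_atoms),
    ]) + np.asarray(spec.lipid_offset)

    base = np.vstack([ca, lip])
    n_atoms = len(base)
    coords = base[None, :, :] + rng.normal(
        0.0, spec.jitter_sigma, size=(spec.n_frames, n_atoms, 3)
    ) if spec.jitter_sigma > 0 else np.repeat(base[None], spec.n_frames, axis=0)

    seq_idx = rng.integers(0, 20, spec.n_residues)
    res_names = np.array(
        [_AA1TO3[AMINO_ACIDS[k]] for k in seq_idx]
        + ["DPP"] * spec.n_lipid_tail_atoms
    )
    frames = FrameSet(
        coords=coords,
        roles=np.array(["protein_ca"] * spec.n_residues
                       + ["lipid_tail_carbon"] * spec.n_lipid_tail_atoms),
        chain_ids=np.array(["A"] * n_atoms),
        residue_indices=np.concatenate([
            np.arange(1, spec.n_residues + 1),
            np.arange(1001, 1001 + spec.n_lipid_tail_atoms),
        ]),
        residue_names=res_names,
        times=np.arange(spec.n_frames, dtype=float),
    )

    # ---- embedded brute-force oracle (plain loops, math.dist) ----
    sel = config.frame_indices(spec.n_frames)
    counts = [0] * spec.n_residues
    for f in sel:
        for r in range(spec.n_residues):
            p = coords[f, r]
            for a in range(spec.n_residues, n_atoms):
                if math.dist(p, coords[f, a]) <= config.cutoff_A:
                    counts[r] += 1
                    break
    values = np.array(counts, dtype=float) / len(sel)
    sequence = "".join(AMINO_ACIDS[k] for k in seq_idx)
    truth = MCPProfile(chain_id="A", sequence=sequence, values=values, source="md")
    return frames, truth


# ---------------------------------------------------------------------------
# planted-signal training data for the sequence-based MCP predictor
# ---------------------------------------------------------------------------

@dataclass
class TrainingRecord:
    """One synthetic protein: sequence, 26 per-residue features, MCP target."""

    record_id: str
    sequence: str
    ss3: np.ndarray  # (L, 3)
    sa3: np.ndarray  # (L, 3)
    pssm: np.ndarray  # (L, 20)
    target: np.ndarray  # (L,)
    ss_labels: str  # H/E/C per residue


def _smooth(x: np.ndarray, width: int = 5) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(x, kernel, mode="same")


def make_mcp_training_set(
    n_records: int,
    length_range: tuple = (30, 60),
    seed: int = 0,
    n_windows_range: tuple = (1, 3),
    feature_noise: float = 0.05,
) -> list:
    """Records with 1–3 planted hydrophobic membrane-spanning windows.

    The target MCP is a smoothed indicator of the windows scaled by the
    residue's hydrophobicity rank; the SS3/SA3/PSSM surrogates carry the
    same signal (helical, buried, hydrophobic inside windows) so the
    sequence-to-MCP mapping is learnable by construction.
    """
    lo, hi = length_range
    if lo < 26 or hi > 700:
        raise ValueError("lengths must lie within [26, 700]")
    rng = np.random.default_rng(seed)
    records = []
    for r in range(n_records):
        L = int(rng.integers(lo, hi + 1))
        n_win = int(rng.integers(n_windows_range[0], n_windows_range[1] + 1))
        seq = [AMINO_ACIDS[k] for k in rng.integers(0, 20, L)]
        indicator = np.zeros(L)
        for _ in range(n_win):
            w = int(rng.integers(19, 24))
            if w >= L:
                w = L - 2
            s = int(rng.integers(0, L - w + 1))
            indicator[s:s + w] = 1.0
            for p in range(s, s + w):
                seq[p] = HYDROPHOBIC_SET[int(rng.integers(0, len(HYDROPHOBIC_SET)))]
        sequence = "".join(seq)
        hyd = np.array([HYDROPHOBICITY_RANK[a] for a in sequence])
        target = np.clip(_smooth(indicator) * (0.4 + 0.6 * hyd), 0.0, 1.0)

        sm = _smooth(indicator)
        h = np.clip(0.15 + 0.7 * sm + rng.normal(0, feature_noise, L), 0, 1)
        e = np.clip(0.1 + rng.normal(0, feature_noise, L), 0, 1)
        c = np.clip(1.0 - h - e, 0, 1)
        ss3 = np.column_stack([h, e, c])
        ss3 /= ss3.sum(axis=1, keepdims=True)

        buried = np.clip(target + rng.normal(0, feature_noise, L), 0, 1)
        mid = (1 - buried) * 0.3
        sa3 = np.column_stack([buried, mid, np.clip(1 - buried - mid, 0, 1)])

        pssm = rng.normal(0, 0.3, (L, 20))
        for i, a in enumerate(sequence):
            pssm[i, AMINO_ACIDS.index(a)] += 2.0

        ss_labels = "".join(
            "H" if row.argmax() == 0 else ("E" if row.argmax() == 1 else "C")
            for row in ss3
        )
        records.append(TrainingRecord(
            record_id=f"syn{r:04d}", sequence=sequence, ss3=ss3, sa3=sa3,
            pssm=pssm, target=target, ss_labels=ss_labels,
        ))
    return records


# ---------------------------------------------------------------------------
# toy MSAs with planted covariation
# ---------------------------------------------------------------------------

def make_msa(
    L: int,
    depth: int,
    covarying_pairs: Sequence[tuple] = (),
    seed: int = 0,
    coupling: float = 1.0,
    gap_fraction: float = 0.0,
) -> MSA:
    """An alignment whose columns are independent except the listed pairs.

    Each covarying pair (i, j) has two letter states; a row uses matched
    letters with probability ``coupling`` and independent ones otherwise,
    which plants a mutual-information signal at exactly those pairs.
    """
    rng = np.random.default_rng(seed)
    cols = rng.integers(0, 20, size=(depth, L))
    for (i, j) in covarying_pairs:
        a1, a2 = rng.choice(20, size=2, replace=False)
        b1, b2 = rng.choice(20, size=2, replace=False)
        state = rng.integers(0, 2, depth)
        cols[:, i] = np.where(state == 0, a1, a2)
        matched = rng.random(depth) < coupling
        b_match = np.where(state == 0, b1, b2)
        b_rand = np.where(rng.integers(0, 2, depth) == 0, b1, b2)
        cols[:, j] = np.where(matched, b_match, b_rand)
    rows = []
    for r in range(depth):
        chars = [AMINO_ACIDS[k] for k in cols[r]]
        if gap_fraction > 0:
            gaps = rng.random(L) < gap_fraction
            chars = ["-" if g else ch for ch, g in zip(chars, gaps)]
        rows.append("".join(chars))
    return MSA(rows=rows)


# ---------------------------------------------------------------------------
# toy structures and the stub folding backend
# ---------------------------------------------------------------------------

def make_toy_structure(L: int, seed: int = 0, jitter: float = 0.15) -> StructureCoords:
    """Self-avoiding helical trace with pseudo-Cβ offset 1.5 Å outward."""
    if L < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    ca = helix_trace(L) + rng.normal(0, jitter, (L, 3))
    radial = ca.copy()
    radial[:, 2] = 0
    norm = np.linalg.norm(radial, axis=1, keepdims=True)
    norm[norm < 1e-9] = 1.0
    cb = ca + 1.5 * radial / norm
    seq = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, L))
    return StructureCoords(ca=ca, cb=cb, sequence=seq)


def make_hairpin_structure(L: int, seed: int = 0, strand_gap: float = 5.0,
                           jitter: float = 0.2) -> StructureCoords:
    """A two-strand hairpin: rich in long-range contacts (i, L-1-i).

    Toy structures for contact-map training need contacts at sequence
    separations >= 6, which a single helix cannot provide.
    """
    if L < 8:
        raise ValueError("hairpin needs at least 8 residues")
    rng = np.random.default_rng(seed)
    half = L // 2
    ca = np.zeros((L, 3))
    for i in range(L):
        if i < half:
            ca[i] = (0.0, 0.0, 3.8 * i)
        else:
            ca[i] = (strand_gap, 0.0, 3.8 * (L - 1 - i))
    ca += rng.normal(0, jitter, (L, 3))
    cb = ca + np.array([0.0, 1.5, 0.0])
    seq = "".join(AMINO_ACIDS[k] for k in rng.integers(0, 20, L))
    return StructureCoords(ca=ca, cb=cb, sequence=seq)


def make_cm_training_set(
    n_records: int = 5,
    L: int = 28,
    seed: int = 0,
    signal_noise: float = 0.1,
):
    """(PairFeatureTensor, native ContactMap) pairs with learnable signal.

    Native maps come from toy hairpin structures; one 2-D channel is the
    native map corrupted by noise (a surrogate for coevolution scores,
    which in real data correlate with true contacts), plus an
    uninformative noise channel.  The 1-D block is a 27-column surrogate
    ([SS3 | SA3 | PSSM | MCP]).
    """
    from .cm_net import assemble_pair_features
    from .contacts import native_contact_map

    rng = np.random.default_rng(seed)
    manifest_1d = (["ss3"] * 3 + ["sa3"] * 3 + ["pssm"] * 20 + ["mcp"])
    dataset = []
    for r in range(n_records):
        structure = make_hairpin_structure(L, seed=seed + 7 * r + 1)
        native = native_contact_map(structure)
        f1d = rng.normal(0, 0.5, (L, 27))
        coevo = np.abs(native.values + rng.normal(0, signal_noise, (L, L)))
        coevo = (coevo + coevo.T) / 2.0
        noise = rng.normal(0, 1.0, (L, L))
        noise = (noise + noise.T) / 2.0
        pft = assemble_pair_features(
            f1d, [coevo, noise],
            manifest_1d=manifest_1d, manifest_2d=["coevolution", "noise"],
        )
        dataset.append((pft, native))
    return dataset


def restraint_violation_score(coords_cb: np.ndarray, restraints: RestraintSet) -> float:
    """Flat-bottom penalty: sum over restraints of distance outside [d_min, d_max]."""
    total = 0.0
    for (i, j, dmin, dmax) in restraints.contacts:
        d = float(np.linalg.norm(coords_cb[i] - coords_cb[j]))
        if d > dmax:
            total += d - dmax
        elif d < dmin:
            total += dmin - d
    return total


def stub_fold_backend(
    restraints: RestraintSet,
    n: int,
    seed: int = 0,
    length: Optional[int] = None,
    noise_step: float = 0.25,
) -> list:
    """A deterministic stand-in for a restraint-based model builder.

    Generates a reference helical trace and perturbs it with seeded noise
    whose magnitude grows with the replicate index (replicate 0 is
    noise-free); backend_score is the flat-bottom restraint violation sum.
    """
    if length is None:
        if not restraints.contacts:
            raise ValueError("length required when restraints are empty")
        length = max(j for (_, j, _, _) in restraints.contacts) + 1
    ref = make_toy_structure(length, seed=seed, jitter=0.0)
    rng = np.random.default_rng(seed)
    models = []
    for r in range(n):
        sigma = noise_step * r
        noise = rng.normal(0, 1.0, (length, 3)) * sigma
        ca = ref.ca + noise
        cb = ref.cb + noise
        score = restraint_violation_score(cb, restraints)
        models.append(ModelCandidate(
            coords=ca, backend_score=score, provenance=(None, r), cb=cb,
        ))
    return models
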