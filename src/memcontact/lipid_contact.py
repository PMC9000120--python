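"""Membrane contact probability from trajectories and annotated structures.

The contact definition: a residue is in direct contact with the bilayer's
hydrophobic core in a frame when its Cα is within ``cutoff_A`` (default
6 Å, closed boundary) of any lipid acyl-chain carbon.  The MCP is the
occupancy of that contact averaged over the selected frame window —
conventionally the trailing production portion of the trajectory.

Periodic boundary conditions are not unwrapped: inputs are assumed whole
and imaged.  This is a documented limitation, not a silent assumption.
"""

from __future__ import annotations

import io
import logging
import re
from typing import Optional, Union

import numpy as np
from scipy.spatial.distance import cdist

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.sequence import ProteinSequence

from .types import (
    ContactConfig,
    EmptySelectionError,
    FrameSet,
    LengthMismatchError,
    DegenerateGeometryError,
    MCPProfile,
    MemcontactError,
)

logger = logging.getLogger(__name__)

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3.items()}


def three_to_one(res_name: str) -> str:
    """3-letter residue name to 1-letter code; unknown names map to 'X'."""
    code = _AA3.get(res_name.upper())
    if code is None:
        logger.warning("non-standard residue name %r mapped to 'X'", res_name)
        return "X"
    return code


def compute_contact_occupancy(frames: FrameSet, config: ContactConfig = None) -> MCPProfile:
    """Per-residue lipid-contact occupancy over the configured frame window.

    For each protein Cα, the returned value is the fraction of selected
    frames in which its minimum distance to any lipid tail carbon is
    <= ``config.cutoff_A``.  The result does not depend on atom ordering.
    """
    if config is None:
        config = ContactConfig()
    ca_mask = frames.roles == "protein_ca"
    if not ca_mask.any():
        raise EmptySelectionError("empty protein selection: no protein_ca atoms")
    tail_mask = frames.roles == "lipid_tail_carbon"

    # stable residue order: file order of the Cα atoms
    ca_idx = np.flatnonzero(ca_mask)
    sequence = "".join(three_to_one(n) for n in frames.residue_names[ca_idx])
    chains = frames.chain_ids[ca_idx]
    chain_id = chains[0] if len(set(chains)) == 1 else ""

    sel = config.frame_indices(frames.n_frames)
    if not tail_mask.any():
        logger.warning("no lipid_tail_carbon atoms: occupancy is all zeros")
        values = np.zeros(len(ca_idx))
    else:
        tail_idx = np.flatnonzero(tail_mask)
        counts = np.zeros(len(ca_idx), dtype=int)
        for f in sel:
            d = cdist(frames.coords[f, ca_idx], frames.coords[f, tail_idx])
            counts += (d.min(axis=1) <= config.cutoff_A)
        values = counts / len(sel)
    return MCPProfile(chain_id=str(chain_id), sequence=sequence, values=values, source="md")


def lipid_interacting_residues(profile: MCPProfile, threshold: float) -> set:
    """Indices of residues whose MCP strictly exceeds ``threshold``."""
    if not (0 <= threshold <= 1):
        raise MemcontactError("threshold must be in [0, 1]")
    return set(np.flatnonzero(profile.values > threshold).tolist())


def profile_overlap(predicted: MCPProfile, observed: MCPProfile, threshold: float) -> set:
    """Residues where both the predicted and observed MCP exceed ``threshold``.

    This is the converged membrane-interacting interface when comparing a
    sequence-based prediction with an MD observation.
    """
    if len(predicted) != len(observed):
        raise LengthMismatchError(
            f"profiles differ in length: {len(predicted)} vs {len(observed)}"
        )
    return lipid_interacting_residues(predicted, threshold) & lipid_interacting_residues(
        observed, threshold
    )


def com_distance_series(frames: FrameSet, group_a, group_b) -> np.ndarray:
    """Per-frame distance between the centroids of two atom selections.

    Centroids are unweighted (coarse-grained beads have near-uniform
    masses); pass ``masses`` explicitly via a pre-weighted selection if
    mass weighting is ever needed.
    """
    mask_a = frames.select(group_a)
    mask_b = frames.select(group_b)
    if not mask_a.any() or not mask_b.any():
        raise EmptySelectionError("empty selection for COM distance")
    com_a = frames.coords[:, mask_a].mean(axis=1)
    com_b = frames.coords[:, mask_b].mean(axis=1)
    return np.linalg.norm(com_a - com_b, axis=1)


def principal_axis_angle_series(frames: FrameSet, group) -> np.ndarray:
    """Per-frame angle (degrees, folded to [0, 90]) between the selection's
    first principal axis and the laboratory Z axis.

    The first principal axis is the eigenvector of the coordinate
    covariance matrix with the largest eigenvalue; its sign is arbitrary,
    hence the folding.
    """
    mask = frames.select(group)
    if mask.sum() < 3:
        raise DegenerateGeometryError("need at least 3 atoms for a principal axis")
    angles = np.empty(frames.n_frames)
    z = np.array([0.0, 0.0, 1.0])
    for f in range(frames.n_frames):
        pts = frames.coords[f, mask]
        centered = pts - pts.mean(axis=0)
        cov = centered.T @ centered / len(pts)
        w, v = np.linalg.eigh(cov)
        if w[-1] < 1e-12 or (w[-1] > 0 and w[-2] / w[-1] < 1e-12 and w[-2] < 1e-12):
            # all mass on one axis with zero spread elsewhere is fine;
            # zero spread on every axis (coincident points) is not
            if w[-1] < 1e-12:
                raise DegenerateGeometryError("coincident atoms: no principal axis")
        axis = v[:, -1]
        cosang = abs(float(np.dot(axis, z)))
        angles[f] = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    return angles


# ---------------------------------------------------------------------------
# annotated-structure I/O (contact probability stored in the B-factor column)
# ---------------------------------------------------------------------------

def read_annotated_pdb(pdb_text: str):
    """Read a structure whose B-factor column carries contact probabilities.

    Returns ``(atoms, profile)`` where ``atoms`` is a biotite AtomArray and
    the profile value of each residue is its Cα B-factor.  Deposited files
    use either a 0–1 or a 0–100 scale; if the maximum Cα B-factor exceeds
    1 the values are divided by 100 (with a warning).  Residues lacking a
    Cα are skipped with a warning; non-standard residue names map to 'X'.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    atoms = pdb.get_structure(model=1, extra_fields=["b_factor"])
    atoms = atoms[struc.filter_amino_acids(atoms) | np.isin(atoms.atom_name, ["CA"])]

    seq_chars = []
    values = []
    chains = []
    for start in struc.get_residue_starts(atoms):
        res_mask = (
            (atoms.chain_id == atoms.chain_id[start])
            & (atoms.res_id == atoms.res_id[start])
        )
        res_atoms = atoms[res_mask]
        ca = res_atoms[res_atoms.atom_name == "CA"]
        if len(ca) == 0:
            logger.warning(
                "residue %s%d lacks a Cα atom; skipped",
                atoms.chain_id[start], atoms.res_id[start],
            )
            continue
        seq_chars.append(three_to_one(str(atoms.res_name[start])))
        values.append(float(ca.b_factor[0]))
        chains.append(str(atoms.chain_id[start]))

    values = np.asarray(values, dtype=float)
    if len(values) and values.max() > 1.0:
        logger.warning("B-factor scale looks like 0–100; dividing by 100")
        values = values / 100.0
    values = np.clip(values, 0.0, 1.0)
    chain_id = chains[0] if len(set(chains)) == 1 else ""
    profile = MCPProfile(
        chain_id=chain_id, sequence="".join(seq_chars), values=values,
        source="annotated_pdb",
    )
    return atoms, profile


def write_annotated_pdb(structure, profile: MCPProfile) -> str:
    """Write a PDB with every atom of residue i carrying B-factor value_i.

    ``structure`` is a biotite AtomArray; the profile must have one value
    per residue (in residue order).  Values are rounded to 2 decimals, the
    precision of the PDB B-factor field.
    """
    atoms = structure.copy()
    starts = struc.get_residue_starts(atoms)
    if len(starts) != len(profile):
        raise LengthMismatchError(
            f"{len(profile)} profile values for {len(starts)} residues"
        )
    b = np.zeros(atoms.array_length())
    bounds = list(starts) + [atoms.array_length()]
    for i in range(len(starts)):
        b[bounds[i]:bounds[i + 1]] = round(float(profile.values[i]), 2)
    atoms.set_annotation("b_factor", b)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# multi-model PDB trajectories
# ---------------------------------------------------------------------------

def assign_roles(
    res_names: np.ndarray,
    atom_names: np.ndarray,
    tail_pattern: str = r"C[0-9]+[AB]?",
) -> np.ndarray:
    """Tag atoms as protein_ca / lipid_tail_carbon / other.

    Protein Cα: atom name CA on a standard amino acid.  Lipid tail carbon:
    atom name matching ``tail_pattern`` on a non-amino-acid residue.
    """
    pat = re.compile(tail_pattern)
    roles = np.full(len(res_names), "other", dtype=object)
    for i, (rn, an) in enumerate(zip(res_names, atom_names)):
        if rn.upper() in _AA3:
            if an == "CA":
                roles[i] = "protein_ca"
        elif pat.fullmatch(an):
            roles[i] = "lipid_tail_carbon"
    return roles.astype(str)


def read_trajectory_pdb(pdb_text: str, tail_pattern: str = r"C[0-9]+[AB]?") -> FrameSet:
    """Read a multi-model (MODEL/ENDMDL) PDB as a FrameSet.

    Other trajectory formats (XTC/DCD) can be adapted to FrameSet through
    any reader that yields coordinates plus atom metadata; the core kernel
    only depends on this container.
    """
    pdb = PDBFile.read(io.StringIO(pdb_text))
    stack = pdb.get_structure()  # AtomArrayStack over all models
    roles = assign_roles(stack.res_name, stack.atom_name, tail_pattern)
    return FrameSet(
        coords=stack.coord,
        roles=roles,
        chain_ids=stack.chain_id.astype(str),
        residue_indices=stack.res_id.astype(int),
        residue_names=stack.res_name.astype(str),
    )


def write_trajectory_pdb(frames: FrameSet) -> str:
    """Write a FrameSet as a multi-model PDB."""
    n = frames.n_atoms
    arr = struc.AtomArrayStack(frames.n_frames, n)
    arr.coord = frames.coords
    arr.chain_id = frames.chain_ids.astype("U4")
    arr.res_id = frames.residue_indices.astype(int)
    arr.res_name = frames.residue_names.astype("U5")
    names = np.where(frames.roles == "protein_ca", "CA", "C1A")
    names = np.where(frames.roles == "other", "X", names)
    arr.atom_name = names.astype("U6")
    arr.element = np.full(n, "C", dtype="U2")
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


def profile_to_tsv(profile: MCPProfile) -> str:
    """TSV export with columns chain, resid, aa, mcp."""
    lines = ["chain\tresid\taa\tmcp"]
    for i, (aa, v) in enumerate(zip(profile.sequence, profile.values)):
        lines.append(f"{profile.chain_id}\t{i + 1}\t{aa}\t{v:.6f}")
    return "\n".join(lines) + "\n"


def profile_from_tsv(text: str, source: str = "md") -> MCPProfile:
    rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
    seq = "".join(r[2] for r in rows)
    vals = np.array([float(r[3]) for r in rows])
    chain = rows[0][0] if rows else "A"
    return MCPProfile(chain_id=chain, sequence=seq, values=vals, source=source)
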