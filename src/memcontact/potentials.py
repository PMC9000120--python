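"""Default residue-pair contact potential.

A symmetric 20×20 table used by the averaged pairwise-potential MSA
feature.  The default shipped here is a deterministic hydrophobicity-based
surrogate: pairs of hydrophobic residues get the most favorable (most
negative) energies, mimicking the shape of knowledge-based contact
potentials.  The table's identity is configuration, not ground truth —
any user-supplied symmetric 20×20 table is accepted wherever this default
is used.
"""

from __future__ import annotations

import numpy as np

from .types import AMINO_ACIDS

POTENTIAL_VERSION = "hydro-surrogate-1"


def default_contact_potential() -> np.ndarray:
    """Symmetric 20×20 surrogate contact potential (AMINO_ACIDS order)."""
    from .synthetic import KYTE_DOOLITTLE

    h = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS]) / 4.5
    table = -np.round(np.outer(h, h), 3)
    return (table + table.T) / 2.0
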