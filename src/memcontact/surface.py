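"""Joint MCP / solvent-accessibility surface characterization.

A residue's membrane contact probability and solvent accessibility jointly
classify it into four regions at a 0.5 cutoff:

  I   mcp > c and sa > c   — water–membrane interface residues
  II  mcp > c and sa <= c  — exposed to the bilayer's hydrophobic core
  III mcp <= c and sa <= c — buried in the protein interior
  IV  mcp <= c and sa > c  — water-exposed

Boundary ties (exactly at the cutoff) fall on the "not exceeding" side.
This module also implements the high-MCP run filter used to flag
membrane-anchoring segments in otherwise soluble proteins: a protein
passes when some window of ``window`` consecutive residues holds at least
``min_count`` values above the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LengthMismatchError, MemcontactError

REGIONS = ("I", "II", "III", "IV")


@dataclass
class QuadrantResult:
    labels: list  # per-residue region label
    counts: dict  # region -> count
    fractions: dict  # region -> fraction of residues
    cutoff: float

    def __post_init__(self):
        if sum(self.counts.values()) != len(self.labels):
            raise MemcontactError("region counts must sum to residue total")


def classify_quadrants(mcp, sa, cutoff: float = 0.5) -> QuadrantResult:
    """Assign each residue to one of the four MCP/SA regions."""
    mcp = np.asarray(mcp, dtype=float)
    sa = np.asarray(sa, dtype=float)
    if mcp.shape != sa.shape:
        raise LengthMismatchError("mcp and sa profiles differ in length")
    if len(mcp) and (min(mcp.min(), sa.min()) < 0 or max(mcp.max(), sa.max()) > 1):
        raise MemcontactError("values must lie in [0, 1]")
    hi_m = mcp > cutoff
    hi_s = sa > cutoff
    labels = np.where(
        hi_m & hi_s, "I",
        np.where(hi_m & ~hi_s, "II", np.where(~hi_m & ~hi_s, "III", "IV")),
    ).tolist()
    counts = {r: labels.count(r) for r in REGIONS}
    n = max(len(labels), 1)
    fractions = {r: counts[r] / n for r in REGIONS}
    return QuadrantResult(labels=labels, counts=counts, fractions=fractions,
                          cutoff=cutoff)


def region_fraction(count: int, total: int) -> tuple:
    """(count, total, percent) with percent rounded to 3 decimal places.

    14 interface residues among 79 796 report as 0.018%.
    """
    if total < 1:
        raise MemcontactError("total must be at least 1")
    return count, total, round(100.0 * count / total, 3)


def dataset_region_fraction(results, region: str) -> tuple:
    """Aggregate a region's share over many QuadrantResults."""
    if region not in REGIONS:
        raise MemcontactError(f"unknown region {region!r}")
    count = sum(r.counts[region] for r in results)
    total = sum(len(r.labels) for r in results)
    return region_fraction(count, total)


def find_anchor_segments(
    mcp,
    high_cutoff: float = 0.5,
    window: int = 10,
    min_count: int = 3,
) -> list:
    """Maximal merged windows containing >= min_count high-MCP residues.

    A protein with an empty result fails the anchoring rule (fewer than
    ``min_count`` high predictions in any ``window`` successive residues)
    and is treated as an outlier.  Segments are returned as (start, end)
    half-open index pairs plus the number of high residues inside.
    Proteins shorter than ``window`` are checked as a single full-length
    window.
    """
    if not (window >= min_count >= 1):
        raise MemcontactError("need window >= min_count >= 1")
    mcp = np.asarray(mcp, dtype=float)
    L = len(mcp)
    high = mcp > high_cutoff
    w = min(window, L)
    starts = [
        s for s in range(L - w + 1) if int(high[s: s + w].sum()) >= min_count
    ]
    if not starts:
        return []
    # merge overlapping/adjacent passing windows into maximal segments
    segments = []
    seg_start, seg_end = starts[0], starts[0] + w
    for s in starts[1:]:
        if s <= seg_end:
            seg_end = s + w
        else:
            segments.append((seg_start, seg_end, int(high[seg_start:seg_end].sum())))
            seg_start, seg_end = s, s + w
    segments.append((seg_start, seg_end, int(high[seg_start:seg_end].sum())))
    return segments
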