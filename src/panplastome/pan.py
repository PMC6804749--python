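"""Per-group consensus pan-plastomes and ambiguity masking.

A pan-plastome collapses all accessions of a group into one consensus:
columns where members agree keep the residue; columns with >=2 distinct
residues get the minimal IUPAC code covering them ("100% of differences,
most ambiguous"); any gap or N among members converts the column to ``N``
(InDels become Ns). When a column both disagrees and contains a gap, ``N``
wins — the more conservative of the two rules.

Masking then removes all within-group signal: every column carrying any
IUPAC code or N in any pan is set to ``N`` in all pans, so the variants
that survive are exclusively fixed between-group differences.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import BITS, CODE_FOR_BITS, AlignedMatrix

PROV_FIXED = 0
PROV_AMBIGUOUS = 1
PROV_INDEL_MASKED = 2
PROVENANCE_LABELS = {PROV_FIXED: "fixed", PROV_AMBIGUOUS: "ambiguous",
                     PROV_INDEL_MASKED: "indel_masked"}

# char -> base bitmask lookup (0 for gap; N handled via its own mask)
_BITS_LUT = np.zeros(256, dtype=np.uint8)
for _c, _b in BITS.items():
    if _c != "N":
        _BITS_LUT[ord(_c)] = _b
_CHAR_LUT = np.full(16, ord("N"), dtype=np.uint8)
for _b, _c in CODE_FOR_BITS.items():
    _CHAR_LUT[_b] = ord(_c)


@dataclass
class PanPlastome:
    """One consensus sequence per group with per-column provenance flags."""

    group: str
    sequence: str
    n_members: int
    provenance: np.ndarray  # uint8 per column: fixed / ambiguous / indel_masked

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_pan_plastome(m: AlignedMatrix, group: str) -> PanPlastome:
    """Collapse the members of ``group`` into a consensus pan-plastome."""
    members = m.group_members(group)
    if not members:
        raise ValueError(f"no members for group {group!r}")
    sub = m.subset(members).to_array()
    any_gap = (sub == ord("-")).any(axis=0)
    any_n = (sub == ord("N")).any(axis=0)
    bits = np.bitwise_or.reduce(_BITS_LUT[sub], axis=0)
    popcount = np.array([bin(b).count("1") for b in range(16)], dtype=np.uint8)[bits]

    cons = _CHAR_LUT[bits]
    prov = np.where(popcount > 1, PROV_AMBIGUOUS, PROV_FIXED).astype(np.uint8)
    masked = any_gap | any_n
    cons[masked] = ord("N")
    prov[masked] = PROV_INDEL_MASKED
    return PanPlastome(group, bytes(cons).decode("ascii"), len(members), prov)


def build_all_pans(m: AlignedMatrix) -> list[PanPlastome]:
    """Pan-plastomes for every group label, in first-appearance order."""
    return [build_pan_plastome(m, g) for g in m.group_labels()]


def mask_ambiguous_columns(pans: list[PanPlastome]
                           ) -> tuple[AlignedMatrix, np.ndarray]:
    """Mask every column carrying any ambiguity or N in any pan.

    Returns the masked pan alignment (one row per group, groups mapping
    each label to itself) and the boolean kept-column mask. Masked columns
    are replaced by ``N`` in all rows, so the output alphabet is
    ``{A,C,G,T,N}`` and every retained variant is fixed within every group.
    """
    if not pans:
        raise ValueError("no pan-plastomes given")
    lengths = {p.length for p in pans}
    if len(lengths) > 1:
        raise ValueError(
            f"pan-plastomes differ in length {sorted(lengths)}; realign them "
            "to a common frame first")
    arr = np.frombuffer("".join(p.sequence for p in pans).encode("ascii"),
                        dtype=np.uint8).reshape(len(pans), -1).copy()
    acgt = np.zeros(256, dtype=bool)
    for b in b"ACGT":
        acgt[b] = True
    clean = acgt[arr].all(axis=0)
    arr[:, ~clean] = ord("N")
    ids = [p.group for p in pans]
    mat = AlignedMatrix(ids, [bytes(r).decode("ascii") for r in arr],
                        groups={g: g for g in ids})
    return mat, clean
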