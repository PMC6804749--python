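"""Quadripartite plastome structure: inverted-repeat detection and IRb trimming.

Plastomes are circular molecules of four segments — a large and a small
single-copy region (LSC, SSC) separated by a pair of inverted repeats
(IRa, IRb) that are exact reverse complements of one another. Detection
finds the longest exact inverted-repeat pair (``N`` acts as a wildcard),
doubling the sequence to handle circularity, and normalizes the rotation
so the LSC starts at coordinate 0.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LocusTable, revcomp

logger = logging.getLogger(__name__)

_N = ord("N")


class NoQuadripartiteStructure(ValueError):
    """No inverted-repeat pair of the requested minimum length exists."""


@dataclass(frozen=True)
class RegionPartition:
    """LSC/IRa/SSC/IRb intervals, 0-based half-open, LSC starting at 0.

    ``rotation`` is the offset such that ``seq[rotation:] + seq[:rotation]``
    places the LSC start at 0; coordinates refer to that rotated frame.
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    rotation: int = 0

    @property
    def ir_length(self) -> int:
        return self.ira[1] - self.ira[0]

    @property
    def length(self) -> int:
        return self.irb[1]

    def to_frame(self) -> pd.DataFrame:
        rows = [("LSC", *self.lsc), ("IRa", *self.ira),
                ("SSC", *self.ssc), ("IRb", *self.irb)]
        return pd.DataFrame(rows, columns=["region", "start", "end"])


def rotate_sequence(seq: str, rotation: int) -> str:
    return seq[rotation:] + seq[:rotation]


def _match(a: int, b: int) -> bool:
    return a == b or a == _N or b == _N


def detect_inverted_repeats(seq: str, min_ir: int = 1000) -> RegionPartition:
    """Find the quadripartite partition whose IR pair is the longest exact
    inverted repeat of at least ``min_ir`` bp.

    Matching is exact over A/C/G/T with ``N`` as a wildcard. The circular
    molecule is handled by doubling the sequence; candidate pairs are found
    by k-mer seeding against the reverse complement and extended along
    their anti-diagonal. Among equal-length candidates the pair giving the
    smallest LSC start wins.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 4 * min_ir:
        raise ValueError(f"sequence of {n} bp too short for min_ir={min_ir}")
    D = seq + seq
    darr = np.frombuffer(D.encode("ascii"), dtype=np.uint8)
    rcd = revcomp(D)

    k = min(24, min_ir)
    index: dict[str, list[int]] = {}
    for j in range(len(rcd) - k + 1):
        w = rcd[j:j + k]
        if "N" in w or "-" in w:
            continue
        index.setdefault(w, []).append(j)

    # group seed hits by anti-diagonal c = i + p (invariant along one IR pair)
    best_by_diag: dict[int, tuple[int, int]] = {}
    for i in range(len(D) - k + 1):
        w = D[i:i + k]
        hits = index.get(w)
        if not hits:
            continue
        for j in hits:
            p = 2 * n - k - j  # start in D of the partner segment
            if p < 0 or p >= 2 * n:
                continue
            c = i + p
            if c not in best_by_diag or i < best_by_diag[c][0]:
                best_by_diag[c] = (i, p)

    comp = {ord(x): ord(y) for x, y in zip("ACGTN", "TGCAN")}
    candidates: dict[tuple[int, int, int], None] = {}
    for i0, p0 in best_by_diag.values():
        i, p, L = i0, p0, k
        # extend left of B (i-1) pairing with right of A (p+L)
        while i - 1 >= 0 and p + L < 2 * n and _match(darr[i - 1], comp.get(darr[p + L], 0)):
            i -= 1
            L += 1
        # extend right of B (i+L) pairing with left of A (p-1)
        while i + L < 2 * n and p - 1 >= 0 and _match(darr[i + L], comp.get(darr[p - 1], 0)):
            p -= 1
            L += 1
        if L < min_ir or L > n:
            continue
        a, b = p % n, i % n
        if a > b:
            a, b = b, a
        # the two copies must be disjoint on the circle
        gap1 = (b - (a + L)) % n
        gap2 = (a - (b + L)) % n
        if gap1 + gap2 + 2 * L != n:
            continue  # overlapping copies (e.g. a palindrome), not a valid IR pair
        candidates[(L, a, b)] = None

    if not candidates:
        raise NoQuadripartiteStructure(
            f"no quadripartite structure: no inverted repeat >= {min_ir} bp"
        )

    def partition_for(L: int, a: int, b: int) -> RegionPartition:
        gap1 = (b - (a + L)) % n  # segment after copy A
        gap2 = (a - (b + L)) % n  # segment after copy B
        if gap1 >= gap2:
            lsc_len, ssc_len = gap1, gap2
            rotation = (a + L) % n  # LSC follows copy A; IRa := copy B
        else:
            lsc_len, ssc_len = gap2, gap1
            rotation = (b + L) % n  # LSC follows copy B; IRa := copy A
        lsc = (0, lsc_len)
        ira = (lsc_len, lsc_len + L)
        ssc = (lsc_len + L, lsc_len + L + ssc_len)
        irb = (lsc_len + L + ssc_len, n)
        return RegionPartition(lsc, ira, ssc, irb, rotation=rotation)

    best_L = max(L for L, _, _ in candidates)
    parts = [partition_for(L, a, b) for (L, a, b) in candidates if L == best_L]
    parts.sort(key=lambda p: p.rotation)
    return parts[0]


def trim_irb(seq: str, partition: RegionPartition, loci: LocusTable,
             junction_locus: str = "ycf1") -> tuple[str, LocusTable]:
    """Trim the IRb, keeping only the prefix needed so the locus spanning the
    SSC/IRb junction (``ycf1`` by default) remains fully contained.

    ``seq`` and ``loci`` must be in the partition's normalized frame
    (LSC start at 0, IRb last). Loci entirely inside the removed tail are
    dropped; a locus with no junction overlap triggers a full IRb trim
    with a warning.
    """
    irb_s, irb_e = partition.irb
    if irb_e != len(seq):
        raise ValueError("partition not normalized to LSC-start-0 frame")
    keep = 0
    sel = loci.df[(loci.df["name"] == junction_locus)
                  & (loci.df["start"] < irb_s) & (loci.df["end"] > irb_s)]
    if sel.empty:
        logger.warning("no locus %r spans the SSC/IRb junction; trimming the whole IRb",
                       junction_locus)
    else:
        keep = int(sel.iloc[0]["end"]) - irb_s
    cut = irb_s + keep
    new_seq = seq[:cut]
    df = loci.df[loci.df["start"] < cut].copy()
    clipped = df["end"] > cut
    if clipped.any():
        kept_names = set(df.loc[clipped, "name"]) - {junction_locus}
        if kept_names:
            logger.warning("loci truncated at IRb cut: %s", sorted(kept_names))
        df.loc[clipped, "end"] = cut
    return new_seq, LocusTable(df, coord_system=loci.coord_system, length=cut)
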