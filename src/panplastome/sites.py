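"""Column-level alignment operations.

Site classification follows the usual population-genetic definitions: a
segregating site has >=2 nucleotide states; a singleton site is a variable
column whose minority states each occur exactly once; a parsimony-informative
site has at least two states each present in >=2 sequences; Eta (the minimum
mutation count) adds ``states - 1`` per variable column. ``N`` and non-N
ambiguity letters are treated as missing data; gaps are tallied separately.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .matrix import AlignedMatrix

logger = logging.getLogger(__name__)

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")


class SiteClass(str, Enum):
    INVARIANT = "invariant"
    SINGLETON = "singleton"
    PARSIMONY_INFORMATIVE = "parsimony_informative"
    ALL_GAP = "all_gap"


@dataclass
class SiteClassification:
    """Per-column state counts and classes plus alignment-wide totals."""

    classes: np.ndarray            # array of SiteClass values, length L
    k_variants: np.ndarray         # distinct non-gap, non-N states per column
    base_counts: np.ndarray        # (4, L) counts of A, C, G, T
    gap_counts: np.ndarray         # gaps per column
    missing_counts: np.ndarray     # N / ambiguity letters per column
    S: int = field(init=False)
    Eta: int = field(init=False)
    n_singleton: int = field(init=False)
    n_pi: int = field(init=False)
    n_invariant: int = field(init=False)
    n_all_gap: int = field(init=False)

    def __post_init__(self) -> None:
        cls = self.classes
        self.n_singleton = int(np.sum(cls == SiteClass.SINGLETON.value))
        self.n_pi = int(np.sum(cls == SiteClass.PARSIMONY_INFORMATIVE.value))
        self.n_invariant = int(np.sum(cls == SiteClass.INVARIANT.value))
        self.n_all_gap = int(np.sum(cls == SiteClass.ALL_GAP.value))
        self.S = self.n_singleton + self.n_pi
        variable = self.k_variants >= 2
        self.Eta = int(np.sum(self.k_variants[variable] - 1))

    def state_counts(self, col: int) -> dict[str, int]:
        counts = {b: int(self.base_counts[i, col]) for i, b in enumerate("ACGT")
                  if self.base_counts[i, col]}
        if self.gap_counts[col]:
            counts["-"] = int(self.gap_counts[col])
        if self.missing_counts[col]:
            counts["N"] = int(self.missing_counts[col])
        return counts


def classify_sites(m: AlignedMatrix) -> SiteClassification:
    """Classify every column as invariant / singleton / parsimony-informative /
    all-gap, counting A/C/G/T states only (N and ambiguity codes are missing)."""
    arr = m.to_array()
    counts = np.stack([(arr == b).sum(axis=0) for b in _ACGT])  # (4, L)
    gaps = (arr == _GAP).sum(axis=0)
    missing = arr.shape[0] - counts.sum(axis=0) - gaps
    k = (counts > 0).sum(axis=0)
    ge2 = (counts >= 2).sum(axis=0)

    cls = np.empty(arr.shape[1], dtype=object)
    cls[k == 0] = SiteClass.ALL_GAP.value
    cls[k == 1] = SiteClass.INVARIANT.value
    singleton = (k >= 2) & (ge2 <= 1)
    cls[singleton] = SiteClass.SINGLETON.value
    cls[(k >= 2) & (ge2 >= 2)] = SiteClass.PARSIMONY_INFORMATIVE.value
    return SiteClassification(cls, k, counts, gaps, missing)


def filter_gap_columns(m: AlignedMatrix, max_gap_fraction: float = 0.996
                       ) -> tuple[AlignedMatrix, np.ndarray]:
    """Drop every column whose gap fraction is >= ``max_gap_fraction``.

    Returns the filtered matrix and an old->new column index map (``-1``
    for removed columns). The default 0.996 removes columns gapped in at
    least 99.6% of rows; a threshold of 1.0 removes only fully gapped
    columns.
    """
    if not (0 < max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must be in (0, 1]")
    arr = m.to_array()
    frac = (arr == _GAP).sum(axis=0) / m.n
    keep = frac < max_gap_fraction
    if not keep.any():
        raise ValueError("gap filtering removed every column")
    col_map = np.full(m.length, -1, dtype=np.int64)
    col_map[keep] = np.arange(int(keep.sum()))
    return m.slice_columns(keep), col_map


@dataclass(frozen=True)
class IndelEvent:
    """A maximal run of contiguous columns sharing one gap-presence pattern."""

    start: int
    end: int
    pattern: frozenset[str]  # ids gapped across the block

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_indel_events(m: AlignedMatrix) -> list[IndelEvent]:
    """Maximal blocks of identical gap-presence pattern containing >=1 gap,
    non-overlapping and sorted by start. The union of event column ranges is
    exactly the set of gap-containing columns."""
    arr = m.to_array()
    G = arr == _GAP  # (n, L)
    L = m.length
    if L == 0:
        return []
    change = np.empty(L, dtype=bool)
    change[0] = True
    if L > 1:
        change[1:] = (G[:, 1:] != G[:, :-1]).any(axis=0)
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], L)
    events = []
    ids = np.array(m.ids, dtype=object)
    for s, e in zip(starts, ends):
        col = G[:, s]
        if col.any():
            events.append(IndelEvent(int(s), int(e), frozenset(ids[col])))
    return events


@dataclass
class Haplotype:
    """An equivalence class of accessions identical under the comparison mode."""

    representative: str       # sequence of the first member in input order
    members: list[str]
    groups: dict[str, int]    # group label -> member count

    @property
    def count(self) -> int:
        return len(self.members)


def _pairwise_identical(arr: np.ndarray, i: int, gap_mode: str) -> np.ndarray:
    """Boolean vector: which rows are 'identical' to row i under the mode."""
    a = arr[i]
    n_char = ord("N")
    if gap_mode == "gaps_as_state":
        eq = (arr == a) | (arr == n_char) | (a == n_char)
        return eq.all(axis=1)
    if gap_mode == "gaps_ignored":
        gap = ord("-")
        usable = (arr != gap) & (a != gap)
        eq = (arr == a) | (arr == n_char) | (a == n_char) | ~usable
        return eq.all(axis=1)
    raise ValueError(f"unknown gap_mode {gap_mode!r}")


def collapse_haplotypes(m: AlignedMatrix, gap_mode: str = "gaps_as_state"
                        ) -> list[Haplotype]:
    """Partition accessions into haplotypes identical under ``gap_mode``.

    ``gaps_as_state`` compares gap characters as a fifth state;
    ``gaps_ignored`` compares only columns where neither sequence is gapped.
    ``N`` matches any residue in both modes. Because both relations can be
    intransitive, classes are the single-linkage (connected-component)
    closure; a closure that merges non-matching pairs is logged.
    """
    arr = m.to_array()
    n = m.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    match_rows = []
    for i in range(n):
        eq = _pairwise_identical(arr, i, gap_mode)
        match_rows.append(eq)
        for j in np.flatnonzero(eq):
            if j > i:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri

    comps: dict[int, list[int]] = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)

    haps = []
    for root in sorted(comps, key=lambda r: min(comps[r])):
        members_idx = sorted(comps[root])
        for i in members_idx:
            if not all(match_rows[i][j] for j in members_idx):
                logger.warning(
                    "haplotype closure (%s) merged non-identical pair within "
                    "class of %s", gap_mode, m.ids[members_idx[0]])
                break
        members = [m.ids[i] for i in members_idx]
        groups: dict[str, int] = {}
        if m.groups:
            for a in members:
                g = m.groups.get(a)
                if g is not None:
                    groups[g] = groups.get(g, 0) + 1
        haps.append(Haplotype(m.seqs[members_idx[0]], members, groups))
    return haps
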