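"""Perfect SSR (microsatellite) and tandem-repeat detection.

Both scanners report maximal perfect runs only. The unit-length domains
are split at 6/7 bp — motifs of 1-6 bp are SSRs, units of 7-200 bp are
tandem repeats — so no run is reported twice. Partial trailing copies are
not counted: a 101 bp AT run is 50 copies with a 1 bp remainder.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import AlignedMatrix, LocusTable, revcomp
from .pan import PanPlastome

logger = logging.getLogger(__name__)

#: MISA-style minimum copy numbers per motif length.
DEFAULT_SSR_MIN_COPIES = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRHit:
    """A maximal perfect microsatellite run.

    ``motif`` is strand-canonical: the lexicographically minimal rotation
    over the motif and its reverse complement. ``run_length`` counts whole
    copies only (``copies * len(motif)``); any partial trailing copy is in
    ``remainder``.
    """

    motif: str
    start: int
    run_length: int
    copies: int
    remainder: int = 0


@dataclass(frozen=True)
class RepeatHit:
    """A maximal perfect tandem array of a primitive 7-200 bp unit."""

    unit: str
    start: int
    copies: int
    span: int
    remainder: int = 0


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of the motif or its reverse complement."""
    variants = [motif[i:] + motif[:i] for i in range(len(motif))]
    rc = revcomp(motif)
    variants += [rc[i:] + rc[:i] for i in range(len(rc))]
    return min(variants)


def is_primitive(unit: str) -> bool:
    """True if the unit is not itself a whole-number repeat of a shorter unit."""
    p = len(unit)
    for d in range(1, p):
        if p % d == 0 and unit == unit[:d] * (p // d):
            return False
    return True


def _maximal_runs(arr: np.ndarray, p: int):
    """Yield (start, region_length) of maximal runs with period ``p``.

    A run [s, s+rlen) satisfies seq[i] == seq[i+p] for all i in
    [s, s+rlen-p) and cannot be extended in either direction.
    """
    n = arr.size
    if n < 2 * p:
        return
    eq = arr[:-p] == arr[p:]
    if not eq.any():
        return
    padded = np.concatenate(([False], eq, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    for s, e in zip(starts, ends):
        yield int(s), int(e - s + p)


def find_ssrs(seq: str, min_copies: dict[int, int] | None = None) -> list[SSRHit]:
    """All maximal perfect SSR runs (motif 1-6 bp) meeting the per-length
    minimum copy numbers, sorted by start; one report per run, under the
    canonical motif. Runs whose motif contains N or a gap are skipped."""
    min_copies = dict(DEFAULT_SSR_MIN_COPIES if min_copies is None else min_copies)
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    hits = []
    for m in range(1, 7):
        need = min_copies.get(m)
        if need is None:
            continue
        for s, rlen in _maximal_runs(arr, m):
            copies, rem = divmod(rlen, m)
            if copies < max(need, 2):
                continue
            unit = seq[s:s + m].upper()
            if not is_primitive(unit) or set(unit) - set("ACGT"):
                continue
            hits.append(SSRHit(canonical_motif(unit), s, copies * m, copies, rem))
    hits.sort(key=lambda h: (h.start, len(h.motif)))
    return hits


def find_perfect_tandem_repeats(seq: str, min_unit: int = 7, max_unit: int = 200,
                                min_copies: int = 2) -> list[RepeatHit]:
    """Maximal perfect tandem arrays with primitive unit in [min_unit,
    max_unit]; arrays whose primitive unit is <= 6 bp belong to the SSR
    domain and are excluded."""
    s_upper = seq.upper()
    arr = np.frombuffer(s_upper.encode("ascii"), dtype=np.uint8)
    hits = []
    for p in range(min_unit, min(max_unit, arr.size // 2) + 1):
        for s, rlen in _maximal_runs(arr, p):
            copies, rem = divmod(rlen, p)
            if copies < min_copies:
                continue
            unit = s_upper[s:s + p]
            if not is_primitive(unit) or set(unit) - set("ACGT"):
                continue
            hits.append(RepeatHit(unit, s, copies, copies * p, rem))
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


def _locus_of(loci: LocusTable, pos: int) -> str | None:
    sel = loci.df[(loci.df["start"] <= pos) & (pos < loci.df["end"])]
    if sel.empty:
        return None
    return str(sel.iloc[0]["name"])


def polymorphic_repeat_loci(pans: list[PanPlastome], loci: LocusTable,
                            members: AlignedMatrix | None = None,
                            ssr_min_copies: dict[int, int] | None = None,
                            ) -> pd.DataFrame:
    """Per (locus, unit) copy numbers across the pan-plastomes.

    A row is flagged ``polymorphic`` when >=2 distinct copy numbers occur
    among the groups (a group without the repeat counts as 0 copies).
    With ``members`` given (per-accession alignment with group labels),
    within-group copy-number variation is flagged separately in
    ``intragroup_polymorphic``.
    """
    records: dict[tuple[str | None, str, str], dict[str, int]] = {}

    def scan(seq: str, pos_map: np.ndarray | None = None):
        found = []
        for h in find_ssrs(seq, ssr_min_copies):
            found.append(("SSR", h.motif, h.start, h.copies))
        for h in find_perfect_tandem_repeats(seq):
            found.append(("tandem", canonical_motif(h.unit), h.start, h.copies))
        for kind, unit, start, copies in found:
            frame_pos = int(pos_map[start]) if pos_map is not None else start
            locus = _locus_of(loci, frame_pos)
            if locus is None:
                logger.warning("repeat at %d outside any locus; skipped", frame_pos)
                continue
            yield_key = (locus, kind, unit)
            yield yield_key, copies

    for p in pans:
        for key, copies in scan(p.sequence):
            records.setdefault(key, {})[p.group] = copies

    if members is not None and members.groups:
        for acc, seq in zip(members.ids, members.seqs):
            g = members.groups.get(acc)
            if g is None:
                continue
            pos_map = np.flatnonzero(
                np.frombuffer(seq.encode(), dtype=np.uint8) != ord("-"))
            ungapped = seq.replace("-", "")
            for key, copies in scan(ungapped, pos_map):
                records.setdefault(key, {})[f"__{g}__{acc}"] = copies

    groups = [p.group for p in pans]
    rows = []
    for (locus, kind, unit), per in sorted(records.items(),
                                           key=lambda kv: (str(kv[0][0]), kv[0][2])):
        copies = {g: per.get(g, 0) for g in groups}
        intra_poly = False
        if members is not None and members.groups:
            for g in sorted(set(members.groups.values())):
                accs = members.group_members(g)
                vals = {per.get(f"__{g}__{a}", 0) for a in accs}
                if len(vals) > 1:
                    intra_poly = True
                    break
        row = {"locus": locus, "kind": kind, "unit": unit,
               "unit_length": len(unit),
               "polymorphic": len(set(copies.values())) > 1,
               "intragroup_polymorphic": intra_poly}
        row.update({f"copies_{g}": c for g, c in copies.items()})
        rows.append(row)
    return pd.DataFrame(rows)
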