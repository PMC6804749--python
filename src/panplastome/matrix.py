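"""Core in-memory containers for aligned plastome data.

Coordinates are 0-based half-open throughout the package; conversion to
1-based happens only when reports are written.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes (upper case) plus gap.
IUPAC_BASES = "ACGT"
IUPAC_AMBIGUOUS = "RYSWKMBDHVN"
GAP = "-"
ALPHABET = frozenset(IUPAC_BASES + IUPAC_AMBIGUOUS + GAP)

#: bitmask per base: A=1, C=2, G=4, T=8; ambiguity codes are unions.
BITS = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "R": 1 | 4, "Y": 2 | 8, "S": 2 | 4, "W": 1 | 8,
    "K": 4 | 8, "M": 1 | 2,
    "B": 2 | 4 | 8, "D": 1 | 4 | 8, "H": 1 | 2 | 8, "V": 1 | 2 | 4,
    "N": 15,
}
CODE_FOR_BITS = {v: k for k, v in BITS.items()}

LOCUS_CLASSES = ("CDS", "intron", "IGS", "tRNA", "rRNA")

_COMPLEMENT = bytes.maketrans(
    b"ACGTRYSWKMBDHVN-", b"TGCAYRSWMKVHDBN-"
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware, gap-preserving)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


class UnalignedInputError(ValueError):
    """Sequences of unequal length where an alignment is required."""


class AlphabetError(ValueError):
    """A character outside the declared nucleotide alphabet."""


@dataclass
class AlignedMatrix:
    """A rectangular multiple alignment with optional group labels.

    Parameters
    ----------
    ids : sequence of str
        Unique accession identifiers, one per row.
    seqs : sequence of str
        Upper-case sequences over ``{A,C,G,T,-,N}`` plus IUPAC ambiguity
        letters; all of identical length.
    groups : mapping id -> group label, optional
        May cover a subset of ``ids``.
    """

    ids: list[str]
    seqs: list[str]
    groups: dict[str, str] | None = None
    _arr: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.seqs = [s.upper().replace("U", "T") for s in self.seqs]
        if not self.seqs:
            raise ValueError("empty alignment")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate accession ids")
        L = len(self.seqs[0])
        if L < 1:
            raise ValueError("alignment length must be >= 1")
        for i, s in enumerate(self.seqs):
            if len(s) != L:
                raise UnalignedInputError(
                    f"unaligned input: record {self.ids[i]!r} has length "
                    f"{len(s)}, expected {L}"
                )
        bad = set("".join(self.seqs)) - ALPHABET
        if bad:
            # locate the first offending character for the error message
            for i, s in enumerate(self.seqs):
                for j, c in enumerate(s):
                    if c in bad:
                        raise AlphabetError(
                            f"illegal character {c!r} in record "
                            f"{self.ids[i]!r} at position {j}"
                        )
        if self.groups is not None:
            unknown = set(self.groups) - set(self.ids)
            if unknown:
                raise ValueError(f"group table names unknown ids: {sorted(unknown)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def to_array(self) -> np.ndarray:
        """(n, length) uint8 view of the alignment (ASCII codes), cached."""
        if self._arr is None:
            buf = "".join(self.seqs).encode("ascii")
            self._arr = np.frombuffer(buf, dtype=np.uint8).reshape(self.n, self.length)
        return self._arr

    # -- derived matrices -----------------------------------------------
    def slice_columns(self, cols: np.ndarray | Sequence[int]) -> "AlignedMatrix":
        """New matrix keeping the given columns (boolean mask or index array)."""
        arr = self.to_array()
        cols = np.asarray(cols)
        sub = arr[:, cols] if cols.dtype != bool else arr[:, cols]
        seqs = [bytes(row).decode("ascii") for row in sub]
        return AlignedMatrix(list(self.ids), seqs, dict(self.groups) if self.groups else None)

    def subset(self, ids: Iterable[str]) -> "AlignedMatrix":
        ids = list(ids)
        index = {a: i for i, a in enumerate(self.ids)}
        missing = [a for a in ids if a not in index]
        if missing:
            raise KeyError(f"ids not in alignment: {missing}")
        seqs = [self.seqs[index[a]] for a in ids]
        groups = None
        if self.groups is not None:
            groups = {a: self.groups[a] for a in ids if a in self.groups}
        return AlignedMatrix(ids, seqs, groups)

    def group_members(self, label: str) -> list[str]:
        if self.groups is None:
            return []
        return [a for a in self.ids if self.groups.get(a) == label]

    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        if self.groups is None:
            return []
        seen: list[str] = []
        for a in self.ids:
            g = self.groups.get(a)
            if g is not None and g not in seen:
                seen.append(g)
        return seen


class LocusTableError(ValueError):
    pass


@dataclass
class LocusTable:
    """Named, classed intervals (CDS/intron/IGS/tRNA/rRNA) on one coordinate system.

    Backed by a DataFrame with columns ``name, cls, start, end, strand``,
    sorted by start. Names are unique within a class; IGS records may not
    overlap CDS records.
    """

    df: pd.DataFrame
    coord_system: str = "alignment"
    length: int | None = None  # length of the coordinate system, if known

    def __post_init__(self) -> None:
        required = ["name", "cls", "start", "end", "strand"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise LocusTableError(f"locus table missing columns: {missing}")
        df = self.df.copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        bad_cls = set(df["cls"]) - set(LOCUS_CLASSES)
        if bad_cls:
            raise LocusTableError(f"unknown locus class(es): {sorted(bad_cls)}")
        bad = df[df["start"] >= df["end"]]
        if not bad.empty:
            r = bad.iloc[0]
            raise LocusTableError(f"locus {r['name']!r}: start {r.start} >= end {r.end}")
        if (df["start"] < 0).any():
            raise LocusTableError("negative start coordinate")
        if self.length is not None and (df["end"] > self.length).any():
            r = df[df["end"] > self.length].iloc[0]
            raise LocusTableError(
                f"locus {r['name']!r} end {r.end} exceeds sequence length {self.length}"
            )
        bad_strand = set(df["strand"]) - {"+", "-"}
        if bad_strand:
            raise LocusTableError(f"strand must be +/-, got {sorted(bad_strand)}")
        for cls, grp in df.groupby("cls"):
            dup = grp["name"][grp["name"].duplicated()]
            if not dup.empty:
                raise LocusTableError(f"duplicate {cls} name {dup.iloc[0]!r}")
        # IGS must not overlap CDS
        igs = df[df["cls"] == "IGS"]
        cds = df[df["cls"] == "CDS"]
        for _, a in igs.iterrows():
            hit = cds[(cds["start"] < a["end"]) & (a["start"] < cds["end"])]
            if not hit.empty:
                b = hit.iloc[0]
                raise LocusTableError(
                    f"IGS {a['name']!r} [{a.start},{a.end}) overlaps "
                    f"CDS {b['name']!r} [{b.start},{b.end})"
                )
        self.df = df.sort_values("start", kind="stable").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return (row for _, row in self.df.iterrows())

    def get(self, name: str, cls: str | None = None) -> pd.Series:
        sel = self.df[self.df["name"] == name]
        if cls is not None:
            sel = sel[sel["cls"] == cls]
        if sel.empty:
            raise KeyError(f"no locus named {name!r}" + (f" of class {cls}" if cls else ""))
        return sel.iloc[0]

    def of_class(self, *classes: str) -> pd.DataFrame:
        return self.df[self.df["cls"].isin(classes)]


def from_dict(records: Mapping[str, str], groups: Mapping[str, str] | None = None) -> AlignedMatrix:
    """Convenience constructor from an ordered ``{id: seq}`` mapping."""
    return AlignedMatrix(list(records), list(records.values()),
                         dict(groups) if groups else None)
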