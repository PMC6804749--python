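"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, Newick through dendropy, tables through
pandas (tab-delimited, header row, ``#`` comments). All loaders validate
into the package's domain types.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .matrix import AlignedMatrix, LocusTable, LocusTableError

logger = logging.getLogger(__name__)

FASTA_WRAP = 70  # fixed line wrap on write, for reproducible output


def load_groups(path: str | Path) -> dict[str, str]:
    """Read an accession -> group label table (TSV with columns id, group)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "id" not in cols or "group" not in cols:
        raise ValueError(f"group table {path} needs columns 'id' and 'group'")
    return dict(zip(df["id"], df["group"]))


def load_alignment(path: str | Path, group_table: str | Path | None = None) -> AlignedMatrix:
    """Load a (multi-)FASTA into an :class:`AlignedMatrix`.

    Lower case is folded to upper and RNA ``U`` mapped to ``T``. Records of
    unequal length raise :class:`UnalignedInputError` naming the offender.
    """
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    groups = load_groups(group_table) if group_table else None
    if groups is not None:
        groups = {a: g for a, g in groups.items() if a in set(ids)}
    return AlignedMatrix(ids, seqs, groups)


def write_fasta(records: AlignedMatrix | Mapping[str, str], path: str | Path) -> None:
    """Write sequences as FASTA with a fixed 70-column wrap."""
    if isinstance(records, AlignedMatrix):
        items = zip(records.ids, records.seqs)
    else:
        items = records.items()
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), FASTA_WRAP):
                fh.write(seq[i:i + FASTA_WRAP] + "\n")


def load_locus_table(path: str | Path, coord_system: str = "alignment",
                     length: int | None = None) -> LocusTable:
    """Read a locus annotation TSV with columns name/class/start/end/strand."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str})
    df.columns = [c.lower() for c in df.columns]
    if "class" in df.columns:
        df = df.rename(columns={"class": "cls"})
    if df.empty:
        logger.warning("locus table %s is empty", path)
        df = pd.DataFrame(columns=["name", "cls", "start", "end", "strand"])
    missing = [c for c in ("name", "cls", "start", "end", "strand") if c not in df.columns]
    if missing:
        raise LocusTableError(f"locus table {path} missing columns: {missing}")
    return LocusTable(df, coord_system=coord_system, length=length)


def write_locus_table(table: LocusTable, path: str | Path) -> None:
    df = table.df.rename(columns={"cls": "class"})
    df.to_csv(path, sep="\t", index=False)


def load_tree(path: str | Path) -> dendropy.Tree:
    """Read a Newick tree; tip labels must be unique, branch lengths >= 0."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    for e in tree.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError(f"negative branch length {e.length}")
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", unquoted_underscores=True,
               suppress_rooting=True)
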