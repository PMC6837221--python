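"""Alignment, tree and annotation-track I/O, coordinate maps and the PKC/GMP split.

Mature kappa-casein is analysed as two concatenated regions: the N-terminal
para-kappa-casein (PKC), which faces the casein-micelle interior, and the
C-terminal glycomacropeptide (GMP), released by gastric cleavage. The split is
defined by the known cleavage position in a reference taxon (bovine: after
residue 105 of the mature chain) and propagated to every other sequence
through the alignment columns.

Coordinate conventions: alignment columns and ungapped residue positions are
both 1-based; a cleavage site is encoded by the index of the residue it
follows (cleavage after residue ``i``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_VALID = frozenset(AMINO_ACIDS + GAP)

PKC = "PKC"
GMP = "GMP"


class AlignmentShapeError(ValueError):
    """Rows of a FASTA alignment have unequal lengths."""


class AlphabetError(ValueError):
    """A sequence contains a symbol outside the 20 amino acids + gap."""


@dataclass(frozen=True)
class Alignment:
    """A gapped multiple sequence alignment of mature protein sequences.

    rows : ordered (taxon_id, gapped_seq) pairs; all sequences share the same
    length and use uppercase one-letter amino-acid codes plus ``-`` for gaps.
    """

    rows: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentShapeError("alignment has no rows")
        n = len(self.rows[0][1])
        seen: set[str] = set()
        for taxon, seq in self.rows:
            if len(seq) != n:
                raise AlignmentShapeError(
                    f"row {taxon!r} has length {len(seq)}, expected {n}"
                )
            if taxon in seen:
                raise ValueError(f"duplicate taxon id {taxon!r}")
            seen.add(taxon)
            bad = set(seq) - _VALID
            if bad:
                col = next(i for i, c in enumerate(seq, 1) if c in bad)
                raise AlphabetError(
                    f"row {taxon!r} column {col}: invalid symbol {seq[col - 1]!r}"
                )
            if set(seq) == {GAP}:
                raise AlignmentShapeError(f"row {taxon!r} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(t for t, _ in self.rows)

    def sequence(self, taxon: str) -> str:
        for t, s in self.rows:
            if t == taxon:
                return s
        raise KeyError(f"taxon {taxon!r} not in alignment")

    def ungapped(self, taxon: str) -> str:
        return self.sequence(taxon).replace(GAP, "")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ColumnMap:
    """Bijection between non-gap alignment columns and 1-based residue positions."""

    taxon_id: str
    col_to_pos: tuple[int | None, ...]

    @property
    def pos_to_col(self) -> tuple[int, ...]:
        return tuple(c for c, p in enumerate(self.col_to_pos, 1) if p is not None)

    def position(self, column: int) -> int | None:
        """1-based residue position at 1-based ``column`` (None at a gap)."""
        return self.col_to_pos[column - 1]

    def column(self, position: int) -> int:
        """1-based alignment column holding 1-based residue ``position``."""
        return self.pos_to_col[position - 1]


@dataclass(frozen=True)
class RegionMap:
    """Per-column PKC/GMP labels derived from a reference cleavage site."""

    region_of_column: tuple[str, ...]
    reference_taxon: str
    cleavage_pos: int

    def columns(self, region: str) -> tuple[int, ...]:
        return tuple(
            c for c, r in enumerate(self.region_of_column, 1) if r == region
        )

    def region_sequence(self, alignment: Alignment, taxon: str, region: str) -> str:
        """Degapped subsequence of ``taxon`` restricted to ``region`` columns."""
        seq = alignment.sequence(taxon)
        return "".join(
            seq[c - 1] for c in self.columns(region) if seq[c - 1] != GAP
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": range(1, len(self.region_of_column) + 1),
                "region": self.region_of_column,
            }
        )


@dataclass
class DatedTree:
    """A rooted tree with nonnegative branch lengths in Myr or subst/site."""

    tree: dendropy.Tree
    length_unit: str = "Myr"

    @property
    def leaf_labels(self) -> tuple[str, ...]:
        return tuple(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def __len__(self) -> int:
        return len(self.leaf_labels)


@dataclass(frozen=True)
class NumericTrack:
    """Per-residue numeric annotation (e.g. disorder or glycosylation score)."""

    taxon_id: str
    values: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.values)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into an :class:`Alignment`.

    Identifiers are the first whitespace-delimited token of each header;
    sequences are uppercased. Ragged records raise
    :class:`AlignmentShapeError`; ambiguity codes (B, Z, X, ...) raise
    :class:`AlphabetError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentShapeError(f"no FASTA records in {path}")
    rows = tuple((rec.id, str(rec.seq).upper()) for rec in records)
    return Alignment(rows)


def write_alignment(alignment: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=taxon, description="") for taxon, seq in alignment.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def read_tree(path, length_unit: str = "Myr") -> DatedTree:
    """Read a rooted Newick tree with branch lengths; polytomies are kept."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("unlabelled leaf in tree")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate leaf labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")
    return DatedTree(tree=tree, length_unit=length_unit)


def write_tree(dated: DatedTree, path) -> None:
    dated.tree.write(path=str(path), schema="newick", suppress_rooting=True)


def prune_to_taxa(dated: DatedTree, taxa: Iterable[str]) -> DatedTree:
    """Restrict the tree to ``taxa``, suppressing degree-2 nodes.

    Branch lengths of suppressed nodes are summed so root-to-leaf path
    lengths of retained leaves are preserved.
    """
    keep = set(taxa)
    present = set(dated.leaf_labels)
    missing = sorted(keep - present)
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    clone = dendropy.Tree(dated.tree)
    clone.retain_taxa_with_labels(sorted(keep))
    # drop any stem edge left above the new root so the root is the MRCA
    clone.seed_node.edge.length = None
    return DatedTree(tree=clone, length_unit=dated.length_unit)


def build_column_map(alignment: Alignment, taxon: str) -> ColumnMap:
    seq = alignment.sequence(taxon)
    pos = 0
    col_to_pos: list[int | None] = []
    for ch in seq:
        if ch == GAP:
            col_to_pos.append(None)
        else:
            pos += 1
            col_to_pos.append(pos)
    return ColumnMap(taxon_id=taxon, col_to_pos=tuple(col_to_pos))


def split_regions(
    alignment: Alignment, reference_taxon: str, cleavage_pos: int = 105
) -> RegionMap:
    """Label every column PKC or GMP from the reference cleavage site.

    Columns at or before the reference's ``cleavage_pos`` residue column are
    PKC; all later columns are GMP. For bovine, ``cleavage_pos=105`` encodes
    the Phe105|Met106 chymosin/pepsin site of the mature chain.
    """
    cmap = build_column_map(alignment, reference_taxon)
    n_res = len(alignment.ungapped(reference_taxon))
    if not 1 <= cleavage_pos <= n_res:
        raise ValueError(
            f"cleavage_pos {cleavage_pos} outside 1..{n_res} for {reference_taxon!r}"
        )
    boundary_col = cmap.column(cleavage_pos)
    labels = tuple(
        PKC if c <= boundary_col else GMP for c in range(1, alignment.n_columns + 1)
    )
    if GMP not in labels:
        warnings.warn("cleavage site at the final column: empty GMP region")
    return RegionMap(
        region_of_column=labels,
        reference_taxon=reference_taxon,
        cleavage_pos=cleavage_pos,
    )


def mature_lengths(alignment: Alignment) -> dict[str, int]:
    """Ungapped (mature-sequence) length per taxon."""
    return {taxon: len(seq.replace(GAP, "")) for taxon, seq in alignment.rows}


def align_taxa_to_tree(
    alignment: Alignment,
    dated: DatedTree,
    remap: Mapping[str, str] | None = None,
) -> Alignment:
    """Validate alignment taxa against tree leaves; optionally rename via ``remap``.

    ``remap`` maps an alignment taxon to the tree leaf standing in for it
    (manual placement of species missing from the supertree). Taxa absent
    from the tree and not remapped are rejected rather than silently dropped.
    """
    remap = dict(remap or {})
    leaves = set(dated.leaf_labels)
    rows = []
    missing = []
    for taxon, seq in alignment.rows:
        name = remap.get(taxon, taxon)
        if name not in leaves:
            missing.append(taxon)
        rows.append((name, seq))
    if missing:
        raise KeyError(
            f"alignment taxa absent from tree (supply a remap): {sorted(missing)}"
        )
    return Alignment(tuple(rows))


def read_tracks(path) -> dict[str, NumericTrack]:
    """Read per-residue numeric tracks from 3-column TSV (taxon, position, value)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["taxon_id", "position", "value"],
        header=None, dtype={"taxon_id": str},
    )
    # tolerate a header row
    if len(df) and not str(df.iloc[0]["position"]).lstrip("-").replace(".", "").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df["position"] = df["position"].astype(int)
    df["value"] = df["value"].astype(float)
    tracks: dict[str, NumericTrack] = {}
    for taxon, grp in df.groupby("taxon_id", sort=False):
        grp = grp.sort_values("position")
        expected = list(range(1, len(grp) + 1))
        if list(grp["position"]) != expected:
            raise ValueError(f"track for {taxon!r} is not contiguous from 1")
        tracks[taxon] = NumericTrack(taxon_id=taxon, values=tuple(grp["value"]))
    return tracks


def write_tracks(tracks: Mapping[str, NumericTrack], path) -> None:
    rows = [
        (t.taxon_id, i, v)
        for t in tracks.values()
        for i, v in enumerate(t.values, 1)
    ]
    pd.DataFrame(rows, columns=["taxon_id", "position", "value"]).to_csv(
        path, sep="\t", index=False
    )


def region_map_to_tsv(regions: RegionMap, alignment: Alignment, path) -> None:
    cmap = build_column_map(alignment, regions.reference_taxon)
    df = pd.DataFrame(
        {
            "column": range(1, len(regions.region_of_column) + 1),
            "region": regions.region_of_column,
            "reference_position": [
                cmap.position(c) if cmap.position(c) is not None else ""
                for c in range(1, len(regions.region_of_column) + 1)
            ],
        }
    )
    df.to_csv(path, sep="\t", index=False)
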