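"""Gerstein-Sonnhammer-Chothia (GSC) leaf weights and pairwise divergence times.

GSC weighting down-weights densely sampled clades: each leaf starts with its
terminal branch length as raw weight, and every internal branch is
apportioned among the leaves below it in proportion to their current raw
weights, visiting nodes leaves-to-root. Raw weights therefore sum to the
total branch length of the tree; they are finally normalised to sum to 1.

Run on a dated species tree (branch lengths in Myr) the weights reflect
independent evolutionary time rather than sequence divergence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .seqio import DatedTree


class DegenerateTreeError(ValueError):
    """All branch lengths are zero: GSC apportionment is undefined."""


@dataclass(frozen=True)
class LeafWeights:
    """Normalised GSC weights, one per tree leaf (sum 1)."""

    weight: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weight.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, expected 1")
        if any(w < 0 for w in self.weight.values()):
            raise ValueError("negative weight")

    def __getitem__(self, taxon: str) -> float:
        return self.weight[taxon]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": list(self.weight), "weight": list(self.weight.values())}
        )

    @classmethod
    def from_tsv(cls, path) -> "LeafWeights":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(weight=dict(zip(df["taxon_id"], df["weight"])))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apportion_at_node(branch_length: float, raw: dict[str, float]) -> dict[str, float]:
    """Distribute ``branch_length`` over leaves in proportion to raw weights.

    If every descendant raw weight is zero (e.g. a cherry of zero-length
    terminal branches) the branch is split equally.
    """
    total = sum(raw.values())
    if total <= 0:
        gain = branch_length / len(raw)
        return {t: w + gain for t, w in raw.items()}
    return {t: w + branch_length * w / total for t, w in raw.items()}


def gsc_raw_weights(dated: DatedTree) -> dict[str, float]:
    """Unnormalised GSC weights; they sum to the total tree branch length."""
    raw: dict[object, dict[str, float]] = {}
    for node in dated.tree.postorder_node_iter():
        if node.is_leaf():
            raw[node] = {node.taxon.label: node.edge.length or 0.0}
        else:
            below: dict[str, float] = {}
            for child in node.child_nodes():
                below.update(raw.pop(child))
            length = node.edge.length or 0.0
            if node.parent_node is not None and length > 0:
                below = apportion_at_node(length, below)
            raw[node] = below
    (weights,) = raw.values()
    return weights


def gsc_weights(dated: DatedTree, uniform_if_degenerate: bool = False) -> LeafWeights:
    """Normalised GSC leaf weights from branch lengths (polytomies allowed)."""
    raw = gsc_raw_weights(dated)
    total = sum(raw.values())
    if total <= 0:
        if uniform_if_degenerate:
            n = len(raw)
            return LeafWeights(weight={t: 1.0 / n for t in raw})
        raise DegenerateTreeError("all branch lengths are zero")
    return LeafWeights(weight={t: w / total for t, w in raw.items()})


def _depths_from_root(dated: DatedTree) -> dict[object, float]:
    depths = {}
    for node in dated.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
        else:
            depths[node] = depths[parent] + (node.edge.length or 0.0)
    return depths


def divergence_time(dated: DatedTree, a: str, b: str) -> float:
    """Height (Myr) of the MRCA of ``a`` and ``b`` above the leaves.

    On an exactly ultrametric tree this is half the patristic distance; for
    slightly non-ultrametric input the mean height of the two leaves above
    the MRCA is used, with a warning above 1e-6 relative asymmetry.
    """
    if a == b:
        return 0.0
    tree = dated.tree
    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    try:
        na, nb = leaves[a], leaves[b]
    except KeyError as exc:
        raise KeyError(f"taxon {exc.args[0]!r} not in tree") from None
    mrca = tree.mrca(taxa=[na.taxon, nb.taxon])
    depths = _depths_from_root(dated)
    ha = depths[na] - depths[mrca]
    hb = depths[nb] - depths[mrca]
    top = max(ha, hb)
    if top > 0 and abs(ha - hb) / top > 1e-6:
        warnings.warn(
            f"tree not ultrametric at MRCA({a},{b}): heights {ha:g} vs {hb:g}"
        )
    return (ha + hb) / 2.0


def divergence_time_matrix(dated: DatedTree) -> pd.DataFrame:
    """All-pairs divergence times as a long DataFrame (unordered pairs)."""
    labels = list(dated.leaf_labels)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            rows.append((a, b, divergence_time(dated, a, b)))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "divergence_time"])
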