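"""Tree-weighted per-column conservation profiles.

Each alignment column is summarised as the weighted fraction of species
carrying each category — a single residue, a residue class (aromatic,
charged, ...), a bin of a numeric per-residue track (disorder,
hydrophobicity), or membership in a predicted site set. Weights are the GSC
leaf weights, so densely sampled clades do not dominate the profile. Gap
mass is reported separately; by default category fractions and the gap
fraction sum to 1 per column, with an optional mode renormalising over
non-gap weight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .phylo_weights import LeafWeights
from .seqio import GAP, Alignment, NumericTrack, build_column_map
from .sites import SiteSet

# Default residue classes. Histidine is counted as charged (it titrates in
# the stomach-pH range central to casein aggregation) and not as aromatic.
DEFAULT_SCHEMES: dict[str, dict[str, frozenset[str]]] = {
    "amide": {"amide": frozenset("NQ")},
    "aromatic": {"aromatic": frozenset("FWY")},
    "charged": {
        "negative": frozenset("DE"),
        "positive": frozenset("KRH"),
    },
}


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column weighted category fractions plus gap fraction.

    ``matrix`` has one row per alignment column and one column per category;
    with ``gap_mode="include"`` each row plus its gap fraction sums to 1.
    """

    categories: tuple[str, ...]
    matrix: np.ndarray
    gap_fraction: np.ndarray
    scheme: str
    gap_mode: str = "include"

    def fraction(self, column: int, category: str) -> float:
        """Weighted fraction of ``category`` at 1-based ``column``."""
        return float(self.matrix[column - 1, self.categories.index(category)])

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in range(self.n_columns):
            for j, cat in enumerate(self.categories):
                rows.append((c + 1, cat, self.matrix[c, j]))
            rows.append((c + 1, "gap", self.gap_fraction[c]))
        return pd.DataFrame(rows, columns=["column", "category", "fraction"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _check_coverage(alignment: Alignment, weights: LeafWeights) -> None:
    missing = [t for t in alignment.taxa if t not in weights.weight]
    if missing:
        raise KeyError(f"taxa without weights: {missing}")


def _finalise(
    matrix: np.ndarray, gap: np.ndarray, categories, scheme: str, gap_mode: str
) -> ConservationProfile:
    if gap_mode == "renormalize":
        nongap = 1.0 - gap
        with np.errstate(invalid="ignore", divide="ignore"):
            matrix = np.where(nongap[:, None] > 0, matrix / nongap[:, None], 0.0)
    elif gap_mode != "include":
        raise ValueError(f"unknown gap_mode {gap_mode!r}")
    return ConservationProfile(
        categories=tuple(categories),
        matrix=matrix,
        gap_fraction=gap,
        scheme=scheme,
        gap_mode=gap_mode,
    )


def residue_conservation(
    alignment: Alignment, weights: LeafWeights, gap_mode: str = "include"
) -> ConservationProfile:
    """Weighted fraction of each amino acid at each column."""
    _check_coverage(alignment, weights)
    categories = tuple(sorted(set("ACDEFGHIKLMNPQRSTVWY")))
    index = {aa: j for j, aa in enumerate(categories)}
    n = alignment.n_columns
    matrix = np.zeros((n, len(categories)))
    gap = np.zeros(n)
    for taxon, seq in alignment.rows:
        w = weights[taxon]
        for c, ch in enumerate(seq):
            if ch == GAP:
                gap[c] += w
            else:
                matrix[c, index[ch]] += w
    return _finalise(matrix, gap, categories, "residue", gap_mode)


def class_conservation(
    alignment: Alignment,
    weights: LeafWeights,
    scheme: Mapping[str, frozenset[str]],
    gap_mode: str = "include",
) -> ConservationProfile:
    """Weighted fraction of residue classes (sums of member-residue fractions).

    Classes need not partition the alphabet; residues in no class contribute
    to an ``other`` category so included mass still accounts for every
    residue.
    """
    if any(len(members) == 0 for members in scheme.values()):
        raise ValueError("empty residue class in scheme")
    base = residue_conservation(alignment, weights, gap_mode="include")
    names = list(scheme)
    cols = []
    covered: set[str] = set()
    for name in names:
        members = scheme[name]
        idx = [base.categories.index(aa) for aa in sorted(members)]
        cols.append(base.matrix[:, idx].sum(axis=1))
        covered |= set(members)
    rest = [j for j, aa in enumerate(base.categories) if aa not in covered]
    names.append("other")
    cols.append(base.matrix[:, rest].sum(axis=1))
    matrix = np.column_stack(cols)
    return _finalise(matrix, base.gap_fraction, names, "class", gap_mode)


def track_conservation(
    alignment: Alignment,
    weights: LeafWeights,
    tracks: Mapping[str, NumericTrack],
    bin_width: float = 0.2,
    lo: float = 0.0,
    hi: float = 1.0,
    gap_mode: str = "include",
) -> ConservationProfile:
    """Weighted fraction per value bin of a numeric per-residue track.

    Bins are half-open ``[lo+k*w, lo+(k+1)*w)`` except the top bin, which is
    right-closed so a score equal to ``hi`` is representable.
    """
    _check_coverage(alignment, weights)
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    categories = tuple(
        f"[{edges[k]:g},{edges[k + 1]:g}{']' if k == n_bins - 1 else ')'}"
        for k in range(n_bins)
    )
    n = alignment.n_columns
    matrix = np.zeros((n, n_bins))
    gap = np.zeros(n)
    for taxon, seq in alignment.rows:
        track = tracks.get(taxon)
        if track is None:
            raise KeyError(f"no track for taxon {taxon!r}")
        ungapped_len = len(seq) - seq.count(GAP)
        if len(track) != ungapped_len:
            raise ValueError(
                f"track for {taxon!r} has {len(track)} values, sequence has "
                f"{ungapped_len} residues"
            )
        w = weights[taxon]
        pos = 0
        for c, ch in enumerate(seq):
            if ch == GAP:
                gap[c] += w
            else:
                v = track.values[pos]
                pos += 1
                k = int(np.floor((v - lo) / bin_width))
                k = min(max(k, 0), n_bins - 1)
                matrix[c, k] += w
    return _finalise(matrix, gap, categories, "bin", gap_mode)


def site_occupancy(
    alignment: Alignment,
    weights: LeafWeights,
    sitesets: Mapping[str, SiteSet],
) -> np.ndarray:
    """Per-column weighted fraction of species with a predicted site there.

    Site positions are 1-based on each taxon's ungapped mature sequence and
    are mapped to alignment columns; taxa gapped at a column (or absent from
    ``sitesets``) contribute nothing there.
    """
    _check_coverage(alignment, weights)
    occ = np.zeros(alignment.n_columns)
    for taxon, seq in alignment.rows:
        ss = sitesets.get(taxon)
        if ss is None or not ss.positions:
            continue
        cmap = build_column_map(alignment, taxon)
        length = len(seq) - seq.count(GAP)
        w = weights[taxon]
        for p in ss.positions:
            if not 1 <= p <= length:
                raise ValueError(
                    f"site position {p} outside 1..{length} for {taxon!r}"
                )
            occ[cmap.column(p) - 1] += w
    return occ


def plot_profile(profile: ConservationProfile, ax=None, region_map=None):
    """Minimal stacked-area rendering of a profile (requires matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(1, profile.n_columns + 1)
    ax.stackplot(x, profile.matrix.T, labels=profile.categories)
    ax.set_xlabel("alignment column")
    ax.set_ylabel("weighted fraction")
    ax.legend(fontsize="x-small", ncol=4)
    return ax
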