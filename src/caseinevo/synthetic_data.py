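"""Synthetic dated trees and region-structured protein alignments.

The generator emulates the structure of the kappa-casein study data so every
pipeline stage is testable without downloads: an ultrametric pure-birth
species tree scaled to a root age in Myr; sequences evolved along it under
JTT exchangeabilities re-weighted to region-specific equilibrium
frequencies (a serine/arginine/aromatic-rich PKC-like region and a
threonine/isoleucine-rich, cysteine-free GMP-like region), with
discrete-gamma rate heterogeneity and an epoch-dependent clock that runs
faster before a breakpoint age; planted S-x-E motifs and cysteines in the
PKC-like region; and optional tandem-duplication insertions confined to the
GMP-like region, realised as gap columns in all other rows so the alignment
truth stays exact.

All randomness flows through one numpy Generator seeded once, so outputs
are bit-reproducible for a given config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .seqio import Alignment, DatedTree
from .substmodel import JTT_FREQS, JTT_ORDER, JttModel, discrete_gamma_rates


def _region_frequencies(boost: dict[str, float], zero: str = "") -> tuple[float, ...]:
    """Re-weight the JTT frequencies: multiply boosted residues, zero others."""
    f = np.array(JTT_FREQS)
    for aa, factor in boost.items():
        f[JTT_ORDER.index(aa)] *= factor
    for aa in zero:
        f[JTT_ORDER.index(aa)] = 0.0
    return tuple(f / f.sum())


# PKC-like: serine/arginine/aromatic-enriched. GMP-like: threonine/isoleucine-
# enriched, leucine/aromatics depleted and cysteine-free, echoing the
# composition contrast between the two parts of kappa-casein.
PKC_LIKE_FREQS = _region_frequencies({"S": 2.0, "R": 1.8, "Y": 2.0, "F": 1.5, "P": 1.5, "Q": 1.5})
GMP_LIKE_FREQS = _region_frequencies(
    {"T": 3.5, "I": 2.5, "S": 1.5, "E": 1.5, "P": 1.5, "L": 0.3, "F": 0.1, "Y": 0.1, "W": 0.1, "R": 0.2, "H": 0.2},
    zero="C",
)


@dataclass
class SimulationConfig:
    """Study-condition defaults for the synthetic kappa-casein-like data.

    Rates are substitutions/site/Myr; the clock runs at ``rate_old`` before
    ``epoch_breakpoint`` (Ma before present) and ``rate_recent`` after it,
    a 2x slow-down matching the two-epoch picture of kappa-casein change.
    """

    n_taxa: int = 99
    seed: int = 0
    birth_rate: float = 0.04
    root_age: float = 166.0
    epoch_breakpoint: float = 60.0
    rate_old: float = 0.004
    rate_recent: float = 0.002
    alpha: float = 1.0
    n_categories: int = 4
    pkc_length: int = 105
    gmp_length: int = 64
    pkc_freqs: tuple[float, ...] = PKC_LIKE_FREQS
    gmp_freqs: tuple[float, ...] = GMP_LIKE_FREQS
    n_planted_motifs: int = 3
    planted_cysteines: tuple[int, ...] = (11, 88)
    n_duplicated_tips: int = 2
    duplication_length: int = 12
    duplication_copies: int = 1  # extra copies inserted after the template block

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        for key in ("pkc_freqs", "gmp_freqs", "planted_cysteines"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SimulationTruth:
    """Planted features and generating parameters, in tip coordinates."""

    motif_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    cysteine_positions: dict[str, tuple[int, ...]] = field(default_factory=dict)
    duplications: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)


def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> DatedTree:
    """Ultrametric pure-birth (Yule) tree on ``n_taxa`` tips, root age fixed.

    Speciation times are drawn forward in time from exponential waiting
    times; node ages are then rescaled so the root sits at ``root_age`` Ma.
    """
    if config.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    # forward simulation: event times at which one lineage splits
    times = [0.0]
    t = 0.0
    k = 2
    while k < config.n_taxa:
        t += rng.exponential(1.0 / (config.birth_rate * k))
        times.append(t)
        k += 1
    total = t + rng.exponential(1.0 / (config.birth_rate * k))
    scale = config.root_age / total
    split_times = [ti * scale for ti in times]  # time since root, split_times[0]=0

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.is_rooted = True
    tree.seed_node.time = 0.0
    # active lineages represented by their (pendant) nodes
    root = tree.seed_node
    a = dendropy.Node()
    b = dendropy.Node()
    root.add_child(a)
    root.add_child(b)
    active = [a, b]
    parent_time = {a: 0.0, b: 0.0}
    for st in split_times[1:]:
        idx = int(rng.integers(len(active)))
        node = active.pop(idx)
        node.time = st
        node.edge.length = st - parent_time[node]
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        parent_time[c1] = parent_time[c2] = st
        active.extend([c1, c2])
    for i, node in enumerate(active, 1):
        label = f"t{i:03d}"
        node.taxon = taxon_ns.new_taxon(label)
        node.edge.length = config.root_age - parent_time[node]
    return DatedTree(tree=tree, length_unit="Myr")


def _effective_length(age_top: float, age_bottom: float, config: SimulationConfig) -> float:
    """Expected substitutions/site along a branch spanning [age_bottom, age_top] Ma.

    Branches crossing the epoch breakpoint are split at it, with the old
    epoch running at ``rate_old`` and the recent one at ``rate_recent``.
    """
    b = config.epoch_breakpoint
    old_span = max(0.0, age_top - max(age_bottom, b))
    recent_span = max(0.0, min(age_top, b) - age_bottom)
    return old_span * config.rate_old + recent_span * config.rate_recent


def _plant_root_features(
    root_seq: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[int], list[int]]:
    """Overwrite sampled root residues with S-x-E motifs and cysteines (PKC-like region)."""
    s, e, c = JTT_ORDER.index("S"), JTT_ORDER.index("E"), JTT_ORDER.index("C")
    motif_starts: list[int] = []
    candidates = np.arange(1, config.pkc_length - 2)  # 1-based start so S at start, E at start+2
    forbidden: set[int] = set(p - 1 for p in config.planted_cysteines)
    n_placed = 0
    rng.shuffle(candidates)
    for start in candidates:
        if n_placed >= config.n_planted_motifs:
            break
        span = {start - 1, start, start + 1}
        if span & forbidden or any(abs(start - m) < 4 for m in motif_starts):
            continue
        root_seq[start - 1] = s
        root_seq[start + 1] = e
        motif_starts.append(int(start))
        n_placed += 1
    for p in config.planted_cysteines:
        if not 1 <= p <= config.pkc_length:
            raise ValueError("planted cysteines must lie in the PKC-like region")
        root_seq[p - 1] = c
    return root_seq, sorted(motif_starts), sorted(config.planted_cysteines)


def simulate_alignment(
    dated: DatedTree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve region-structured sequences along the tree; return alignment + truth.

    Sites evolve independently under JTT re-weighted to per-region
    frequencies; each site carries a discrete-gamma rate category; branch
    lengths in expected substitutions/site combine the per-epoch clock with
    the category rate. Tandem duplications are applied to chosen tips
    afterwards, as inserted blocks aligned by gap columns elsewhere.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_sites = config.pkc_length + config.gmp_length
    region_of_site = np.array([0] * config.pkc_length + [1] * config.gmp_length)
    models = (JttModel(np.array(config.pkc_freqs)), JttModel(np.array(config.gmp_freqs)))
    rates = discrete_gamma_rates(config.alpha, config.n_categories)
    site_cat = rng.integers(config.n_categories, size=n_sites)

    root_seq = np.empty(n_sites, dtype=int)
    for r in (0, 1):
        mask = region_of_site == r
        root_seq[mask] = rng.choice(20, size=mask.sum(), p=models[r].freqs)
    root_seq, motif_starts, cys = _plant_root_features(root_seq, config, rng)

    depths: dict[object, float] = {}
    seqs: dict[object, np.ndarray] = {dated.tree.seed_node: root_seq}
    tip_seqs: dict[str, np.ndarray] = {}
    for node in dated.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depths[node] = 0.0
            continue
        depths[node] = depths[parent] + (node.edge.length or 0.0)
        age_top = config.root_age - depths[parent]
        age_bottom = config.root_age - depths[node]
        base_len = _effective_length(age_top, age_bottom, config)
        parent_seq = seqs[parent]
        child_seq = parent_seq.copy()
        if base_len > 0:
            for r in (0, 1):
                for k in range(config.n_categories):
                    mask = (region_of_site == r) & (site_cat == k)
                    if not mask.any():
                        continue
                    p = models[r].transition_matrix(base_len * rates[k])
                    cum = p.cumsum(axis=1)
                    u = rng.random(mask.sum())
                    rows = cum[parent_seq[mask]]
                    child_seq[mask] = (u[:, None] > rows).sum(axis=1)
        seqs[node] = child_seq
        if node.is_leaf():
            tip_seqs[node.taxon.label] = child_seq
        if parent in seqs and all(ch in seqs for ch in parent.child_nodes()):
            del seqs[parent]

    truth = SimulationTruth()
    order = sorted(tip_seqs)
    for label in order:
        seq = tip_seqs[label]
        letters = "".join(JTT_ORDER[i] for i in seq)
        truth.motif_positions[label] = tuple(
            m for m in motif_starts
            if letters[m - 1] == "S" and letters[m + 1] == "E"
        )
        truth.cysteine_positions[label] = tuple(
            p for p in cys if letters[p - 1] == "C"
        )

    rows = {label: "".join(JTT_ORDER[i] for i in tip_seqs[label]) for label in order}

    # region-2-restricted tandem duplications on a few tips
    if config.n_duplicated_tips > 0 and config.duplication_length > 0:
        chosen = list(rng.choice(order, size=min(config.n_duplicated_tips, len(order)), replace=False))
        dup_len = config.duplication_length
        copies = config.duplication_copies
        # insertion bookkeeping: list of (column_after_which, tip, block) applied
        inserts: list[tuple[int, str, str]] = []
        for tip in chosen:
            lo = config.pkc_length + 1
            hi = n_sites - dup_len
            start = int(rng.integers(lo, hi + 1))  # 1-based start of template block
            block = rows[tip][start - 1 : start - 1 + dup_len]
            inserts.append((start + dup_len - 1, tip, block * copies))
            truth.duplications[tip] = tuple(
                (start, start + dup_len - 1) for _ in range(copies)
            )
        # apply from rightmost column so earlier coordinates stay valid
        for col, tip, block in sorted(inserts, reverse=True):
            for label in order:
                if label == tip:
                    rows[label] = rows[label][:col] + block + rows[label][col:]
                else:
                    rows[label] = rows[label][:col] + "-" * len(block) + rows[label][col:]

    alignment = Alignment(tuple((label, rows[label]) for label in order))
    return alignment, truth


def simulate(config: SimulationConfig) -> tuple[DatedTree, Alignment, SimulationTruth]:
    """Tree + alignment + truth from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    alignment, truth = simulate_alignment(tree, config, rng)
    return tree, alignment, truth


def truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """Long-format TSV-ready table of planted features per tip."""
    rows = []
    for tip, positions in truth.motif_positions.items():
        for p in positions:
            rows.append((tip, "motif_SxE", p, p + 2))
    for tip, positions in truth.cysteine_positions.items():
        for p in positions:
            rows.append((tip, "cysteine", p, p))
    for tip, spans in truth.duplications.items():
        for a, b in spans:
            rows.append((tip, "tandem_duplication", a, b))
    return pd.DataFrame(rows, columns=["taxon", "feature", "start", "end"])
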