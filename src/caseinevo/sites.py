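"""Motif-based site prediction: Fam20C phosphorylation, protease cleavage,
glyco-score thresholding, cysteines and disulfide scenarios.

Fam20C phosphorylates serines in an S-x-E context, and phosphoserines can
themselves anchor further serines two residues away (S-x-pS), so predicted
sites are the closure of chains S-x-(S-x)*-E read in either direction,
truncated at chain length ``n``. Pepsin cleavage follows the ExPASy
PeptideCutter context rules; plasmin cleaves after Lys/Arg. Positions are
1-based on the ungapped mature sequence; a protease site ``i`` means
cleavage of the bond after residue ``i`` (so the final residue never hosts
a site).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import Alignment, NumericTrack, RegionMap

SITE_KINDS = ("phospho", "glyco", "pepsin", "plasmin", "cysteine")


@dataclass(frozen=True)
class SiteSet:
    """Typed set of 1-based positions on an ungapped mature sequence."""

    taxon: str
    kind: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.kind not in SITE_KINDS:
            raise ValueError(f"unknown site kind {self.kind!r}")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("positions must be sorted and unique")
        if self.positions and self.positions[0] < 1:
            raise ValueError("positions are 1-based")

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, position: int) -> bool:
        return position in self.positions


def fam20c_sites(seq: str, n: int = 10, taxon: str = "") -> SiteSet:
    """Serines in S-x-E or chained S-x-(S-x)^k-E context (k <= n), both directions.

    A serine at ``i`` is predicted if, walking in steps of two residues
    toward either terminus, it reaches a glutamate through at most ``n``
    intermediate serines: forward, positions i+2..i+2k are S and i+2(k+1)
    is E; backward, positions i-2..i-2k are S and i-2(k+1) is E.
    """
    if n < 0:
        raise ValueError("chain length n must be >= 0")
    L = len(seq)
    hits = []
    for i in range(1, L + 1):
        if seq[i - 1] != "S":
            continue
        matched = False
        for step in (2, -2):
            j = i + step
            chain = 0
            while not matched and chain <= n:
                if not 1 <= j <= L:
                    break
                ch = seq[j - 1]
                if ch == "E":
                    matched = True
                elif ch == "S":
                    chain += 1
                    j += step
                else:
                    break
            if matched:
                break
        if matched:
            hits.append(i)
    return SiteSet(taxon=taxon, kind="phospho", positions=tuple(hits))


PEPSIN_VARIANTS = {"pH1.3": frozenset("FL"), "pH>2": frozenset("FLWY")}
_BLOCK_P3 = frozenset("HKR")


def pepsin_sites(seq: str, variant: str = "pH>2", taxon: str = "") -> SiteSet:
    """Pepsin cleavage sites under the PeptideCutter context rules.

    Cleavage after residue ``i`` (between P1 = seq[i] and P1' = seq[i+1])
    when either P1' or P1 is hydrophobic/aromatic (F/L at pH 1.3, F/L/W/Y
    above pH 2), with the context exclusions: no Pro at P2 or P2', no
    His/Lys/Arg at P3, and (for the P1' branch) no Arg at P1. Context
    positions that fall outside the sequence do not block.
    """
    try:
        targets = PEPSIN_VARIANTS[variant]
    except KeyError:
        raise ValueError(f"unknown pepsin variant {variant!r}") from None
    L = len(seq)
    hits = []
    for i in range(1, L):  # cleave after residue i
        p1 = seq[i - 1]
        p1p = seq[i]
        p2 = seq[i - 2] if i >= 2 else None
        p3 = seq[i - 3] if i >= 3 else None
        p2p = seq[i + 1] if i + 1 < L else None
        context_ok = (
            (p2p is None or p2p != "P")
            and (p2 is None or p2 != "P")
            and (p3 is None or p3 not in _BLOCK_P3)
        )
        if not context_ok:
            continue
        if (p1p in targets and p1 != "R") or p1 in targets:
            hits.append(i)
    return SiteSet(taxon=taxon, kind="pepsin", positions=tuple(hits))


def plasmin_sites(seq: str, taxon: str = "") -> SiteSet:
    """Cleavage after every non-terminal Lys or Arg."""
    hits = [i for i in range(1, len(seq)) if seq[i - 1] in "KR"]
    return SiteSet(taxon=taxon, kind="plasmin", positions=tuple(hits))


def glyco_threshold(
    track: NumericTrack, seq: str, cutoff: float = 0.4, taxon: str = ""
) -> SiteSet:
    """Ser/Thr positions whose glycosylation score is >= ``cutoff``."""
    if len(track) != len(seq):
        raise ValueError(
            f"track length {len(track)} != sequence length {len(seq)}"
        )
    hits = [
        i
        for i, (ch, v) in enumerate(zip(seq, track.values), 1)
        if ch in "ST" and v >= cutoff
    ]
    return SiteSet(taxon=taxon or track.taxon_id, kind="glyco", positions=tuple(hits))


def cysteine_positions(seq: str, taxon: str = "") -> SiteSet:
    hits = [i for i, ch in enumerate(seq, 1) if ch == "C"]
    return SiteSet(taxon=taxon, kind="cysteine", positions=tuple(hits))


@dataclass(frozen=True)
class DisulfideScenario:
    """Covalent-bonding capabilities implied by cysteine count and spacing.

    dimer: at least one cysteine. oligomer: at least two. intrachain: two
    cysteines separated by at least one residue (positions differing by >= 2).
    """

    taxon: str
    n_cysteines: int
    dimer: bool
    oligomer: bool
    intrachain: bool


def classify_disulfide(cys: SiteSet) -> DisulfideScenario:
    if cys.kind != "cysteine":
        raise ValueError("expected a cysteine SiteSet")
    pos = cys.positions
    n = len(pos)
    intrachain = any(
        b - a >= 2 for idx, a in enumerate(pos) for b in pos[idx + 1 :]
    )
    return DisulfideScenario(
        taxon=cys.taxon,
        n_cysteines=n,
        dimer=n >= 1,
        oligomer=n >= 2,
        intrachain=intrachain,
    )


def scenario_table(alignment: Alignment) -> pd.DataFrame:
    """Per-taxon disulfide scenario flags (Fig-7-style right panel)."""
    rows = []
    for taxon, _ in alignment.rows:
        sc = classify_disulfide(
            cysteine_positions(alignment.ungapped(taxon), taxon=taxon)
        )
        rows.append(
            (taxon, sc.n_cysteines, sc.dimer, sc.oligomer, sc.intrachain)
        )
    return pd.DataFrame(
        rows, columns=["taxon", "n_cysteines", "dimer", "oligomer", "intrachain"]
    )


_PREDICTORS = {
    "pepsin": pepsin_sites,
    "plasmin": plasmin_sites,
}


def cleavage_density(
    alignment: Alignment,
    regions: RegionMap,
    kinds: Iterable[str] = ("pepsin", "plasmin"),
    pepsin_variant: str = "pH>2",
) -> pd.DataFrame:
    """Cleavage sites per residue in each taxon's PKC and GMP.

    Each region subsequence is degapped and scanned as a free peptide; the
    density is the pooled site count of the requested proteases divided by
    the region's ungapped length.
    """
    rows = []
    for taxon, _ in alignment.rows:
        for region in ("PKC", "GMP"):
            sub = regions.region_sequence(alignment, taxon, region)
            if not sub:
                continue
            n_sites = 0
            for kind in kinds:
                if kind == "pepsin":
                    n_sites += len(pepsin_sites(sub, variant=pepsin_variant))
                elif kind == "plasmin":
                    n_sites += len(plasmin_sites(sub))
                else:
                    raise ValueError(f"unknown protease {kind!r}")
            rows.append((taxon, region, n_sites, len(sub), n_sites / len(sub)))
    return pd.DataFrame(
        rows, columns=["taxon", "region", "n_sites", "length", "density"]
    )


def paired_one_tailed_t(
    pkc_densities: Iterable[float], gmp_densities: Iterable[float]
) -> tuple[float, float]:
    """Paired one-tailed t-test for PKC density exceeding GMP density.

    Returns (t, p) for the alternative mean(PKC - GMP) > 0 with n-1 degrees
    of freedom. Zero variance with zero mean difference gives p = 0.5 by
    convention; zero variance with a positive mean gives p = 0.
    """
    a = np.asarray(list(pkc_densities), dtype=float)
    b = np.asarray(list(gmp_densities), dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd <= 1e-12 * max(1.0, abs(mean)):
        if mean == 0:
            return 0.0, 0.5
        return (np.inf if mean > 0 else -np.inf), (0.0 if mean > 0 else 1.0)
    t = mean / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, df=n - 1))
    return float(t), p


def site_table(sitesets: Iterable[SiteSet]) -> pd.DataFrame:
    """Long-format site table (taxon, kind, position)."""
    rows = [
        (ss.taxon, ss.kind, p) for ss in sitesets for p in ss.positions
    ]
    return pd.DataFrame(rows, columns=["taxon", "kind", "position"])


def region_site_counts(
    alignment: Alignment,
    regions: RegionMap,
    sitesets: Mapping[str, SiteSet],
) -> pd.DataFrame:
    """Per-taxon, per-region counts of sites (Fig-6-style count matrix).

    Sites are positions on each taxon's ungapped mature chain; the split
    point is where the taxon's PKC region ends.
    """
    rows = []
    for taxon, _ in alignment.rows:
        pkc_len = len(regions.region_sequence(alignment, taxon, "PKC"))
        ss = sitesets.get(taxon)
        positions = ss.positions if ss else ()
        n_pkc = sum(1 for p in positions if p <= pkc_len)
        n_gmp = len(positions) - n_pkc
        rows.append((taxon, n_pkc, n_gmp))
    return pd.DataFrame(rows, columns=["taxon", "n_PKC", "n_GMP"])
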