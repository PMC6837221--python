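"""Charge-vs-pH (NCPR), GRAVY hydropathy and per-region composition ranges.

Net charge follows the Henderson-Hasselbalch model: at a given pH each basic
group (N-terminus, His, Lys, Arg) contributes +1/(1+10^(pH-pK)) and each
acidic group (C-terminus, Asp, Glu, Cys, Tyr) contributes -1/(1+10^(pK-pH)).
pK values default to the Bjellqvist scale. NCPR (net charge per residue) is
the net charge divided by the ungapped sequence length; for kappa-casein it
is evaluated from pH 1.5 (stomach) to 7.5 (milk) for the mature chain and
for the PKC and GMP separately. Post-translational charge (phosphate, sialic
acid) is deliberately not modelled: curves describe the primary sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .seqio import Alignment, RegionMap

ACIDIC_GROUPS = ("C-terminus", "D", "E", "C", "Y")
BASIC_GROUPS = ("N-terminus", "H", "K", "R")


@dataclass(frozen=True)
class PKScale:
    """Named set of pK values for the ionisable groups of a peptide."""

    name: str
    pK: Mapping[str, float]

    def __post_init__(self) -> None:
        groups = set(ACIDIC_GROUPS) | set(BASIC_GROUPS)
        missing = groups - set(self.pK)
        if missing:
            raise ValueError(f"pK scale {self.name!r} missing groups: {sorted(missing)}")
        for g, v in self.pK.items():
            if not 0 < v < 14:
                raise ValueError(f"pK of {g} out of range: {v}")


# Bjellqvist pK values as distributed with common peptide-property engines.
BJELLQVIST = PKScale(
    name="Bjellqvist",
    pK={
        "C-terminus": 3.55,
        "D": 4.05,
        "E": 4.45,
        "H": 5.98,
        "C": 9.00,
        "N-terminus": 7.50,
        "Y": 10.00,
        "K": 10.00,
        "R": 12.00,
    },
)

# Kyte-Doolittle hydropathy values.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average amino-acid frequencies in UniProtKB/Swiss-Prot (release-level
# statistics, percent/100), used as the background in composition plots.
SWISSPROT_FREQUENCIES: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

TERMINI_MODES = ("both", "none", "N-only", "C-only")


def net_charge(
    seq: str,
    pH: float,
    scale: PKScale = BJELLQVIST,
    termini: str = "both",
) -> float:
    """Henderson-Hasselbalch net charge of an ungapped sequence at ``pH``."""
    if not seq:
        raise ValueError("empty sequence")
    if termini not in TERMINI_MODES:
        raise ValueError(f"termini must be one of {TERMINI_MODES}")
    counts = {g: 0 for g in ACIDIC_GROUPS + BASIC_GROUPS}
    for ch in seq:
        if ch in counts:
            counts[ch] += 1
    if termini in ("both", "N-only"):
        counts["N-terminus"] = 1
    if termini in ("both", "C-only"):
        counts["C-terminus"] = 1
    positive = sum(
        counts[g] / (1.0 + 10.0 ** (pH - scale.pK[g])) for g in BASIC_GROUPS
    )
    negative = sum(
        counts[g] / (1.0 + 10.0 ** (scale.pK[g] - pH)) for g in ACIDIC_GROUPS
    )
    return positive - negative


DEFAULT_PH_GRID = tuple(np.arange(1.5, 7.5 + 1e-9, 0.5))


@dataclass(frozen=True)
class ChargeCurve:
    """NCPR samples over a pH grid for one taxon and region."""

    taxon: str
    region: str
    samples: tuple[tuple[float, float], ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.taxon, self.region, ph, v) for ph, v in self.samples],
            columns=["taxon", "region", "pH", "NCPR"],
        )

    def at(self, pH: float) -> float:
        for p, v in self.samples:
            if abs(p - pH) < 1e-9:
                return v
        raise KeyError(f"pH {pH} not on the sampled grid")


def ncpr(seq: str, pH: float, scale: PKScale = BJELLQVIST, termini: str = "both") -> float:
    """Net charge per residue at a single pH."""
    return net_charge(seq, pH, scale, termini) / len(seq)


def ncpr_curve(
    seq: str,
    taxon: str = "",
    region: str = "mature",
    pH_grid: Iterable[float] = DEFAULT_PH_GRID,
    scale: PKScale = BJELLQVIST,
    termini: str = "both",
) -> ChargeCurve:
    """NCPR evaluated over a pH grid (default 1.5..7.5 step 0.5)."""
    samples = tuple((float(ph), ncpr(seq, ph, scale, termini)) for ph in pH_grid)
    return ChargeCurve(taxon=taxon, region=region, samples=samples)


def gravy(seq: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle value)."""
    if not seq:
        raise ValueError("empty sequence")
    return sum(KYTE_DOOLITTLE[ch] for ch in seq) / len(seq)


def composition_ranges(
    alignment: Alignment,
    regions: RegionMap | None = None,
    background: Mapping[str, float] = SWISSPROT_FREQUENCIES,
) -> pd.DataFrame:
    """Min/max amino-acid frequency across taxa, per region.

    Frequencies are computed on each taxon's degapped region subsequence;
    taxa with an empty region are excluded from that region's ranges. The
    configurable ``background`` column carries proteome-average frequencies
    for comparison.
    """
    import warnings

    aas = sorted(KYTE_DOOLITTLE)
    region_names = ["mature"] if regions is None else ["mature", "PKC", "GMP"]
    rows = []
    for region in region_names:
        freqs_per_taxon = []
        for taxon, _ in alignment.rows:
            if region == "mature":
                sub = alignment.ungapped(taxon)
            else:
                sub = regions.region_sequence(alignment, taxon, region)
            if not sub:
                warnings.warn(f"taxon {taxon!r} has an empty {region} region; excluded")
                continue
            freqs_per_taxon.append(
                np.array([sub.count(aa) / len(sub) for aa in aas])
            )
        mat = np.vstack(freqs_per_taxon)
        for j, aa in enumerate(aas):
            rows.append(
                (
                    region, aa,
                    float(mat[:, j].min()), float(mat[:, j].max()),
                    background[aa],
                )
            )
    return pd.DataFrame(
        rows, columns=["region", "amino_acid", "min_frequency", "max_frequency", "background"]
    )
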