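"""JTT amino-acid substitution model and discrete-gamma rate heterogeneity.

The Jones-Taylor-Thornton (JTT) model is specified by a symmetric matrix of
exchangeabilities and a vector of equilibrium amino-acid frequencies. The
instantaneous rate matrix is Q = S diag(pi), rescaled so that the expected
number of substitutions per site per unit time is 1. Among-site rate
variation uses Yang's discrete gamma with K equiprobable categories, each
represented by its conditional mean rate.

The exchangeability constants below are the published JTT values (the
jones.dat parameterisation used by phylogenetics software); a checksum test
pins them against accidental edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

# Amino-acid order of the JTT matrix (PAML convention).
JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"

# Lower triangle (row 2 onward) of the symmetric JTT exchangeability matrix.
JTT_LOWER = (
    58.0, 54.0, 81.0, 56.0, 57.0, 105.0, 179.0, 27.0, 36.0, 30.0,
    35.0, 54.0, 15.0, 194.0, 378.0, 475.0, 9.0, 11.0, 298.0, 45.0,
    16.0, 113.0, 310.0, 29.0, 137.0, 328.0, 22.0, 38.0, 646.0, 44.0,
    5.0, 74.0, 101.0, 64.0, 126.0, 20.0, 17.0, 528.0, 34.0, 86.0,
    58.0, 81.0, 391.0, 47.0, 12.0, 263.0, 30.0, 10.0, 15.0, 503.0,
    232.0, 8.0, 70.0, 16.0, 10.0, 49.0, 767.0, 130.0, 112.0, 11.0,
    7.0, 26.0, 15.0, 4.0, 15.0, 59.0, 38.0, 4.0, 46.0, 31.0,
    9.0, 5.0, 59.0, 69.0, 17.0, 23.0, 7.0, 31.0, 78.0, 14.0,
    223.0, 42.0, 115.0, 209.0, 62.0, 323.0, 26.0, 597.0, 9.0, 72.0,
    292.0, 43.0, 4.0, 164.0, 53.0, 51.0, 18.0, 24.0, 20.0, 119.0,
    26.0, 12.0, 9.0, 181.0, 18.0, 5.0, 18.0, 30.0, 32.0, 10.0,
    7.0, 45.0, 23.0, 6.0, 6.0, 27.0, 14.0, 5.0, 24.0, 201.0,
    33.0, 55.0, 8.0, 47.0, 16.0, 56.0, 45.0, 33.0, 40.0, 115.0,
    73.0, 46.0, 8.0, 573.0, 11.0, 229.0, 21.0, 479.0, 89.0, 10.0,
    40.0, 245.0, 9.0, 32.0, 961.0, 14.0, 388.0, 248.0, 102.0, 59.0,
    25.0, 52.0, 24.0, 180.0, 65.0, 4.0, 21.0, 47.0, 103.0, 10.0,
    8.0, 14.0, 43.0, 16.0, 29.0, 226.0, 24.0, 18.0, 323.0, 17.0,
    92.0, 12.0, 53.0, 536.0, 62.0, 285.0, 118.0, 6.0, 10.0, 23.0,
    477.0, 35.0, 63.0, 38.0, 12.0, 21.0, 112.0, 71.0, 25.0, 16.0,
)

# JTT equilibrium amino-acid frequencies, same order.
JTT_FREQS = (
    0.0767479232520767579, 0.0516909483090516944, 0.0426449573550426522,
    0.0515439484560515498, 0.0198029801970198045, 0.0407519592480407519,
    0.0618299381700618406, 0.0731519268480731594, 0.022943977056022944,
    0.0537609462390537668, 0.0919039080960919047, 0.058675941324058678,
    0.0238259761740238288, 0.0401259598740401346, 0.0509009490990509073,
    0.0687649312350687714, 0.0585649414350585679, 0.0142609857390142616,
    0.0321019678980321022, 0.0660049339950660036,
)


def exchangeability_matrix() -> np.ndarray:
    """The symmetric 20x20 JTT exchangeability matrix S (zero diagonal)."""
    s = np.zeros((20, 20))
    k = 0
    for j in range(19):  # column-major lower triangle
        for i in range(j + 1, 20):
            s[i, j] = s[j, i] = JTT_LOWER[k]
            k += 1
    return s


def discrete_gamma_rates(alpha: float, n_categories: int = 4) -> np.ndarray:
    """Mean rates of K equiprobable discrete-gamma categories (mean 1).

    Category boundaries are gamma(alpha, alpha) quantiles; each category rate
    is the conditional mean within its boundaries (Yang's mean method).
    """
    if alpha <= 0:
        raise ValueError("gamma shape alpha must be > 0")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    k = n_categories
    if k == 1:
        return np.ones(1)
    probs = np.arange(1, k) / k
    # quantiles of gamma(shape=alpha, rate=alpha); scale = 1/alpha
    bounds = gamma_dist.ppf(probs, a=alpha, scale=1.0 / alpha)
    bounds = np.concatenate([[0.0], bounds, [np.inf]])
    # E[X; a<X<b] for X~Gamma(alpha, rate=alpha) equals P(alpha+1, alpha*b) - P(alpha+1, alpha*a)
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(alpha + 1, alpha * bounds[1:]))
    lower = gammainc(alpha + 1, alpha * bounds[:-1])
    rates = k * (upper - lower)
    return rates / rates.mean()


@dataclass
class JttModel:
    """Time-reversible JTT rate matrix, optionally with custom frequencies.

    ``freqs`` defaults to the published JTT equilibrium frequencies; region-
    specific compositions (e.g. a threonine/isoleucine-rich GMP-like region)
    are modelled by swapping in their own frequency vector (a "+F" style
    re-weighting). Q is normalised to one expected substitution per site per
    unit branch length.
    """

    freqs: np.ndarray = field(default_factory=lambda: np.array(JTT_FREQS))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (20,):
            raise ValueError("need 20 amino-acid frequencies")
        if np.any(self.freqs < 0) or not np.isclose(self.freqs.sum(), 1.0):
            raise ValueError("frequencies must be nonnegative and sum to 1")
        s = exchangeability_matrix()
        q = s * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        q /= mu
        self.rate_matrix = q
        # symmetrised eigendecomposition for stable matrix exponentials;
        # zero-frequency states are absorbing-from and unreachable-to, handled
        # by masking.
        nz = self.freqs > 0
        rt = np.sqrt(self.freqs[nz])
        # B = diag(rt) Q diag(1/rt) is symmetric for a reversible Q
        b = (q[np.ix_(nz, nz)] * rt[:, np.newaxis]) / rt[np.newaxis, :]
        w, v = np.linalg.eigh((b + b.T) / 2.0)
        self._nz = nz
        self._eigvals = w
        # P(t) = diag(1/rt) V exp(wt) V' diag(rt)
        self._right = v / rt[:, np.newaxis]
        self._left = v * rt[:, np.newaxis]

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows for zero-frequency states are identity."""
        if t < 0:
            raise ValueError("branch length must be nonnegative")
        nz = self._nz
        p_nz = (self._right * np.exp(self._eigvals * t)) @ self._left.T
        p_nz = np.clip(p_nz, 0.0, None)
        p_nz /= p_nz.sum(axis=1, keepdims=True)
        p = np.eye(20)
        p[np.ix_(nz, nz)] = p_nz
        return p


def encode(seq: str) -> np.ndarray:
    """Encode an ungapped amino-acid string as JTT-order indices."""
    idx = np.fromiter((JTT_ORDER.index(c) for c in seq), dtype=int, count=len(seq))
    return idx
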