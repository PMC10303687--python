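"""Empirical amino-acid substitution models and transition probabilities.

Implements a general-time-reversible amino-acid model built from an
exchangeability matrix and equilibrium frequencies, with the Jones-Taylor-
Thornton (JTT) model shipped as packaged constants.  Rate matrices are
normalised so that one unit of branch length equals one expected
substitution per site, the convention of trees produced by standard
maximum-likelihood software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid ordering used throughout the package.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Characters treated as missing data in likelihood computations.
MISSING_CHARS = frozenset("-X?.*")

# JTT exchangeabilities (Jones, Taylor & Thornton 1992): the classic
# integer accepted-point-mutation counts, lower triangle of the symmetric
# 20x20 exchangeability matrix in column-major order over AMINO_ACIDS.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101,
    64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15,
    503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59,
    38, 4, 46, 31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209,
    62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26,
    12, 9, 181, 18, 5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24,
    201, 33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229,
    21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52,
    24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323,
    17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21,
    112, 71, 25, 16,
]

#: JTT equilibrium amino-acid frequencies.
_JTT_FREQS = [
    0.0767479232521, 0.0516909483091, 0.0426449573550, 0.0515439484561,
    0.0198029801970, 0.0407519592480, 0.0618299381701, 0.0731519268481,
    0.0229439770560, 0.0537609462391, 0.0919039080961, 0.0586759413241,
    0.0238259761740, 0.0401259598740, 0.0509009490991, 0.0687649312351,
    0.0585649414351, 0.0142609857390, 0.0321019678980, 0.0660049339951,
]


def _expand_lower_triangle(values: list[float], n: int = 20) -> np.ndarray:
    """Expand a column-major lower triangle into a symmetric matrix."""
    mat = np.zeros((n, n))
    it = iter(values)
    for j in range(n):
        for i in range(j + 1, n):
            mat[i, j] = mat[j, i] = next(it)
    return mat


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible amino-acid rate matrix with its stationary distribution.

    Parameters
    ----------
    Q : (20, 20) ndarray
        Rate matrix; rows sum to zero, off-diagonals non-negative, scaled
        to one expected substitution per unit time at stationarity.
    pi : (20,) ndarray
        Equilibrium frequencies (sums to 1).
    name : str
        Human-readable model name.
    """

    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    # spectral decomposition of the symmetrised rate matrix, cached so that
    # exp(Qt) is a pair of matrix products per call
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if Q.shape != (20, 20) or pi.shape != (20,):
            raise ValueError("Q must be 20x20 and pi length 20")
        if not np.isclose(pi.sum(), 1.0, atol=1e-8):
            raise ValueError("equilibrium frequencies must sum to 1")
        off = Q[~np.eye(20, dtype=bool)]
        if np.any(off < -1e-12):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(Q.sum(axis=1), 0.0, atol=1e-8):
            raise ValueError("rows of Q must sum to 0")
        if not np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-8):
            raise ValueError("model must be reversible: pi_i Q_ij == pi_j Q_ji")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "pi", pi)
        # pi^1/2 Q pi^-1/2 is symmetric for a reversible Q; its eigenbasis
        # gives numerically stable transition matrices for any t >= 0
        sqrt_pi = np.sqrt(pi)
        sym = sqrt_pi[:, None] * Q / sqrt_pi[None, :]
        w, U = np.linalg.eigh((sym + sym.T) / 2.0)
        left = U.T * sqrt_pi[None, :]          # U' diag(sqrt_pi)
        right = (U.T / sqrt_pi[None, :]).T     # diag(1/sqrt_pi) U
        object.__setattr__(self, "_eig", (w, right, left))

    @property
    def expected_rate(self) -> float:
        """Expected substitutions per unit time, -sum_i pi_i Q_ii."""
        return float(-np.sum(self.pi * np.diag(self.Q)))

    def transition_matrix(self, t: float) -> np.ndarray:
        """Transition probabilities P(t) = exp(Qt) for branch length ``t``.

        Parameters
        ----------
        t : float
            Branch length in expected substitutions per site; must be >= 0.

        Returns
        -------
        (20, 20) ndarray
            Row-stochastic matrix; entry (i, j) is the probability of state
            j after time t given state i.
        """
        if not np.isfinite(t) or t < 0:
            raise ValueError(f"branch length must be finite and >= 0, got {t}")
        w, right, left = self._eig
        P = (right * np.exp(w * t)) @ left
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P


def build_reversible_model(
    exchangeabilities: np.ndarray, pi: np.ndarray, name: str = "custom"
) -> SubstitutionModel:
    """Assemble a normalised GTR rate matrix from exchangeabilities S and pi.

    Q_ij = S_ij * pi_j for i != j, diagonal set so rows sum to zero, then the
    whole matrix rescaled to one expected substitution per unit time.
    """
    S = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    pi = pi / pi.sum()
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    Q /= rate
    return SubstitutionModel(Q=Q, pi=pi, name=name)


def jtt_model() -> SubstitutionModel:
    """The JTT empirical amino-acid substitution model."""
    S = _expand_lower_triangle(_JTT_LOWER)
    return build_reversible_model(S, np.array(_JTT_FREQS), name="JTT")


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(t)
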