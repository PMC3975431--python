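"""Pseudo amino acid composition (PseAAC) of a protein from its sequence and
evolutionary profile.

The encoding is a fixed 500-component vector:

==========  =====  =======================================================
components  count  content
==========  =====  =======================================================
1-20          20   amino acid composition (AAC), canonical residue order
21-420       400   ordered dipeptide composition, lexicographic order
421-440       20   column means of the sigmoid-scaled PSSM
441-500       60   grey-model features: per residue type j, the triple
                   (w1*f_j*a1_j, w2*f_j*a2_j, w3*f_j*b_j)
==========  =====  =======================================================

The grey-model coefficients (a1, a2, b) per scaled-PSSM column come from a
least-squares fit to the column's first differences against the column values
and their accumulated sums — a small-sample trend model from grey system
theory. The fit is solved by minimum-norm least squares: for constant columns
the design matrix is rank-deficient (the difference vector is zero) and the
natural coefficients are all zero; whenever the design has full column rank
the solution coincides with the normal-equation formula (B'B)^{-1}B'U.

Composition blocks are proportions (each sums to 1); scaled-PSSM entries and
their column means lie strictly in (0, 1). The minimum sequence length for
the full encoding is 4, so the grey-model design has at least 3 rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_INDEX
from .errors import ValidationError
from .io import ProteinSequence, RawPSSM

N_PSEAAC = 500
MIN_LENGTH = 4

#: Segment boundaries of the 500-component vector (start, stop) 0-based.
SEGMENTS = {
    "aac": (0, 20),
    "dipeptide": (20, 420),
    "pssm_means": (420, 440),
    "grey": (440, 500),
}


@dataclass(frozen=True)
class ScaledPSSM:
    """L x 20 matrix of sigmoid-scaled evolution scores, entries in (0, 1)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValidationError(f"expected an Lx20 matrix, got shape {values.shape}")
        if not (np.all(values > 0.0) and np.all(values < 1.0)):
            raise ValidationError("scaled PSSM entries must lie strictly in (0, 1)")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


def aac(seq: ProteinSequence) -> np.ndarray:
    """Amino acid composition: 20 occurrence frequencies in canonical order."""
    counts = np.zeros(20)
    for residue in seq.residues:
        counts[AA_INDEX[residue]] += 1
    return counts / len(seq)


def dipeptide_composition(seq: ProteinSequence) -> np.ndarray:
    """Frequencies of the 400 ordered adjacent residue pairs.

    Index enumerates (first, second) lexicographically in canonical order:
    AA, AC, ..., AY, CA, ..., YY. Divisor is L - 1, the number of adjacent
    pairs, so the block sums to 1.
    """
    if len(seq) < 2:
        raise ValidationError(
            f"protein {seq.id!r}: dipeptide composition needs length >= 2, got {len(seq)}"
        )
    counts = np.zeros(400)
    idx = [AA_INDEX[aa] for aa in seq.residues]
    for first, second in zip(idx, idx[1:]):
        counts[first * 20 + second] += 1
    return counts / (len(seq) - 1)


def sigmoid_scale(raw: RawPSSM) -> ScaledPSSM:
    """Map raw scores elementwise through the logistic sigmoid 1/(1+e^-x)."""
    with np.errstate(over="ignore"):
        scaled = 1.0 / (1.0 + np.exp(-raw.scores))
    # guard against exact 0/1 from extreme scores; keep entries in the open interval
    tiny = np.finfo(float).tiny
    scaled = np.clip(scaled, tiny, 1.0 - np.finfo(float).epsneg)
    return ScaledPSSM(scaled)


def pssm_column_means(scaled: ScaledPSSM) -> np.ndarray:
    """Arithmetic mean of each scaled-PSSM column; 20 values in (0, 1)."""
    return scaled.values.mean(axis=0)


def grey_design(column: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix B ((L-1) x 3) and difference vector U (L-1) for one
    scaled-PSSM column.

    Row k (k = 1..L-1) of B is [-e_{k+1}, -(sum_{i<=k} e_i + 0.5 e_{k+1}), 1]
    and U_k = e_{k+1} - e_k, where e is the column.
    """
    e = np.asarray(column, dtype=float).ravel()
    u = np.diff(e)
    cumsum = np.cumsum(e)[:-1]
    b = np.column_stack([-e[1:], -(cumsum + 0.5 * e[1:]), np.ones(len(e) - 1)])
    return b, u


def grey_coefficients(column: np.ndarray) -> np.ndarray:
    """Least-squares grey-model coefficients (a1, a2, b) for one column.

    Solved by minimum-norm least squares; see the module docstring for why
    the literal normal-equation inverse is not used.
    """
    e = np.asarray(column, dtype=float).ravel()
    if e.size < MIN_LENGTH:
        raise ValidationError(
            f"grey model needs a column of length >= {MIN_LENGTH}, got {e.size}"
        )
    b, u = grey_design(e)
    coeffs, *_ = np.linalg.lstsq(b, u, rcond=None)
    return coeffs


def grey_features(
    scaled: ScaledPSSM,
    f1: np.ndarray,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """60 grey features: the AAC-weighted coefficient triple per residue type.

    For residue type j with composition f_j and coefficients (a1_j, a2_j, b_j),
    the triple (w1*f_j*a1_j, w2*f_j*a2_j, w3*f_j*b_j) occupies positions
    3j-2, 3j-1, 3j of the block. All three weights default to 1.
    """
    if len(scaled) < MIN_LENGTH:
        raise ValidationError(
            f"grey features need sequence length >= {MIN_LENGTH}, got {len(scaled)}"
        )
    f1 = np.asarray(f1, dtype=float).ravel()
    if f1.shape != (20,):
        raise ValidationError(f"expected 20 composition values, got {f1.size}")
    w = np.asarray(weights, dtype=float)
    out = np.empty(60)
    for j in range(20):
        coeffs = grey_coefficients(scaled.values[:, j])
        out[3 * j : 3 * j + 3] = w * f1[j] * coeffs
    return out


def encode_protein(
    seq: ProteinSequence,
    raw: RawPSSM,
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Full 500-component PseAAC vector for one protein.

    Parameters
    ----------
    seq
        The protein sequence (length >= 4).
    raw
        The protein's raw PSSM; row count must equal the sequence length.
    weights
        The three grey-feature weight factors (all 1 by default).
    """
    if len(raw) != len(seq):
        raise ValidationError(
            f"protein {seq.id!r}: sequence length {len(seq)} != PSSM rows {len(raw)}"
        )
    if len(seq) < MIN_LENGTH:
        raise ValidationError(
            f"protein {seq.id!r}: encoding needs length >= {MIN_LENGTH}, got {len(seq)}"
        )
    f1 = aac(seq)
    scaled = sigmoid_scale(raw)
    psi = np.empty(N_PSEAAC)
    psi[0:20] = f1
    psi[20:420] = dipeptide_composition(seq)
    psi[420:440] = pssm_column_means(scaled)
    psi[440:500] = grey_features(scaled, f1, weights)
    return psi
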