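"""Natural-vector fingerprints of nucleotide sequences.

A natural vector summarizes, per nucleotide k in {A, C, G, T}, the count
n_k, the mean 1-based sequence position mu_k, and the normalized central
positional moments

    D_k^j = sum_i (i - mu_k)^j w_k(s_i) / (n_k^{j-1} L^{j-1}),   j = 2..jmax,

where w_k(s_i) is the soft-encoding weight of nucleotide k at position i
(fractional for IUPAC ambiguity codes).  The vector is the concatenation of
the blocks (n_k, mu_k, D_k^2, ..., D_k^jmax) in A, C, G, T order, so its
dimension is 4 * (jmax + 1).  Equality of all moments of two sequences
implies equality of the positional distributions, which is what makes these
vectors usable as alignment-free fingerprints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, Sequence, SoftEncoding, encode_weights

__all__ = ["NaturalVector", "natural_vector", "nv_feature_table", "nv_feature_names"]

#: Practical upper bound on the moment order: higher moments are numerically
#: vanishing after the n^{j-1} normalization for realistic sequence lengths.
JMAX_CAP = 15


@dataclass
class NaturalVector:
    """Natural-vector values for one sequence, blocks ordered A, C, G, T."""

    jmax: int
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4 * (self.jmax + 1),):
            raise ValueError("values must have length 4 * (jmax + 1)")
        self.values = v


def _check_jmax(jmax: int) -> None:
    if not 2 <= jmax <= JMAX_CAP:
        raise ValueError(f"jmax must be in [2, {JMAX_CAP}], got {jmax}")


def natural_vector(enc: SoftEncoding | Sequence | str, jmax: int) -> NaturalVector:
    """Compute the natural vector of one sequence.

    Positions are 1-based.  For a nucleotide with no mass (n_k = 0) the
    convention mu_k = 0 and D_k^j = 0 keeps the vector finite and the
    dimension fixed.  For an unambiguous sequence in which a nucleotide
    occurs at most once the central moments vanish automatically (a single
    position has no spread).
    """
    _check_jmax(jmax)
    if isinstance(enc, (Sequence, str)):
        enc = encode_weights(enc)
    w = enc.weights
    L = w.shape[0]
    pos = np.arange(1, L + 1, dtype=float)

    values = np.zeros(4 * (jmax + 1))
    for k in range(4):
        wk = w[:, k]
        nk = float(wk.sum())
        block = values[k * (jmax + 1) : (k + 1) * (jmax + 1)]
        block[0] = nk
        if nk == 0.0:
            continue
        mu = float((pos * wk).sum() / nk)
        block[1] = mu
        # two-pass: center on the exact mean, then accumulate powers
        centered = pos - mu
        powers = centered.copy()
        for j in range(2, jmax + 1):
            powers = powers * centered
            block[j] = float((powers * wk).sum()) / (nk ** (j - 1) * L ** (j - 1))
    return NaturalVector(jmax=jmax, values=values)


def nv_feature_names(jmax: int) -> list[str]:
    _check_jmax(jmax)
    stats = ["n", "mu"] + [f"D{j}" for j in range(2, jmax + 1)]
    return [f"NV_{nuc}_{stat}" for nuc in ALPHABET for stat in stats]


def nv_feature_table(seqs: Iterable[Sequence], jmax: int) -> pd.DataFrame:
    """One natural-vector row per sequence (columns ``id``, ``label``, NV_...)."""
    names = nv_feature_names(jmax)
    rows, ids, labels = [], [], []
    for s in seqs:
        ids.append(s.id)
        labels.append(s.label)
        rows.append(natural_vector(s, jmax).values)
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "label", labels)
    df.insert(0, "id", ids)
    return df
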