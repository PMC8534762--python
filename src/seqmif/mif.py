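"""Mutual information function (MIF) profiles of nucleotide sequences.

The auto mutual information of a sequence at positional shift tau is the
information-theoretic analogue of the autocorrelation function: it measures
the statistical dependence between a nucleotide and the nucleotide tau
positions downstream (3' direction).  The *resolved* MIF (rMIF) decomposes
this quantity into four per-nucleotide contributions F(x, tau) whose sum over
the alphabet recovers the MIF.  Both exist for the Shannon entropy and for
its one-parameter Renyi and Tsallis generalizations; the F-quantities of the
Renyi and Tsallis families coincide, only the final information transforms
differ (logarithmic vs affine in F).

Estimation is plug-in: the joint distribution of the pair (s_i, s_{i+tau}) is
estimated over the L - tau available position pairs, with IUPAC ambiguity
codes contributing fractional counts through products of their soft-encoding
weights.  Marginals are the row/column sums of the joint (the non-symmetric
convention: the first marginal is over positions 1..L-tau, the second over
positions tau+1..L), so marginal consistency holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .sequence_io import ALPHABET, Sequence, SoftEncoding, encode_weights

__all__ = [
    "Family",
    "PairDistribution",
    "MIFProfile",
    "RMIFProfile",
    "ShiftTooLargeError",
    "pair_distribution",
    "shannon_rmif",
    "renyi_rmif",
    "tsallis_rmif",
    "rmif",
    "mif_value",
    "mutual_information",
    "mif_profile",
    "rmif_profile",
    "feature_table",
]

Family = Literal["shannon", "renyi", "tsallis"]
_FAMILIES = ("shannon", "renyi", "tsallis")


class ShiftTooLargeError(ValueError):
    """Raised when the shift tau leaves no position pair to estimate from."""


@dataclass
class PairDistribution:
    """Estimated joint/marginal nucleotide distributions at a fixed shift.

    ``joint[k, l]`` is the estimated probability of nucleotide ``k`` at a
    position and nucleotide ``l`` tau positions downstream; rows/columns are
    indexed A, C, G, T.  ``marginal_first`` / ``marginal_second`` are the row
    and column sums of the joint.  ``n_pairs`` is the number of position
    pairs the estimate is based on (L - tau).
    """

    tau: int
    joint: np.ndarray = field(repr=False)
    marginal_first: np.ndarray = field(repr=False)
    marginal_second: np.ndarray = field(repr=False)
    n_pairs: int

    def __post_init__(self) -> None:
        j = np.asarray(self.joint, dtype=float)
        if j.shape != (4, 4):
            raise ValueError("joint must be 4 x 4")
        if np.any(j < 0) or abs(j.sum() - 1.0) > 1e-12:
            raise ValueError("joint must be non-negative and sum to 1 (tol 1e-12)")
        if np.any(np.abs(j.sum(axis=1) - self.marginal_first) > 1e-12):
            raise ValueError("marginal_first must equal the row sums of joint")
        if np.any(np.abs(j.sum(axis=0) - self.marginal_second) > 1e-12):
            raise ValueError("marginal_second must equal the column sums of joint")


def _as_weights(enc: SoftEncoding | Sequence | str | np.ndarray) -> np.ndarray:
    if isinstance(enc, SoftEncoding):
        return enc.weights
    if isinstance(enc, (Sequence, str)):
        return encode_weights(enc).weights
    return np.asarray(enc, dtype=float)


def pair_distribution(enc: SoftEncoding | Sequence | str, tau: int) -> PairDistribution:
    """Estimate the joint nucleotide distribution at shift ``tau``.

    ``joint[k, l] = sum_{i=1}^{L-tau} w_k(s_i) w_l(s_{i+tau}) / (L - tau)``;
    for an unambiguous sequence this is exactly the relative frequency of the
    ordered pair (k, l) among all (i, i+tau) position pairs.
    """
    if tau < 1:
        raise ValueError(f"tau must be >= 1, got {tau}")
    w = _as_weights(enc)
    L = w.shape[0]
    if L <= tau:
        raise ShiftTooLargeError(
            f"shift tau={tau} too large for sequence of length {L} "
            "(need L >= tau + 1)"
        )
    n_pairs = L - tau
    joint = (w[:-tau].T @ w[tau:]) / n_pairs
    # clip tiny negative rounding noise, then renormalize exactly
    joint = np.clip(joint, 0.0, None)
    joint /= joint.sum()
    return PairDistribution(
        tau=tau,
        joint=joint,
        marginal_first=joint.sum(axis=1),
        marginal_second=joint.sum(axis=0),
        n_pairs=n_pairs,
    )


def shannon_rmif(pd_: PairDistribution, base: float = 2.0) -> np.ndarray:
    """Resolved Shannon MIF: per-nucleotide Kullback-Leibler contributions.

    Entry k is ``sum_l p(k,l) log[p(k,l) / (p(k) q(l))]`` with 0 log 0 := 0.
    The four entries sum to the Shannon mutual information at this shift.
    """
    j = pd_.joint
    denom = np.outer(pd_.marginal_first, pd_.marginal_second)
    out = np.zeros(4)
    mask = j > 0
    # a positive joint entry forces both marginals positive
    ratio = np.ones_like(j)
    ratio[mask] = j[mask] / denom[mask]
    terms = np.where(mask, j * np.log(ratio), 0.0) / np.log(base)
    out = terms.sum(axis=1)
    return out


def renyi_rmif(pd_: PairDistribution, alpha: float = 2.0) -> np.ndarray:
    """Resolved Renyi F-function: entry k is
    ``sum_l p(k,l)^alpha / (p(k) q(l))^(alpha-1)`` (zero-joint terms vanish).

    Identical to the Tsallis resolved F; only the scalar information
    transforms of the two families differ.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if alpha == 1.0:
        raise ValueError("alpha=1 is the Shannon case; use shannon_rmif")
    j = pd_.joint
    denom = np.outer(pd_.marginal_first, pd_.marginal_second)
    mask = j > 0
    terms = np.zeros_like(j)
    terms[mask] = j[mask] ** alpha / denom[mask] ** (alpha - 1.0)
    return terms.sum(axis=1)


# The Tsallis resolved F coincides with the Renyi one; a single code path
# guarantees the family equality bit-exactly.
tsallis_rmif = renyi_rmif


def rmif(pd_: PairDistribution, family: Family = "shannon",
         alpha: float = 2.0, base: float = 2.0) -> np.ndarray:
    """Resolved MIF vector (length 4, order A, C, G, T) for any family."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if family == "shannon":
        return shannon_rmif(pd_, base=base)
    return renyi_rmif(pd_, alpha=alpha)


def mif_value(pd_: PairDistribution, family: Family = "shannon",
              alpha: float = 2.0, base: float = 2.0) -> float:
    """MIF at one shift: the sum of the four resolved contributions."""
    return float(rmif(pd_, family, alpha=alpha, base=base).sum())


def mutual_information(
    pd_: PairDistribution,
    family: Family = "shannon",
    alpha: float = 2.0,
    base: float = 2.0,
    convention: Literal["nonnegative", "printed"] = "nonnegative",
) -> float:
    """Mutual information I at one shift, per entropy family.

    Shannon: I = F.  Renyi: I = log(F) / (alpha - 1).  Tsallis (default
    ``nonnegative`` convention): I = (F - 1) / (alpha - 1), which is >= 0 for
    alpha > 1 since F >= 1; the ``printed`` convention (1 - F)/(alpha - 1)
    is its negation and is exposed for completeness.
    """
    F = mif_value(pd_, family, alpha=alpha, base=base)
    if family == "shannon":
        return F
    if family == "renyi":
        if F <= 0:
            raise ValueError("Renyi information undefined: F <= 0")
        return float(np.log(F) / np.log(base) / (alpha - 1.0))
    # tsallis
    if convention == "printed":
        return float((1.0 - F) / (alpha - 1.0))
    return float((F - 1.0) / (alpha - 1.0))


@dataclass
class MIFProfile:
    """MIF feature vector: entry tau-1 holds F(X, tau) for tau = 1..tau_max."""

    family: Family
    alpha: float
    tau_max: int
    values: np.ndarray = field(repr=False)

    def feature_names(self) -> list[str]:
        return [f"F_{self.family}_X_{t}" for t in range(1, self.tau_max + 1)]

    def flatten(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


@dataclass
class RMIFProfile:
    """Resolved MIF feature table: ``values[k, tau-1] = F(nuc_k, tau)``.

    Flattening order is nucleotide-major: the A block tau=1..tau_max, then
    C, G, T — 4 * tau_max features in total.
    """

    family: Family
    alpha: float
    tau_max: int
    values: np.ndarray = field(repr=False)

    def feature_names(self) -> list[str]:
        return [
            f"F_{self.family}_{nuc}_{t}"
            for nuc in ALPHABET
            for t in range(1, self.tau_max + 1)
        ]

    def flatten(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float).reshape(-1)


def _profile_pds(enc, tau_max: int) -> list[PairDistribution]:
    if tau_max < 1:
        raise ValueError(f"tau_max must be >= 1, got {tau_max}")
    w = _as_weights(enc)
    if w.shape[0] <= tau_max:
        raise ShiftTooLargeError(
            f"tau_max={tau_max} too large for sequence of length {w.shape[0]}"
        )
    return [pair_distribution(w, t) for t in range(1, tau_max + 1)]


def mif_profile(enc, tau_max: int, family: Family = "shannon",
                alpha: float = 2.0, base: float = 2.0) -> MIFProfile:
    """MIF profile over shifts 1..tau_max (tau_max features)."""
    vals = np.array(
        [mif_value(p, family, alpha=alpha, base=base) for p in _profile_pds(enc, tau_max)]
    )
    return MIFProfile(family=family, alpha=alpha, tau_max=tau_max, values=vals)


def rmif_profile(enc, tau_max: int, family: Family = "shannon",
                 alpha: float = 2.0, base: float = 2.0) -> RMIFProfile:
    """Resolved MIF profile over shifts 1..tau_max (4 * tau_max features)."""
    cols = [rmif(p, family, alpha=alpha, base=base) for p in _profile_pds(enc, tau_max)]
    return RMIFProfile(
        family=family, alpha=alpha, tau_max=tau_max,
        values=np.stack(cols, axis=1),  # shape (4, tau_max)
    )


def feature_table(
    seqs: Iterable[Sequence],
    method: Literal["mif", "rmif"] = "rmif",
    tau_max: int = 7,
    family: Family = "shannon",
    alpha: float = 2.0,
    base: float = 2.0,
    on_short: Literal["error", "nan"] = "error",
) -> pd.DataFrame:
    """Featurize a corpus into a data frame (columns ``id``, ``label``, F_...).

    ``on_short="nan"`` fills the row of a sequence shorter than tau_max + 1
    with NaN instead of raising, so heterogeneous-length corpora can still be
    featurized; the caller must then filter.
    """
    seqs = list(seqs)
    profile_fn = rmif_profile if method == "rmif" else mif_profile
    n_feat = 4 * tau_max if method == "rmif" else tau_max
    names: list[str] | None = None
    rows, ids, labels = [], [], []
    for s in seqs:
        ids.append(s.id)
        labels.append(s.label)
        try:
            prof = profile_fn(s, tau_max, family=family, alpha=alpha, base=base)
        except ShiftTooLargeError:
            if on_short == "error":
                raise ShiftTooLargeError(
                    f"sequence {s.id!r} (length {len(s)}) shorter than "
                    f"tau_max + 1 = {tau_max + 1}"
                ) from None
            rows.append(np.full(n_feat, np.nan))
            continue
        if names is None:
            names = prof.feature_names()
        rows.append(prof.flatten())
    if names is None:  # every row short, or empty input
        nuc_blocks = list(ALPHABET) if method == "rmif" else ["X"]
        names = [f"F_{family}_{b}_{t}" for b in nuc_blocks for t in range(1, tau_max + 1)]
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "label", labels)
    df.insert(0, "id", ids)
    return df
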