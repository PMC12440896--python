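"""Burt constraint and structural-hole indices on egocentric networks.

The ego names exactly four peers; ties are binary and undirected, giving a
5x5 adjacency matrix with the ego at node 0.  For each ego-peer pair the
dyadic constraint

    C_ij = (P_ij + sum_{q != i,j} P_iq * P_qj)^2

measures how strongly peer j's embeddedness among the ego's other contacts
constrains ego i, where P_ij is the proportional tie strength: the i-j tie
divided by i's total tie strength.  The reciprocal 1/C_ij is the
structural-hole index of the dyad: low constraint means peer j bridges
otherwise unconnected parts of the ego's network.

Proportional strengths for peer rows are normalized over the peer's whole
neighbourhood *including the ego* (Burt's original whole-network
normalization).

Dyads are pooled across egos and split at empirical tertiles of the
structural-hole index into "low" / "middle" / "high" categories; ties go to
the lower category, so with heavy ties group sizes can be unequal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProportionMatrix",
    "ConstraintResult",
    "TertileCategorization",
    "proportional_strengths",
    "dyadic_constraint",
    "structural_hole_index",
    "aggregate_constraint",
    "ego_constraints",
    "tertile_categorize",
]

TERTILE_LABELS = ("low", "middle", "high")


@dataclass(frozen=True)
class ProportionMatrix:
    """Row-normalized adjacency: P[i, j] = z_ij / sum_q z_iq."""

    P: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        if P.ndim != 2 or P.shape[0] != P.shape[1]:
            raise ValueError("proportion matrix must be square")
        if np.any(np.diag(P) != 0):
            raise ValueError("proportion matrix must have zero diagonal")
        rowsum = P.sum(axis=1)
        ok = np.isclose(rowsum, 1.0, atol=1e-12) | (rowsum == 0)
        if not np.all(ok):
            raise ValueError("each non-isolated row must sum to 1")

    @property
    def n(self) -> int:
        return self.P.shape[0]


@dataclass(frozen=True)
class ConstraintResult:
    """Per-dyad constraint for one ego network (ego = node 0)."""

    ego_id: object
    constraint: np.ndarray  # C_ij for peers 1..4, in peer order
    sh_index: np.ndarray = field(init=False)  # 1 / C_ij

    def __post_init__(self) -> None:
        c = np.asarray(self.constraint, dtype=float)
        if np.any(c <= 0):
            raise ValueError("constraint must be positive for nominated peers")
        object.__setattr__(self, "constraint", c)
        object.__setattr__(self, "sh_index", 1.0 / c)

    @property
    def aggregate(self) -> float:
        """Total constraint on the ego, C_i = sum_j C_ij."""
        return float(self.constraint.sum())


@dataclass(frozen=True)
class TertileCategorization:
    """Three-way split of a pooled variable at its empirical tertiles."""

    cut_low: float
    cut_high: float
    labels: np.ndarray  # dtype object, values in TERTILE_LABELS
    counts: dict

    def __post_init__(self) -> None:
        if self.cut_low > self.cut_high:
            raise ValueError("cut_low must not exceed cut_high")


def _check_adjacency(adjacency: np.ndarray) -> np.ndarray:
    z = np.asarray(adjacency)
    if z.ndim != 2 or z.shape[0] != z.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.isin(z, (0, 1)).all():
        raise ValueError("adjacency entries must be 0 or 1")
    if np.any(np.diag(z) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if not np.array_equal(z, z.T):
        raise ValueError("adjacency must be symmetric")
    return z.astype(float)


def proportional_strengths(adjacency: np.ndarray) -> ProportionMatrix:
    """Row-normalize a validated binary adjacency into tie proportions.

    Rows of isolated nodes are left all-zero.
    """
    z = _check_adjacency(adjacency)
    deg = z.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(deg > 0, z / deg, 0.0)
    return ProportionMatrix(P)


def dyadic_constraint(P: ProportionMatrix, i: int, j: int) -> float:
    """Dyadic constraint C_ij = (P_ij + sum_{q != i,j} P_iq P_qj)^2."""
    if i == j:
        raise ValueError("constraint is defined for distinct nodes i != j")
    M = P.P
    indirect = M[i] @ M[:, j] - M[i, i] * M[i, j] - M[i, j] * M[j, j]
    # diagonal is zero, so only the q == i and q == j terms need removing;
    # both vanish with a zero diagonal but are written out for clarity
    total = M[i, j] + indirect
    return float(total * total)


def ego_constraints(P: ProportionMatrix, ego: int = 0) -> np.ndarray:
    """C_ij from the ego to every other node, vectorized over j."""
    M = P.P
    others = [j for j in range(P.n) if j != ego]
    # (P M)[ego, j] includes q == ego and q == j; zero diagonal kills both
    two_step = (M[ego] @ M)[others]
    direct = M[ego, others]
    return (direct + two_step) ** 2


def structural_hole_index(c_ij: float) -> float:
    """Structural-hole index of a dyad: the reciprocal of its constraint."""
    if c_ij <= 0:
        raise ValueError("constraint must be positive")
    return 1.0 / c_ij


def aggregate_constraint(P: ProportionMatrix, i: int) -> float:
    """Total constraint on node i: sum of C_ij over all other nodes j."""
    return float(sum(dyadic_constraint(P, i, j) for j in range(P.n) if j != i))


def tertile_categorize(values) -> TertileCategorization:
    """Split pooled values into tertile categories with ties going lower.

    Cut points are the ceil(n/3)-th and ceil(2n/3)-th order statistics;
    values <= cut_low are "low", <= cut_high "middle", else "high".
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot categorize an empty vector")
    if not np.isfinite(v).all():
        raise ValueError("values must be finite (no NaN/inf)")
    n = v.size
    s = np.sort(v)
    cut_low = float(s[math.ceil(n / 3) - 1])
    cut_high = float(s[math.ceil(2 * n / 3) - 1])
    labels = np.where(v <= cut_low, "low", np.where(v <= cut_high, "middle", "high"))
    labels = labels.astype(object)
    counts = {lab: int((labels == lab).sum()) for lab in TERTILE_LABELS}
    return TertileCategorization(cut_low=cut_low, cut_high=cut_high, labels=labels, counts=counts)
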