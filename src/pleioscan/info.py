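"""Exact plug-in information measures on small discrete alphabets.

All quantities are computed from an explicit joint distribution
(:class:`JointDistribution`), so every measure is an exact finite sum —
no sampling, no approximation beyond the plug-in (maximum likelihood)
frequency estimate used when a joint is built from data.

Units default to bits (log base 2); every public function accepts a
``base`` argument for natural-log users.  No small-sample bias correction
is applied: downstream permutation nulls are computed with the identical
estimator and therefore absorb the bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import xlogy

__all__ = [
    "JointDistribution",
    "DeltaScores",
    "entropy",
    "mutual_information",
    "conditional_mutual_information",
    "interaction_information",
    "deltas",
    "joint_from_samples",
]

MISSING = -2

_PROB_TOL = 1e-12


def _log_base_factor(base: float) -> float:
    if base <= 0 or base == 1:
        raise ValueError(f"invalid logarithm base: {base}")
    return np.log(base)


@dataclass(frozen=True)
class JointDistribution:
    """Empirical joint distribution over a cross-product of small alphabets.

    Parameters
    ----------
    probs
        Array of cell probabilities; ``probs.ndim`` is the number of
        variables and ``probs.shape`` the per-variable alphabet sizes.
    counts
        Optional raw cell counts (same shape) when the distribution was
        estimated from samples.
    n_samples
        Number of samples behind ``counts`` (``None`` for analytic
        distributions).
    """

    probs: np.ndarray
    counts: np.ndarray | None = None
    n_samples: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", p)
        if np.any(p < -_PROB_TOL):
            raise ValueError("negative cell probability")
        total = p.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")
        if self.counts is not None:
            c = np.asarray(self.counts)
            if c.shape != p.shape:
                raise ValueError("counts shape does not match probs shape")
            if np.any(c < 0):
                raise ValueError("negative cell count")
            object.__setattr__(self, "counts", c)

    @property
    def n_vars(self) -> int:
        return self.probs.ndim

    @property
    def alphabet_sizes(self) -> tuple[int, ...]:
        return self.probs.shape

    @classmethod
    def from_counts(cls, counts: np.ndarray) -> "JointDistribution":
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValueError("negative cell count")
        total = c.sum()
        if total <= 0:
            raise ValueError("empty count table")
        return cls(probs=c / total, counts=counts, n_samples=int(round(total)))

    @classmethod
    def from_probs(cls, probs: np.ndarray) -> "JointDistribution":
        return cls(probs=np.asarray(probs, dtype=float))

    def marginal(self, axes: int | Sequence[int]) -> "JointDistribution":
        """Marginal distribution over the given variable axes (kept in order)."""
        if isinstance(axes, (int, np.integer)):
            axes = (int(axes),)
        axes = tuple(int(a) for a in axes)
        drop = tuple(a for a in range(self.n_vars) if a not in axes)
        p = self.probs.sum(axis=drop)
        # reorder surviving axes to requested order
        kept = [a for a in range(self.n_vars) if a in axes]
        perm = [kept.index(a) for a in axes]
        p = np.transpose(p, perm)
        c = None
        if self.counts is not None:
            c = np.transpose(np.asarray(self.counts).sum(axis=drop), perm)
        return JointDistribution(probs=p, counts=c, n_samples=self.n_samples)


def _require_arity(dist: JointDistribution, arity: int, op: str) -> None:
    if dist.n_vars != arity:
        raise ValueError(
            f"{op} requires a {arity}-variable joint, got {dist.n_vars} variables"
        )


def entropy(dist: JointDistribution | np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy of a joint (or marginal) distribution.

    Uses the convention 0*log(0) = 0.  Returns bits for the default base.
    """
    p = dist.probs if isinstance(dist, JointDistribution) else np.asarray(dist, float)
    if np.any(p < -_PROB_TOL):
        raise ValueError("negative probability")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    h = -xlogy(p, p).sum() / _log_base_factor(base)
    return max(float(h), 0.0)


def mutual_information(dist: JointDistribution, base: float = 2.0) -> float:
    """I(X,Y) = H(X) + H(Y) - H(X,Y) on a 2-variable joint."""
    _require_arity(dist, 2, "mutual_information")
    hx = entropy(dist.marginal(0), base)
    hy = entropy(dist.marginal(1), base)
    hxy = entropy(dist, base)
    return hx + hy - hxy


def conditional_mutual_information(
    dist: JointDistribution, cond_axis: int = 2, base: float = 2.0
) -> float:
    """I of the two non-conditioned variables given variable ``cond_axis``.

    For a joint over (X, Y, Z) with ``cond_axis=2`` this is I(X;Y|Z)
    = H(X,Z) + H(Y,Z) - H(Z) - H(X,Y,Z).
    """
    _require_arity(dist, 3, "conditional_mutual_information")
    others = [a for a in range(3) if a != cond_axis]
    h_xz = entropy(dist.marginal((others[0], cond_axis)), base)
    h_yz = entropy(dist.marginal((others[1], cond_axis)), base)
    h_z = entropy(dist.marginal(cond_axis), base)
    h_xyz = entropy(dist, base)
    return h_xz + h_yz - h_z - h_xyz


def interaction_information(dist: JointDistribution, base: float = 2.0) -> float:
    """Three-variable interaction information I(X,Y,Z) = I(X,Y) - I(X,Y|Z).

    Negative for synergistic relations (XOR gives -1 bit); invariant under
    any permutation of the three variables.
    """
    _require_arity(dist, 3, "interaction_information")
    hs = [entropy(dist.marginal(a), base) for a in range(3)]
    hp = [
        entropy(dist.marginal((0, 1)), base),
        entropy(dist.marginal((0, 2)), base),
        entropy(dist.marginal((1, 2)), base),
    ]
    h3 = entropy(dist, base)
    return sum(hs) - sum(hp) + h3


@dataclass(frozen=True)
class DeltaScores:
    """Bundle of three-variable dependency scores (bits; delta_sym bits^3).

    ``delta_x`` targets the first variable of the joint, ``delta_y`` the
    second, ``delta_z`` the third.  ``pairwise_mi`` holds
    (I(X,Y), I(X,Z), I(Y,Z)).
    """

    i3: float
    delta_x: float
    delta_y: float
    delta_z: float
    delta_sym: float
    omega: float
    pairwise_mi: tuple[float, float, float] = field(default=(0.0, 0.0, 0.0))


def deltas(dist: JointDistribution, base: float = 2.0) -> DeltaScores:
    """Asymmetric deltas, symmetric delta and multi-information of a triple.

    delta_X = I(X,Y,Z) - I(Y,Z); equivalently -I(Y;Z|X), hence always <= 0
    on exact distributions.  delta_sym is the product of the three
    asymmetric deltas and omega the total correlation
    sum(H(single)) - H(joint).
    """
    _require_arity(dist, 3, "deltas")
    hx = entropy(dist.marginal(0), base)
    hy = entropy(dist.marginal(1), base)
    hz = entropy(dist.marginal(2), base)
    h_xy = entropy(dist.marginal((0, 1)), base)
    h_xz = entropy(dist.marginal((0, 2)), base)
    h_yz = entropy(dist.marginal((1, 2)), base)
    h3 = entropy(dist, base)

    i_xy = hx + hy - h_xy
    i_xz = hx + hz - h_xz
    i_yz = hy + hz - h_yz
    i3 = (hx + hy + hz) - (h_xy + h_xz + h_yz) + h3
    dx = i3 - i_yz
    dy = i3 - i_xz
    dz = i3 - i_xy
    omega = hx + hy + hz - h3
    return DeltaScores(
        i3=i3,
        delta_x=dx,
        delta_y=dy,
        delta_z=dz,
        delta_sym=dx * dy * dz,
        omega=omega,
        pairwise_mi=(i_xy, i_xz, i_yz),
    )


def joint_from_samples(
    columns: Sequence[np.ndarray] | np.ndarray,
    missing_sentinel: int = MISSING,
) -> JointDistribution:
    """Plug-in joint distribution from equal-length integer-coded columns.

    Rows containing ``missing_sentinel`` in any column are excluded
    (complete-case estimation); alphabet per variable is the set of codes
    actually observed among retained rows.
    """
    cols = [np.asarray(c) for c in columns]
    if len(cols) == 0:
        raise ValueError("no columns supplied")
    n = len(cols[0])
    for c in cols:
        if c.ndim != 1 or len(c) != n:
            raise ValueError("columns must be equal-length 1-D arrays")
    keep = np.ones(n, dtype=bool)
    for c in cols:
        keep &= c != missing_sentinel
    if not keep.any():
        raise ValueError("no complete-case rows remain after removing missing values")
    coded = []
    sizes = []
    for c in cols:
        levels, inv = np.unique(c[keep], return_inverse=True)
        coded.append(inv)
        sizes.append(len(levels))
    flat = np.ravel_multi_index(tuple(coded), tuple(sizes))
    counts = np.bincount(flat, minlength=int(np.prod(sizes))).reshape(sizes)
    return JointDistribution.from_counts(counts)
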