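"""Permutation significance, confounding adjustment, stratified K-S tests.

The permutation null pools dependency scores across all scanned tuples:
for each shuffle the phenotype values are permuted (leaving genotype
linkage intact; for three-way scans the two phenotype sets are permuted
independently) and the full score vector recomputed with the identical
estimator.  The pooled p-value of an observed score is the fraction of
all null scores at least as extreme; the family-wise error rate is the
fraction of per-shuffle maximum scores at least as extreme.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .datatypes import MISSING

__all__ = [
    "NullDistribution",
    "EthnicityLabels",
    "permutation_null",
    "pooled_pvalue",
    "fwer",
    "adjusted_mutual_information",
    "ks_stratified",
    "SCHEMES",
]

SCHEMES = ("permute_phenotype", "permute_both_phenotypes_independently")


def null_cache_key(data_arrays, scheme: str, n_shuffles: int, seed) -> str:
    """Stable cache key: hash of the input data plus the null settings."""
    import hashlib

    h = hashlib.sha256()
    for arr in data_arrays:
        a = np.ascontiguousarray(arr)
        h.update(str(a.shape).encode())
        h.update(a.tobytes())
    h.update(f"{scheme}|{n_shuffles}|{seed}".encode())
    return h.hexdigest()[:32]


@dataclass
class NullDistribution:
    """Pooled permutation null for a family of tuple scores.

    ``pooled_scores`` has shape (n_shuffles, n_tuples) and stores the
    extremeness-transformed scores (larger = more extreme);
    ``per_shuffle_max`` is the row-wise maximum.
    """

    pooled_scores: np.ndarray
    per_shuffle_max: np.ndarray
    n_shuffles: int
    n_tuples: int
    scheme: str
    orientation: str = "greater"

    def __post_init__(self) -> None:
        self.pooled_scores = np.asarray(self.pooled_scores, float)
        if self.pooled_scores.shape != (self.n_shuffles, self.n_tuples):
            raise ValueError("pooled_scores shape must be (n_shuffles, n_tuples)")
        if len(self.per_shuffle_max) != self.n_shuffles:
            raise ValueError("per_shuffle_max length must equal n_shuffles")

    @property
    def total(self) -> int:
        return self.n_shuffles * self.n_tuples

    def save(self, path) -> None:
        """Persist to a binary (npz) cache file."""
        np.savez_compressed(
            path,
            pooled_scores=self.pooled_scores,
            per_shuffle_max=np.asarray(self.per_shuffle_max, float),
            scheme=np.array(self.scheme),
            orientation=np.array(self.orientation),
        )

    @classmethod
    def load(cls, path) -> "NullDistribution":
        with np.load(path, allow_pickle=False) as z:
            pooled = z["pooled_scores"]
            return cls(
                pooled_scores=pooled,
                per_shuffle_max=z["per_shuffle_max"],
                n_shuffles=pooled.shape[0],
                n_tuples=pooled.shape[1],
                scheme=str(z["scheme"]),
                orientation=str(z["orientation"]),
            )


def extremeness(scores: np.ndarray, orientation: str) -> np.ndarray:
    """Map raw scores to a scale where larger means more extreme.

    'greater' keeps scores as-is (mutual information); 'abs' takes the
    absolute value (delta scores, which are non-positive).
    """
    scores = np.asarray(scores, dtype=float)
    if orientation == "greater":
        return scores
    if orientation == "abs":
        return np.abs(scores)
    raise ValueError(f"unknown orientation: {orientation!r}")


def permutation_null(
    score_fn: Callable[..., np.ndarray],
    data: tuple,
    n_shuffles: int = 1000,
    scheme: str = "permute_phenotype",
    seed: int | None = 0,
    orientation: str = "greater",
) -> NullDistribution:
    """Pooled permutation null distribution.

    ``data`` is (genotypes, phenotypes) for scheme 'permute_phenotype'
    (phenotype rows are shuffled jointly, preserving genotype linkage) or
    (genotypes, bayley, growth) for
    'permute_both_phenotypes_independently' (the two phenotype blocks are
    shuffled with independent permutations).  ``score_fn`` receives the
    shuffled blocks and must return the full tuple-score vector computed
    with the same estimator as the observed scan.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown permutation scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    pooled = []
    for _ in range(n_shuffles):
        if scheme == "permute_phenotype":
            g, ph = data
            perm = rng.permutation(ph.shape[0])
            scores = score_fn(g, ph[perm])
        else:
            g, bay, gro = data
            perm_b = rng.permutation(bay.shape[0])
            perm_g = rng.permutation(gro.shape[0])
            scores = score_fn(g, bay[perm_b], gro[perm_g])
        pooled.append(extremeness(np.ravel(scores), orientation))
    pooled = np.asarray(pooled)
    return NullDistribution(
        pooled_scores=pooled,
        per_shuffle_max=pooled.max(axis=1),
        n_shuffles=pooled.shape[0],
        n_tuples=pooled.shape[1],
        scheme=scheme,
        orientation=orientation,
    )


def pooled_pvalue(
    observed: float | np.ndarray,
    null: NullDistribution,
    return_floor_flag: bool = False,
):
    """Pooled permutation p-value(s) of observed score(s).

    p = #{null scores >= observed} / (n_tuples * n_shuffles), where
    scores are compared on the extremeness scale of the null.  Values
    with no exceeding null score are reported at the attainable floor
    1/(n_tuples * n_shuffles) and flagged.
    """
    if null.total == 0:
        raise ValueError("empty null distribution")
    obs = extremeness(np.atleast_1d(observed), null.orientation)
    flat = np.sort(null.pooled_scores, axis=None)
    exceed = len(flat) - np.searchsorted(flat, obs, side="left")
    at_floor = exceed == 0
    p = np.maximum(exceed, 1) / null.total
    if np.isscalar(observed) or np.ndim(observed) == 0:
        p, at_floor = float(p[0]), bool(at_floor[0])
    if return_floor_flag:
        return p, at_floor
    return p


def fwer(observed: float | np.ndarray, null: NullDistribution):
    """Family-wise error rate: fraction of per-shuffle maxima >= observed."""
    obs = extremeness(np.atleast_1d(observed), null.orientation)
    maxima = np.sort(null.per_shuffle_max)
    count = len(maxima) - np.searchsorted(maxima, obs, side="left")
    out = count / null.n_shuffles
    if np.isscalar(observed) or np.ndim(observed) == 0:
        return float(out[0])
    return out


@dataclass(frozen=True)
class EthnicityLabels:
    """Binary ethnicity-group assignment with group priors.

    ``groups`` maps each subject (positionally) to group 1 or 2; priors
    default to the empirical group frequencies and must sum to 1.
    """

    groups: np.ndarray
    priors: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.groups)
        if not np.isin(g, (1, 2)).all():
            raise ValueError("ethnicity groups must be coded 1 or 2")
        object.__setattr__(self, "groups", g)
        if self.priors is not None and abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("group priors must sum to 1")

    def effective_priors(self) -> tuple[float, float]:
        if self.priors is not None:
            return self.priors
        p1 = float(np.mean(self.groups == 1))
        return (p1, 1.0 - p1)


def adjusted_mutual_information(
    snp: np.ndarray,
    phenotype: np.ndarray,
    eth: EthnicityLabels,
    base: float = 2.0,
    literal_standardization: bool = False,
    return_flags: bool = False,
):
    """Ethnicity-standardized mutual information between a SNP and a phenotype.

    Replaces the conditional p(b|s) with the standardized
    pi(b|s) = sum_i P(eps_i) p(b|s, eps_i) before evaluating
    I~ = sum_s p(s) sum_b pi(b|s) log(pi(b|s) / p(b)).  With a single
    group, or when the within-group conditionals agree, this equals the
    unadjusted mutual information exactly.  (s, group) cells with no
    subjects fall back to the group-free conditional and are flagged.

    ``literal_standardization`` uses the unweighted sum over groups
    instead of the prior-weighted one (not a proper distribution; for
    comparison only).
    """
    snp = np.asarray(snp)
    phenotype = np.asarray(phenotype)
    groups = np.asarray(eth.groups)
    keep = (snp != MISSING) & (phenotype != MISSING)
    s, b, e = snp[keep], phenotype[keep], groups[keep]
    if len(s) == 0:
        raise ValueError("no complete-case subjects")
    s_levels, s_idx = np.unique(s, return_inverse=True)
    b_levels, b_idx = np.unique(b, return_inverse=True)
    ns, nb = len(s_levels), len(b_levels)
    n = len(s)

    p_s = np.bincount(s_idx, minlength=ns) / n
    p_b = np.bincount(b_idx, minlength=nb) / n

    present = [np.unique(e) == g for g in (1, 2)]
    priors = eth.effective_priors()
    single_group = len(np.unique(e)) < 2
    flagged_cells: list[tuple[int, int]] = []

    # group-free conditional p(b|s)
    joint = np.zeros((ns, nb))
    np.add.at(joint, (s_idx, b_idx), 1.0)
    cond_free = joint / np.maximum(joint.sum(axis=1, keepdims=True), 1e-300)

    if single_group:
        pi = cond_free
    else:
        pi = np.zeros((ns, nb))
        weight_used = np.zeros(ns)
        for gi, gval in enumerate((1, 2)):
            sel = e == gval
            jg = np.zeros((ns, nb))
            np.add.at(jg, (s_idx[sel], b_idx[sel]), 1.0)
            rowsum = jg.sum(axis=1)
            w = 1.0 if literal_standardization else priors[gi]
            for si in range(ns):
                if rowsum[si] > 0:
                    pi[si] += w * jg[si] / rowsum[si]
                    weight_used[si] += w
                else:
                    flagged_cells.append((int(s_levels[si]), gval))
        # cells with an absent (s, group) combination: fall back so each
        # row still integrates the full prior mass
        for si in range(ns):
            deficit = (2.0 if literal_standardization else 1.0) - weight_used[si]
            if deficit > 1e-12:
                pi[si] += deficit * cond_free[si]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(pi > 0, pi / p_b[None, :], 1.0)
        terms = pi * np.log(ratio)
    mi = float((p_s[:, None] * terms).sum() / np.log(base))
    if return_flags:
        return mi, flagged_cells
    return mi


def ks_stratified(
    values: np.ndarray,
    strata: np.ndarray,
    min_stratum_size: int = 2,
) -> pd.DataFrame:
    """Two-sample Kolmogorov-Smirnov test for every pair of strata.

    Returns a long-format table (stratum_a, stratum_b, n_a, n_b,
    statistic, p_value) over all unordered pairs including the diagonal
    (statistic 0, p 1).  Missing values (-2 or NaN) are dropped first.
    """
    values = np.asarray(values, dtype=float)
    strata = np.asarray(strata)
    ok = np.isfinite(values) & (values != MISSING) & (strata != MISSING)
    values, strata = values[ok], strata[ok]
    levels = np.unique(strata)
    if len(levels) < 2:
        raise ValueError("need at least 2 non-empty strata")
    samples = {lv: values[strata == lv] for lv in levels}
    for lv, x in samples.items():
        if len(x) < min_stratum_size:
            raise ValueError(f"stratum {lv!r} has fewer than {min_stratum_size} values")
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i:]:
            if a == b:
                stat, p = 0.0, 1.0
            else:
                res = ks_2samp(samples[a], samples[b], method="auto")
                stat, p = float(res.statistic), float(res.pvalue)
            rows.append(
                {
                    "stratum_a": a,
                    "stratum_b": b,
                    "n_a": len(samples[a]),
                    "n_b": len(samples[b]),
                    "statistic": stat,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)
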