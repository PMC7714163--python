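"""Genotype and phenotype preprocessing.

Genotype cleaning applies, in order: removal of constant SNPs, collapsing
of completely correlated SNPs, removal of high-missingness SNPs,
mutual-information-based collapsing, removal of near-constant SNPs, and
relocation of X/Y-chromosome SNPs to a separate matrix for sex-stratified
analysis.  Every input SNP is accounted for exactly once in the report.

Numeric phenotypes are discretized into four bins delimited by the mean
and the medians of the below-/above-mean values.  Low-missingness
subject/variable subsets are selected by an exact 0/1 integer program
(falling back to alternating elimination on very large inputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "LPSelection",
    "preprocess_genotypes",
    "collapse_by_mi",
    "pairwise_snp_mi",
    "discretize_numeric",
    "discretize_table",
    "screen_categorical",
    "select_subset_lp",
    "ld_r2",
    "genotype_r2",
]


@dataclass(frozen=True)
class PreprocessConfig:
    missing_threshold: float = 0.25
    mi_threshold: float = 1.2
    near_constant_threshold: float = 0.95
    log_base: float = 2.0
    # all-pairs duplicate detection is O(m^2 n); above this column count only
    # exact (byte-identical) duplicates are collapsed at step 2
    pairwise_complete_limit: int = 3000


@dataclass
class PreprocessReport:
    """Per-step accounting of the genotype cleaning pipeline."""

    n_input: int
    n_output: int
    step_counts: dict[str, int]
    removed: dict[str, list[str]]
    collapsed_identical: dict[str, list[str]]
    collapsed_mi: dict[str, list[str]]
    sex_snp_ids: list[str]
    retained_ids: list[str]
    sex_matrix: GenotypeMatrix | None = field(default=None, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "step_counts": self.step_counts,
            "removed": self.removed,
            "collapsed_identical": self.collapsed_identical,
            "collapsed_mi": self.collapsed_mi,
            "sex_snp_ids": self.sex_snp_ids,
            "retained_ids": self.retained_ids,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _chrom_order_key(chrom: str) -> tuple[int, str]:
    try:
        return (int(chrom), "")
    except ValueError:
        return (1000, str(chrom))


def _nonmissing_profile(codes: np.ndarray):
    obs = codes != MISSING
    n_obs = obs.sum(axis=0)
    counts = np.stack([(codes == lv).sum(axis=0) for lv in (0, 1, 2)])
    return obs, n_obs, counts


def _constant_mask(codes: np.ndarray) -> np.ndarray:
    _, n_obs, counts = _nonmissing_profile(codes)
    n_levels = (counts > 0).sum(axis=0)
    return (n_levels <= 1) | (n_obs == 0)


def _pairwise_complete_equal_groups(codes: np.ndarray) -> list[list[int]]:
    """Single-linkage groups of columns equal on mutually observed subjects."""
    m = codes.shape[1]
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    obs = codes != MISSING
    for i in range(m):
        ci, oi = codes[:, i], obs[:, i]
        for j in range(i + 1, m):
            both = oi & obs[:, j]
            if both.any() and np.array_equal(ci[both], codes[both, j]):
                union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for v in groups.values() if len(v) > 1]


def _identical_groups(codes: np.ndarray) -> list[list[int]]:
    """Groups of byte-identical columns (missing pattern included)."""
    seen: dict[bytes, list[int]] = {}
    arr = np.ascontiguousarray(codes.T)
    for j in range(arr.shape[0]):
        seen.setdefault(arr[j].tobytes(), []).append(j)
    return [v for v in seen.values() if len(v) > 1]


def _pick_representatives(
    groups: list[list[int]], snp_map: pd.DataFrame
) -> tuple[list[int], dict[str, list[str]]]:
    """Lowest (chromosome, position) member represents each group."""
    keep = []
    mapping: dict[str, list[str]] = {}
    for grp in groups:
        order = sorted(
            grp,
            key=lambda j: (
                _chrom_order_key(str(snp_map.iloc[j]["chrom"])),
                int(snp_map.iloc[j]["pos"]),
                str(snp_map.iloc[j]["rsid"]),
            ),
        )
        rep = order[0]
        keep.append(rep)
        mapping[str(snp_map.iloc[rep]["rsid"])] = [
            str(snp_map.iloc[j]["rsid"]) for j in order[1:]
        ]
    return keep, mapping


def pairwise_snp_mi(
    codes_a: np.ndarray,
    codes_b: np.ndarray | None = None,
    log_base: float = 2.0,
) -> np.ndarray:
    """Pairwise-complete mutual information between genotype columns.

    Returns an (m_a, m_b) matrix; genotype alphabet {0, 1, 2}, missing
    excluded per pair.  Vectorized via level-indicator matrix products.
    """
    b_same = codes_b is None
    codes_b = codes_a if b_same else codes_b
    ind_a = [(codes_a == lv).astype(np.float32) for lv in (0, 1, 2)]
    ind_b = ind_a if b_same else [(codes_b == lv).astype(np.float32) for lv in (0, 1, 2)]
    ma, mb = codes_a.shape[1], codes_b.shape[1]
    N = np.zeros((3, 3, ma, mb))
    for a in range(3):
        for b in range(3):
            N[a, b] = ind_a[a].T @ ind_b[b]
    n_pair = N.sum(axis=(0, 1))
    with np.errstate(invalid="ignore", divide="ignore"):
        p = N / n_pair
        pa = p.sum(axis=1)  # (3, ma, mb)
        pb = p.sum(axis=0)
        h_a = -xlogy(pa, pa).sum(axis=0)
        h_b = -xlogy(pb, pb).sum(axis=0)
        h_ab = -xlogy(p, p).sum(axis=(0, 1))
    mi = (h_a + h_b - h_ab) / np.log(log_base)
    mi[~np.isfinite(mi)] = 0.0
    return mi


def collapse_by_mi(
    g: GenotypeMatrix,
    threshold: float = 1.2,
    log_base: float = 2.0,
    chunk: int = 512,
) -> tuple[GenotypeMatrix, dict[str, list[str]]]:
    """Collapse single-linkage clusters of SNP pairs with MI above threshold.

    One representative (lowest chromosome/position) is kept per cluster;
    the returned mapping lists the absorbed members per representative.
    """
    if threshold <= 0:
        raise ValueError("MI threshold must be positive")
    m = g.n_snps
    parent = list(range(m))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    if np.isfinite(threshold):
        for start in range(0, m, chunk):
            stop = min(start + chunk, m)
            mi = pairwise_snp_mi(g.codes[:, start:stop], g.codes, log_base=log_base)
            rows, cols = np.nonzero(mi > threshold)
            for r, c in zip(rows, cols):
                if start + r != c:
                    union(start + r, c)

    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)
    multi = [sorted(v) for v in groups.values() if len(v) > 1]
    reps, mapping = _pick_representatives(multi, g.snp_map)
    drop = {j for grp in multi for j in grp} - set(reps)
    keep_idx = [j for j in range(m) if j not in drop]
    return g.take_snps(keep_idx), mapping


def preprocess_genotypes(
    g: GenotypeMatrix, config: PreprocessConfig | None = None
) -> tuple[GenotypeMatrix, PreprocessReport]:
    """Six-step genotype cleaning; see module docstring for the order."""
    cfg = config or PreprocessConfig()
    n_input = g.n_snps

    # step 1: constant SNPs
    const = _constant_mask(g.codes)
    removed_constant = [g.rsids[j] for j in np.nonzero(const)[0]]
    g1 = g.take_snps(np.nonzero(~const)[0])

    # step 2: completely correlated SNPs (equal on mutually observed subjects)
    if g1.n_snps <= cfg.pairwise_complete_limit:
        groups = _pairwise_complete_equal_groups(g1.codes)
    else:
        groups = _identical_groups(g1.codes)
    reps, collapsed_identical = _pick_representatives(groups, g1.snp_map)
    drop2 = {j for grp in groups for j in grp} - set(reps)
    g2 = g1.take_snps([j for j in range(g1.n_snps) if j not in drop2])

    # step 3: high missingness
    miss_frac = (g2.codes == MISSING).mean(axis=0)
    high_miss = miss_frac > cfg.missing_threshold
    removed_missing = [g2.rsids[j] for j in np.nonzero(high_miss)[0]]
    g3 = g2.take_snps(np.nonzero(~high_miss)[0])

    # step 4: MI-based collapsing
    g4, collapsed_mi = collapse_by_mi(g3, cfg.mi_threshold, cfg.log_base)

    # step 5: near-constant SNPs (>threshold of observed genotypes identical)
    _, n_obs, counts = _nonmissing_profile(g4.codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        top_frac = counts.max(axis=0) / n_obs
    near_const = top_frac > cfg.near_constant_threshold
    removed_near_constant = [g4.rsids[j] for j in np.nonzero(near_const)[0]]
    g5 = g4.take_snps(np.nonzero(~near_const)[0])

    # step 6: move X/Y (incl. pseudoautosomal) SNPs to a separate matrix
    is_sex = g5.is_sex_chromosome()
    sex_ids = [g5.rsids[j] for j in np.nonzero(is_sex)[0]]
    sex_matrix = g5.take_snps(np.nonzero(is_sex)[0]) if is_sex.any() else None
    g6 = g5.take_snps(np.nonzero(~is_sex)[0])

    n_collapsed_identical = sum(len(v) for v in collapsed_identical.values())
    n_collapsed_mi = sum(len(v) for v in collapsed_mi.values())
    report = PreprocessReport(
        n_input=n_input,
        n_output=g6.n_snps,
        step_counts={
            "constant": len(removed_constant),
            "collapsed_identical": n_collapsed_identical,
            "high_missing": len(removed_missing),
            "collapsed_mi": n_collapsed_mi,
            "near_constant": len(removed_near_constant),
            "sex_chromosome": len(sex_ids),
        },
        removed={
            "constant": removed_constant,
            "high_missing": removed_missing,
            "near_constant": removed_near_constant,
        },
        collapsed_identical=collapsed_identical,
        collapsed_mi=collapsed_mi,
        sex_snp_ids=sex_ids,
        retained_ids=g6.rsids,
        sex_matrix=sex_matrix,
    )
    return g6, report


def discretize_numeric(
    values: np.ndarray, missing_sentinel: float = np.nan
) -> np.ndarray:
    """Four-bin discretization: (-inf, l], (l, mu], (mu, r], (r, inf).

    mu is the mean of the non-missing values, l the median of values <= mu
    and r the median of values > mu.  Output codes are 1..4; missing
    entries are preserved as -2.
    """
    x = np.asarray(values, dtype=float)
    if np.isnan(missing_sentinel):
        miss = np.isnan(x)
    else:
        miss = (x == missing_sentinel) | np.isnan(x)
    obs = x[~miss]
    if len(obs) == 0:
        raise ValueError("no non-missing values to discretize")
    if np.all(obs == obs[0]):
        raise ValueError("cannot discretize a constant variable")
    if len(np.unique(obs)) < 4:
        raise ValueError("need at least 4 distinct values for four-bin discretization")
    mu = obs.mean()
    lower = obs[obs <= mu]
    upper = obs[obs > mu]
    l = np.median(lower)
    r = np.median(upper) if len(upper) else mu
    codes = np.full(x.shape, MISSING, dtype=np.int64)
    ok = ~miss
    codes[ok & (x <= l)] = 1
    codes[ok & (x > l) & (x <= mu)] = 2
    codes[ok & (x > mu) & (x <= r)] = 3
    codes[ok & (x > r)] = 4
    return codes


def discretize_table(table: PhenotypeTable, missing_sentinel: float = np.nan) -> PhenotypeTable:
    """Discretize every numeric column of a phenotype table to 4 bins."""
    out = table.copy()
    for name in out.phenotype_names:
        if out.kinds.get(name) == "numeric":
            out.data[name] = discretize_numeric(
                out.data[name].to_numpy(float), missing_sentinel
            )
            out.kinds[name] = "coded"
    return out


def screen_categorical(
    table: PhenotypeTable,
    max_categories: int = 10,
    constant_threshold: float = 0.95,
) -> tuple[PhenotypeTable, dict[str, str]]:
    """Drop coded variables with too many categories or near-constant values.

    Variables with more than ``max_categories`` distinct non-missing codes,
    or with one code in more than ``constant_threshold`` of the observed
    subjects, are removed.  Returns the screened table and a map of
    dropped name -> reason.
    """
    dropped: dict[str, str] = {}
    keep = ["subject_id"]
    for name in table.phenotype_names:
        if table.kinds.get(name) != "coded":
            keep.append(name)
            continue
        col = table.coded(name)
        obs = col[col != MISSING]
        if len(obs) == 0:
            dropped[name] = "all_missing"
            continue
        values, counts = np.unique(obs, return_counts=True)
        if len(values) > max_categories:
            dropped[name] = "too_many_categories"
        elif counts.max() / len(obs) > constant_threshold:
            dropped[name] = "near_constant"
        else:
            keep.append(name)
    out = PhenotypeTable(
        data=table.data[keep].copy(),
        kinds={k: v for k, v in table.kinds.items() if k in keep},
    )
    return out, dropped


@dataclass(frozen=True)
class LPSelection:
    """Result of the low-missingness subject/variable subset selection."""

    kept_subjects: tuple[int, ...]
    kept_variables: tuple[int, ...]
    tau: float
    objective: int

    def submatrix(self, matrix: np.ndarray) -> np.ndarray:
        return matrix[np.ix_(self.kept_subjects, self.kept_variables)]


def _greedy_selection(miss: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    """Alternating row/column elimination fallback."""
    rows = np.ones(miss.shape[0], dtype=bool)
    cols = np.ones(miss.shape[1], dtype=bool)
    while True:
        changed = False
        if cols.any() and rows.any():
            frac = miss[np.ix_(rows, cols)].mean(axis=0)
            bad = np.nonzero(cols)[0][frac > tau]
            # drop the single worst-offending variable, then re-evaluate
            if len(bad):
                worst = bad[np.argmax(frac[frac > tau])]
                cols[worst] = False
                changed = True
        if rows.any() and cols.any():
            all_missing = miss[np.ix_(rows, cols)].all(axis=1)
            if all_missing.any():
                rows[np.nonzero(rows)[0][all_missing]] = False
                changed = True
        if not changed or not cols.any() or not rows.any():
            break
    return np.nonzero(rows)[0], np.nonzero(cols)[0]


def select_subset_lp(
    matrix: np.ndarray,
    tau: float,
    missing_sentinel: int = MISSING,
    exact_limit: int = 200_000,
) -> LPSelection:
    """Select subjects and variables maximizing count under missingness limits.

    Solved as a 0/1 integer program: indicator x_i per subject and y_j per
    variable, maximizing sum(x) + sum(y) subject to (a) every kept subject
    having at least one observed value among kept variables and (b) every
    kept variable having missing fraction <= tau among kept subjects.
    Exact (HiGHS MILP) up to ``exact_limit`` cells, alternating-elimination
    heuristic beyond.
    """
    if not (0.0 <= tau <= 1.0):
        raise ValueError("tau must be in [0, 1]")
    matrix = np.asarray(matrix)
    n, m = matrix.shape
    miss = matrix == missing_sentinel

    if n * m > exact_limit:
        rows, cols = _greedy_selection(miss, tau)
    else:
        rows, cols = _milp_selection(miss, tau)
        grows, gcols = _greedy_selection(miss, tau)
        if len(grows) + len(gcols) > len(rows) + len(cols):  # pragma: no cover
            rows, cols = grows, gcols
    if len(rows) == 0 or len(cols) == 0:
        raise ValueError("no feasible nonempty subject/variable selection")
    return LPSelection(
        kept_subjects=tuple(int(i) for i in rows),
        kept_variables=tuple(int(j) for j in cols),
        tau=tau,
        objective=int(len(rows) + len(cols)),
    )


def _milp_selection(miss: np.ndarray, tau: float) -> tuple[np.ndarray, np.ndarray]:
    from scipy.optimize import LinearConstraint, milp
    from scipy.sparse import lil_matrix

    n, m = miss.shape
    nonmiss = ~miss
    n_var = n + m  # x_0..x_{n-1}, y_0..y_{m-1}
    c = -np.ones(n_var)

    A = lil_matrix((n + m + 2, n_var))
    lb = np.full(n + m + 2, -np.inf)
    ub = np.full(n + m + 2, np.inf)
    # non-empty selection: at least one subject and one variable, so the
    # per-variable missingness fraction is well defined
    A[n + m, :n] = 1.0
    lb[n + m] = 1.0
    A[n + m + 1, n:] = 1.0
    lb[n + m + 1] = 1.0
    # (a) sum_j nonmiss_ij y_j - x_i >= 0
    for i in range(n):
        A[i, i] = -1.0
        for j in np.nonzero(nonmiss[i])[0]:
            A[i, n + j] = 1.0
        lb[i] = 0.0
    # (b) sum_i (miss_ij - tau) x_i + M_j y_j <= M_j
    mj = miss.sum(axis=0).astype(float)
    for j in range(m):
        big = max(mj[j], 1.0)
        for i in range(n):
            coef = (1.0 if miss[i, j] else 0.0) - tau
            if coef != 0.0:
                A[n + j, i] = coef
        A[n + j, n + j] = big
        ub[n + j] = big
    res = milp(
        c,
        constraints=LinearConstraint(A.tocsr(), lb, ub),
        integrality=np.ones(n_var),
        bounds=(0, 1),
    )
    if res.status != 0 or res.x is None:  # pragma: no cover
        return _greedy_selection(miss, tau)
    x = res.x[:n] > 0.5
    y = res.x[n:] > 0.5
    return np.nonzero(x)[0], np.nonzero(y)[0]


def genotype_r2(col1: np.ndarray, col2: np.ndarray) -> float:
    """Squared Pearson correlation of two genotype columns, pairwise-complete."""
    both = (col1 != MISSING) & (col2 != MISSING)
    a, b = col1[both].astype(float), col2[both].astype(float)
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def ld_r2(
    g: GenotypeMatrix,
    candidate_snps: Sequence[str],
    window_bp: int = 500_000,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Report SNPs in linkage disequilibrium with each candidate.

    Partners are SNPs on the same chromosome within ``window_bp`` of the
    candidate whose genotype-correlation r^2 reaches the threshold.
    """
    rsid_to_idx = {r: j for j, r in enumerate(g.rsids)}
    rows = []
    chroms = g.snp_map["chrom"].astype(str).to_numpy()
    pos = g.snp_map["pos"].to_numpy(int)
    for cand in candidate_snps:
        if cand not in rsid_to_idx:
            raise KeyError(f"candidate SNP not in matrix: {cand}")
        cj = rsid_to_idx[cand]
        near = np.nonzero(
            (chroms == chroms[cj]) & (np.abs(pos - pos[cj]) <= window_bp)
        )[0]
        for j in near:
            if j == cj:
                continue
            r2 = genotype_r2(g.codes[:, cj], g.codes[:, j])
            if np.isfinite(r2) and r2 >= r2_threshold:
                rows.append(
                    {
                        "candidate": cand,
                        "partner": g.rsids[j],
                        "r2": r2,
                        "distance_bp": int(abs(pos[j] - pos[cj])),
                    }
                )
    return pd.DataFrame(rows, columns=["candidate", "partner", "r2", "distance_bp"])
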