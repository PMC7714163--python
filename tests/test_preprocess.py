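"""Tests for genotype/phenotype preprocessing and subset selection."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from pleioscan.datatypes import MISSING, GenotypeMatrix, PhenotypeTable
from pleioscan.preprocess import (
    PreprocessConfig,
    collapse_by_mi,
    discretize_numeric,
    genotype_r2,
    ld_r2,
    pairwise_snp_mi,
    preprocess_genotypes,
    screen_categorical,
    select_subset_lp,
)
from pleioscan.simulate import CohortSpec, simulate_genotypes


def make_matrix(columns, chroms=None, positions=None):
    codes = np.column_stack(columns).astype(np.int8)
    m = codes.shape[1]
    snp_map = pd.DataFrame(
        {
            "rsid": [f"rs{j}" for j in range(m)],
            "chrom": chroms if chroms is not None else ["1"] * m,
            "pos": positions if positions is not None else list(range(100, 100 + m)),
            "major": ["A"] * m,
            "minor": ["G"] * m,
        }
    )
    return GenotypeMatrix(
        codes=codes,
        snp_map=snp_map,
        subject_ids=[f"S{i}" for i in range(codes.shape[0])],
    )


# ---------------------------------------------------------------------------
# preprocess_genotypes step behavior


def test_constant_snp_removed_step1():
    g = make_matrix([np.ones(20, dtype=int), np.arange(20) % 3])
    out, report = preprocess_genotypes(g)
    assert report.step_counts["constant"] == 1
    assert "rs0" in report.removed["constant"]
    assert out.rsids == ["rs1"]


def test_high_missing_removed_step3():
    rng = np.random.default_rng(0)
    col_ok = rng.integers(0, 3, 40)
    col_bad = col_ok.copy()
    col_bad[:12] = MISSING  # 30% missing > 25%
    # perturb so it is not collapsed as identical at step 2
    col_bad[12:20] = (col_bad[12:20] + 1) % 3
    g = make_matrix([col_ok, col_bad])
    out, report = preprocess_genotypes(g)
    assert report.step_counts["high_missing"] == 1
    assert report.removed["high_missing"] == ["rs1"]


def test_identical_columns_collapsed_step2():
    rng = np.random.default_rng(1)
    col = rng.integers(0, 3, 30)
    g = make_matrix([col, col.copy(), rng.integers(0, 3, 30)],
                    positions=[100, 50, 200])
    out, report = preprocess_genotypes(g)
    # rs1 has the lower position -> representative; rs0 absorbed
    assert report.step_counts["collapsed_identical"] == 1
    assert report.collapsed_identical == {"rs1": ["rs0"]}
    assert "rs0" not in out.rsids


def test_pairwise_complete_equality_collapses_despite_missing():
    rng = np.random.default_rng(2)
    col = rng.integers(0, 3, 50)
    col2 = col.copy()
    col2[3] = MISSING  # equal wherever both observed
    g = make_matrix([col, col2, (col + 1) % 3])
    _, report = preprocess_genotypes(g)
    assert report.step_counts["collapsed_identical"] == 1


def test_near_constant_removed_step5():
    col = np.zeros(100, dtype=int)
    col[:4] = 1  # 96% share genotype 0
    other = np.arange(100) % 3
    g = make_matrix([col, other])
    _, report = preprocess_genotypes(g)
    assert report.step_counts["near_constant"] == 1


def test_sex_chromosome_moved_step6():
    rng = np.random.default_rng(3)
    g = make_matrix(
        [rng.integers(0, 3, 30), rng.integers(0, 3, 30)],
        chroms=["1", "X"],
    )
    out, report = preprocess_genotypes(g)
    assert report.sex_snp_ids == ["rs1"]
    assert report.sex_matrix is not None
    assert report.sex_matrix.rsids == ["rs1"]
    assert out.rsids == ["rs0"]


def test_report_accounting_invariant(small_cohort):
    g = small_cohort.genotypes
    out, report = preprocess_genotypes(g)
    total_removed = sum(report.step_counts.values())
    assert report.n_input - report.n_output == total_removed
    accounted = set(report.retained_ids)
    for ids in report.removed.values():
        accounted |= set(ids)
    accounted |= set(report.sex_snp_ids)
    for rep, members in report.collapsed_identical.items():
        accounted |= set(members)
    for rep, members in report.collapsed_mi.items():
        accounted |= set(members)
    assert accounted == set(g.rsids)


def test_preprocess_idempotent(small_cohort):
    out1, _ = preprocess_genotypes(small_cohort.genotypes)
    out2, report2 = preprocess_genotypes(out1)
    assert out2.rsids == out1.rsids
    assert np.array_equal(out2.codes, out1.codes)
    assert sum(report2.step_counts.values()) == 0


def test_unknown_genotype_code_rejected():
    with pytest.raises(ValueError, match="unknown genotype code"):
        make_matrix([np.array([0, 1, 5, 2])])


# ---------------------------------------------------------------------------
# MI collapsing


def test_collapse_by_mi_identical_high_entropy_columns():
    rng = np.random.default_rng(4)
    # near-uniform tri-level column: H ~ 1.58 bits > 1.2
    col = np.repeat([0, 1, 2], 40)
    rng.shuffle(col)
    g = make_matrix([col, col.copy(), rng.integers(0, 3, 120)],
                    positions=[10, 5, 99])
    out, groups = collapse_by_mi(g, threshold=1.2)
    assert groups == {"rs1": ["rs0"]}
    assert out.n_snps == 2


def test_collapse_by_mi_independent_no_collapse():
    rng = np.random.default_rng(5)
    cols = [rng.integers(0, 3, 200) for _ in range(5)]
    out, groups = collapse_by_mi(make_matrix(cols), threshold=1.2)
    assert groups == {}
    assert out.n_snps == 5


def test_collapse_by_mi_infinite_threshold_identity(small_cohort):
    g = small_cohort.genotypes
    out, groups = collapse_by_mi(g, threshold=np.inf)
    assert out.rsids == g.rsids
    assert groups == {}


def test_collapse_by_mi_invalid_threshold():
    g = make_matrix([np.arange(10) % 3])
    with pytest.raises(ValueError):
        collapse_by_mi(g, threshold=0.0)


def test_pairwise_snp_mi_matches_exact():
    from pleioscan.info import joint_from_samples, mutual_information

    rng = np.random.default_rng(6)
    a = rng.integers(0, 3, 300)
    b = (a + rng.integers(0, 2, 300)) % 3
    g = make_matrix([a, b])
    mi = pairwise_snp_mi(g.codes)
    expected = mutual_information(joint_from_samples([a, b]))
    assert mi[0, 1] == pytest.approx(expected, abs=1e-9)
    # diagonal equals the entropy H(X) = MI(X, X)
    hx = mutual_information(joint_from_samples([a, a]))
    assert mi[0, 0] == pytest.approx(hx, abs=1e-9)


def test_pairwise_snp_mi_chunk_independence():
    rng = np.random.default_rng(7)
    cols = [rng.integers(0, 3, 100) for _ in range(9)]
    g = make_matrix(cols)
    out1, groups1 = collapse_by_mi(g, threshold=0.5, chunk=2)
    out2, groups2 = collapse_by_mi(g, threshold=0.5, chunk=100)
    assert out1.rsids == out2.rsids
    assert groups1 == groups2


# ---------------------------------------------------------------------------
# discretization


def test_discretize_one_to_eight():
    codes = discretize_numeric(np.arange(1, 9, dtype=float))
    # mu=4.5, l=2.5, r=6.5 -> two values per bin
    assert np.bincount(codes, minlength=5)[1:].tolist() == [2, 2, 2, 2]
    assert codes.tolist() == [1, 1, 2, 2, 3, 3, 4, 4]


def test_discretize_gaussian_quartiles():
    rng = np.random.default_rng(8)
    x = rng.standard_normal(100_000)
    codes = discretize_numeric(x)
    fracs = np.bincount(codes, minlength=5)[1:] / len(x)
    assert np.allclose(fracs, 0.25, atol=0.01)


def test_discretize_value_at_mean_in_second_bin():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])  # mu = 2.0
    codes = discretize_numeric(x)
    assert codes[x == 2.0][0] == 2


def test_discretize_preserves_missing():
    x = np.array([1.0, 2.0, np.nan, 3.0, 4.0, 5.0])
    codes = discretize_numeric(x)
    assert codes[2] == MISSING
    assert set(codes[codes != MISSING]) <= {1, 2, 3, 4}


def test_discretize_sentinel_missing():
    x = np.array([1.0, 2.0, -2.0, 3.0, 4.0, 5.0])
    codes = discretize_numeric(x, missing_sentinel=-2.0)
    assert codes[2] == MISSING


def test_discretize_constant_errors():
    with pytest.raises(ValueError):
        discretize_numeric(np.full(10, 3.0))


def test_discretize_too_few_distinct_errors():
    with pytest.raises(ValueError):
        discretize_numeric(np.array([1.0, 2.0, 1.0, 2.0, 3.0]))


def test_discretize_bins_partition_real_line():
    rng = np.random.default_rng(9)
    x = rng.standard_cauchy(1000)  # heavy tails
    codes = discretize_numeric(x)
    assert (codes != MISSING).all()
    assert set(np.unique(codes)) <= {1, 2, 3, 4}


# ---------------------------------------------------------------------------
# categorical screening


def _coded_table(**cols):
    n = len(next(iter(cols.values())))
    data = {"subject_id": [f"S{i}" for i in range(n)]}
    data.update({k: np.asarray(v, dtype=np.int64) for k, v in cols.items()})
    return PhenotypeTable(data=pd.DataFrame(data))


def test_screen_drops_too_many_categories():
    t = _coded_table(big=np.arange(100) % 11, ok=np.arange(100) % 3)
    out, dropped = screen_categorical(t)
    assert dropped == {"big": "too_many_categories"}
    assert out.phenotype_names == ["ok"]


def test_screen_keeps_ten_categories():
    t = _coded_table(ten=np.arange(100) % 10)
    out, dropped = screen_categorical(t)
    assert dropped == {}
    assert out.phenotype_names == ["ten"]


def test_screen_drops_near_constant():
    col = np.zeros(100, dtype=int)
    col[:4] = 1  # 96% constant
    t = _coded_table(flat=col, ok=np.arange(100) % 4)
    out, dropped = screen_categorical(t)
    assert dropped == {"flat": "near_constant"}


# ---------------------------------------------------------------------------
# LP subset selection


def brute_force_selection(miss, tau):
    """Exhaustive-search optimum of the subset-selection problem."""
    n, m = miss.shape
    best = 0
    for rows_bits in range(1, 2**n):
        rows = [i for i in range(n) if rows_bits >> i & 1]
        for cols_bits in range(1, 2**m):
            cols = [j for j in range(m) if cols_bits >> j & 1]
            sub = miss[np.ix_(rows, cols)]
            if sub.all(axis=1).any():  # a kept subject with no observed value
                continue
            if (sub.mean(axis=0) > tau + 1e-12).any():
                continue
            best = max(best, len(rows) + len(cols))
    return best


def test_lp_complete_matrix_keeps_everything():
    mat = np.ones((5, 4), dtype=int)
    sel = select_subset_lp(mat, tau=0.5)
    assert sel.objective == 9
    assert len(sel.kept_subjects) == 5 and len(sel.kept_variables) == 4


def test_lp_tau_zero_no_missing_left():
    rng = np.random.default_rng(10)
    mat = rng.integers(0, 3, (12, 8))
    mask = rng.random((12, 8)) < 0.15
    mat[mask] = MISSING
    sel = select_subset_lp(mat, tau=0.0)
    assert (sel.submatrix(mat) != MISSING).all()


def test_lp_matches_brute_force_small_instances():
    rng = np.random.default_rng(11)
    for trial in range(30):
        n = int(rng.integers(2, 7))
        m = int(rng.integers(2, 7))
        mat = np.zeros((n, m), dtype=int)
        mat[rng.random((n, m)) < 0.35] = MISSING
        tau = float(rng.choice([0.0, 0.25, 0.5]))
        expected = brute_force_selection(mat == MISSING, tau)
        if expected == 0:
            with pytest.raises(ValueError):
                select_subset_lp(mat, tau)
            continue
        sel = select_subset_lp(mat, tau)
        assert sel.objective == expected, (trial, mat, tau)


def test_lp_invariants_hold():
    rng = np.random.default_rng(12)
    mat = rng.integers(0, 4, (15, 10))
    mat[rng.random((15, 10)) < 0.2] = MISSING
    sel = select_subset_lp(mat, tau=0.25)
    sub = sel.submatrix(mat)
    assert (sub != MISSING).any(axis=1).all()  # every kept subject observed
    assert ((sub == MISSING).mean(axis=0) <= 0.25 + 1e-12).all()


def test_lp_invalid_tau():
    with pytest.raises(ValueError):
        select_subset_lp(np.zeros((3, 3), dtype=int), tau=1.5)


# ---------------------------------------------------------------------------
# LD r2


def test_genotype_r2_self_is_one():
    rng = np.random.default_rng(13)
    col = rng.integers(0, 3, 100)
    assert genotype_r2(col, col) == pytest.approx(1.0)


def test_ld_r2_duplicate_column_reported():
    rng = np.random.default_rng(14)
    col = rng.integers(0, 3, 200)
    g = make_matrix([col, col.copy(), rng.integers(0, 3, 200)],
                    positions=[1000, 2000, 3000])
    out = ld_r2(g, ["rs0"], window_bp=10_000, r2_threshold=0.8)
    assert out["partner"].tolist() == ["rs1"]
    assert out["r2"].iloc[0] == pytest.approx(1.0)


def test_ld_r2_independent_snps_not_reported():
    rng = np.random.default_rng(15)
    g = make_matrix(
        [rng.integers(0, 3, 500), rng.integers(0, 3, 500)], positions=[100, 200]
    )
    out = ld_r2(g, ["rs0"], window_bp=10_000, r2_threshold=0.5)
    assert out.empty


def test_ld_r2_window_excludes_distant():
    rng = np.random.default_rng(16)
    col = rng.integers(0, 3, 100)
    g = make_matrix([col, col.copy()], positions=[1000, 900_000])
    out = ld_r2(g, ["rs0"], window_bp=100_000, r2_threshold=0.8)
    assert out.empty


def test_ld_r2_unknown_candidate_errors(small_cohort):
    with pytest.raises(KeyError):
        ld_r2(small_cohort.genotypes, ["rs_nope"], 1000, 0.5)
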