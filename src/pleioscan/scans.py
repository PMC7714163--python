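"""Dependency scans over genotype and phenotype tables.

Scans compute mutual information (2-way) or delta scores (3-way) for
every tuple on the complete-case subject set, then attach pooled
permutation p-values and family-wise error rates.  Scoring is vectorized
across SNPs: genotype level indicators and phenotype one-hot matrices are
combined by matrix products into contingency tensors, from which all
entropies are evaluated in closed form.  Results are independent of
chunking and bit-for-bit reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable

__all__ = [
    "NullConfig",
    "ScanResult",
    "scan_pairwise",
    "scan_phenotype_dependencies",
    "scan_threeway",
    "scan_asymmetric",
    "scan_snp_interaction",
    "scan_sex_stratified",
    "annotate_nearest_gene",
    "mi_profile",
    "delta_profile",
]

_LN2 = np.log(2.0)

# default report cutoffs for flagging rows (configurable per call)
PAIRWISE_BAYLEY_CUTOFF = 2.7e-6
PAIRWISE_GROWTH_CUTOFF = 8e-6
THREEWAY_CUTOFF = 3.2e-6


@dataclass(frozen=True)
class NullConfig:
    """Permutation-null settings for a scan."""

    n_shuffles: int = 1000
    seed: int = 0
    compute_fwer: bool = True

    def __post_init__(self) -> None:
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")


@dataclass
class ScanResult:
    """Ranked tuples with scores, pooled p-values and FWER."""

    table: pd.DataFrame
    kind: str
    n_subjects: int
    n_shuffles: int
    n_tuples: int

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.table.head(k)


# ---------------------------------------------------------------------------
# vectorized scoring kernels


def _genotype_indicators(codes: np.ndarray, levels=(0, 1, 2)) -> np.ndarray:
    """(L, n, m) float32 level indicators; missing rows are all-zero."""
    return np.stack([(codes == lv) for lv in levels]).astype(np.float32)


def _onehot(col: np.ndarray, n_levels: int) -> np.ndarray:
    """(K, n) float32 one-hot of an integer column with codes 0..K-1."""
    out = np.zeros((n_levels, len(col)), dtype=np.float32)
    valid = col >= 0
    out[col[valid], np.nonzero(valid)[0]] = 1.0
    return out


def _compact(col: np.ndarray) -> tuple[np.ndarray, int]:
    """Re-code observed values to 0..K-1 (missing stays negative)."""
    obs = col != MISSING
    levels, inv = np.unique(col[obs], return_inverse=True)
    out = np.full(len(col), -1, dtype=np.int64)
    out[obs] = inv
    return out, len(levels)


def mi_profile(g_ind: np.ndarray, ph_onehot: np.ndarray) -> np.ndarray:
    """MI (bits) between one phenotype and every SNP column.

    g_ind: (L, n, m) genotype indicators; ph_onehot: (K, n).
    Assumes complete cases (no missing in either input).
    """
    L = g_ind.shape[0]
    N = np.stack([ph_onehot @ g_ind[lv] for lv in range(L)], axis=1).astype(float)
    # N: (K, L, m)
    n = N.sum(axis=(0, 1))
    p = N / n
    pk = p.sum(axis=1)
    pl = p.sum(axis=0)
    h_k = -xlogy(pk, pk).sum(axis=0)
    h_l = -xlogy(pl, pl).sum(axis=0)
    h_kl = -xlogy(p, p).sum(axis=(0, 1))
    return (h_k + h_l - h_kl) / _LN2


def delta_profile(
    g_ind: np.ndarray,
    b_onehot: np.ndarray,
    r_onehot: np.ndarray,
) -> dict[str, np.ndarray]:
    """Three-way scores of (bayley, growth, SNP_j) for every SNP column.

    Returns delta_sym (bits^3), the asymmetric deltas, interaction
    information, omega and the three pairwise MIs (bits), each as an
    (m,) array.  Assumes complete cases.
    """
    Kb, n = b_onehot.shape
    Kr = r_onehot.shape[0]
    L = g_ind.shape[0]
    # combined phenotype-pair code, then contingency with each SNP
    q = (b_onehot[:, None, :] * r_onehot[None, :, :]).reshape(Kb * Kr, n)
    N = np.stack([q @ g_ind[lv] for lv in range(L)], axis=1).astype(float)
    T = N.reshape(Kb, Kr, L, -1)
    n_sub = T.sum(axis=(0, 1, 2))
    p = T / n_sub

    def H(arr, axes):
        return -xlogy(arr, arr).sum(axis=axes) / _LN2

    pxy = p.sum(axis=2)
    pxz = p.sum(axis=1)
    pyz = p.sum(axis=0)
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    pz = pxz.sum(axis=0)
    hx, hy, hz = H(px, 0), H(py, 0), H(pz, 0)
    hxy, hxz, hyz = H(pxy, (0, 1)), H(pxz, (0, 1)), H(pyz, (0, 1))
    hxyz = H(p, (0, 1, 2))
    i_xy = hx + hy - hxy
    i_xz = hx + hz - hxz
    i_yz = hy + hz - hyz
    i3 = (hx + hy + hz) - (hxy + hxz + hyz) + hxyz
    d_b = i3 - i_yz  # target: bayley (axis 0)
    d_r = i3 - i_xz  # target: growth (axis 1)
    d_s = i3 - i_xy  # target: SNP (axis 2)
    return {
        "delta_sym": d_b * d_r * d_s,
        "delta_bayley": d_b,
        "delta_growth": d_r,
        "delta_snp": d_s,
        "i3": i3,
        "omega": hx + hy + hz - hxyz,
        "mi_bayley_growth": i_xy,
        "mi_bayley_snp": i_xz,
        "mi_growth_snp": i_yz,
    }


# ---------------------------------------------------------------------------
# complete-case alignment


def _align_subjects(g: GenotypeMatrix, *tables: PhenotypeTable):
    """Intersect subjects by id, preserving genotype-matrix order."""
    common = set(g.subject_ids)
    for t in tables:
        common &= set(t.subject_ids)
    g_idx = [i for i, s in enumerate(g.subject_ids) if s in common]
    order = [g.subject_ids[i] for i in g_idx]
    aligned = []
    for t in tables:
        lookup = {s: i for i, s in enumerate(t.subject_ids)}
        aligned.append(t.data.iloc[[lookup[s] for s in order]].reset_index(drop=True))
    return g.take_subjects(g_idx), [
        PhenotypeTable(data=df, kinds=dict(t.kinds)) for df, t in zip(aligned, tables)
    ]


def _complete_case(g: GenotypeMatrix, *tables: PhenotypeTable):
    """Drop subjects with any missing phenotype, then SNPs with missing values."""
    g, tables = _align_subjects(g, *tables)
    keep = np.ones(g.n_subjects, dtype=bool)
    for t in tables:
        for name in t.phenotype_names:
            col = t.data[name].to_numpy()
            if t.kinds.get(name) == "coded":
                keep &= col != MISSING
            else:
                keep &= np.isfinite(col.astype(float))
    idx = np.nonzero(keep)[0]
    if len(idx) == 0:
        raise ValueError("no complete-case subjects remain")
    g = g.take_subjects(idx)
    tables = [
        PhenotypeTable(data=t.data.iloc[idx].reset_index(drop=True), kinds=dict(t.kinds))
        for t in tables
    ]
    snp_ok = np.nonzero(~(g.codes == MISSING).any(axis=0))[0]
    if len(snp_ok) == 0:
        raise ValueError("no SNPs without missing values remain")
    return g.take_snps(snp_ok), tables


# ---------------------------------------------------------------------------
# streaming pooled null


class _PooledNull:
    """Accumulates exceedance counts against a fixed observed-score vector."""

    def __init__(self, observed_extreme: np.ndarray):
        self.obs = np.asarray(observed_extreme, float)
        self.exceed = np.zeros(len(self.obs), dtype=np.int64)
        self.maxima: list[float] = []
        self.n_tuples = len(self.obs)

    def update(self, null_scores: np.ndarray) -> None:
        ns = np.sort(np.ravel(null_scores))
        if len(ns) != self.n_tuples:
            raise ValueError("null score vector length changed between shuffles")
        self.exceed += len(ns) - np.searchsorted(ns, self.obs, side="left")
        self.maxima.append(float(ns[-1]))

    def pvalues(self) -> tuple[np.ndarray, np.ndarray]:
        total = len(self.maxima) * self.n_tuples
        at_floor = self.exceed == 0
        p = np.maximum(self.exceed, 1) / total
        return p, at_floor

    def fwer(self) -> np.ndarray:
        maxima = np.sort(self.maxima)
        return (len(maxima) - np.searchsorted(maxima, self.obs, side="left")) / len(
            maxima
        )


def _rank_table(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic ranking: p asc, |score| desc, rsid/variable lex."""
    df = df.copy()
    df["_abs"] = df["score"].abs()
    tie_cols = [c for c in ("rsid", "var1", "var2", "var3") if c in df.columns]
    df = df.sort_values(
        ["p_value", "_abs"] + tie_cols, ascending=[True, False] + [True] * len(tie_cols)
    ).drop(columns="_abs")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# scans


def scan_pairwise(
    g: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    null_cfg: NullConfig | None = None,
    cutoff: float = PAIRWISE_BAYLEY_CUTOFF,
) -> ScanResult:
    """MI of every SNP x phenotype pair with pooled permutation p-values.

    Phenotype rows are shuffled jointly per permutation (SNP linkage
    preserved); the null pools scores over all tuples of the scan.
    """
    cfg = null_cfg or NullConfig()
    g, (ph,) = _complete_case(g, phenotypes)
    names = ph.phenotype_names
    cols = []
    for name in names:
        c, k = _compact(ph.coded(name))
        cols.append((name, c, k))
    g_ind = _genotype_indicators(g.codes)
    m = g.n_snps

    observed = np.concatenate(
        [mi_profile(g_ind, _onehot(c, k)) for _, c, k in cols]
    )
    pool = _PooledNull(observed)
    rng = np.random.default_rng(cfg.seed)
    n = g.n_subjects
    for _ in range(cfg.n_shuffles):
        perm = rng.permutation(n)
        null = np.concatenate(
            [mi_profile(g_ind, _onehot(c[perm], k)) for _, c, k in cols]
        )
        pool.update(null)
    p, at_floor = pool.pvalues()
    fw = pool.fwer() if cfg.compute_fwer else np.full(len(observed), np.nan)

    table = pd.DataFrame(
        {
            "phenotype": np.repeat([nm for nm, _, _ in cols], m),
            "rsid": np.tile(g.rsids, len(cols)),
            "chrom": np.tile(g.snp_map["chrom"].to_numpy(), len(cols)),
            "pos": np.tile(g.snp_map["pos"].to_numpy(), len(cols)),
            "major": np.tile(g.snp_map["major"].to_numpy(), len(cols)),
            "minor": np.tile(g.snp_map["minor"].to_numpy(), len(cols)),
            "score": observed,
            "p_value": p,
            "p_at_floor": at_floor,
            "fwer": fw,
        }
    )
    table["flagged"] = table["p_value"] <= cutoff
    table["n_subjects"] = g.n_subjects
    return ScanResult(
        table=_rank_table(table),
        kind="pairwise",
        n_subjects=g.n_subjects,
        n_shuffles=cfg.n_shuffles,
        n_tuples=len(observed),
    )


def _phenotype_joint_scores(cols: dict[str, np.ndarray]):
    """All pairwise MIs and all triple symmetric deltas on coded columns."""
    from .info import deltas, joint_from_samples, mutual_information

    names = list(cols)
    pair_rows, triple_rows = [], []
    for a, b in combinations(names, 2):
        mi = mutual_information(joint_from_samples([cols[a], cols[b]]))
        pair_rows.append((a, b, mi))
    for a, b, c in combinations(names, 3):
        ds = deltas(joint_from_samples([cols[a], cols[b], cols[c]])).delta_sym
        triple_rows.append((a, b, c, ds))
    return pair_rows, triple_rows


def scan_phenotype_dependencies(
    phenotypes: PhenotypeTable,
    null_cfg: NullConfig | None = None,
) -> ScanResult:
    """Phenotype-phenotype dependencies: all pairs (MI) and triples (delta).

    The permutation null shuffles every phenotype column independently,
    breaking all inter-phenotype links; pair scores and triple scores are
    pooled separately.
    """
    cfg = null_cfg or NullConfig()
    names = [n for n in phenotypes.phenotype_names if phenotypes.kinds.get(n) == "coded"]
    if len(names) < 2:
        raise ValueError("need at least two coded phenotypes")
    mat = phenotypes.coded_matrix(names)
    keep = (mat != MISSING).all(axis=1)
    if not keep.any():
        raise ValueError("no complete-case subjects")
    mat = mat[keep]
    cols = {n: mat[:, i] for i, n in enumerate(names)}

    pair_obs, triple_obs = _phenotype_joint_scores(cols)
    pool_pair = _PooledNull(np.array([x[-1] for x in pair_obs]))
    pool_triple = (
        _PooledNull(np.abs([x[-1] for x in triple_obs])) if triple_obs else None
    )
    rng = np.random.default_rng(cfg.seed)
    n = mat.shape[0]
    for _ in range(cfg.n_shuffles):
        shuffled = {nm: c[rng.permutation(n)] for nm, c in cols.items()}
        pr, tr = _phenotype_joint_scores(shuffled)
        pool_pair.update([x[-1] for x in pr])
        if pool_triple is not None:
            pool_triple.update(np.abs([x[-1] for x in tr]))

    p_pair, floor_pair = pool_pair.pvalues()
    fw_pair = pool_pair.fwer()
    rows = [
        {
            "var1": a,
            "var2": b,
            "var3": "",
            "tuple_kind": "pair",
            "score": mi,
            "p_value": p_pair[i],
            "p_at_floor": floor_pair[i],
            "fwer": fw_pair[i],
        }
        for i, (a, b, mi) in enumerate(pair_obs)
    ]
    if pool_triple is not None:
        p_tri, floor_tri = pool_triple.pvalues()
        fw_tri = pool_triple.fwer()
        rows += [
            {
                "var1": a,
                "var2": b,
                "var3": c,
                "tuple_kind": "triple",
                "score": ds,
                "p_value": p_tri[i],
                "p_at_floor": floor_tri[i],
                "fwer": fw_tri[i],
            }
            for i, (a, b, c, ds) in enumerate(triple_obs)
        ]
    table = pd.DataFrame(rows)
    table["n_subjects"] = n
    return ScanResult(
        table=_rank_table(table),
        kind="phenotype",
        n_subjects=n,
        n_shuffles=cfg.n_shuffles,
        n_tuples=len(rows),
    )


def _threeway_scores(g_ind, b_cols, r_cols, score_key):
    parts = []
    for _, bc, bk in b_cols:
        b1h = _onehot(bc, bk)
        for _, rc, rk in r_cols:
            prof = delta_profile(g_ind, b1h, _onehot(rc, rk))
            parts.append(prof[score_key])
    return np.concatenate(parts)


def _threeway_scan_impl(
    g: GenotypeMatrix,
    bayley: PhenotypeTable,
    growth: PhenotypeTable,
    cfg: NullConfig,
    score_key: str,
    kind: str,
    cutoff: float,
) -> ScanResult:
    overlap = set(bayley.phenotype_names) & set(growth.phenotype_names)
    if overlap:
        raise ValueError(f"phenotype sets overlap: {sorted(overlap)}")
    g, (bay, gro) = _complete_case(g, bayley, growth)
    b_cols = [(nm,) + _compact(bay.coded(nm)) for nm in bay.phenotype_names]
    r_cols = [(nm,) + _compact(gro.coded(nm)) for nm in gro.phenotype_names]
    g_ind = _genotype_indicators(g.codes)
    m = g.n_snps

    observed = _threeway_scores(g_ind, b_cols, r_cols, score_key)
    pool = _PooledNull(np.abs(observed))
    rng = np.random.default_rng(cfg.seed)
    n = g.n_subjects
    for _ in range(cfg.n_shuffles):
        perm_b = rng.permutation(n)
        perm_r = rng.permutation(n)
        b_sh = [(nm, c[perm_b], k) for nm, c, k in b_cols]
        r_sh = [(nm, c[perm_r], k) for nm, c, k in r_cols]
        pool.update(np.abs(_threeway_scores(g_ind, b_sh, r_sh, score_key)))
    p, at_floor = pool.pvalues()
    fw = pool.fwer() if cfg.compute_fwer else np.full(len(observed), np.nan)

    bay_names = [nm for nm, _, _ in b_cols]
    gro_names = [nm for nm, _, _ in r_cols]
    pair_labels = [(b, r) for b in bay_names for r in gro_names]
    table = pd.DataFrame(
        {
            "bayley_phenotype": np.repeat([b for b, _ in pair_labels], m),
            "growth_phenotype": np.repeat([r for _, r in pair_labels], m),
            "rsid": np.tile(g.rsids, len(pair_labels)),
            "chrom": np.tile(g.snp_map["chrom"].to_numpy(), len(pair_labels)),
            "pos": np.tile(g.snp_map["pos"].to_numpy(), len(pair_labels)),
            "major": np.tile(g.snp_map["major"].to_numpy(), len(pair_labels)),
            "minor": np.tile(g.snp_map["minor"].to_numpy(), len(pair_labels)),
            "score": observed,
            "p_value": p,
            "p_at_floor": at_floor,
            "fwer": fw,
        }
    )
    table["flagged"] = table["p_value"] <= cutoff
    table["n_subjects"] = g.n_subjects
    return ScanResult(
        table=_rank_table(table),
        kind=kind,
        n_subjects=g.n_subjects,
        n_shuffles=cfg.n_shuffles,
        n_tuples=len(observed),
    )


def scan_threeway(
    g: GenotypeMatrix,
    bayley: PhenotypeTable,
    growth: PhenotypeTable,
    null_cfg: NullConfig | None = None,
    cutoff: float = THREEWAY_CUTOFF,
    pairwise: ScanResult | None = None,
    pairwise_cutoff: float = PAIRWISE_BAYLEY_CUTOFF,
) -> ScanResult:
    """Symmetric-delta scan over (SNP, bayley, growth) triples.

    The permutation null shuffles the two phenotype blocks with
    independent permutations.  If a pairwise ScanResult is supplied, each
    row gains a ``pairwise_significant`` column recording whether the SNP
    reached the pairwise cutoff in that scan.
    """
    res = _threeway_scan_impl(
        g, bayley, growth, null_cfg or NullConfig(), "delta_sym", "threeway", cutoff
    )
    if pairwise is not None:
        best = pairwise.table.groupby("rsid")["p_value"].min()
        res.table["pairwise_significant"] = (
            res.table["rsid"].map(best).fillna(1.0) <= pairwise_cutoff
        )
    return res


def scan_asymmetric(
    g: GenotypeMatrix,
    bayley: PhenotypeTable,
    growth: PhenotypeTable,
    target: str = "snp",
    null_cfg: NullConfig | None = None,
    cutoff: float = THREEWAY_CUTOFF,
) -> ScanResult:
    """Asymmetric-delta scan ranking triples by the chosen target's delta."""
    keys = {"growth": "delta_growth", "bayley": "delta_bayley", "snp": "delta_snp"}
    if target not in keys:
        raise ValueError(f"target must be one of {sorted(keys)}")
    return _threeway_scan_impl(
        g,
        bayley,
        growth,
        null_cfg or NullConfig(),
        keys[target],
        f"asymmetric_{target}",
        cutoff,
    )


def scan_snp_interaction(
    g: GenotypeMatrix,
    anchor_snps: list[str],
    phenotype: PhenotypeTable,
    null_cfg: NullConfig | None = None,
    cutoff: float = THREEWAY_CUTOFF,
) -> ScanResult:
    """Symmetric delta over (anchor SNP, partner SNP, phenotype) triples.

    Each anchor is paired with every other SNP in the matrix (anchors
    never pair with themselves); the null permutes the phenotype only,
    preserving all SNP-SNP linkage.
    """
    if len(phenotype.phenotype_names) != 1:
        raise ValueError("scan_snp_interaction takes a single-phenotype table")
    cfg = null_cfg or NullConfig()
    missing_anchors = [a for a in anchor_snps if a not in set(g.rsids)]
    if missing_anchors:
        raise KeyError(f"anchor SNPs not in matrix: {missing_anchors}")
    g, (ph,) = _complete_case(g, phenotype)
    still = set(g.rsids)
    anchors = [a for a in anchor_snps if a in still]
    (pname,) = ph.phenotype_names
    pcol, pk = _compact(ph.coded(pname))
    g_ind = _genotype_indicators(g.codes)
    anchor_set = set(anchors)
    partner_idx = np.array([j for j, r in enumerate(g.rsids) if r not in anchor_set])
    if len(partner_idx) == 0:
        raise ValueError("no partner SNPs available")
    g_part = g_ind[:, :, partner_idx]

    def all_scores(pcol_current):
        p1h = _onehot(pcol_current, pk)
        parts = []
        for a in anchors:
            acol, ak = _compact(g.column(a))
            parts.append(delta_profile(g_part, _onehot(acol, ak), p1h)["delta_sym"])
        return np.concatenate(parts)

    observed = all_scores(pcol)
    pool = _PooledNull(np.abs(observed))
    rng = np.random.default_rng(cfg.seed)
    n = g.n_subjects
    for _ in range(cfg.n_shuffles):
        pool.update(np.abs(all_scores(pcol[rng.permutation(n)])))
    p, at_floor = pool.pvalues()
    fw = pool.fwer() if cfg.compute_fwer else np.full(len(observed), np.nan)

    partner_rsids = [g.rsids[j] for j in partner_idx]
    table = pd.DataFrame(
        {
            "anchor": np.repeat(anchors, len(partner_idx)),
            "rsid": np.tile(partner_rsids, len(anchors)),
            "phenotype": pname,
            "score": observed,
            "p_value": p,
            "p_at_floor": at_floor,
            "fwer": fw,
        }
    )
    table["flagged"] = table["p_value"] <= cutoff
    table["n_subjects"] = g.n_subjects
    return ScanResult(
        table=_rank_table(table),
        kind="snp_interaction",
        n_subjects=g.n_subjects,
        n_shuffles=cfg.n_shuffles,
        n_tuples=len(observed),
    )


def scan_sex_stratified(
    g_xy: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    sex: np.ndarray,
    null_cfg: NullConfig | None = None,
    growth: PhenotypeTable | None = None,
    cutoff: float = PAIRWISE_BAYLEY_CUTOFF,
) -> ScanResult:
    """Pairwise (and optional three-way) scans run separately per sex.

    ``sex`` is aligned with the genotype matrix rows and coded 'M'/'F'.
    Male haploid codes ({0, 2}) and female diploid codes are never mixed
    within a stratum.  Output gains ``sex`` and ``n_subjects`` columns.
    """
    cfg = null_cfg or NullConfig()
    sex = np.asarray(sex)
    if len(sex) != g_xy.n_subjects:
        raise ValueError("sex labels must align with genotype rows")
    tables = []
    n_tuples = 0
    for label in ("M", "F"):
        idx = np.nonzero(sex == label)[0]
        if len(idx) == 0:
            raise ValueError(f"sex stratum {label!r} is empty")
        g_s = g_xy.take_subjects(idx)
        ph_s = PhenotypeTable(
            data=phenotypes.data.iloc[
                [phenotypes.subject_ids.index(s) for s in g_s.subject_ids]
            ].reset_index(drop=True),
            kinds=dict(phenotypes.kinds),
        )
        res = scan_pairwise(g_s, ph_s, cfg, cutoff=cutoff)
        t = res.table.copy()
        t["sex"] = label
        t["scan"] = "pairwise"
        tables.append(t)
        n_tuples += res.n_tuples
        if growth is not None:
            gr_s = PhenotypeTable(
                data=growth.data.iloc[
                    [growth.subject_ids.index(s) for s in g_s.subject_ids]
                ].reset_index(drop=True),
                kinds=dict(growth.kinds),
            )
            res3 = scan_threeway(g_s, ph_s, gr_s, cfg)
            t3 = res3.table.copy()
            t3["sex"] = label
            t3["scan"] = "threeway"
            tables.append(t3)
            n_tuples += res3.n_tuples
    table = pd.concat(tables, ignore_index=True).sort_values("p_value").reset_index(
        drop=True
    )
    return ScanResult(
        table=table,
        kind="sex_stratified",
        n_subjects=g_xy.n_subjects,
        n_shuffles=cfg.n_shuffles,
        n_tuples=n_tuples,
    )


def annotate_nearest_gene(table: pd.DataFrame, bed_path) -> pd.DataFrame:
    """Add a ``gene`` column from a BED file, nearest by midpoint distance.

    Rows whose chromosome has no gene in the BED stay blank.
    """
    bed = pd.read_csv(
        bed_path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str},
    )
    bed["mid"] = (bed["start"] + bed["end"]) / 2.0
    out = table.copy()
    genes = []
    by_chrom = {c: grp for c, grp in bed.groupby("chrom")}
    for _, row in out.iterrows():
        grp = by_chrom.get(str(row.get("chrom", "")))
        if grp is None or "pos" not in row:
            genes.append("")
            continue
        j = (grp["mid"] - float(row["pos"])).abs().idxmin()
        genes.append(str(grp.loc[j, "name"]))
    out["gene"] = genes
    return out
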