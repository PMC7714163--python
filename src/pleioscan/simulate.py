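"""Synthetic cohort generation.

Produces genotype matrices under Hardy-Weinberg equilibrium with
group-specific allele frequencies, correlated ordinal development-scale
phenotypes, Gompertz-style growth trajectories, and planted effects
(additive single-SNP shifts and XOR-style pleiotropy with null pairwise
marginals) so that every downstream stage of the pipeline can be tested
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .datatypes import MISSING, GenotypeMatrix, PhenotypeTable, SubjectTable
from .growth import GrowthObservations, GrowthPopulationParams, predict
from .info import JointDistribution

__all__ = [
    "CohortSpec",
    "PlantedEffect",
    "Cohort",
    "simulate_genotypes",
    "simulate_subjects",
    "simulate_bayley",
    "simulate_numeric_phenotypes",
    "simulate_growth_trajectories",
    "simulate_cohort",
    "plant_additive_effect",
    "plant_xor_pleiotropy",
    "plant_xor_across",
    "xor_joint",
]

_ALLELES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``ethnicity_af_delta`` is the allele-frequency offset applied (split
    evenly) between the two ethnicity groups for the confounded SNPs;
    ``confounded_fraction`` controls how many SNPs receive it.
    ``n_sex_snps`` columns are placed on the X chromosome with haploid
    ({0, 2}) coding for males.
    """

    n_subjects: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    ethnicity_fractions: tuple[float, float] = (0.6, 0.4)
    ethnicity_af_delta: float = 0.0
    confounded_fraction: float = 0.0
    missing_rate: float = 0.0
    # fraction of SNP columns carrying the missingness (1.0 = uniform);
    # within-column rate is scaled so the overall -2 fraction stays
    # missing_rate, letting complete-case scans retain the clean columns
    missing_snp_fraction: float = 1.0
    sex_fraction_male: float = 0.5
    n_sex_snps: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        fr = self.ethnicity_fractions
        if len(fr) != 2 or any(f < 0 or f > 1 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("ethnicity_fractions must be two proportions summing to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0.0 < self.missing_snp_fraction <= 1.0):
            raise ValueError("missing_snp_fraction must be in (0, 1]")
        if self.missing_rate / self.missing_snp_fraction >= 1.0 and self.missing_rate > 0:
            raise ValueError("missing_rate / missing_snp_fraction must be < 1")
        if not (0.0 <= self.sex_fraction_male <= 1.0):
            raise ValueError("sex_fraction_male must be in [0, 1]")
        if not (0.0 <= self.confounded_fraction <= 1.0):
            raise ValueError("confounded_fraction must be in [0, 1]")
        if not (0 <= self.n_sex_snps <= self.n_snps):
            raise ValueError("n_sex_snps must be in [0, n_snps]")


@dataclass(frozen=True)
class PlantedEffect:
    """A planted genotype-phenotype effect.

    kind "additive_pairwise" shifts one numeric phenotype by
    effect_size * minor-allele count; kind "xor_pleiotropic" rewires two
    phenotypes into a noisy XOR of the dichotomized SNP with penetrance
    effect_size; kind "null" does nothing.
    """

    kind: str
    snp_index: int
    phenotype_names: tuple[str, ...]
    effect_size: float

    def __post_init__(self) -> None:
        if self.kind not in {"additive_pairwise", "xor_pleiotropic", "null"}:
            raise ValueError(f"unknown planted-effect kind: {self.kind!r}")
        if self.kind == "additive_pairwise" and len(self.phenotype_names) != 1:
            raise ValueError("additive_pairwise names exactly 1 phenotype")
        if self.kind == "xor_pleiotropic" and len(self.phenotype_names) != 2:
            raise ValueError("xor_pleiotropic names exactly 2 phenotypes")
        if not (0.0 <= self.effect_size or self.kind == "additive_pairwise"):
            raise ValueError("effect_size must be non-negative")


def simulate_subjects(spec: CohortSpec, rng: np.random.Generator | None = None) -> SubjectTable:
    """Draw sex and ethnicity-group labels."""
    rng = rng or np.random.default_rng(spec.seed)
    n = spec.n_subjects
    sex = np.where(rng.random(n) < spec.sex_fraction_male, "M", "F")
    eth = np.where(rng.random(n) < spec.ethnicity_fractions[0], 1, 2)
    return SubjectTable(
        data=pd.DataFrame(
            {
                "subject_id": [f"S{i:05d}" for i in range(n)],
                "sex": sex,
                "ethnicity": eth,
            }
        )
    )


def simulate_genotypes(
    spec: CohortSpec, subjects: SubjectTable | None = None
) -> tuple[GenotypeMatrix, SubjectTable]:
    """HWE genotypes with optional group-specific allele frequencies.

    Autosomal SNPs are binomial(2, p) per subject.  The last
    ``n_sex_snps`` columns live on chromosome X: females are diploid,
    males haploid-coded {0, 2}.  Missing entries are set to -2 at
    ``missing_rate``.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = subjects or simulate_subjects(spec, rng)
    n, m = spec.n_subjects, spec.n_snps
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=m)

    confounded = np.zeros(m, dtype=bool)
    n_conf = int(round(spec.confounded_fraction * m))
    if n_conf > 0 and spec.ethnicity_af_delta > 0:
        confounded[rng.choice(m, size=n_conf, replace=False)] = True

    eth = subjects.ethnicity
    p = np.tile(maf, (n, 1))
    if confounded.any():
        half = spec.ethnicity_af_delta / 2.0
        p[:, confounded] += np.where(eth[:, None] == 1, -half, half)
        p = np.clip(p, 0.005, 0.995)

    codes = rng.binomial(2, p).astype(np.int8)

    is_male = subjects.sex == "M"
    sex_snp = np.zeros(m, dtype=bool)
    if spec.n_sex_snps > 0:
        sex_snp[m - spec.n_sex_snps :] = True
        # haploid male coding on X: one draw, reported as 0 or 2
        hap = (rng.random((n, spec.n_sex_snps)) < p[:, sex_snp]).astype(np.int8) * 2
        codes[np.ix_(is_male, sex_snp)] = hap[is_male]

    if spec.missing_rate > 0:
        rate = spec.missing_rate / spec.missing_snp_fraction
        n_cols = max(1, int(round(spec.missing_snp_fraction * m)))
        cols = rng.choice(m, size=n_cols, replace=False)
        mask = np.zeros((n, m), dtype=bool)
        mask[:, cols] = rng.random((n, n_cols)) < rate
        codes[mask] = MISSING

    chrom = rng.integers(1, 23, size=m).astype(str)
    chrom[sex_snp] = "X"
    pos = rng.integers(1, 250_000_000, size=m)
    alleles = np.array(
        [rng.choice(4, size=2, replace=False) for _ in range(m)]
    )
    snp_map = pd.DataFrame(
        {
            "rsid": [f"rs{1_000_000 + j}" for j in range(m)],
            "chrom": chrom,
            "pos": pos,
            "major": _ALLELES[alleles[:, 0]],
            "minor": _ALLELES[alleles[:, 1]],
            "maf": maf,
            "confounded": confounded,
        }
    )
    return GenotypeMatrix(codes=codes, snp_map=snp_map, subject_ids=subjects.subject_ids), subjects


def simulate_bayley(
    n_subjects: int,
    n_scales: int = 5,
    n_levels: int = 4,
    rho: float = 0.3,
    seed: int = 0,
    ethnicity: np.ndarray | None = None,
    ethnicity_shift: float = 0.0,
    missing_rate: float = 0.0,
) -> PhenotypeTable:
    """Correlated ordinal composite scales.

    A latent equicorrelated Gaussian (correlation ``rho``) is cut at
    equally-probable quantiles into ``n_levels`` ordered codes 1..n_levels.
    ``ethnicity_shift`` adds a latent mean offset to group-2 subjects
    (confounding mechanism).  rho=0 gives independent scales; rho=1
    identical ones.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal((n_subjects, 1))
    noise = rng.standard_normal((n_subjects, n_scales))
    latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
    if ethnicity is not None and ethnicity_shift != 0.0:
        latent = latent + ethnicity_shift * (np.asarray(ethnicity) == 2)[:, None]
    cuts = norm.ppf(np.linspace(0, 1, n_levels + 1)[1:-1])
    codes = (np.searchsorted(cuts, latent) + 1).astype(np.int64)
    if missing_rate > 0:
        codes[rng.random(codes.shape) < missing_rate] = MISSING
    names = [f"bayley_{s}" for s in ["cognitive", "language", "motor", "adaptive", "socioemotional"][:n_scales]]
    if n_scales > 5:
        names += [f"bayley_extra{k}" for k in range(n_scales - 5)]
    df = pd.DataFrame(codes, columns=names)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(n_subjects)])
    return PhenotypeTable(data=df, kinds={n: "coded" for n in names})


def simulate_numeric_phenotypes(
    n_subjects: int,
    names: list[str],
    seed: int = 0,
    ethnicity: np.ndarray | None = None,
    ethnicity_shift: float = 0.0,
) -> PhenotypeTable:
    """Independent standard-normal numeric phenotypes (pre-discretization)."""
    rng = np.random.default_rng(seed)
    values = rng.standard_normal((n_subjects, len(names)))
    if ethnicity is not None and ethnicity_shift != 0.0:
        values = values + ethnicity_shift * (np.asarray(ethnicity) == 2)[:, None]
    df = pd.DataFrame(values, columns=names)
    df.insert(0, "subject_id", [f"S{i:05d}" for i in range(n_subjects)])
    return PhenotypeTable(data=df, kinds={n: "numeric" for n in names})


def simulate_growth_trajectories(
    params: GrowthPopulationParams,
    n_subjects: int,
    obs_per_subject: tuple[int, int] = (2, 18),
    seed: int = 0,
    time_window: tuple[float, float] = (8.0, 290.0),
    fetal_cut: float = 40.0,
) -> tuple[GrowthObservations, pd.DataFrame]:
    """Longitudinal trajectories from the population model.

    Subject effects on (linf, alpha, lambda) are independent normals with
    the spec'd variances (diagonal covariance); residual noise is i.i.d.
    Measurement times follow a two-phase schedule mimicking antenatal
    scans plus childhood visits: about half of each subject's
    observations fall in the early window up to ``fetal_cut`` weeks, the
    rest later — the early phase is what identifies the alpha/lambda
    variance components.  Returns the observations and a table of true
    per-subject effects.
    """
    lo, hi = obs_per_subject
    if not (2 <= lo <= hi <= 18):
        raise ValueError("obs_per_subject must lie within [2, 18]")
    rng = np.random.default_rng(seed)
    sd = np.sqrt(params.variances)
    effects = rng.standard_normal((n_subjects, 3)) * sd
    resid_sd = np.sqrt(params.var_resid)
    rows = []
    truth = []
    for i in range(n_subjects):
        sid = f"S{i:05d}"
        k = int(rng.integers(lo, hi + 1))
        k_early = max(1, k // 2)
        t = np.sort(
            np.concatenate(
                [
                    rng.uniform(time_window[0], fetal_cut, size=k_early),
                    rng.uniform(fetal_cut, time_window[1], size=k - k_early),
                ]
            )
        )
        y = predict(t, params, tuple(effects[i])) + resid_sd * rng.standard_normal(k)
        for tj, yj in zip(t, y):
            rows.append({"subject_id": sid, "time_weeks": tj, "hc_cm": yj})
        truth.append(
            {
                "subject_id": sid,
                "linf": params.linf + effects[i, 0],
                "alpha": params.alpha + effects[i, 1],
                "lambda": params.lam + effects[i, 2],
            }
        )
    obs = GrowthObservations(data=pd.DataFrame(rows), time_window=time_window)
    return obs, pd.DataFrame(truth)


def plant_additive_effect(
    g: GenotypeMatrix, pheno: PhenotypeTable, effect: PlantedEffect
) -> PhenotypeTable:
    """Shift a numeric phenotype by effect_size * minor-allele count.

    Operates before discretization; missing genotypes contribute no
    shift.  effect_size=0 returns an identical copy.
    """
    if effect.kind not in {"additive_pairwise", "null"}:
        raise ValueError("plant_additive_effect requires an additive_pairwise effect")
    out = pheno.copy()
    if effect.kind == "null":
        return out
    (name,) = effect.phenotype_names
    if name not in out.data.columns:
        raise KeyError(f"unknown phenotype: {name}")
    if out.kinds.get(name) != "numeric":
        raise ValueError(f"phenotype {name!r} must be numeric to plant an additive effect")
    dose = g.codes[:, effect.snp_index].astype(float)
    dose[dose == MISSING] = 0.0
    out.data[name] = out.data[name].to_numpy(float) + effect.effect_size * dose
    return out


def _binarize_codes(col: np.ndarray, name: str) -> np.ndarray:
    """Split integer codes to {0,1} at the cut nearest a 50/50 balance.

    A balanced split keeps the XOR construction's pairwise marginals
    near-null; missing entries are preserved.
    """
    obs = col[col != MISSING]
    if len(obs) == 0 or np.all(obs == obs[0]):
        raise ValueError(f"phenotype {name!r} is not reducible to binary (constant)")
    values = np.unique(obs)
    candidates = values[:-1]  # split as col > v keeps both classes non-empty
    cdf = np.array([(obs <= v).mean() for v in candidates])
    thr = candidates[np.argmin(np.abs(cdf - 0.5))]
    out = np.where(col > thr, 1, 0).astype(np.int64)
    out[col == MISSING] = MISSING
    return out


def plant_xor_pleiotropy(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    effect: PlantedEffect,
    seed: int = 0,
) -> PhenotypeTable:
    """Rewire two phenotypes into a noisy XOR of the dichotomized SNP.

    The SNP is dichotomized as {0} vs {1, 2}.  The first named phenotype
    is binarized by median split and kept; the second is replaced by
    XOR(SNP', P1) with probability ``effect_size`` (else an independent
    fair coin).  At effect_size=1 the construction has zero mutual
    information between the SNP and each phenotype by design, while the
    three-way symmetric delta is strictly negative.
    """
    if effect.kind != "xor_pleiotropic":
        raise ValueError("plant_xor_pleiotropy requires an xor_pleiotropic effect")
    if not (0.0 <= effect.effect_size <= 1.0):
        raise ValueError("xor penetrance must be in [0, 1]")
    name1, name2 = effect.phenotype_names
    out = pheno.copy()
    for name in (name1, name2):
        if name not in out.data.columns:
            raise KeyError(f"unknown phenotype: {name}")
    rng = np.random.default_rng(seed)
    snp = g.codes[:, effect.snp_index]
    snp_bin = np.where(snp > 0, 1, 0)
    snp_missing = snp == MISSING

    if out.kinds.get(name1) == "numeric":
        raise ValueError(f"phenotype {name1!r} must be integer-coded before XOR planting")
    p1 = _binarize_codes(out.data[name1].to_numpy(np.int64), name1)

    n = len(p1)
    coin = rng.integers(0, 2, size=n)
    use_xor = rng.random(n) < effect.effect_size
    p2 = np.where(use_xor, np.bitwise_xor(snp_bin, np.maximum(p1, 0)), coin)
    # undefined inputs give an independent coin
    undef = snp_missing | (p1 == MISSING)
    p2 = np.where(undef, coin, p2).astype(np.int64)
    p2[p1 == MISSING] = coin[p1 == MISSING]

    out.data[name1] = p1
    out.data[name2] = p2
    out.kinds[name1] = "coded"
    out.kinds[name2] = "coded"
    return out


def plant_xor_across(
    g: GenotypeMatrix,
    table_a: PhenotypeTable,
    name_a: str,
    table_b: PhenotypeTable,
    name_b: str,
    snp_index: int,
    penetrance: float = 1.0,
    seed: int = 0,
) -> tuple[PhenotypeTable, PhenotypeTable]:
    """Plant an XOR pleiotropy spanning two phenotype tables.

    Convenience wrapper around :func:`plant_xor_pleiotropy` for the
    common case where one phenotype lives in the neurodevelopment table
    and the other in the growth table (the configuration the three-way
    scan searches for).
    """
    merged = PhenotypeTable(
        data=pd.DataFrame(
            {
                "subject_id": table_a.subject_ids,
                name_a: table_a.data[name_a].to_numpy(),
                name_b: table_b.data[name_b].to_numpy(),
            }
        ),
        kinds={name_a: table_a.kinds[name_a], name_b: table_b.kinds[name_b]},
    )
    effect = PlantedEffect("xor_pleiotropic", snp_index, (name_a, name_b), penetrance)
    planted = plant_xor_pleiotropy(g, merged, effect, seed=seed)
    out_a, out_b = table_a.copy(), table_b.copy()
    out_a.data[name_a] = planted.data[name_a]
    out_a.kinds[name_a] = "coded"
    out_b.data[name_b] = planted.data[name_b]
    out_b.kinds[name_b] = "coded"
    return out_a, out_b


def xor_joint(penetrance: float = 1.0) -> JointDistribution:
    """Exact 2x2x2 joint of (SNP', P1, P2) under the noisy-XOR planting.

    SNP' and P1 are independent fair bits; P2 = SNP' xor P1 with
    probability ``penetrance``, else an independent fair bit.  At
    penetrance 1 all pairwise mutual informations are exactly zero and
    the symmetric delta is -1 bit^3.
    """
    if not (0.0 <= penetrance <= 1.0):
        raise ValueError("penetrance must be in [0, 1]")
    p = np.zeros((2, 2, 2))
    for s in (0, 1):
        for a in (0, 1):
            for b in (0, 1):
                match = 1.0 if b == (s ^ a) else 0.0
                p[s, a, b] = 0.25 * (penetrance * match + (1 - penetrance) * 0.5)
    return JointDistribution.from_probs(p)


@dataclass
class Cohort:
    """Bundle of all synthetic tables for one cohort."""

    genotypes: GenotypeMatrix
    subjects: SubjectTable
    bayley: PhenotypeTable
    growth_numeric: PhenotypeTable
    growth_obs: GrowthObservations | None = None
    growth_truth: pd.DataFrame | None = None


def simulate_cohort(
    spec: CohortSpec,
    n_bayley: int = 5,
    n_levels: int = 4,
    bayley_rho: float = 0.3,
    growth_params: GrowthPopulationParams | None = None,
    with_trajectories: bool = False,
    ethnicity_phenotype_shift: float = 0.0,
) -> Cohort:
    """Full synthetic cohort: genotypes, subjects, phenotypes.

    Growth phenotypes are provided as numeric columns (linf, alpha,
    lambda) drawn from the population model's random-effect distribution;
    set ``with_trajectories`` to also generate longitudinal observations.
    """
    g, subjects = simulate_genotypes(spec)
    bayley = simulate_bayley(
        spec.n_subjects,
        n_scales=n_bayley,
        n_levels=n_levels,
        rho=bayley_rho,
        seed=spec.seed + 1,
        ethnicity=subjects.ethnicity,
        ethnicity_shift=ethnicity_phenotype_shift,
    )
    gp = growth_params or GrowthPopulationParams(
        linf=50.0, alpha=5.6, beta=0.105, theta=0.76, lam=0.0167,
        var_linf=1.3, var_alpha=0.165, var_lam=5.6e-4, var_resid=0.72,
    )
    rng = np.random.default_rng(spec.seed + 2)
    sd = np.sqrt(np.maximum(gp.variances, 1e-12))
    eff = rng.standard_normal((spec.n_subjects, 3)) * sd
    growth_numeric = PhenotypeTable(
        data=pd.DataFrame(
            {
                "subject_id": subjects.subject_ids,
                "linf": gp.linf + eff[:, 0],
                "alpha": gp.alpha + eff[:, 1],
                "lambda": gp.lam + eff[:, 2],
            }
        ),
        kinds={"linf": "numeric", "alpha": "numeric", "lambda": "numeric"},
    )
    obs = truth = None
    if with_trajectories:
        obs, truth = simulate_growth_trajectories(
            gp, spec.n_subjects, seed=spec.seed + 3
        )
    return Cohort(
        genotypes=g,
        subjects=subjects,
        bayley=bayley,
        growth_numeric=growth_numeric,
        growth_obs=obs,
        growth_truth=truth,
    )
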