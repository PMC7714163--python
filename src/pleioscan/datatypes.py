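"""Core tabular containers shared across the pipeline.

Genotypes are coded as minor-allele counts 0/1/2 with -2 for missing
(male X/Y genotypes use the haploid codes {0, 2}).  Phenotype tables are
either numeric (pre-discretization) or integer-coded; -2 marks missing in
both.  All containers round-trip through plain TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -2

SEX_CHROMS = frozenset({"X", "Y", "XY", "PAR1", "PAR2"})

SNP_MAP_COLUMNS = ["rsid", "chrom", "pos", "major", "minor"]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs genotype codes plus the SNP map.

    ``codes`` is an (n_subjects, n_snps) integer array; ``snp_map`` a
    DataFrame with columns rsid, chrom, pos, major, minor aligned with the
    code columns.
    """

    codes: np.ndarray
    snp_map: pd.DataFrame
    subject_ids: list[str]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("genotype codes must be a 2-D array")
        if self.codes.shape[1] != len(self.snp_map):
            raise ValueError("SNP map length does not match number of genotype columns")
        if self.codes.shape[0] != len(self.subject_ids):
            raise ValueError("subject_ids length does not match number of rows")
        missing_cols = [c for c in SNP_MAP_COLUMNS if c not in self.snp_map.columns]
        if missing_cols:
            raise ValueError(f"SNP map missing columns: {missing_cols}")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            codes = np.unique(self.codes[bad])
            raise ValueError(f"unknown genotype codes: {codes.tolist()}")

    @property
    def n_subjects(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def rsids(self) -> list[str]:
        return self.snp_map["rsid"].tolist()

    def is_sex_chromosome(self) -> np.ndarray:
        return self.snp_map["chrom"].astype(str).isin(SEX_CHROMS).to_numpy()

    def column(self, rsid: str) -> np.ndarray:
        idx = self.snp_map.index[self.snp_map["rsid"] == rsid]
        if len(idx) == 0:
            raise KeyError(f"unknown SNP: {rsid}")
        return self.codes[:, int(idx[0])]

    def take_snps(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[:, indices],
            snp_map=self.snp_map.iloc[indices].reset_index(drop=True),
            subject_ids=list(self.subject_ids),
        )

    def take_subjects(self, indices: np.ndarray | list[int]) -> "GenotypeMatrix":
        indices = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            codes=self.codes[indices, :],
            snp_map=self.snp_map.copy(),
            subject_ids=[self.subject_ids[i] for i in indices],
        )

    def to_tsv(self, genotype_path: str | Path, map_path: str | Path) -> None:
        df = pd.DataFrame(self.codes, columns=self.rsids)
        df.insert(0, "subject_id", self.subject_ids)
        df.to_csv(genotype_path, sep="\t", index=False)
        self.snp_map.to_csv(map_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, genotype_path: str | Path, map_path: str | Path) -> "GenotypeMatrix":
        df = pd.read_csv(genotype_path, sep="\t")
        snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
        subject_ids = df["subject_id"].astype(str).tolist()
        codes = df.drop(columns=["subject_id"]).to_numpy(dtype=np.int8)
        return cls(codes=codes, snp_map=snp_map, subject_ids=subject_ids)


@dataclass
class PhenotypeTable:
    """Per-subject phenotype values, numeric or integer-coded.

    ``kinds`` maps each column to "numeric" or "coded"; -2 (or NaN for
    numeric input) marks missing.
    """

    data: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "subject_id" not in self.data.columns:
            raise ValueError("phenotype table requires a subject_id column")
        for name in self.phenotype_names:
            self.kinds.setdefault(name, "coded" if self._looks_coded(name) else "numeric")

    def _looks_coded(self, name: str) -> bool:
        col = self.data[name]
        return pd.api.types.is_integer_dtype(col)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()

    @property
    def phenotype_names(self) -> list[str]:
        return [c for c in self.data.columns if c != "subject_id"]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    def values(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"unknown phenotype: {name}")
        return self.data[name].to_numpy()

    def coded(self, name: str) -> np.ndarray:
        """Integer codes for a coded column (missing -> -2)."""
        if self.kinds.get(name) != "coded":
            raise ValueError(f"phenotype {name!r} is not integer-coded")
        return self.data[name].to_numpy(dtype=np.int64)

    def coded_matrix(self, names: list[str] | None = None) -> np.ndarray:
        names = names or self.phenotype_names
        return np.column_stack([self.coded(n) for n in names])

    def copy(self) -> "PhenotypeTable":
        return PhenotypeTable(data=self.data.copy(), kinds=dict(self.kinds))

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeTable":
        return cls(data=pd.read_csv(path, sep="\t"))


@dataclass
class SubjectTable:
    """Subject metadata: sex (``M``/``F``) and ethnicity group (1/2)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject_id", "sex", "ethnicity"):
            if col not in self.data.columns:
                raise ValueError(f"subject table requires column {col!r}")

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].astype(str).tolist()

    @property
    def sex(self) -> np.ndarray:
        return self.data["sex"].to_numpy()

    @property
    def ethnicity(self) -> np.ndarray:
        return self.data["ethnicity"].to_numpy(dtype=int)

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubjectTable":
        return cls(data=pd.read_csv(path, sep="\t"))


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Export genotypes as an uncompressed VCF with GT fields.

    Codes count minor alleles, so 0 -> major/major.  Missing (-2) becomes
    ``./.``; haploid male sex-chromosome codes are written diploid-style
    (0 -> 0/0, 2 -> 1/1), which is lossless for re-import.
    """
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.subject_ids)
            + "\n"
        )
        for j, row in g.snp_map.iterrows():
            gts = "\t".join(gt_map[int(c)] for c in g.codes[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{row['rsid']}\t"
                f"{row['major']}\t{row['minor']}\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Import a VCF, coding genotypes by ALT (minor) allele count."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subject_ids = list(vcf.samples)
    codes_cols: list[np.ndarray] = []
    rows = []
    for variant in vcf:
        gt = np.asarray(variant.gt_types)  # 0=hom ref,1=het,2=unknown,3=hom alt
        col = np.full(len(subject_ids), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        codes_cols.append(col)
        rows.append(
            {
                "rsid": variant.ID or f"{variant.CHROM}_{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "major": variant.REF,
                "minor": variant.ALT[0] if variant.ALT else ".",
            }
        )
    return GenotypeMatrix(
        codes=np.column_stack(codes_cols) if codes_cols else np.empty((len(subject_ids), 0), dtype=np.int8),
        snp_map=pd.DataFrame(rows, columns=SNP_MAP_COLUMNS),
        subject_ids=subject_ids,
    )
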