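"""Sampling case-control datasets from a hierarchy model.

The workflow mirrors a population study: draw a finite population i.i.d.
from the locus distributions, compute each subject's liability through the
model chain, call subjects with liability >= threshold cases (threshold
chosen beforehand on the exact distribution), then sample the requested
numbers of cases and controls without replacement. The environmental factor
contributes to liability but is not exported — it is treated as unmeasured.
Noise SNPs unlinked to disease can be appended under Hardy-Weinberg
genotype frequencies with allele frequencies drawn from a user range.

Datasets are written in the MDR tab-delimited text format: one column per
variant, a final "Class" column (0 control / 1 case), one row per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import GENETIC_LOCI, HierarchyModel, LiabilityDistribution, liability_table

__all__ = [
    "Population",
    "CaseControlDataset",
    "simulate_population",
    "sample_case_control",
    "simulate_case_control",
    "add_noise_snps",
    "write_dataset",
    "read_dataset",
]


@dataclass
class Population:
    """A simulated population: genotypes at the six functional loci, the
    environment value, the liability and case status of every subject."""

    genotypes: np.ndarray  # (n, 6) values in {0,1,2}, columns = GENETIC_LOCI
    environment: np.ndarray  # (n,) values in {-2..2}
    liability: np.ndarray  # (n,) int
    status: np.ndarray  # (n,) 1 = case (liability >= threshold)
    threshold: int

    @property
    def n(self) -> int:
        return len(self.status)

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())


@dataclass
class CaseControlDataset:
    """Genotype matrix with binary disease status.

    ``variants`` names the columns (functional loci first, then any noise
    SNPs); genotype values are minor-allele counts 0/1/2; ``status`` is 0
    for controls and 1 for cases.
    """

    variants: list[str]
    genotypes: np.ndarray  # (n_subjects, n_variants) int
    status: np.ndarray  # (n_subjects,) in {0, 1}

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        self.status = np.asarray(self.status, dtype=np.int64)
        if self.genotypes.ndim != 2 or self.genotypes.shape[1] != len(self.variants):
            raise ValueError("genotype matrix shape does not match variant names")
        if len(self.status) != len(self.genotypes):
            raise ValueError("status and genotype row counts differ")
        if self.genotypes.size and not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype values must be in {0, 1, 2}")
        if self.status.size and not np.isin(self.status, (0, 1)).all():
            raise ValueError("status values must be in {0, 1}")

    @property
    def n(self) -> int:
        return len(self.status)

    def column(self, variant: str) -> np.ndarray:
        return self.genotypes[:, self.variants.index(variant)]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaseControlDataset):
            return NotImplemented
        return (
            self.variants == other.variants
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.status, other.status)
        )


def _sample_axis(rng: np.random.Generator, values, probs, n: int) -> np.ndarray:
    return rng.choice(np.asarray(values, dtype=np.int64), size=n, p=np.asarray(probs))


def simulate_population(
    model: HierarchyModel,
    n: int,
    threshold: int,
    seed: int | np.random.Generator,
) -> Population:
    """Draw ``n`` subjects i.i.d. from the model's locus distributions and
    assign case status by the (pre-selected) liability threshold."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    table = liability_table(model)
    idx_cols = []
    geno_cols = []
    for name in GENETIC_LOCI:
        dist = model.loci[name].dist
        col = _sample_axis(rng, dist.support, [p for _, p in dist.items()], n)
        geno_cols.append(col)
        idx_cols.append(col)  # genotype value == table index
    env_dist = model.loci["environment"].dist
    env = _sample_axis(rng, env_dist.support, [p for _, p in env_dist.items()], n)
    liability = table[
        idx_cols[0], idx_cols[1], idx_cols[2], idx_cols[3], idx_cols[4], idx_cols[5],
        env + 2,
    ]
    status = (liability >= threshold).astype(np.int64)
    return Population(
        genotypes=np.column_stack(geno_cols),
        environment=env,
        liability=liability,
        status=status,
        threshold=int(threshold),
    )


def sample_case_control(
    population: Population,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator,
) -> CaseControlDataset:
    """Sample cases and controls without replacement from a population.

    Only the six functional genotype columns are kept; the environment is
    dropped as if unmeasured.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_idx = np.flatnonzero(population.status == 1)
    ctrl_idx = np.flatnonzero(population.status == 0)
    if len(case_idx) < n_cases or len(ctrl_idx) < n_controls:
        raise ValueError(
            f"population has {len(case_idx)} cases and {len(ctrl_idx)} controls; "
            f"requested {n_cases} cases and {n_controls} controls"
        )
    chosen = np.concatenate(
        [
            rng.choice(case_idx, size=n_cases, replace=False),
            rng.choice(ctrl_idx, size=n_controls, replace=False),
        ]
    ).astype(np.int64)
    return CaseControlDataset(
        variants=list(GENETIC_LOCI),
        genotypes=population.genotypes[chosen],
        status=population.status[chosen],
    )


def simulate_case_control(
    model: HierarchyModel,
    prevalence: float,
    pop_size: int,
    n_cases: int,
    n_controls: int,
    seed: int | np.random.Generator,
    noise_snps: int = 0,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[CaseControlDataset, LiabilityDistribution]:
    """End-to-end convenience: exact liability + threshold, population,
    case-control sample and optional noise SNPs, from one seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    liab = LiabilityDistribution.from_model(model, prevalence)
    population = simulate_population(model, pop_size, liab.threshold, rng)
    dataset = sample_case_control(population, n_cases, n_controls, rng)
    if noise_snps:
        dataset = add_noise_snps(dataset, noise_snps, maf_range, rng)
    return dataset, liab


def add_noise_snps(
    dataset: CaseControlDataset,
    k: int,
    maf_range: tuple[float, float],
    seed: int | np.random.Generator,
) -> CaseControlDataset:
    """Append ``k`` SNP columns independent of disease status, each with a
    minor allele frequency drawn uniformly in ``maf_range`` and genotypes
    under Hardy-Weinberg equilibrium."""
    low, high = maf_range
    if not (0.0 < low <= high <= 0.5):
        raise ValueError(f"MAF range must satisfy 0 < low <= high <= 0.5, got {maf_range}")
    if k < 0:
        raise ValueError(f"number of noise SNPs must be >= 0, got {k}")
    if k == 0:
        return dataset
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mafs = rng.uniform(low, high, size=k)
    u = rng.random((dataset.n, k))
    p_hom = (1.0 - mafs) ** 2  # P(genotype 0)
    p_het = 2.0 * mafs * (1.0 - mafs)
    geno = (u >= p_hom).astype(np.int64) + (u >= p_hom + p_het).astype(np.int64)
    names = [f"N{i + 1}" for i in range(k)]
    return CaseControlDataset(
        variants=dataset.variants + names,
        genotypes=np.hstack([dataset.genotypes, geno]),
        status=dataset.status.copy(),
    )


def write_dataset(dataset: CaseControlDataset, path) -> None:
    """Write a dataset in MDR tab-delimited text format."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join([*dataset.variants, "Class"]) + "\n")
        for row, cls in zip(dataset.genotypes, dataset.status):
            fh.write("\t".join(str(int(v)) for v in row) + f"\t{int(cls)}\n")


def read_dataset(path) -> CaseControlDataset:
    """Read an MDR tab-delimited text dataset, validating genotype and
    class values; parse errors report 1-based line numbers."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        columns = header.split("\t")
        if columns[-1] != "Class":
            raise ValueError(f"{path}: line 1: last column must be 'Class'")
        variants = columns[:-1]
        genotypes: list[list[int]] = []
        status: list[int] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(columns):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(columns)} fields, "
                    f"got {len(fields)}"
                )
            try:
                values = [int(v) for v in fields]
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer value") from None
            if any(g not in (0, 1, 2) for g in values[:-1]):
                raise ValueError(f"{path}: line {lineno}: genotype not in {{0,1,2}}")
            if values[-1] not in (0, 1):
                raise ValueError(f"{path}: line {lineno}: Class not in {{0,1}}")
            genotypes.append(values[:-1])
            status.append(values[-1])
    return CaseControlDataset(
        variants=variants,
        genotypes=np.array(genotypes, dtype=np.int64).reshape(len(status), len(variants)),
        status=np.array(status, dtype=np.int64),
    )
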