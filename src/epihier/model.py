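"""The biology-structured liability model.

Six genetic variants — two transcription factors (TF1, TF2), an enhancer, a
promoter, a coding variant and a microRNA variant — plus an environmental
factor are combined in a fixed chain of six integer functions:

    r1 = f1(TF1, enhancer)
    r2 = f2(r1, TF2)
    r3 = f3(r2, promoter)
    r4 = f4(r3, coding)
    r5 = f5(r4, microRNA)
    liability = f6(r5, environment)

Genotypes are coded 0/1/2 (default Hardy-Weinberg 0.25/0.5/0.25); the
environment is coded -2..2 (default uniform). Because the inputs are
independent finite discrete variables, the liability distribution is exact
and computable either by folding pushforward distributions along the chain
or by enumerating all 3^6 * 5 = 3,645 input combinations. Disease is the
upper tail: a subject is a case when liability >= threshold, with the
threshold chosen on the exact distribution to achieve a target prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import DiscreteDistribution, hwe_distribution
from .functions import (
    FUNCTIONS,
    apply_function,
    function_output_distribution,
    normalize_function_name,
)

__all__ = [
    "GENETIC_LOCI",
    "LOCUS_NAMES",
    "GENOTYPE_VALUES",
    "ENVIRONMENT_VALUES",
    "Locus",
    "HierarchyModel",
    "LiabilityDistribution",
    "evaluate",
    "liability_distribution",
    "liability_table",
    "select_threshold",
    "default_loci",
]

GENETIC_LOCI = ("TF1", "TF2", "enhancer", "promoter", "coding", "microRNA")
LOCUS_NAMES = GENETIC_LOCI + ("environment",)
GENOTYPE_VALUES = (0, 1, 2)
ENVIRONMENT_VALUES = (-2, -1, 0, 1, 2)

# chain wiring: which locus feeds each of the six function slots
_SLOT_LOCUS = ("enhancer", "TF2", "promoter", "coding", "microRNA", "environment")


def _default_environment() -> DiscreteDistribution:
    return DiscreteDistribution({v: 0.2 for v in ENVIRONMENT_VALUES})


@dataclass(frozen=True)
class Locus:
    """A discrete random input: a genetic variant (support {0,1,2}) or the
    environmental factor (support {-2,...,2}) with its distribution."""

    name: str
    dist: DiscreteDistribution

    def __post_init__(self):
        if self.name not in LOCUS_NAMES:
            raise ValueError(f"unknown locus name {self.name!r}")
        expected = ENVIRONMENT_VALUES if self.name == "environment" else GENOTYPE_VALUES
        if set(self.dist.support) - set(expected):
            raise ValueError(
                f"locus {self.name!r} support {self.dist.support} not within {expected}"
            )

    @property
    def values(self) -> tuple[int, ...]:
        return ENVIRONMENT_VALUES if self.name == "environment" else GENOTYPE_VALUES


def default_loci() -> dict[str, Locus]:
    loci = {name: Locus(name, hwe_distribution(0.5)) for name in GENETIC_LOCI}
    loci["environment"] = Locus("environment", _default_environment())
    return loci


@dataclass(frozen=True)
class HierarchyModel:
    """A choice of six combination functions over the fixed scaffold.

    ``functions`` are the canonical names for slots f1..f6; 25^6 distinct
    models exist. Locus distributions default to HWE 0.25/0.5/0.25 genotypes
    and a uniform environment but may be overridden per locus.
    """

    functions: tuple[str, ...]
    loci: dict[str, Locus] = field(default_factory=default_loci)

    def __post_init__(self):
        if len(self.functions) != 6:
            raise ValueError(f"expected 6 function slots, got {len(self.functions)}")
        object.__setattr__(
            self, "functions", tuple(normalize_function_name(f) for f in self.functions)
        )
        missing = set(LOCUS_NAMES) - set(self.loci)
        if missing:
            raise ValueError(f"missing loci: {sorted(missing)}")

    def evaluate(self, genotypes, environment: int) -> int:
        return evaluate(self, genotypes, environment)

    def liability_distribution(self, method: str = "fold") -> DiscreteDistribution:
        return liability_distribution(self, method=method)


def evaluate(model: HierarchyModel, genotypes, environment: int) -> int:
    """Liability of one subject: fold the genotype and environment values
    through the model's function chain."""
    genotypes = tuple(int(g) for g in genotypes)
    if len(genotypes) != 6:
        raise ValueError(f"expected 6 genotypes, got {len(genotypes)}")
    values = dict(zip(GENETIC_LOCI, genotypes))
    values["environment"] = int(environment)
    for name in GENETIC_LOCI:
        if values[name] not in GENOTYPE_VALUES:
            raise ValueError(f"locus {name!r}: genotype {values[name]} not in {{0,1,2}}")
    if values["environment"] not in ENVIRONMENT_VALUES:
        raise ValueError(
            f"locus 'environment': value {values['environment']} not in {{-2..2}}"
        )
    result = values["TF1"]
    for fname, locus in zip(model.functions, _SLOT_LOCUS):
        result = apply_function(fname, result, values[locus])
    return result


def liability_distribution(
    model: HierarchyModel, method: str = "fold"
) -> DiscreteDistribution:
    """Exact distribution of the model's liability output.

    ``method="fold"`` pushes distributions through the chain one function at
    a time; ``method="enumerate"`` sums product probabilities over all 3,645
    input combinations. Both are exact and agree to rounding error.
    """
    if method == "fold":
        dist = model.loci["TF1"].dist
        for fname, locus in zip(model.functions, _SLOT_LOCUS):
            dist = function_output_distribution(fname, dist, model.loci[locus].dist)
        return dist
    if method == "enumerate":
        table = liability_table(model)
        axes = [model.loci[name].dist for name in LOCUS_NAMES]
        prob = np.ones((1,) * 7)
        for axis, dist in enumerate(axes):
            # the table axis always spans the full coding range, even if the
            # locus distribution puts zero mass on some values
            vals = np.array([dist[v] for v in _axis_values(model, axis)])
            shape = [1] * 7
            shape[axis] = len(vals)
            prob = prob * vals.reshape(shape)
        out: dict[int, float] = {}
        flat_v = table.ravel()
        flat_p = prob.ravel()
        uniq, inv = np.unique(flat_v, return_inverse=True)
        sums = np.bincount(inv, weights=flat_p)
        for v, p in zip(uniq.tolist(), sums.tolist()):
            if p > 0:
                out[int(v)] = p
        return DiscreteDistribution(out)
    raise ValueError(f"unknown method {method!r}")


def _axis_values(model: HierarchyModel, axis: int):
    name = LOCUS_NAMES[axis]
    return ENVIRONMENT_VALUES if name == "environment" else GENOTYPE_VALUES


def _fold_values(fname: str, arr: np.ndarray, support) -> np.ndarray:
    """Apply ``fname`` to every (value in arr, value in support) pair,
    computing only on the unique values of ``arr``."""
    fn = FUNCTIONS[fname]
    uniq, inv = np.unique(arr, return_inverse=True)
    table = np.array(
        [[fn(int(u), int(s)) for s in support] for u in uniq], dtype=np.int64
    )
    return table[inv].reshape(arr.shape + (len(support),))


def liability_table(model: HierarchyModel) -> np.ndarray:
    """Liability for every input combination.

    Returns an int64 array of shape (3,3,3,3,3,3,5) indexed by the genotype
    of TF1, TF2, enhancer, promoter, coding, microRNA (values 0/1/2) and the
    environment index (value -2..2 at index 0..4).
    """
    arr = np.array(GENOTYPE_VALUES, dtype=np.int64)  # TF1 axis
    arr = _fold_values(model.functions[0], arr, GENOTYPE_VALUES)  # enhancer
    arr = _fold_values(model.functions[1], arr, GENOTYPE_VALUES)  # TF2
    arr = _fold_values(model.functions[2], arr, GENOTYPE_VALUES)  # promoter
    arr = _fold_values(model.functions[3], arr, GENOTYPE_VALUES)  # coding
    arr = _fold_values(model.functions[4], arr, GENOTYPE_VALUES)  # microRNA
    arr = _fold_values(model.functions[5], arr, ENVIRONMENT_VALUES)  # environment
    # arr axes: TF1, enhancer, TF2, promoter, coding, microRNA, env
    # reorder to TF1, TF2, enhancer, promoter, coding, microRNA, env
    return np.ascontiguousarray(arr.transpose(0, 2, 1, 3, 4, 5, 6))


@dataclass(frozen=True)
class LiabilityDistribution:
    """Exact liability distribution with its disease threshold.

    Disease is the upper tail: prevalence = P(liability >= threshold).
    ``achieved_prevalence`` is the closest value to the requested prevalence
    attainable on the discrete support.
    """

    dist: DiscreteDistribution
    threshold: int
    achieved_prevalence: float

    @classmethod
    def from_model(
        cls, model: HierarchyModel, target_prevalence: float, mode: str = "quantile"
    ) -> "LiabilityDistribution":
        dist = liability_distribution(model)
        threshold, achieved = select_threshold(dist, target_prevalence, mode=mode)
        return cls(dist=dist, threshold=threshold, achieved_prevalence=achieved)


def select_threshold(
    dist: DiscreteDistribution, target_prevalence: float, mode: str = "quantile"
) -> tuple[int, float]:
    """Choose the disease threshold t on the exact liability distribution.

    ``mode="quantile"`` (default): the largest support value t with
    P(X >= t) >= target, i.e. the discrete upper quantile — the achieved
    prevalence is the smallest attainable value not below the target. This
    is the convention under which the reference two-function models
    reproduce their published interaction-information and MDR accuracies.

    ``mode="closest"``: the support value whose tail probability is closest
    to the target, ties broken toward the smaller achieved prevalence.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError(f"target prevalence must be in (0, 1), got {target_prevalence}")
    support = dist.support
    if len(support) < 2:
        raise ValueError("no threshold achieves a two-class split")
    # suffix sums from the top avoid cancellation error in the tails
    tails = []
    tail = 0.0
    for v in reversed(support):
        tail += dist[v]
        tails.append((v, tail))  # tail = P(X >= v)
    tails.reverse()
    if mode == "quantile":
        threshold, achieved = max(
            ((v, t) for v, t in tails if t >= target_prevalence - 1e-12),
            key=lambda vt: vt[0],
        )
    elif mode == "closest":
        _, achieved, threshold = min(
            (abs(t - target_prevalence), t, v) for v, t in tails
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return int(threshold), float(achieved)
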