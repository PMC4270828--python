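"""Small deterministic datasets and reference model configurations.

All fixtures are generated programmatically (synthetic); they exercise the
two ends of the genetic-architecture spectrum:

* a noiseless parity dataset whose class is (A + B + C) mod 2 — the exact
  pure-epistasis limit: zero main-effect and pairwise information, 1 bit of
  three-way interaction information, MDR training accuracy 1;
* eight reference two-function model configurations spanning additive /
  multiplicative main-effect models and parity-type interaction models;
* a null dataset whose status is independent of every genotype.
"""

from __future__ import annotations

import numpy as np

from .model import HierarchyModel
from .simulate import CaseControlDataset

__all__ = [
    "REFERENCE_MODEL_FUNCTIONS",
    "reference_model",
    "parity_dataset",
    "null_dataset",
    "make_fixtures",
]

# the varied (f1, f2) pairs of the eight reference configurations;
# the remaining four slots are additive
REFERENCE_MODEL_FUNCTIONS: dict[int, tuple[str, str]] = {
    1: ("ADD", "ADD"),
    2: ("ADD", "MULT"),
    3: ("MULT", "MULT"),
    4: ("XOR", "XOR"),
    5: ("MOD2", "XOR"),
    6: ("BITX", "XOR"),
    7: ("BITX", "MOD2"),
    8: ("CHS", "BITA"),
}


def reference_model(number: int) -> HierarchyModel:
    """Reference model ``number`` (1-8): (f1, f2) from the table above,
    f3..f6 = ADD, default locus distributions."""
    f1, f2 = REFERENCE_MODEL_FUNCTIONS[number]
    return HierarchyModel(functions=(f1, f2, "ADD", "ADD", "ADD", "ADD"))


def parity_dataset() -> CaseControlDataset:
    """Noiseless three-locus parity data: class = (A + B + C) mod 2.

    Each of the 27 genotype combinations is replicated with Hardy-Weinberg
    multiplicities (1, 2, 1 per locus; 64 rows total) so that every locus's
    genotype-parity split is exactly balanced: main-effect and pairwise
    interaction information are exactly zero while the triple determines the
    class completely (three-way IG = 1 bit).
    """
    weight = {0: 1, 1: 2, 2: 1}
    rows = []
    status = []
    for a in (0, 1, 2):
        for b in (0, 1, 2):
            for c in (0, 1, 2):
                for _ in range(weight[a] * weight[b] * weight[c]):
                    rows.append((a, b, c))
                    status.append((a + b + c) % 2)
    return CaseControlDataset(
        variants=["A", "B", "C"],
        genotypes=np.array(rows, dtype=np.int64),
        status=np.array(status, dtype=np.int64),
    )


def null_dataset(
    n_cases: int = 500, n_controls: int = 500, n_variants: int = 3, seed: int = 0
) -> CaseControlDataset:
    """Status independent of every genotype by construction: genotypes are
    drawn HWE (0.25/0.5/0.25) regardless of the label."""
    rng = np.random.default_rng(seed)
    n = n_cases + n_controls
    geno = rng.choice([0, 1, 2], size=(n, n_variants), p=[0.25, 0.5, 0.25])
    status = np.array([1] * n_cases + [0] * n_controls, dtype=np.int64)
    return CaseControlDataset(
        variants=[f"V{i + 1}" for i in range(n_variants)],
        genotypes=geno,
        status=status,
    )


def make_fixtures(seed: int = 0) -> dict:
    """Bundle of the toy inputs used across tests and examples."""
    return {
        "parity": parity_dataset(),
        "null": null_dataset(seed=seed),
        "models": {k: reference_model(k) for k in REFERENCE_MODEL_FUNCTIONS},
    }
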