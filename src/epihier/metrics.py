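"""Entropy-based interaction metrics, the MDR classifier and permutation tests.

Mutual information and interaction information are plug-in estimates (in
bits) from the empirical contingency tables of a case-control dataset. The
pure three-way interaction information of variants A, B, C with status Y is

    IG(A;B;C;Y) = I(A,B,C;Y) - I(A,B;Y) - I(A,C;Y) - I(B,C;Y)
                  + I(A;Y) + I(B;Y) + I(C;Y)

i.e. the information the triple carries jointly about status after
subtracting all one-way and two-way effects. It can be negative
(redundancy); for a pure parity pattern it is 1 bit.

Multifactor dimensionality reduction (MDR) pools each multi-locus genotype
cell into high-risk or low-risk by comparing the cell's case:control ratio
to the overall ratio, then classifies every subject by its cell label.
Two permutation tests are provided: the standard test shuffles case-control
labels; the explicit test of epistasis shuffles each variant's genotypes
within cases and within controls separately, preserving the marginal
genotype-status associations while destroying inter-variant interactions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import CaseControlDataset

__all__ = [
    "InteractionResult",
    "MDRModel",
    "entropy",
    "mutual_information",
    "pairwise_ig",
    "threeway_ig",
    "mdr_fit",
    "permutation_test_standard",
    "permutation_test_epistasis",
]


def entropy(counts) -> float:
    """Shannon entropy in bits of a count vector or mapping; 0*log(0) = 0."""
    if isinstance(counts, dict):
        counts = list(counts.values())
    arr = np.asarray(counts, dtype=float).ravel()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    p = arr[arr > 0] / total
    return float(-(p * np.log2(p)).sum())


def _encode(columns: list[np.ndarray]) -> np.ndarray:
    """Encode the joint value of several integer columns as one code column."""
    code = np.zeros(len(columns[0]), dtype=np.int64)
    for col in columns:
        u, inv = np.unique(col, return_inverse=True)
        code = code * len(u) + inv
    return code


def _mi_bits(code_x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information I(X;Y) in bits from paired samples."""
    joint = _encode([code_x, y])
    return (
        entropy(np.bincount(code_x))
        + entropy(np.bincount(y))
        - entropy(np.bincount(joint))
    )


def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) between two discrete columns."""
    x = np.asarray(x)
    y = np.asarray(y)
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    return _mi_bits(xi, yi)


@dataclass(frozen=True)
class InteractionResult:
    """One-way, two-way and pure three-way interaction information (bits)
    of a variant triple with case-control status."""

    variants: tuple[str, str, str]
    main_ig: dict[str, float]
    pairwise_ig: dict[tuple[str, str], float]
    threeway_ig: float
    degenerate: tuple[str, ...] = ()


def pairwise_ig(dataset: CaseControlDataset, a: str, b: str) -> float:
    """Pairwise interaction information IG(A;B;Y) = I(A,B;Y) - I(A;Y) - I(B;Y)."""
    y = dataset.status
    ca, cb = dataset.column(a), dataset.column(b)
    return _mi_bits(_encode([ca, cb]), y) - _mi_bits(_encode([ca]), y) - _mi_bits(
        _encode([cb]), y
    )


def threeway_ig(dataset: CaseControlDataset, a: str, b: str, c: str) -> InteractionResult:
    """Pure three-way interaction information of (a, b, c) with status,
    together with the main-effect and pairwise terms it subtracts."""
    names = (a, b, c)
    if len(set(names)) != 3:
        raise ValueError(f"variants must be distinct, got {names}")
    y = dataset.status
    cols = {n: dataset.column(n) for n in names}
    degenerate = tuple(n for n in names if len(np.unique(cols[n])) < 2)
    main = {n: _mi_bits(_encode([cols[n]]), y) for n in names}
    pair_names = [(a, b), (a, c), (b, c)]
    pairs = {
        (u, v): _mi_bits(_encode([cols[u], cols[v]]), y) - main[u] - main[v]
        for u, v in pair_names
    }
    # IG = I(ABC;Y) - sum I(pair;Y) + sum I(single;Y); pairs already have
    # the singles subtracted, so subtract each single once more overall
    i_abc = _mi_bits(_encode([cols[a], cols[b], cols[c]]), y)
    three = i_abc - sum(pairs.values()) - sum(main.values())
    return InteractionResult(
        variants=names,
        main_ig=main,
        pairwise_ig=pairs,
        threeway_ig=float(three),
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class MDRModel:
    """A fitted MDR labeling of the k-locus genotype cells.

    ``cell_labels`` maps each observed genotype combination to 1 (high-risk)
    or 0 (low-risk); ``accuracy`` is the training classification accuracy of
    predicting case for high-risk cells.
    """

    loci: tuple[str, ...]
    cell_labels: dict[tuple[int, ...], int]
    threshold_ratio: float
    accuracy: float

    def predict(self, genotypes: np.ndarray) -> np.ndarray:
        """Predicted status for a (n, k) genotype matrix; unseen cells are
        low-risk."""
        genotypes = np.asarray(genotypes, dtype=np.int64)
        return np.array(
            [self.cell_labels.get(tuple(row), 0) for row in genotypes], dtype=np.int64
        )


def _cell_counts(codes: np.ndarray, status: np.ndarray, n_cells: int):
    case = np.bincount(codes[status == 1], minlength=n_cells)
    ctrl = np.bincount(codes[status == 0], minlength=n_cells)
    return case, ctrl


def _mdr_labels(case: np.ndarray, ctrl: np.ndarray, n_case: int, n_ctrl: int):
    """High-risk iff cell case:control ratio >= overall ratio (ties high);
    empty cells low-risk. Cross-multiplied to avoid division."""
    occupied = (case + ctrl) > 0
    high = occupied & (case * n_ctrl >= ctrl * n_case)
    return high


def _mdr_accuracy(codes, status, n_cells, n_case, n_ctrl) -> float:
    case, ctrl = _cell_counts(codes, status, n_cells)
    high = _mdr_labels(case, ctrl, n_case, n_ctrl)
    correct = case[high].sum() + ctrl[~high].sum()
    return correct / (n_case + n_ctrl)


def mdr_fit(dataset: CaseControlDataset, loci) -> MDRModel:
    """Fit a k-locus MDR model and report training accuracy."""
    loci = tuple(loci)
    if len(loci) < 1:
        raise ValueError("MDR requires at least one locus")
    cols = [dataset.column(n) for n in loci]
    grid = np.array(np.meshgrid(*[np.unique(c) for c in cols], indexing="ij"))
    combos = grid.reshape(len(loci), -1).T
    # per-subject cell code on the observed value grid
    sizes = [len(np.unique(c)) for c in cols]
    code = np.zeros(dataset.n, dtype=np.int64)
    for col, size in zip(cols, sizes):
        _, inv = np.unique(col, return_inverse=True)
        code = code * size + inv
    n_cells = int(np.prod(sizes))
    n_case = int((dataset.status == 1).sum())
    n_ctrl = int((dataset.status == 0).sum())
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("MDR requires both cases and controls")
    case, ctrl = _cell_counts(code, dataset.status, n_cells)
    high = _mdr_labels(case, ctrl, n_case, n_ctrl)
    labels = {tuple(int(v) for v in combos[i]): int(high[i]) for i in range(n_cells)}
    accuracy = (case[high].sum() + ctrl[~high].sum()) / dataset.n
    return MDRModel(
        loci=loci,
        cell_labels=labels,
        threshold_ratio=n_case / n_ctrl,
        accuracy=float(accuracy),
    )


def _locus_codes(dataset: CaseControlDataset, loci) -> tuple[np.ndarray, list, int]:
    cols = [dataset.column(n) for n in loci]
    invs = []
    sizes = []
    for col in cols:
        u, inv = np.unique(col, return_inverse=True)
        invs.append(inv.astype(np.int64))
        sizes.append(len(u))
    return invs, sizes, int(np.prod(sizes))


def _combine_codes(invs, sizes) -> np.ndarray:
    code = np.zeros(len(invs[0]), dtype=np.int64)
    for inv, size in zip(invs, sizes):
        code = code * size + inv
    return code


def permutation_test_standard(
    dataset: CaseControlDataset, loci, n_perm: int, seed
) -> float:
    """Permutation p-value for MDR accuracy under label shuffling.

    p = (1 + #{permuted accuracy >= observed}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = tuple(loci)
    invs, sizes, n_cells = _locus_codes(dataset, loci)
    code = _combine_codes(invs, sizes)
    status = dataset.status
    n_case = int((status == 1).sum())
    n_ctrl = int((status == 0).sum())
    observed = _mdr_accuracy(code, status, n_cells, n_case, n_ctrl)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(status)
        if _mdr_accuracy(code, perm, n_cells, n_case, n_ctrl) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def permutation_test_epistasis(
    dataset: CaseControlDataset, loci, n_perm: int, seed
) -> float:
    """Explicit test of epistasis: each variant's genotype column is
    shuffled independently within cases and within controls, preserving all
    marginal genotype-status associations while destroying interactions.
    The statistic is MDR accuracy; p-value as in the standard test."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    loci = tuple(loci)
    invs, sizes, n_cells = _locus_codes(dataset, loci)
    code = _combine_codes(invs, sizes)
    status = dataset.status
    n_case = int((status == 1).sum())
    n_ctrl = int((status == 0).sum())
    observed = _mdr_accuracy(code, status, n_cells, n_case, n_ctrl)
    case_idx = np.flatnonzero(status == 1)
    ctrl_idx = np.flatnonzero(status == 0)
    hits = 0
    for _ in range(n_perm):
        shuffled = []
        for inv in invs:
            col = inv.copy()
            col[case_idx] = col[case_idx][rng.permutation(len(case_idx))]
            col[ctrl_idx] = col[ctrl_idx][rng.permutation(len(ctrl_idx))]
            shuffled.append(col)
        perm_code = _combine_codes(shuffled, sizes)
        if _mdr_accuracy(perm_code, status, n_cells, n_case, n_ctrl) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)
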