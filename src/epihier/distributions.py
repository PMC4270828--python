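"""Finite discrete distributions over integers.

These are the exact probability objects the whole simulator is built on:
each locus carries one, and the liability of a model is the pushforward of
the locus distributions through the model's function chain. Supports stay
small (at most a few thousand values), so a plain dict representation is
both exact and fast.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

__all__ = ["DiscreteDistribution", "hwe_distribution"]

_PROB_TOL = 1e-12


class DiscreteDistribution:
    """An exact finite probability distribution on integers.

    Parameters
    ----------
    probs
        Mapping from integer support values to probabilities. Probabilities
        must be non-negative and sum to 1 within ``1e-12``; zero-probability
        entries are dropped.
    """

    __slots__ = ("_probs",)

    def __init__(self, probs: Mapping[int, float]):
        cleaned: dict[int, float] = {}
        total = 0.0
        for value, p in probs.items():
            value = int(value)
            p = float(p)
            if p < 0:
                raise ValueError(f"negative probability {p!r} for value {value}")
            if p > 0.0:
                cleaned[value] = cleaned.get(value, 0.0) + p
                total += p
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        self._probs = dict(sorted(cleaned.items()))

    @property
    def support(self) -> tuple[int, ...]:
        """Support values in increasing order."""
        return tuple(self._probs)

    def items(self) -> Iterable[tuple[int, float]]:
        return self._probs.items()

    def __getitem__(self, value: int) -> float:
        return self._probs.get(int(value), 0.0)

    def __len__(self) -> int:
        return len(self._probs)

    def __iter__(self):
        return iter(self._probs)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscreteDistribution):
            return NotImplemented
        return self.allclose(other, tol=0.0)

    def __hash__(self):
        return hash(tuple(self._probs.items()))

    def __repr__(self) -> str:
        body = ", ".join(f"{v}: {p:.6g}" for v, p in self._probs.items())
        return f"DiscreteDistribution({{{body}}})"

    def allclose(self, other: "DiscreteDistribution", tol: float = _PROB_TOL) -> bool:
        """True if both distributions agree on every value within ``tol``."""
        values = set(self._probs) | set(other._probs)
        return all(abs(self[v] - other[v]) <= tol for v in values)

    def tail_probability(self, threshold: int) -> float:
        """P(X >= threshold)."""
        return sum(p for v, p in self._probs.items() if v >= threshold)

    def mean(self) -> float:
        return sum(v * p for v, p in self._probs.items())


def hwe_distribution(maf: float = 0.5) -> DiscreteDistribution:
    """Genotype distribution (minor-allele count 0/1/2) under Hardy-Weinberg
    equilibrium at minor allele frequency ``maf``.

    Equal allele frequencies (maf=0.5) give the 0.25/0.5/0.25 genotype
    probabilities used for every functional locus by default.
    """
    if not 0.0 < maf <= 0.5:
        raise ValueError(f"minor allele frequency must be in (0, 0.5], got {maf}")
    q = maf
    p = 1.0 - q
    return DiscreteDistribution({0: p * p, 1: 2 * p * q, 2: q * q})
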