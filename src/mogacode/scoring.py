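"""Error-minimisation scoring of genetic codes.

A code's robustness to point mutation / mistranslation is measured as the
mean squared difference of an amino-acid property over all single-nucleotide
substitutions between sense codons:

    Ms(C)  = sum_{<i,j>} (X(i,C) - X(j,C))^2 / (number of pairs)
    Mst(C) = sum_{<i,j>} w(i,j) (X(i,C) - X(j,C))^2 / sum_{<i,j>} w(i,j)

where the sum runs over the 263 unordered sense-codon pairs one base apart,
X(i,C) is the property of the amino acid code C assigns to codon i, and the
mistranslation weight w depends on the substituted base position and on
whether the change is a transition or a transversion.  Lower is better: a
robust code places similar amino acids on neighbouring codons.

Three property scales are built in — polar requirement, the Kyte-Doolittle
hydropathy index, and Grantham molecular volume — and arbitrary scales can
be supplied as CSV.

Evaluation is done at block level: substitution pairs are aggregated once
into a 20x20 matrix of block-pair weights, after which scoring any
permutation code is an O(20^2) bilinear form.  The block evaluator is exact
(it equals direct enumeration over the 263 codon pairs) and vectorises over
millions of codes at once.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .codespace import (
    AMINO_ACIDS,
    BlockStructure,
    GeneticCode,
    canonical_blocks,
    substitution_pairs,
)

__all__ = [
    "PropertyTable",
    "WeightScheme",
    "ObjectiveSpec",
    "BlockPairWeights",
    "block_pair_weights",
    "ms",
    "mst",
    "evaluate",
    "evaluate_many",
    "parse_objectives",
]

# Built-in amino-acid property scales.
_POLAR_REQUIREMENT = {
    "Ala": 7.0, "Arg": 9.1, "Asn": 10.0, "Asp": 13.0, "Cys": 4.8,
    "Gln": 8.6, "Glu": 12.5, "Gly": 7.9, "His": 8.4, "Ile": 4.9,
    "Leu": 4.9, "Lys": 10.1, "Met": 5.3, "Phe": 5.0, "Pro": 6.6,
    "Ser": 7.5, "Thr": 6.6, "Trp": 5.2, "Tyr": 5.4, "Val": 5.6,
}
_HYDROPATHY = {
    "Ala": 1.8, "Arg": -4.5, "Asn": -3.5, "Asp": -3.5, "Cys": 2.5,
    "Gln": -3.5, "Glu": -3.5, "Gly": -0.4, "His": -3.2, "Ile": 4.5,
    "Leu": 3.8, "Lys": -3.9, "Met": 1.9, "Phe": 2.8, "Pro": -1.6,
    "Ser": -0.8, "Thr": -0.7, "Trp": -0.9, "Tyr": -1.3, "Val": 4.2,
}
_MOLECULAR_VOLUME = {
    "Ala": 31.0, "Arg": 124.0, "Asn": 56.0, "Asp": 54.0, "Cys": 55.0,
    "Gln": 85.0, "Glu": 83.0, "Gly": 3.0, "His": 96.0, "Ile": 111.0,
    "Leu": 111.0, "Lys": 119.0, "Met": 105.0, "Phe": 132.0, "Pro": 32.5,
    "Ser": 32.0, "Thr": 61.0, "Trp": 170.0, "Tyr": 136.0, "Val": 84.0,
}

_BUILTINS = {
    "polar_requirement": _POLAR_REQUIREMENT,
    "hydropathy": _HYDROPATHY,
    "molecular_volume": _MOLECULAR_VOLUME,
}

_SHORT_NAMES = {"pr": "polar_requirement", "hi": "hydropathy", "mv": "molecular_volume"}


@dataclass(frozen=True)
class PropertyTable:
    """A scalar property value for each of the 20 standard amino acids."""

    name: str
    values: tuple[float, ...] = field(repr=False)  # aligned to AMINO_ACIDS

    def __post_init__(self) -> None:
        if len(self.values) != 20:
            raise ValueError("a property table needs exactly 20 values")

    def __getitem__(self, amino_acid: str) -> float:
        return self.values[AMINO_ACIDS.index(amino_acid)]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @classmethod
    def from_dict(cls, name: str, mapping: dict[str, float]) -> "PropertyTable":
        missing = set(AMINO_ACIDS) - set(mapping)
        extra = set(mapping) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"property table must cover the 20 standard amino acids "
                f"(missing {sorted(missing)}, unknown {sorted(extra)})"
            )
        return cls(name, tuple(float(mapping[aa]) for aa in AMINO_ACIDS))

    @classmethod
    def builtin(cls, name: str) -> "PropertyTable":
        """One of ``polar_requirement``, ``hydropathy``, ``molecular_volume``
        (short forms ``pr``, ``hi``, ``mv`` accepted)."""
        key = _SHORT_NAMES.get(name.lower(), name.lower())
        if key not in _BUILTINS:
            raise KeyError(f"no built-in property scale {name!r}")
        return cls.from_dict(key, _BUILTINS[key])

    @classmethod
    def from_csv(cls, text: str, name: str = "custom") -> "PropertyTable":
        """Read a two-column CSV ``amino_acid,value``."""
        frame = pd.read_csv(io.StringIO(text))
        cols = [c.strip().lower() for c in frame.columns]
        if cols[:2] != ["amino_acid", "value"]:
            raise ValueError("property CSV needs columns amino_acid,value")
        frame.columns = cols
        return cls.from_dict(
            name, dict(zip(frame["amino_acid"].str.strip(), frame["value"]))
        )

    def to_csv(self) -> str:
        lines = ["amino_acid,value"]
        lines += [f"{aa},{v:g}" for aa, v in zip(AMINO_ACIDS, self.values)]
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class WeightScheme:
    """Mistranslation weights by base position (1-3) and substitution kind.

    The default scheme encodes the empirical translation-error pattern:
    second-base errors are rare (and mostly transitions), first-base errors
    are mostly transitions, third-base errors are frequent with little
    transition bias.
    """

    transitions: tuple[float, float, float] = (1.0, 0.5, 1.0)
    transversions: tuple[float, float, float] = (0.5, 0.1, 1.0)

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.transitions + self.transversions):
            raise ValueError("mistranslation weights must be nonnegative")

    def weight(self, position: int, kind: str) -> float:
        row = self.transitions if kind == "transition" else self.transversions
        return row[position - 1]

    @classmethod
    def mistranslation(cls) -> "WeightScheme":
        return cls()

    @classmethod
    def uniform(cls) -> "WeightScheme":
        return cls((1.0, 1.0, 1.0), (1.0, 1.0, 1.0))


@dataclass(frozen=True)
class ObjectiveSpec:
    """One objective: a measure (``ms`` or ``mst``) over a property scale."""

    property_table: PropertyTable
    measure: Literal["ms", "mst"] = "ms"
    weights: WeightScheme = WeightScheme.mistranslation()

    def __post_init__(self) -> None:
        if self.measure not in ("ms", "mst"):
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def label(self) -> str:
        return f"{self.measure}:{self.property_table.name}"


@dataclass(frozen=True)
class BlockPairWeights:
    """Substitution weight totals aggregated by block pair.

    ``matrix`` is symmetric 20x20: entry (a, b), a != b, is the total
    substitution weight linking blocks a and b (a plain neighbour count in
    the unweighted case).  ``normalizer`` is the total weight over all 263
    pairs, including intra-block pairs, which contribute weight to the
    denominator but zero to the numerator (their property difference
    vanishes).
    """

    matrix: np.ndarray
    normalizer: float

    def score(self, indices: np.ndarray, prop: np.ndarray) -> np.ndarray:
        """Mean squared property error for codes given as index rows.

        ``indices`` has shape (n, 20) (or (20,) for one code): row r maps
        block b to amino-acid index ``indices[r, b]``.  Uses the bilinear
        identity sum_{a<b} M_ab (x_a - x_b)^2 = x'diag(M1)x - x'Mx for
        symmetric M with zero diagonal.
        """
        x = prop[np.atleast_2d(indices)]
        row_sums = self.matrix.sum(axis=1)
        quad = (x**2) @ row_sums - np.einsum("na,ab,nb->n", x, self.matrix, x)
        return quad / self.normalizer


@lru_cache(maxsize=8)
def _cached_block_pair_weights(
    blocks: BlockStructure, weights: WeightScheme | None
) -> BlockPairWeights:
    matrix = np.zeros((20, 20))
    normalizer = 0.0
    for pair in substitution_pairs(blocks):
        w = 1.0 if weights is None else weights.weight(pair.position, pair.kind)
        normalizer += w
        if pair.block_i != pair.block_j:
            matrix[pair.block_i, pair.block_j] += w
            matrix[pair.block_j, pair.block_i] += w
    matrix.setflags(write=False)
    return BlockPairWeights(matrix, normalizer)


def block_pair_weights(
    blocks: BlockStructure | None = None, weights: WeightScheme | None = None
) -> BlockPairWeights:
    """Aggregate substitution pairs into block-pair weight totals.

    ``weights=None`` gives the unweighted (Ms) aggregation whose normalizer
    is the plain pair count (263 for the canonical structure).
    """
    return _cached_block_pair_weights(blocks or canonical_blocks(), weights)


def _spec_weights(spec: ObjectiveSpec) -> BlockPairWeights:
    return block_pair_weights(None, spec.weights if spec.measure == "mst" else None)


def ms(code: GeneticCode, property_table: PropertyTable) -> float:
    """Unweighted mean squared property error of ``code`` (Ms)."""
    bpw = block_pair_weights()
    return float(bpw.score(code.as_indices(), property_table.as_array())[0])


def mst(
    code: GeneticCode,
    property_table: PropertyTable,
    weights: WeightScheme | None = None,
) -> float:
    """Mistranslation-weighted mean squared property error (Mst)."""
    bpw = block_pair_weights(None, weights or WeightScheme.mistranslation())
    return float(bpw.score(code.as_indices(), property_table.as_array())[0])


def evaluate(code: GeneticCode, specs: Sequence[ObjectiveSpec]) -> np.ndarray:
    """Objective vector of ``code`` under ``specs`` (order preserved)."""
    return evaluate_many(code.as_indices(), specs)[0]


def evaluate_many(indices: np.ndarray, specs: Sequence[ObjectiveSpec]) -> np.ndarray:
    """Objective matrix, shape (n_codes, n_specs), for index-array codes."""
    if len(specs) == 0:
        raise ValueError("at least one objective spec is required")
    indices = np.atleast_2d(indices)
    out = np.empty((indices.shape[0], len(specs)))
    for k, spec in enumerate(specs):
        out[:, k] = _spec_weights(spec).score(
            indices, spec.property_table.as_array()
        )
    return out


def parse_objectives(text: str) -> tuple[ObjectiveSpec, ...]:
    """Parse an objective list such as ``"ms:pr,ms:hi"`` or ``"mst:mv"``."""
    specs = []
    for token in text.split(","):
        token = token.strip().lower()
        if not token:
            continue
        try:
            measure, prop = token.split(":")
        except ValueError:
            raise ValueError(f"bad objective {token!r}; expected measure:property")
        specs.append(ObjectiveSpec(PropertyTable.builtin(prop), measure))
    if not specs:
        raise ValueError("no objectives given")
    return tuple(specs)
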