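"""Codons, the canonical code, and the restrictive code space.

The restrictive encoding keeps the canonical code's synonymous-codon blocks
and its three stop codons fixed, and represents a hypothetical genetic code
as a permutation of the 20 standard amino acids over the 20 blocks.  The
search space is therefore the 20! possible block-to-amino-acid assignments
rather than the full set of 61-codon maps.

Codons are RNA triplets over {U, C, A, G}; DNA input (T) is normalised to U
on read.  All block indexing is by the lexicographically smallest codon of
each block, and every serialised output carries explicit labels so the
internal ordering is never load-bearing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from functools import lru_cache
from itertools import product
from typing import Iterator, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "AMINO_ACIDS",
    "BASES",
    "STOP_CODONS",
    "Codon",
    "BlockStructure",
    "GeneticCode",
    "SubstitutionPair",
    "normalize_codon",
    "all_codons",
    "canonical_blocks",
    "canonical_code",
    "substitution_pairs",
    "random_code",
    "parse_code_table",
]

BASES = "UCAG"

#: The 20 standard amino acids (three-letter codes), alphabetical.
AMINO_ACIDS: tuple[str, ...] = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

_ONE_TO_THREE = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})

#: Purine/pyrimidine pairs whose interchange is a transition.
_TRANSITIONS = frozenset({frozenset("AG"), frozenset("CU")})

Codon = str  # a validated RNA triplet; see :func:`normalize_codon`


def normalize_codon(text: str) -> Codon:
    """Validate a codon string, mapping DNA T to RNA U and upper-casing.

    Raises ``ValueError`` for anything that is not a triplet over UCAG/T.
    """
    codon = text.strip().upper().replace("T", "U")
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a codon: {text!r}")
    return codon


def all_codons() -> list[Codon]:
    """The 64 codons in lexicographic (U < C < A < G) order."""
    return ["".join(p) for p in product(BASES, repeat=3)]


@dataclass(frozen=True)
class BlockStructure:
    """The partition of the 61 sense codons into synonymous-codon blocks.

    ``blocks`` holds 20 disjoint, nonempty codon groups ordered by their
    lexicographically smallest codon; ``stop_codons`` holds the three fixed
    stop triplets.  Together they cover all 64 codons.
    """

    blocks: tuple[frozenset[Codon], ...]
    stop_codons: frozenset[Codon]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty codon block")
            if seen & block:
                raise ValueError("codon blocks are not disjoint")
            seen |= block
        if seen & self.stop_codons:
            raise ValueError("a stop codon appears inside a sense block")
        if len(seen) + len(self.stop_codons) != 64:
            raise ValueError("blocks plus stops must cover all 64 codons")

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def block_of(self, codon: Codon) -> int:
        """Index of the block containing ``codon`` (stops raise KeyError)."""
        return self._codon_to_block()[codon]

    @lru_cache(maxsize=None)
    def _codon_to_block(self) -> dict[Codon, int]:
        return {c: k for k, block in enumerate(self.blocks) for c in block}


@dataclass(frozen=True)
class GeneticCode:
    """A restrictive-encoding genetic code.

    ``assignment[k]`` is the amino acid carried by block ``k`` of the
    canonical block structure; the assignment is always a permutation of
    the 20 standard amino acids.
    """

    assignment: tuple[str, ...]

    def __post_init__(self) -> None:
        if sorted(self.assignment) != sorted(AMINO_ACIDS):
            raise ValueError(
                "assignment must be a permutation of the 20 standard amino acids"
            )

    def translate(self, codon: Codon) -> str:
        """Amino acid encoded by ``codon``, or ``'Stop'`` for a stop codon."""
        codon = normalize_codon(codon)
        if codon in STOP_CODONS:
            return "Stop"
        return self.assignment[canonical_blocks().block_of(codon)]

    def as_indices(self) -> np.ndarray:
        """Assignment as amino-acid indices into :data:`AMINO_ACIDS`."""
        return np.array([_AA_INDEX[aa] for aa in self.assignment], dtype=np.int64)

    @classmethod
    def from_indices(cls, indices: Sequence[int]) -> "GeneticCode":
        return cls(tuple(AMINO_ACIDS[int(i)] for i in indices))

    def swap(self, i: int, j: int) -> "GeneticCode":
        """A copy with the amino acids of blocks ``i`` and ``j`` exchanged."""
        a = list(self.assignment)
        a[i], a[j] = a[j], a[i]
        return GeneticCode(tuple(a))


@dataclass(frozen=True)
class SubstitutionPair:
    """An unordered pair of sense codons one nucleotide apart.

    ``position`` is the differing base position (1-3); ``kind`` is
    ``"transition"`` for A<->G or C<->U changes and ``"transversion"``
    otherwise; ``block_i``/``block_j`` are the codons' block indices.
    """

    codon_i: Codon
    codon_j: Codon
    position: int
    kind: str
    block_i: int
    block_j: int


@lru_cache(maxsize=1)
def canonical_blocks() -> BlockStructure:
    """Block structure of the canonical genetic code.

    The 20 synonymous-codon groups (one per amino acid) and the three stop
    codons of the standard code, with blocks ordered by smallest codon.
    """
    table = CodonTable.unambiguous_rna_by_id[1]
    by_aa: dict[str, set[str]] = {}
    for codon, aa1 in table.forward_table.items():
        by_aa.setdefault(_ONE_TO_THREE[aa1], set()).add(codon)
    order = {c: i for i, c in enumerate(all_codons())}
    blocks = sorted(
        (frozenset(codons) for codons in by_aa.values()),
        key=lambda b: min(order[c] for c in b),
    )
    structure = BlockStructure(tuple(blocks), frozenset(table.stop_codons))
    assert structure.stop_codons == STOP_CODONS
    return structure


@lru_cache(maxsize=1)
def canonical_code() -> GeneticCode:
    """The canonical assignment: each block keeps its standard amino acid."""
    table = CodonTable.unambiguous_rna_by_id[1]
    blocks = canonical_blocks()
    assignment = tuple(
        _ONE_TO_THREE[table.forward_table[min(block)]] for block in blocks.blocks
    )
    return GeneticCode(assignment)


@lru_cache(maxsize=4)
def substitution_pairs(blocks: BlockStructure | None = None) -> tuple[SubstitutionPair, ...]:
    """Every unordered single-nucleotide substitution between sense codons.

    Pairs involving a stop codon are excluded; 263 pairs remain for the
    canonical structure.  Order is lexicographic by (codon_i, codon_j)
    with codon_i < codon_j in UCAG order.
    """
    if blocks is None:
        blocks = canonical_blocks()
    order = {c: i for i, c in enumerate(all_codons())}
    sense = sorted(
        (c for block in blocks.blocks for c in block), key=order.__getitem__
    )
    pairs: list[SubstitutionPair] = []
    for idx, a in enumerate(sense):
        for b in sense[idx + 1:]:
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            kind = (
                "transition"
                if frozenset((a[k], b[k])) in _TRANSITIONS
                else "transversion"
            )
            pairs.append(
                SubstitutionPair(a, b, k + 1, kind, blocks.block_of(a), blocks.block_of(b))
            )
    return tuple(pairs)


def random_code(rng: np.random.Generator) -> GeneticCode:
    """A uniformly random permutation of the amino acids over the blocks."""
    return GeneticCode.from_indices(rng.permutation(20))


def random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` uniform random codes as an ``(n, 20)`` index array.

    Row ``r`` holds the amino-acid index assigned to each block by the
    ``r``-th sampled code; the vectorised counterpart of
    :func:`random_code` for mass sampling.
    """
    tiled = np.tile(np.arange(20, dtype=np.int64), (n, 1))
    return rng.permuted(tiled, axis=1)


def parse_code_table(text: str) -> GeneticCode:
    """Read a 64-row codon table (TSV: ``codon<TAB>amino_acid``).

    Requires a header, exactly one row per codon, stops on exactly
    {UAA, UAG, UGA}, block-constant assignments (every codon of a
    canonical block maps to the same amino acid — the restrictive
    encoding), and a permutation over the 20 amino acids.
    """
    mapping: dict[Codon, str] = {}
    lines = [ln for ln in io.StringIO(text) if ln.strip()]
    if not lines:
        raise ValueError("empty code table")
    header = [f.strip().lower() for f in lines[0].split("\t")]
    if header[:2] != ["codon", "amino_acid"]:
        raise ValueError("code table must start with a 'codon<TAB>amino_acid' header")
    for ln in lines[1:]:
        fields = [f.strip() for f in ln.split("\t")]
        if len(fields) < 2:
            raise ValueError(f"malformed code-table row: {ln!r}")
        codon = normalize_codon(fields[0])
        if codon in mapping:
            raise ValueError(f"duplicate codon {codon}")
        mapping[codon] = fields[1]
    if len(mapping) != 64:
        raise ValueError(f"expected 64 codons, got {len(mapping)}")
    stops = {c for c, aa in mapping.items() if aa == "Stop"}
    if stops != set(STOP_CODONS):
        raise ValueError(
            "stop codons must be exactly UAA, UAG, UGA (restrictive encoding)"
        )
    blocks = canonical_blocks()
    assignment: list[str] = []
    for k, block in enumerate(blocks.blocks):
        aas = {mapping[c] for c in block}
        if len(aas) != 1:
            raise ValueError(
                f"block {min(block)} maps to several amino acids {sorted(aas)}: "
                "the restrictive encoding requires block-constant assignment"
            )
        (aa,) = aas
        if aa not in _AA_INDEX:
            raise ValueError(f"unknown amino acid {aa!r}")
        assignment.append(aa)
    return GeneticCode(tuple(assignment))


def iter_code_rows(code: GeneticCode) -> Iterator[tuple[Codon, str]]:
    """(codon, amino acid) rows for all 64 codons in lexicographic order."""
    for codon in all_codons():
        yield codon, code.translate(codon)
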