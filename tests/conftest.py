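import numpy as np
import pytest

from mogacode import (
    GeneticCode,
    ObjectiveSpec,
    PropertyTable,
    WeightScheme,
    canonical_code,
)
from mogacode.codespace import STOP_CODONS, all_codons


@pytest.fixture(scope="session")
def properties():
    return {
        "pr": PropertyTable.builtin("pr"),
        "hi": PropertyTable.builtin("hi"),
        "mv": PropertyTable.builtin("mv"),
    }


@pytest.fixture(scope="session")
def all_specs(properties):
    """The six (measure, property) combinations used throughout."""
    return tuple(
        ObjectiveSpec(properties[p], meas)
        for meas in ("ms", "mst")
        for p in ("pr", "hi", "mv")
    )


def brute_force_score(
    code: GeneticCode,
    table: PropertyTable,
    weights: WeightScheme | None = None,
) -> float:
    """Independent codon-level oracle for Ms/Mst.

    Enumerates all 64x64 codon pairs directly, keeps unordered sense-sense
    pairs differing at exactly one base, and computes the (weighted) mean
    squared property difference.  Shares nothing with the package's pair
    enumeration or block-level evaluator.
    """
    codons = all_codons()
    transitions = ({"A", "G"}, {"C", "U"})
    num = den = 0.0
    for a_idx, a in enumerate(codons):
        for b in codons[a_idx + 1:]:
            if a in STOP_CODONS or b in STOP_CODONS:
                continue
            diff = [k for k in range(3) if a[k] != b[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            if weights is None:
                w = 1.0
            else:
                kind = (
                    "transition" if {a[k], b[k]} in transitions else "transversion"
                )
                w = weights.weight(k + 1, kind)
            xa = table[code.translate(a)]
            xb = table[code.translate(b)]
            num += w * (xa - xb) ** 2
            den += w
    return num / den


@pytest.fixture(scope="session")
def canonical():
    return canonical_code()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
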