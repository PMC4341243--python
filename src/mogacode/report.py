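"""Serialisation of codes, fronts and summaries, and comparison tables.

All outputs are plain text (TSV/CSV/JSON) readable by the package's own
parsers; figure rendering is left to downstream tools.
"""

from __future__ import annotations

import json
from typing import Sequence

import pandas as pd

from .codespace import (
    AMINO_ACIDS,
    GeneticCode,
    canonical_blocks,
    canonical_code,
    iter_code_rows,
)
from .moga import GAConfig, Individual, ParetoFront
from .scoring import ObjectiveSpec, PropertyTable, parse_objectives

__all__ = [
    "write_code_table",
    "block_labels",
    "front_to_frame",
    "write_front",
    "read_front",
    "grayscale_table",
]


def write_code_table(code: GeneticCode) -> str:
    """64-row TSV (``codon<TAB>amino_acid``) for a code; round-trips through
    :func:`mogacode.codespace.parse_code_table`."""
    lines = ["codon\tamino_acid"]
    lines += [f"{codon}\t{aa}" for codon, aa in iter_code_rows(code)]
    return "\n".join(lines) + "\n"


def block_labels() -> list[str]:
    """One label per canonical block: its lexicographically smallest codon."""
    order = {c: i for i, c in enumerate(
        sorted({c for b in canonical_blocks().blocks for c in b}))}
    return [min(block, key=order.__getitem__) for block in canonical_blocks().blocks]


def front_to_frame(front: ParetoFront) -> pd.DataFrame:
    """Front as a table: block-wise assignment, objectives, provenance."""
    labels = block_labels()
    rows = []
    for member in front.members:
        row: dict[str, object] = {
            f"block_{lab}": aa for lab, aa in zip(labels, member.code.assignment)
        }
        for spec, value in zip(front.specs, member.objectives):
            row[spec.label] = value
        row["rank"] = member.rank
        row["run_id"] = member.run_id
        row["generation"] = member.generation
        rows.append(row)
    return pd.DataFrame(rows)


def write_front(front: ParetoFront, config: GAConfig | None = None) -> tuple[str, str]:
    """Serialise a front to (TSV table, JSON summary)."""
    tsv = front_to_frame(front).to_csv(sep="\t", index=False)
    summary = {
        "objectives": [s.label for s in front.specs],
        "front_size": len(front),
    }
    if config is not None:
        summary["config"] = {
            "population_size": config.population_size,
            "generations": config.generations,
            "swap_probability": config.swap_probability,
            "tournament_fraction": config.tournament_fraction,
            "runs": config.runs,
            "seed": config.seed,
            "run_seeds": [config.run_seed(r) for r in range(config.runs)],
        }
    return tsv, json.dumps(summary, indent=2) + "\n"


def read_front(tsv: str, specs: Sequence[ObjectiveSpec] | None = None) -> ParetoFront:
    """Read a front TSV written by :func:`write_front`.

    ``specs`` defaults to re-deriving the objective columns by label.
    """
    import io

    frame = pd.read_csv(io.StringIO(tsv), sep="\t")
    labels = block_labels()
    if specs is None:
        obj_cols = [c for c in frame.columns
                    if c.split(":")[0] in ("ms", "mst") and ":" in c]
        specs = parse_objectives(",".join(obj_cols))
    members = []
    for _, row in frame.iterrows():
        code = GeneticCode(tuple(row[f"block_{lab}"] for lab in labels))
        objectives = tuple(float(row[s.label]) for s in specs)
        members.append(
            Individual(
                code=code,
                objectives=objectives,
                rank=int(row["rank"]) if pd.notna(row.get("rank")) else None,
                run_id=int(row["run_id"]) if pd.notna(row.get("run_id")) else None,
                generation=int(row["generation"])
                if pd.notna(row.get("generation"))
                else None,
            )
        )
    return ParetoFront(tuple(members), tuple(specs))


def grayscale_table(
    codes: Sequence[GeneticCode], property_table: PropertyTable
) -> pd.DataFrame:
    """Code-comparison table with amino acids sorted by a property.

    One row per amino acid, ascending property value (ties broken
    alphabetically).  Columns: the canonical amino acid order, its property
    value, the canonical codon group, then for each supplied code the codon
    group that code assigns to the row's amino acid.  Shading by property
    value is a downstream presentation concern.
    """
    if not codes:
        raise ValueError("at least one code is required")
    labels = block_labels()
    group_of_aa_canon = {
        aa: lab for lab, aa in zip(labels, canonical_code().assignment)
    }
    order = sorted(AMINO_ACIDS, key=lambda aa: (property_table[aa], aa))
    table: dict[str, list] = {
        "amino_acid": list(order),
        "property": [property_table[aa] for aa in order],
        "canonical_group": [group_of_aa_canon[aa] for aa in order],
    }
    for idx, code in enumerate(codes, start=1):
        group_of_aa = {aa: lab for lab, aa in zip(labels, code.assignment)}
        table[f"HC{idx}"] = [group_of_aa[aa] for aa in order]
    return pd.DataFrame(table)
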