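"""Random-code statistics and comparison metrics.

The statistical approach asks how special the canonical code is among the
20! restrictive codes: a large sample of uniform random amino-acid
permutations is evaluated under each objective and the canonical value is
located within the resulting empirical distribution (mean, histogram, and
the count of random codes strictly better than canonical).

Codes found by the optimiser are compared with the canonical code via

* Pareto dominance of each front member over the canonical objective vector;
* the percentage of minimisation distance

      pmd_i = 100 * | (fbar_i - f_i(canonical)) / (fbar_i - f_i(C)) |

  where fbar_i is the mean evaluation of objective i over random codes —
  pmd = 100 means the code matches the canonical value exactly, and larger
  departures of C below the random mean push pmd below 100;
* a Euclidean distance between normalised objective vectors.

For the restrictive space the random-code mean is also available in closed
form (see :func:`mean_random_code`): under a uniform permutation every
ordered pair of distinct blocks carries an exchangeable pair of distinct
amino acids, so the expected squared difference is the same for every
inter-block pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .codespace import canonical_code, random_codes
from .moga import ParetoFront, dominates
from .scoring import ObjectiveSpec, evaluate, evaluate_many, _spec_weights

__all__ = [
    "ObjectiveStats",
    "SampleSummary",
    "PmdResult",
    "sample_summary",
    "pmd",
    "mean_random_code",
    "count_better_report",
    "compare_to_canonical",
    "empirical_distribution",
]


@dataclass(frozen=True)
class ObjectiveStats:
    """Streaming sample statistics of one objective over random codes."""

    label: str
    mean: float
    std: float
    minimum: float
    maximum: float
    count_better: int
    canonical: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]


@dataclass(frozen=True)
class SampleSummary:
    """Summary of ``n`` uniform random restrictive codes under some specs."""

    n: int
    seed: int | None
    per_objective: tuple[ObjectiveStats, ...]

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.per_objective])

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "objectives": [
                {
                    "label": s.label,
                    "mean": s.mean,
                    "std": s.std,
                    "min": s.minimum,
                    "max": s.maximum,
                    "count_better": s.count_better,
                    "canonical": s.canonical,
                    "bin_edges": list(s.bin_edges),
                    "bin_counts": list(s.bin_counts),
                }
                for s in self.per_objective
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SampleSummary":
        return cls(
            n=int(payload["n"]),
            seed=payload.get("seed"),
            per_objective=tuple(
                ObjectiveStats(
                    label=o["label"],
                    mean=float(o["mean"]),
                    std=float(o["std"]),
                    minimum=float(o["min"]),
                    maximum=float(o["max"]),
                    count_better=int(o["count_better"]),
                    canonical=float(o["canonical"]),
                    bin_edges=tuple(o["bin_edges"]),
                    bin_counts=tuple(o["bin_counts"]),
                )
                for o in payload["objectives"]
            ),
        )


@dataclass(frozen=True)
class PmdResult:
    """pmd for one objective; ``defined`` is False when fbar equals f(C)."""

    pmd: float | None
    f_code: float
    f_canonical: float
    f_mean: float

    @property
    def defined(self) -> bool:
        return self.pmd is not None


def pmd(f_code: float, f_canonical: float, f_mean: float) -> float:
    """Percentage of minimisation distance of a code to the canonical code.

    Raises ``ZeroDivisionError`` when the code's evaluation equals the
    random-code mean (the measure is undefined there).
    """
    if f_mean == f_code:
        raise ZeroDivisionError("pmd undefined: code evaluation equals the random mean")
    return 100.0 * abs((f_mean - f_canonical) / (f_mean - f_code))


def mean_random_code(spec: ObjectiveSpec) -> float:
    """Exact expectation of an objective over uniform restrictive codes.

    By exchangeability of a uniform permutation, every inter-block
    substitution pair carries an expected squared property difference of
    sum_{i != j} (x_i - x_j)^2 / (20 * 19); intra-block pairs contribute
    zero.  Serves as an independent check on Monte-Carlo sampling.
    """
    bpw = _spec_weights(spec)
    x = spec.property_table.as_array()
    diff2 = (x[:, None] - x[None, :]) ** 2
    expected_pair = diff2.sum() / (20 * 19)
    inter_weight = bpw.matrix.sum() / 2.0  # matrix stores both orientations
    return float(inter_weight * expected_pair / bpw.normalizer)


def sample_summary(
    n: int,
    specs: Sequence[ObjectiveSpec],
    rng: np.random.Generator | int,
    bins: int = 50,
    batch_size: int = 100_000,
) -> SampleSummary:
    """Evaluate ``n`` uniform random restrictive codes under ``specs``.

    Statistics (mean, sample std, min/max, count strictly better than
    canonical, histogram) are accumulated streaming over batches, so
    memory is independent of ``n``.  Histogram edges are fixed from the
    first batch's range, widened by half a range on each side; later
    values outside the span are clipped into the end bins so counts
    always sum to ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng
    canon = evaluate(canonical_code(), specs)

    k = len(specs)
    total = np.zeros(k)
    total_sq = np.zeros(k)
    count_better = np.zeros(k, dtype=np.int64)
    mins = np.full(k, np.inf)
    maxs = np.full(k, -np.inf)
    edges: list[np.ndarray] | None = None
    hist = np.zeros((k, bins), dtype=np.int64)

    done = 0
    while done < n:
        m = min(batch_size, n - done)
        F = evaluate_many(random_codes(m, gen), specs)
        total += F.sum(axis=0)
        total_sq += (F**2).sum(axis=0)
        count_better += (F < canon).sum(axis=0)
        mins = np.minimum(mins, F.min(axis=0))
        maxs = np.maximum(maxs, F.max(axis=0))
        if edges is None:
            edges = []
            for j in range(k):
                lo, hi = F[:, j].min(), F[:, j].max()
                span = max(hi - lo, 1e-12)
                edges.append(np.linspace(lo - 0.5 * span, hi + 0.5 * span, bins + 1))
        for j in range(k):
            clipped = np.clip(F[:, j], edges[j][0], edges[j][-1])
            hist[j] += np.histogram(clipped, bins=edges[j])[0]
        done += m

    mean = total / n
    var = np.maximum(total_sq / n - mean**2, 0.0)
    std = np.sqrt(var * n / (n - 1)) if n > 1 else np.zeros(k)
    assert edges is not None

    per_objective = tuple(
        ObjectiveStats(
            label=spec.label,
            mean=float(mean[j]),
            std=float(std[j]),
            minimum=float(mins[j]),
            maximum=float(maxs[j]),
            count_better=int(count_better[j]),
            canonical=float(canon[j]),
            bin_edges=tuple(float(e) for e in edges[j]),
            bin_counts=tuple(int(c) for c in hist[j]),
        )
        for j, spec in enumerate(specs)
    )
    return SampleSummary(n=n, seed=int(seed) if seed is not None else None,
                         per_objective=per_objective)


def count_better_report(summary: SampleSummary) -> pd.DataFrame:
    """Random codes strictly better than canonical, per objective."""
    rows = [
        {
            "objective": s.label,
            "count_better": s.count_better,
            "n": summary.n,
            "frequency": s.count_better / summary.n,
            "canonical": s.canonical,
            "mean_random": s.mean,
        }
        for s in summary.per_objective
    ]
    return pd.DataFrame(rows)


def _normalize(F: np.ndarray, summary: SampleSummary, scheme: str) -> np.ndarray:
    stats = summary.per_objective
    if scheme == "mean":
        scale = np.array([s.mean for s in stats])
        return F / scale
    if scheme == "zscore":
        mu = np.array([s.mean for s in stats])
        sd = np.array([s.std for s in stats])
        return (F - mu) / sd
    if scheme == "minmax":
        lo = np.array([s.minimum for s in stats])
        hi = np.array([s.maximum for s in stats])
        return (F - lo) / (hi - lo)
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def compare_to_canonical(
    front: ParetoFront,
    summary: SampleSummary,
    normalization: str = "mean",
) -> pd.DataFrame:
    """Dominance, pmd and normalised distance of front members vs canonical.

    pmd columns are reported only for members that dominate the canonical
    code (elsewhere the member is farther than canonical from the random
    mean on some objective and the ratio exceeds 100%).
    """
    labels = [s.label for s in summary.per_objective]
    if [s.label for s in front.specs] != labels:
        raise ValueError("front and summary were built under different objectives")
    canon = np.array([s.canonical for s in summary.per_objective])
    means = summary.means
    F = front.objective_matrix()
    Fn = _normalize(F, summary, normalization)
    canon_n = _normalize(canon[None, :], summary, normalization)[0]

    rows = []
    for i, member in enumerate(front.members):
        dom = dominates(F[i], canon)
        row: dict[str, object] = {"code": f"HC{i + 1}"}
        for j, label in enumerate(labels):
            row[label] = F[i, j]
        row["distance"] = float(np.linalg.norm(Fn[i] - canon_n))
        row["dominates_canonical"] = dom
        for j, label in enumerate(labels):
            row[f"pmd_{label}"] = (
                pmd(F[i, j], canon[j], means[j]) if dom else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def empirical_distribution(summary: SampleSummary, spec_index: int) -> pd.DataFrame:
    """Histogram table of one objective's random-code distribution.

    Columns are bin edges and counts; the canonical value is attached as a
    DataFrame attribute (``frame.attrs['canonical']``) for marker use.
    """
    s = summary.per_objective[spec_index]
    frame = pd.DataFrame(
        {
            "bin_left": s.bin_edges[:-1],
            "bin_right": s.bin_edges[1:],
            "count": s.bin_counts,
        }
    )
    frame.attrs["canonical"] = s.canonical
    frame.attrs["label"] = s.label
    return frame
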