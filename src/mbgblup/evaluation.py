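"""Validation accuracy, accuracy comparisons and theoretical benchmarks.

Accuracy is the within-breed Pearson correlation between genomic breeding
values and progeny-test EBVs in a withheld validation group. Accuracies
from different reference populations are compared with a Fisher-z test
(independent groups) or Steiger's test (the same validation animals under
two predictors). The deterministic expected accuracy
sqrt(N h^2 / (N h^2 + Me)) with Me = 2 Ne L / ln(4 Ne L) serves as a
theory benchmark. Scenario summaries follow the reference-design x GRM
layout with compact letter displays from the pairwise tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import atanh, log, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AccuracyResult",
    "ExpectedAccuracyParams",
    "accuracy",
    "compare_accuracies",
    "expected_accuracy",
    "compact_letters",
    "summarize_scenarios",
]


@dataclass
class AccuracyResult:
    breed: str
    n_validation: int
    correlation: float
    reference_description: str = ""
    grm_flavor: str = ""

    def __post_init__(self) -> None:
        if self.n_validation < 3:
            raise ValueError("need at least 3 validation animals")
        if np.isfinite(self.correlation) and abs(self.correlation) > 1:
            raise ValueError("|correlation| must be <= 1")


def accuracy(
    gbv: Sequence[float],
    ebv: Sequence[float],
    breed: str = "",
    reference_description: str = "",
    grm_flavor: str = "",
) -> AccuracyResult:
    """Pearson correlation between predicted and progeny-test breeding
    values for one validation group (within-breed accuracy). Zero
    variance in either vector yields an undefined (NaN) correlation."""
    g = np.asarray(gbv, float)
    e = np.asarray(ebv, float)
    if g.shape != e.shape:
        raise ValueError("gbv and ebv must be the same length")
    if len(g) < 3:
        raise ValueError("need at least 3 paired values")
    if g.std() == 0 or e.std() == 0:
        r = float("nan")
    else:
        r = float(np.corrcoef(g, e)[0, 1])
    return AccuracyResult(breed, len(g), r, reference_description, grm_flavor)


def compare_accuracies(
    r1: float,
    n1: int,
    r2: float,
    n2: int,
    dependent: bool = False,
    r12: float | None = None,
) -> tuple[float, float]:
    """Z-test for the difference between two accuracies (correlations).

    Independent mode (default): Fisher's z transformation,
    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``.
    Dependent mode: Steiger's test for two correlations sharing one
    variable measured on the same ``n = n1 = n2`` animals (two GBV vectors
    against the same EBVs); ``r12`` is the correlation between the two
    predictors. Returns (z, two-sided p).
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must satisfy |r| < 1")
    if n1 <= 3 or n2 <= 3:
        raise ValueError("group sizes must exceed 3")
    z1, z2 = atanh(r1), atanh(r2)
    if not dependent:
        z = (z1 - z2) / sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    else:
        if r12 is None:
            raise ValueError("dependent mode needs the inter-predictor correlation r12")
        if n1 != n2:
            raise ValueError("dependent mode requires the same animals (n1 == n2)")
        n = n1
        rbar2 = ((r1 + r2) / 2) ** 2
        f = min((1 - r12) / (2 * (1 - rbar2)), 1.0)
        h = (1 - f * rbar2) / (1 - rbar2)
        z = (z1 - z2) * sqrt((n - 3) / (2 * (1 - r12) * h))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


@dataclass
class ExpectedAccuracyParams:
    n_reference: int
    heritability: float
    effective_size: int
    genome_length: float  # Morgans

    @property
    def me(self) -> float:
        """Effective number of independent chromosome segments."""
        arg = 4 * self.effective_size * self.genome_length
        if arg <= 1:
            raise ValueError("4*Ne*L must exceed 1")
        return 2 * self.effective_size * self.genome_length / log(arg)


def expected_accuracy(params: ExpectedAccuracyParams) -> float:
    """Deterministic expected accuracy of genomic prediction,
    sqrt(N h^2 / (N h^2 + Me)); increases with reference size and
    heritability, decreases with effective population size."""
    if params.n_reference <= 0 or params.effective_size <= 0:
        raise ValueError("N and Ne must be positive")
    if not 0 <= params.heritability <= 1:
        raise ValueError("heritability must lie in [0, 1]")
    nh2 = params.n_reference * params.heritability
    if nh2 == 0:
        return 0.0
    return sqrt(nh2 / (nh2 + params.me))


def compact_letters(labels: Sequence[str], not_different: np.ndarray) -> dict[str, str]:
    """Compact letter display from a pairwise non-significance matrix.

    Two treatments share a letter if and only if they are not
    significantly different. Letters correspond to the maximal cliques of
    the non-significance graph (clique cover), ordered for stable output;
    this guarantees both directions of the display at the cost of
    occasionally using more letters than the minimal covering.
    """
    import networkx as nx

    m = np.asarray(not_different, bool)
    k = len(labels)
    gph = nx.Graph()
    gph.add_nodes_from(range(k))
    for i in range(k):
        for j in range(i + 1, k):
            if m[i, j]:
                gph.add_edge(i, j)
    cliques = sorted(nx.find_cliques(gph), key=lambda c: (-len(c), sorted(c)))
    letters: dict[str, list[str]] = {lab: [] for lab in labels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, clique in enumerate(cliques):
        ch = alphabet[idx % len(alphabet)] * (idx // len(alphabet) + 1)
        for node in clique:
            letters[labels[node]].append(ch)
    return {lab: "".join(sorted(v)) for lab, v in letters.items()}


def summarize_scenarios(
    results: Sequence[AccuracyResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Comparison table across reference designs.

    Rows are reference designs, columns are (target breed, GRM flavor)
    pairs; each cell shows the accuracy with significance letters from
    pairwise Fisher-z tests within that column (designs sharing a letter
    are not significantly different at ``alpha``).
    """
    if not results:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        [
            {
                "design": r.reference_description,
                "breed": r.breed,
                "flavor": r.grm_flavor,
                "r": r.correlation,
                "n": r.n_validation,
            }
            for r in results
        ]
    )
    if df.duplicated(["design", "breed", "flavor"]).any():
        raise ValueError("duplicated design labels in results")
    table = {}
    for (breed, flavor), grp in df.groupby(["breed", "flavor"]):
        grp = grp.reset_index(drop=True)
        k = len(grp)
        nd = np.ones((k, k), bool)
        for i in range(k):
            for j in range(i + 1, k):
                ri, rj = grp.loc[i, "r"], grp.loc[j, "r"]
                if np.isnan(ri) or np.isnan(rj):
                    continue
                _, p = compare_accuracies(
                    min(ri, 0.999999), int(grp.loc[i, "n"]),
                    min(rj, 0.999999), int(grp.loc[j, "n"]),
                )
                nd[i, j] = nd[j, i] = p >= alpha
        lett = (
            compact_letters(list(grp["design"]), nd)
            if k > 1
            else {grp.loc[0, "design"]: ""}
        )
        for _, row in grp.iterrows():
            cell = f"{row['r']:.3f}"
            if lett[row["design"]]:
                cell += f" {lett[row['design']]}"
            table.setdefault(row["design"], {})[f"{breed}:{flavor}"] = cell
    out = pd.DataFrame.from_dict(table, orient="index").sort_index()
    out.index.name = "design"
    return out
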