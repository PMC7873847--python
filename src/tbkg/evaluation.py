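"""Co-occurrence baseline and agreement statistics.

The baseline ranks entity pairs by the number of documents in which
both appear — the traditional co-occurrence analysis the knowledge-graph
ranking is compared against.  Agreement with a gold-standard ADR list is
summarized by Cohen's kappa, sensitivity, and specificity over a 2x2
table built from the ranking's labeled extremes (top 5% = model
positive, bottom 5% = model negative; the unlabeled middle is excluded
from the table).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus import DocEntityMatrix, EntityLexicon
from .discovery import LABEL_IMPORTANT, LABEL_UNLIKELY, DrugAdrFinding
from .exceptions import ConfigurationError, UndefinedStatisticError


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 agreement table: a = both positive, b = model positive only,
    c = gold positive only, d = both negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("confusion-table counts must be non-negative")
        if self.n == 0:
            raise ConfigurationError("confusion table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class AgreementStats:
    kappa: float
    sensitivity: float
    specificity: float


def agreement(table: ConfusionTable) -> AgreementStats:
    """Cohen's kappa, sensitivity and specificity of a 2x2 table.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement
    p_o = (a+d)/n and chance agreement
    p_e = ((a+b)(a+c) + (c+d)(b+d)) / n^2.
    """
    a, b, c, d, n = table.a, table.b, table.c, table.d, table.n
    if a + c == 0:
        raise UndefinedStatisticError("sensitivity", "no gold-positive items (a+c=0)")
    if b + d == 0:
        raise UndefinedStatisticError("specificity", "no gold-negative items (b+d=0)")
    sensitivity = a / (a + c)
    specificity = d / (b + d)
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    if p_e == 1.0:
        raise UndefinedStatisticError("kappa", "expected agreement is 1")
    kappa = (p_o - p_e) / (1 - p_e)
    return AgreementStats(kappa=kappa, sensitivity=sensitivity, specificity=specificity)


# ---------------------------------------------------------------------------
# co-occurrence baseline


def cooccurrence_rank(
    matrix: DocEntityMatrix, type_pair: tuple[str, str]
) -> pd.DataFrame:
    """Entity pairs of a type pair ranked by document co-occurrence count.

    Returns a DataFrame (a_id, b_id, count) ordered by count descending,
    ties broken by the concept-id pair.
    """
    ta, tb = type_pair
    ents_a = matrix.columns_of_type(ta)
    ents_b = matrix.columns_of_type(tb)
    if len(ents_a) == 0 or len(ents_b) == 0:
        raise ValueError(f"matrix lacks columns for type pair {type_pair!r}")
    Xa = matrix.X[:, ents_a.index.to_numpy()]
    Xb = matrix.X[:, ents_b.index.to_numpy()]
    counts = np.asarray((Xa.T @ Xb).todense())
    rows = [
        (ca, cb, int(counts[i, j]))
        for i, ca in enumerate(ents_a["concept_id"])
        for j, cb in enumerate(ents_b["concept_id"])
    ]
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return pd.DataFrame(rows, columns=["a_id", "b_id", "count"])


# ---------------------------------------------------------------------------
# gold-standard comparison


def load_gold(path: str | Path, lexicon: EntityLexicon) -> set[str]:
    """Read a gold ADR list (one term or concept id per line) and resolve
    each line to a concept id via exact lexicon lookup.

    Unresolvable lines are ignored; an empty resolved set raises.
    """
    resolved: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid = lexicon.resolve(line)
            if cid is not None:
                resolved.add(cid)
    if not resolved:
        raise ConfigurationError(f"gold list {path} resolved to zero concepts")
    return resolved


def evaluate_against_gold(
    findings: Sequence[DrugAdrFinding], gold: set[str]
) -> tuple[ConfusionTable, AgreementStats]:
    """Compare labeled findings against a gold ADR concept set.

    Model-positive = labeled important; model-negative = labeled
    unlikely.  The unlabeled middle of the ranking enters neither row of
    the table.
    """
    if not gold:
        raise ConfigurationError("gold ADR set is empty")
    a = b = c = d = 0
    for f in findings:
        if f.label == LABEL_IMPORTANT:
            if f.adr in gold:
                a += 1
            else:
                b += 1
        elif f.label == LABEL_UNLIKELY:
            if f.adr in gold:
                c += 1
            else:
                d += 1
    table = ConfusionTable(a=a, b=b, c=c, d=d)
    return table, agreement(table)


def report_json(table: ConfusionTable, stats: AgreementStats) -> str:
    return json.dumps(
        {
            "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d, "n": table.n},
            "kappa": stats.kappa,
            "sensitivity": stats.sensitivity,
            "specificity": stats.specificity,
        },
        indent=2,
    )
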