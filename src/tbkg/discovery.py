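"""Ranking candidate adverse drug reactions for a drug, with
explanation paths, and labeling the extremes of the ranking.

Each candidate ADR gets a score: the importance of the direct drug-ADR
edge when one exists, otherwise a widest-bottleneck fallback over its
explanation paths (the best path's weakest edge).  Directly connected
ADRs always outrank path-only ones, keeping the direct statistical
signal primary and the paths explanatory.  The top and bottom 5% of the
ranking are labeled "important" and "unlikely" respectively; the middle
stays unlabeled.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import pandas as pd

from .exceptions import ConfigurationError, UnknownEntityError
from .graph import ExplanationPath, TBKG

LABEL_IMPORTANT = "important"
LABEL_UNLIKELY = "unlikely"
LABEL_NONE = "unlabeled"


@dataclass(frozen=True)
class DrugAdrFinding:
    """One scored drug-ADR pair with its explanation paths."""

    drug: str
    adr: str
    direct_importance: float | None
    path_support: float | None
    score: float
    paths: tuple[ExplanationPath, ...]
    rank: int | None = None
    label: str = LABEL_NONE


def rank_adrs(graph: TBKG, drug: str, max_len: int = 3) -> list[DrugAdrFinding]:
    """Rank every reachable ADR for *drug*, attaching all explanation paths.

    Candidates are ADR nodes with a direct edge to the drug or at least
    one explanation path of <= *max_len* edges (an ADR with neither has
    no defined score and is omitted).  Ordering: direct-edge ADRs first
    by direct importance, then path-only ADRs by path support; ties
    break by path support then concept id.  Ranks are 1-based.
    """
    if drug not in graph:
        raise UnknownEntityError(f"drug node {drug!r} not in graph")
    if graph.node_type(drug) != "drug":
        raise UnknownEntityError(f"node {drug!r} has type {graph.node_type(drug)!r}, not drug")
    findings: list[DrugAdrFinding] = []
    for adr in graph.nodes_of_type("adr"):
        direct = graph.edge_weight(drug, adr)
        paths = tuple(graph.enumerate_paths(drug, adr, max_len=max_len))
        indirect = [p.bottleneck for p in paths if p.n_edges >= 2]
        support = max(indirect) if indirect else None
        if direct is None and support is None:
            continue
        findings.append(
            DrugAdrFinding(
                drug=drug,
                adr=adr,
                direct_importance=direct,
                path_support=support,
                score=direct if direct is not None else support,
                paths=paths,
            )
        )
    neg_inf = -math.inf
    findings.sort(
        key=lambda f: (
            0 if f.direct_importance is not None else 1,
            -f.score,
            -(f.path_support if f.path_support is not None else neg_inf),
            f.adr,
        )
    )
    return [replace(f, rank=i + 1) for i, f in enumerate(findings)]


def label_extremes(
    findings: Sequence[DrugAdrFinding], fraction: float = 0.05
) -> list[DrugAdrFinding]:
    """Label the top ceil(fraction*N) findings important and the bottom
    ceil(fraction*N) unlikely; the middle stays unlabeled.

    ``fraction=0`` labels nothing.  Raises when the two labeled blocks
    would overlap (N < 2*ceil(fraction*N)).
    """
    if not findings:
        raise ConfigurationError("cannot label an empty findings list")
    if not 0 <= fraction <= 1:
        raise ConfigurationError("fraction must be in [0, 1]")
    n = len(findings)
    m = math.ceil(fraction * n)
    if m == 0:
        return [replace(f, label=LABEL_NONE) for f in findings]
    if n < 2 * m:
        raise ConfigurationError(
            f"{n} findings are too few for disjoint top/bottom blocks of {m}"
        )
    out = []
    for i, f in enumerate(findings):
        if i < m:
            label = LABEL_IMPORTANT
        elif i >= n - m:
            label = LABEL_UNLIKELY
        else:
            label = LABEL_NONE
        out.append(replace(f, label=label))
    return out


# ---------------------------------------------------------------------------
# report serialization


def findings_to_frame(findings: Sequence[DrugAdrFinding]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (f.drug, f.adr, f.rank, f.score, f.label, len(f.paths))
            for f in findings
        ],
        columns=["drug", "adr", "rank", "score", "label", "n_paths"],
    )


def write_findings(
    findings: Sequence[DrugAdrFinding], directory: str | Path
) -> None:
    """Write findings.tsv plus findings_paths.jsonl (one record per
    finding carrying its full path list with per-edge weights)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "findings.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug\tadr\trank\tscore\tlabel\tn_paths\n")
        for f in findings:
            fh.write(
                f"{f.drug}\t{f.adr}\t{f.rank}\t{f.score!r}\t{f.label}\t{len(f.paths)}\n"
            )
    with open(directory / "findings_paths.jsonl", "w", encoding="utf-8") as fh:
        for f in findings:
            fh.write(
                json.dumps(
                    {
                        "drug": f.drug,
                        "adr": f.adr,
                        "rank": f.rank,
                        "score": f.score,
                        "label": f.label,
                        "direct_importance": f.direct_importance,
                        "path_support": f.path_support,
                        "paths": [
                            {"nodes": list(p.nodes), "weights": list(p.weights)}
                            for p in f.paths
                        ],
                    }
                )
                + "\n"
            )
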