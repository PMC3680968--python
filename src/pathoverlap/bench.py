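"""Leave-one-out benchmark over a directory of SBML maps.

Every map is used once as the query and compared against all the others; hits
are ranked by the query-side overlap score.  When the maps share a reaction-id
namespace (as curated databases such as Reactome do), the a-priori overlap of
two maps is the fraction of the query's reaction ids found in the target —
the *gold standard*: a positive fraction means the pair is related.  Per-query
and pooled ROC/AUC measure how well the overlap score ranks related maps above
unrelated ones.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .clique_solver import SolverLimits, UNBOUNDED, iterative_overlap
from .errors import DegenerateGraphError, ParameterError, PathOverlapError
from .path_matching import EquivalenceSpec
from .sbml_graph import load_pathway, parse_sbml
from .scoring import overlap_score

__all__ = ["BenchmarkResult", "reactome_gold_standard", "run_benchmark"]

logger = logging.getLogger(__name__)


def reactome_gold_standard(query_doc: str | Path, target_doc: str | Path) -> float:
    """Fraction of the query's reaction ids present in the target document.

    Uses the documents' full reaction-id sets (no filtering): the gold standard
    is a property of the curated database, not of the graph model.
    """
    _, query_reactions = parse_sbml(query_doc)
    _, target_reactions = parse_sbml(target_doc)
    query_ids = {r.id for r in query_reactions}
    if not query_ids:
        raise DegenerateGraphError(f"{query_doc}: query document has no reactions")
    target_ids = {r.id for r in target_reactions}
    return len(query_ids & target_ids) / len(query_ids)


def _safe_auc(labels: list[int], values: list[float]) -> float | None:
    """AUC, or None when only one class is present (undefined)."""
    if len(set(labels)) < 2:
        return None
    return float(roc_auc_score(labels, values))


@dataclasses.dataclass
class BenchmarkResult:
    """Score matrix, gold matrix, ranked hits and AUC summaries."""

    scores: pd.DataFrame  # query x target, query-side overlap score
    gold: pd.DataFrame  # query x target, shared-reaction fraction
    hits: pd.DataFrame  # one row per ordered pair, ranked per query
    per_query_auc: dict[str, float | None]
    pooled_auc: float | None

    def write_tsv(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = []
        for tag, frame in (("scores", self.scores), ("gold", self.gold), ("hits", self.hits)):
            path = prefix.parent / f"{prefix.name}_{tag}.tsv"
            frame.to_csv(path, sep="\t")
            paths.append(path)
        summary = prefix.parent / f"{prefix.name}_auc.tsv"
        rows = ["query\tauc"]
        for query, auc in sorted(self.per_query_auc.items()):
            rows.append(f"{query}\t{'NA' if auc is None else f'{auc:.4f}'}")
        rows.append(f"POOLED\t{'NA' if self.pooled_auc is None else f'{self.pooled_auc:.4f}'}")
        summary.write_text("\n".join(rows) + "\n")
        paths.append(summary)
        return paths


def run_benchmark(
    directory: str | Path,
    n_max: int = 3,
    limits: SolverLimits = UNBOUNDED,
    spec: EquivalenceSpec | None = None,
) -> BenchmarkResult:
    """All-vs-all leave-one-out comparison of the SBML maps in ``directory``.

    Unparseable member files are skipped with a warning.  Hits of each query
    are ranked by descending score with ties broken by target id.
    """
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".xml", ".sbml")
    )
    maps = {}
    for path in files:
        try:
            maps[path.stem] = (path, load_pathway(path))
        except (PathOverlapError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
    if len(maps) < 2:
        raise ParameterError(f"{directory}: need at least 2 parseable SBML maps")

    names = sorted(maps)
    scores = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    gold = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    rows = []
    for query in names:
        qpath, qgraph = maps[query]
        for target in names:
            if target == query:
                continue
            tpath, tgraph = maps[target]
            solution = iterative_overlap(qgraph, tgraph, n_max, spec, limits)
            score = overlap_score(qgraph, solution, side=1)
            standard = reactome_gold_standard(qpath, tpath)
            scores.loc[query, target] = score
            gold.loc[query, target] = standard
            rows.append(
                {
                    "query": query,
                    "target": target,
                    "score": score,
                    "gold": standard,
                    "related": int(standard > 0),
                }
            )

    hits = pd.DataFrame(rows).sort_values(
        ["query", "score", "target"], ascending=[True, False, True]
    )
    hits["rank"] = hits.groupby("query").cumcount() + 1
    hits = hits.reset_index(drop=True)

    per_query_auc = {
        query: _safe_auc(
            group["related"].tolist(), group["score"].tolist()
        )
        for query, group in hits.groupby("query")
    }
    pooled_auc = _safe_auc(hits["related"].tolist(), hits["score"].tolist())
    return BenchmarkResult(
        scores=scores,
        gold=gold,
        hits=hits,
        per_query_auc=per_query_auc,
        pooled_auc=pooled_auc,
    )
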