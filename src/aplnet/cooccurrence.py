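"""Pairwise gene co-occurrence statistics and the significant co-occurrence network.

For each unordered gene pair the 2x2 cross-tabulation of carriers is
tested for association with the chi-square statistic (1 df, no continuity
correction) or Fisher's exact test.  The chi-square statistic is computed
through the phi-coefficient identity chi2 = n * phi^2; when any table
margin is zero the statistic is 0 and p = 1.  Edges at p <= alpha form the
co-occurrence network; each edge carries the co-mutated sample count and
whether the joint count sits above or below the independence expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MutationMatrix


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier cross-tabulation of two genes: a=both, b=gene1 only,
    c=gene2 only, d=neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        """Joint-carrier count expected under independence: n * p1 * p2."""
        if self.n == 0:
            return 0.0
        return (self.a + self.b) * (self.a + self.c) / self.n


@dataclass(frozen=True)
class CooccurrenceEdge:
    """A gene pair with its table, statistic, p-value and direction."""

    gene1: str
    gene2: str
    table: ContingencyTable2x2
    expected_a: float
    statistic: float
    p_value: float
    direction: str  # "above" | "below"


def pair_contingency(matrix: MutationMatrix, gene1: str, gene2: str) -> ContingencyTable2x2:
    """Exact 2x2 cross-tabulation of two binary gene columns."""
    if gene1 == gene2:
        raise ValueError(f"cannot cross-tabulate gene {gene1!r} with itself")
    x = matrix.column(gene1)
    y = matrix.column(gene2)
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    d = int(np.sum((x == 0) & (y == 0)))
    return ContingencyTable2x2(a, b, c, d)


def cooccurrence_test(
    table: ContingencyTable2x2, method: str = "chi2"
) -> tuple[float, float, str]:
    """Association test on a 2x2 table.

    chi2: statistic = n * phi^2 with 1 df, no continuity correction; a zero
    margin gives statistic 0 and p = 1.  fisher: two-sided exact p with the
    same above/below-expected direction.  Returns (statistic, p, direction).
    """
    if table.n == 0:
        raise ValueError("empty table")
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    direction = "above" if a > table.expected_a else "below"
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if method == "chi2":
        if 0 in (r1, r2, c1, c2):
            return 0.0, 1.0, direction
        phi2 = (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        statistic = n * phi2
        return float(statistic), float(stats.chi2.sf(statistic, df=1)), direction
    if method == "fisher":
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        return float(odds) if np.isfinite(odds) else float("inf"), float(p), direction
    raise ValueError(f"unknown method {method!r}")


def _pairwise_chi2(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized chi-square over all column pairs of a binary matrix.

    Returns (a, statistic, p) as G x G arrays; zero-margin pairs get
    statistic 0 / p 1.
    """
    n = data.shape[0]
    col = data.sum(axis=0).astype(np.int64)
    a = (data.T @ data).astype(np.int64)
    r1 = col[:, None]
    c1 = col[None, :]
    b = r1 - a
    c = c1 - a
    d = n - r1 - c1 + a
    num = n * (a * d - b * c).astype(float) ** 2
    den = (r1 * (n - r1) * c1 * (n - c1)).astype(float)
    statistic = np.zeros_like(num)
    ok = den > 0
    statistic[ok] = num[ok] / den[ok]
    p = stats.chi2.sf(statistic, df=1)
    p[~ok] = 1.0
    statistic[~ok] = 0.0
    return a, statistic, p


def pairwise_tests(
    matrix: MutationMatrix, method: str = "chi2", min_carriers: int = 1
) -> pd.DataFrame:
    """Association test for every unordered pair of genes with >= ``min_carriers``.

    Returns one row per tested pair: gene1, gene2 (lexicographic), a,
    expected_a, statistic, p, direction.
    """
    genes = [g for g, k in matrix.carrier_counts().items() if k >= min_carriers]
    if len(genes) < 2:
        return pd.DataFrame(
            columns=["gene1", "gene2", "a", "expected_a", "statistic", "p", "direction"]
        )
    sub = matrix.df[genes]
    data = sub.to_numpy(dtype=np.int64)
    n = data.shape[0]
    if method == "chi2":
        a_mat, stat_mat, p_mat = _pairwise_chi2(data)
        col = data.sum(axis=0)
        rows = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                expected = col[i] * col[j] / n
                rows.append(
                    {
                        "gene1": min(genes[i], genes[j]),
                        "gene2": max(genes[i], genes[j]),
                        "a": int(a_mat[i, j]),
                        "expected_a": expected,
                        "statistic": float(stat_mat[i, j]),
                        "p": float(p_mat[i, j]),
                        "direction": "above" if a_mat[i, j] > expected else "below",
                    }
                )
    else:
        rows = []
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                table = pair_contingency(matrix, genes[i], genes[j])
                statistic, p, direction = cooccurrence_test(table, method=method)
                rows.append(
                    {
                        "gene1": min(genes[i], genes[j]),
                        "gene2": max(genes[i], genes[j]),
                        "a": table.a,
                        "expected_a": table.expected_a,
                        "statistic": statistic,
                        "p": p,
                        "direction": direction,
                    }
                )
    df = pd.DataFrame(rows)
    return df.sort_values(["p", "gene1", "gene2"], kind="mergesort").reset_index(drop=True)


def build_cooccurrence_network(
    matrix: MutationMatrix,
    alpha: float = 0.05,
    min_pair_count: int = 0,
    method: str = "chi2",
) -> tuple[list[CooccurrenceEdge], pd.DataFrame]:
    """Build the significant co-occurrence network.

    Tests all unordered pairs of genes with at least one carrier, keeps
    edges at p <= ``alpha`` (and joint count a >= ``min_pair_count``), and
    summarizes each gene's significant-degree (its node size in a
    rendering).  Returns (edges, node summary).
    """
    if len(matrix.genes) < 2:
        return [], pd.DataFrame(columns=["gene", "significant_degree"])
    tests = pairwise_tests(matrix, method=method)
    edges: list[CooccurrenceEdge] = []
    for row in tests.itertuples(index=False):
        if row.p <= alpha and row.a >= min_pair_count:
            table = pair_contingency(matrix, row.gene1, row.gene2)
            edges.append(
                CooccurrenceEdge(
                    gene1=row.gene1,
                    gene2=row.gene2,
                    table=table,
                    expected_a=row.expected_a,
                    statistic=row.statistic,
                    p_value=row.p,
                    direction=row.direction,
                )
            )
    degree: dict[str, int] = {}
    for edge in edges:
        degree[edge.gene1] = degree.get(edge.gene1, 0) + 1
        degree[edge.gene2] = degree.get(edge.gene2, 0) + 1
    summary = pd.DataFrame(
        sorted(degree.items()), columns=["gene", "significant_degree"]
    )
    return edges, summary


def edges_table(edges: Iterable[CooccurrenceEdge]) -> pd.DataFrame:
    rows = [
        {
            "gene1": e.gene1,
            "gene2": e.gene2,
            "a": e.table.a,
            "expected_a": e.expected_a,
            "statistic": e.statistic,
            "p": e.p_value,
            "direction": e.direction,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["gene1", "gene2", "a", "expected_a", "statistic", "p", "direction"]
    )


def to_graph(edges: Sequence[CooccurrenceEdge]) -> nx.Graph:
    """Co-occurrence network as an undirected graph with edge attributes
    count/p/direction and node attribute significant_degree."""
    graph = nx.Graph()
    for edge in sorted(edges, key=lambda e: (e.gene1, e.gene2)):
        graph.add_edge(
            edge.gene1,
            edge.gene2,
            count=edge.table.a,
            p=edge.p_value,
            direction=edge.direction,
        )
    for node in graph.nodes:
        graph.nodes[node]["significant_degree"] = graph.degree[node]
    return graph


def write_sif(edges: Sequence[CooccurrenceEdge], path: str | Path) -> None:
    """Write edges as a SIF file ('gene1 co gene2'), sorted for reproducibility."""
    with open(path, "w", encoding="utf-8") as fh:
        for edge in sorted(edges, key=lambda e: (e.gene1, e.gene2)):
            fh.write(f"{edge.gene1}\tco\t{edge.gene2}\n")


def write_graphml(edges: Sequence[CooccurrenceEdge], path: str | Path) -> None:
    nx.write_graphml(to_graph(edges), str(path))
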