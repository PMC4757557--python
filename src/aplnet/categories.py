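"""Functional-category burden, reference comparison and category co-mutation.

Genes map to one or more functional-category labels from a user-supplied
configuration (no live ontology lookups).  The category analyses are:

* per-category mutated-sample counts (burden),
* gene-count-normalized excess: are a category's hit-events over-represented
  relative to its share of genes?  The expectation model distributes
  patient-gene-label hit-events multinomially over categories in proportion
  to their gene-label counts; each category gets a one-sided binomial
  margin test.  A label-permutation null (patient-preserving gene-label
  shuffle) is available as a model-free alternative.
* comparison of per-category carrier rates against a reference population
  (one-sided two-proportion Fisher tests in both directions),
* category-level co-mutation, reusing the co-occurrence machinery on the
  patient x category matrix.

Multi-label genes count once per label; this inflates cross-category
co-mutation, which the permutation null accounts for.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cooccurrence import ContingencyTable2x2, cooccurrence_test
from .enrichment import binomial_tail
from .matrix import MutationMatrix

logger = logging.getLogger(__name__)

#: Default category vocabulary.
DEFAULT_VOCABULARY = frozenset(
    {
        "ubiquitination",
        "spliceosome",
        "cohesin complex",
        "signaling",
        "metabolism",
        "transmembrane protein",
        "protein kinase",
        "tyrosine-protein kinase",
        "transcription factor/regulator",
        "other cell functions",
    }
)

FALLBACK_CATEGORY = "other cell functions"


class CategoryMap:
    """Gene -> functional-category labels (one or more per gene)."""

    def __init__(
        self,
        mapping: Mapping[str, Iterable[str]],
        vocabulary: frozenset[str] = DEFAULT_VOCABULARY,
    ) -> None:
        self.vocabulary = vocabulary
        self._map: dict[str, frozenset[str]] = {}
        for gene, labels in mapping.items():
            labelset = frozenset(labels)
            if not labelset:
                raise ValueError(f"gene {gene!r} has no category labels")
            unknown = labelset - vocabulary
            if unknown:
                raise ValueError(
                    f"labels {sorted(unknown)} for gene {gene!r} outside the vocabulary"
                )
            self._map[gene] = labelset

    def labels(self, gene: str) -> frozenset[str]:
        return self._map.get(gene, frozenset())

    def __contains__(self, gene: str) -> bool:
        return gene in self._map

    @property
    def genes(self) -> list[str]:
        return list(self._map)

    @property
    def categories(self) -> list[str]:
        return sorted({label for labels in self._map.values() for label in labels})

    @classmethod
    def from_tsv(
        cls, path: str | Path, vocabulary: frozenset[str] = DEFAULT_VOCABULARY
    ) -> "CategoryMap":
        """Read a two-column (gene, category) TSV; repeated gene rows accumulate labels."""
        df = pd.read_csv(path, sep="\t", comment="#")
        gene_col, label_col = df.columns[:2]
        mapping: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            mapping.setdefault(str(row[gene_col]), set()).add(str(row[label_col]))
        return cls(mapping, vocabulary=vocabulary)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("gene\tcategory\n")
            for gene in sorted(self._map):
                for label in sorted(self._map[gene]):
                    fh.write(f"{gene}\t{label}\n")


def assign_categories(matrix: MutationMatrix, cmap: CategoryMap) -> pd.DataFrame:
    """Patient x category binary matrix: 1 iff the patient has >= 1 mutated
    gene carrying that label.

    Matrix genes missing from the map fall back to the
    ``other cell functions`` label with a logged warning.
    """
    if not cmap.genes:
        raise ValueError("empty category map")
    unmapped = [g for g in matrix.genes if g not in cmap]
    if unmapped:
        logger.warning(
            "%d genes missing from category map assigned to %r: %s",
            len(unmapped), FALLBACK_CATEGORY, ", ".join(unmapped[:10]),
        )
    categories = sorted(set(cmap.categories) | ({FALLBACK_CATEGORY} if unmapped else set()))
    data = np.zeros((matrix.n_patients, len(categories)), dtype=np.int8)
    cat_index = {c: j for j, c in enumerate(categories)}
    for gene in matrix.genes:
        labels = cmap.labels(gene) or frozenset({FALLBACK_CATEGORY})
        carriers = matrix.column(gene) == 1
        for label in labels:
            data[carriers, cat_index[label]] = 1
    return pd.DataFrame(data, index=matrix.patients, columns=categories)


def _gene_label_counts(genes: Iterable[str], cmap: CategoryMap) -> pd.Series:
    counts: dict[str, int] = {}
    for gene in genes:
        for label in cmap.labels(gene) or frozenset({FALLBACK_CATEGORY}):
            counts[label] = counts.get(label, 0) + 1
    return pd.Series(counts).sort_index()


def category_excess(
    matrix: MutationMatrix,
    cmap: CategoryMap,
    alpha: float = 0.05,
    n_permutations: int = 0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Gene-count-normalized burden test per category.

    Hit-events are (patient, gene, label) triples over mutated entries.
    Under the expectation model each event lands in category c with
    probability gene_labels(c)/total_gene_labels; observed event counts get
    a one-sided binomial tail test.  With ``n_permutations`` > 0 an
    add-one permutation p-value from patient-preserving gene-label
    shuffles is reported alongside.
    """
    gene_counts = _gene_label_counts(matrix.genes, cmap)
    total_labels = int(gene_counts.sum())

    def event_counts(label_of: Mapping[str, frozenset[str]]) -> pd.Series:
        counts = {c: 0 for c in gene_counts.index}
        for gene in matrix.genes:
            k = int(matrix.column(gene).sum())
            for label in label_of[gene]:
                counts[label] += k
        return pd.Series(counts).sort_index()

    true_labels = {
        g: (cmap.labels(g) or frozenset({FALLBACK_CATEGORY})) for g in matrix.genes
    }
    observed = event_counts(true_labels)
    n_events = int(observed.sum())
    sample_counts = assign_categories(matrix, cmap).sum(axis=0)

    rows = []
    perm_exceed = {c: 0 for c in gene_counts.index}
    if n_permutations > 0:
        rng = np.random.default_rng(rng_seed)
        genes = list(matrix.genes)
        for _ in range(n_permutations):
            perm = rng.permutation(len(genes))
            shuffled = {genes[i]: true_labels[genes[j]] for i, j in enumerate(perm)}
            perm_counts = event_counts(shuffled)
            for c in gene_counts.index:
                if perm_counts[c] >= observed[c]:
                    perm_exceed[c] += 1
    for category in gene_counts.index:
        share = gene_counts[category] / total_labels
        p = binomial_tail(int(observed[category]), n_events, share) if n_events else 1.0
        row = {
            "category": category,
            "gene_count": int(gene_counts[category]),
            "mutated_samples": int(sample_counts.get(category, 0)),
            "events": int(observed[category]),
            "expected_events": n_events * share,
            "burden_ratio": (
                float(sample_counts.get(category, 0)) / gene_counts[category]
            ),
            "p": p,
            "excess": p <= alpha,
        }
        if n_permutations > 0:
            row["p_perm"] = (1 + perm_exceed[category]) / (n_permutations + 1)
        rows.append(row)
    return pd.DataFrame(rows)


def category_vs_reference(
    cohort_rates: Mapping[str, float],
    reference_rates: Mapping[str, float],
    n: int,
    n_ref: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-category carrier rates against a reference population.

    One-sided two-proportion Fisher tests in both directions; each category
    is labelled more-mutated, less-mutated or indistinguishable at
    ``alpha``.  Categories absent from the reference are skipped with a
    warning.
    """
    rows = []
    for category in sorted(cohort_rates):
        if category not in reference_rates:
            logger.warning("category %r missing from reference rates; skipped", category)
            continue
        k = int(round(cohort_rates[category] * n))
        k_ref = int(round(reference_rates[category] * n_ref))
        table = [[k, n - k], [k_ref, n_ref - k_ref]]
        _, p_more = stats.fisher_exact(table, alternative="greater")
        _, p_less = stats.fisher_exact(table, alternative="less")
        if p_more <= alpha:
            status = "more-mutated"
        elif p_less <= alpha:
            status = "less-mutated"
        else:
            status = "indistinguishable"
        rows.append(
            {
                "category": category,
                "cohort_rate": cohort_rates[category],
                "reference_rate": reference_rates[category],
                "p_more": float(p_more),
                "p_less": float(p_less),
                "status": status,
            }
        )
    return pd.DataFrame(rows)


def category_comutation(category_matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Significant category pairs by the chi-square co-occurrence test.

    Takes the patient x category binary matrix; reports pair, joint count
    n_xy, statistic, p and direction for pairs at p <= ``alpha``.
    """
    categories = list(category_matrix.columns)
    if len(categories) < 2:
        raise ValueError("need >= 2 categories for co-mutation analysis")
    rows = []
    data = category_matrix.to_numpy(dtype=np.int64)
    for i in range(len(categories)):
        for j in range(i + 1, len(categories)):
            x, y = data[:, i], data[:, j]
            table = ContingencyTable2x2(
                a=int(np.sum((x == 1) & (y == 1))),
                b=int(np.sum((x == 1) & (y == 0))),
                c=int(np.sum((x == 0) & (y == 1))),
                d=int(np.sum((x == 0) & (y == 0))),
            )
            statistic, p, direction = cooccurrence_test(table)
            if p <= alpha:
                rows.append(
                    {
                        "category1": min(categories[i], categories[j]),
                        "category2": max(categories[i], categories[j]),
                        "n_xy": table.a,
                        "statistic": statistic,
                        "p": p,
                        "direction": direction,
                    }
                )
    df = pd.DataFrame(
        rows, columns=["category1", "category2", "n_xy", "statistic", "p", "direction"]
    )
    if len(df):
        df = df.sort_values(["p", "category1", "category2"], kind="mergesort").reset_index(
            drop=True
        )
    return df
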