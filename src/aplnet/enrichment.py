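"""Gene recurrence enrichment against a reference-population carrier table.

Each gene's cohort carrier count k of n patients is tested against the
gene's carrier frequency f0 in a reference population (one-sided exact
binomial: P(X >= k) for X ~ Binomial(n, f0)).  Genes catalogued at zero
frequency are floored at 1/(N_ref + 1) — the add-one estimate for a
carrier count of zero among N_ref reference individuals — so the tail
probability stays positive.  A two-proportion Fisher variant is available
for sensitivity analysis.  Carrier (per-individual) semantics are assumed
for the reference frequencies throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import MutationMatrix

DEFAULT_N_REF = 2504  # phase-3 reference panel size


class ReferenceFrequencies:
    """Per-gene carrier frequencies in a reference cohort of ``n_ref`` individuals."""

    def __init__(self, freqs: Mapping[str, float], n_ref: int = DEFAULT_N_REF) -> None:
        if n_ref < 1:
            raise ValueError(f"n_ref must be >= 1, got {n_ref}")
        for gene, f0 in freqs.items():
            if not 0.0 <= f0 <= 1.0:
                raise ValueError(f"frequency for {gene!r} outside [0, 1]: {f0}")
        self._freqs = dict(freqs)
        self.n_ref = int(n_ref)

    def get(self, gene: str, default: float = 0.0) -> float:
        return self._freqs.get(gene, default)

    def __contains__(self, gene: str) -> bool:
        return gene in self._freqs

    @property
    def genes(self) -> list[str]:
        return list(self._freqs)

    @property
    def floor(self) -> float:
        """Zero-frequency floor: 1/(n_ref + 1)."""
        return 1.0 / (self.n_ref + 1)

    def to_tsv(self, path: str | Path, percent: bool = False) -> None:
        col = "frequency_pct" if percent else "frequency"
        scale = 100.0 if percent else 1.0
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# n_ref={self.n_ref}\n")
            fh.write(f"gene\t{col}\n")
            for gene in sorted(self._freqs):
                fh.write(f"{gene}\t{self._freqs[gene] * scale:.10g}\n")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        gene_col: str = "gene",
        freq_col: str | None = None,
        n_ref: int | None = None,
    ) -> "ReferenceFrequencies":
        """Read a gene/frequency TSV.

        Percent vs fraction is resolved by the header token: a column named
        with a ``%`` or ``_pct`` suffix holds percentages; plain
        ``frequency`` holds fractions.  ``n_ref`` may come from a leading
        ``# n_ref=...`` comment line.
        """
        file_n_ref = None
        with open(path, encoding="utf-8") as fh:
            head = fh.readline()
            while head.startswith("#"):
                token = head.lstrip("#").strip()
                if token.startswith("n_ref="):
                    file_n_ref = int(token.split("=", 1)[1])
                head = fh.readline()
        df = pd.read_csv(path, sep="\t", comment="#")
        if freq_col is None:
            candidates = [
                c for c in df.columns if "%" in c or c.lower().endswith("_pct")
                or c.lower().startswith("frequency")
            ]
            if not candidates:
                raise ValueError(f"{path}: no frequency column found in {list(df.columns)}")
            freq_col = candidates[0]
        percent = "%" in freq_col or freq_col.lower().endswith("_pct")
        scale = 0.01 if percent else 1.0
        freqs = {
            str(row[gene_col]): float(row[freq_col]) * scale for _, row in df.iterrows()
        }
        return cls(freqs, n_ref=n_ref or file_n_ref or DEFAULT_N_REF)


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of one gene's recurrence test."""

    gene: str
    n: int
    k: int
    f0: float
    f0_used: float
    p_value: float
    alpha: float
    q_value: float | None = None

    @property
    def cohort_freq(self) -> float:
        return self.k / self.n if self.n else 0.0

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha


def binomial_tail(k: int, n: int, p0: float) -> float:
    """Upper binomial tail P(X >= k), X ~ Binomial(n, p0).

    Computed through the regularized-beta survival function, numerically
    stable far into the tail (agrees with direct summation to better than
    1e-10 relative error).  ``p0 = 0`` is rejected: callers must floor a
    zero reference frequency first.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 <= 1.0:
        raise ValueError(f"require 0 < p0 <= 1, got {p0} (floor zero frequencies first)")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def enrichment_test(
    gene: str,
    matrix: MutationMatrix,
    ref: ReferenceFrequencies,
    alpha: float = 0.05,
    zero_floor: float | None = None,
) -> EnrichmentResult:
    """Test one gene's cohort carrier count against its reference frequency.

    A gene missing from the reference table is treated as frequency 0 and
    floored.  The floor defaults to ``1/(n_ref + 1)``.
    """
    if gene not in matrix.df.columns:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    floor = ref.floor if zero_floor is None else zero_floor
    f0 = ref.get(gene, 0.0)
    f0_used = max(f0, floor)
    k = int(matrix.column(gene).sum())
    n = matrix.n_patients
    return EnrichmentResult(
        gene=gene, n=n, k=k, f0=f0, f0_used=f0_used,
        p_value=binomial_tail(k, n, f0_used), alpha=alpha,
    )


def fisher_enrichment_test(
    gene: str,
    matrix: MutationMatrix,
    ref: ReferenceFrequencies,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Two-proportion alternative: one-sided Fisher exact test of cohort
    carriers k/n against reference carriers round(f0*N_ref)/N_ref."""
    if gene not in matrix.df.columns:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    k = int(matrix.column(gene).sum())
    n = matrix.n_patients
    f0 = ref.get(gene, 0.0)
    k_ref = int(round(f0 * ref.n_ref))
    _, p = stats.fisher_exact(
        [[k, n - k], [k_ref, ref.n_ref - k_ref]], alternative="greater"
    )
    return EnrichmentResult(
        gene=gene, n=n, k=k, f0=f0, f0_used=max(f0, ref.floor),
        p_value=float(p), alpha=alpha,
    )


def screen_cohort(
    matrix: MutationMatrix,
    ref: ReferenceFrequencies,
    alpha: float = 0.05,
    method: str = "binomial",
    zero_floor: float | None = None,
) -> list[EnrichmentResult]:
    """Run the recurrence screen over every gene in the matrix.

    Results come back sorted by (p-value, gene symbol), each carrying a
    Benjamini-Hochberg q-value; the significance flag uses the raw p-value
    at ``alpha``.
    """
    if method == "binomial":
        results = [
            enrichment_test(g, matrix, ref, alpha, zero_floor) for g in matrix.genes
        ]
    elif method == "fisher":
        results = [fisher_enrichment_test(g, matrix, ref, alpha) for g in matrix.genes]
    else:
        raise ValueError(f"unknown method {method!r}")
    pvals = np.array([r.p_value for r in results])
    qvals = stats.false_discovery_control(pvals) if len(pvals) else np.array([])
    results = [
        EnrichmentResult(
            gene=r.gene, n=r.n, k=r.k, f0=r.f0, f0_used=r.f0_used,
            p_value=r.p_value, alpha=r.alpha, q_value=float(q),
        )
        for r, q in zip(results, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.gene))


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate screen results (frequencies in percent, as printed reports do)."""
    rows = [
        {
            "gene": r.gene,
            "k": r.k,
            "n": r.n,
            "cohort_frequency_pct": 100.0 * r.cohort_freq,
            "reference_frequency_pct": 100.0 * r.f0,
            "p": r.p_value,
            "q": r.q_value,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
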