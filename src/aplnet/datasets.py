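"""Bundled example data: a published-style recurrence screen and filter audit.

Two small plain-text tables ship with the package:

* ``recurrence_screen_cohort.tsv`` — carrier frequencies (percent) of 15
  recurrently mutated genes in a 25-patient APL cohort together with
  their carrier frequencies in the 1000-genomes reference population and
  a functional-category label per gene.
* ``discovery_audit.tsv`` — per-patient surviving-variant counts of the
  filter cascade on a five-patient matched whole-exome discovery cohort.

These double as documentation examples and as regression fixtures for the
screen and audit arithmetic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .categories import CategoryMap
from .enrichment import ReferenceFrequencies
from .filtering import FilterAudit
from .matrix import MutationMatrix

_SCREEN = "recurrence_screen_cohort.tsv"
_AUDIT = "discovery_audit.tsv"


def _data_path(name: str):
    return resources.files("aplnet.data").joinpath(name)


def load_screen_table() -> pd.DataFrame:
    """The raw bundled screen table (frequencies in percent)."""
    with resources.as_file(_data_path(_SCREEN)) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_screen_reference() -> ReferenceFrequencies:
    """Reference-population carrier frequencies of the screen genes."""
    with resources.as_file(_data_path(_SCREEN)) as path:
        return ReferenceFrequencies.from_tsv(
            path, gene_col="gene", freq_col="reference_frequency_pct"
        )


def load_screen_cohort_matrix(n_patients: int = 25) -> MutationMatrix:
    """Cohort mutation matrix reconstructed from the printed carrier percentages.

    Each gene's carrier count is round(pct/100 * n_patients); carriers are
    assigned to the first k patients (the screen statistics depend only on
    column sums).
    """
    table = load_screen_table()
    genes = list(table["gene"])
    patients = [f"APL_{i + 1:02d}" for i in range(n_patients)]
    data = np.zeros((n_patients, len(genes)), dtype=np.int8)
    for j, pct in enumerate(table["cohort_frequency_pct"]):
        k = int(round(float(pct) / 100.0 * n_patients))
        data[:k, j] = 1
    return MutationMatrix(pd.DataFrame(data, index=patients, columns=genes))


def load_category_map() -> CategoryMap:
    """Functional-category labels of the bundled screen genes."""
    table = load_screen_table()
    mapping: dict[str, set[str]] = {}
    for _, row in table.iterrows():
        mapping.setdefault(str(row["gene"]), set()).add(str(row["category"]))
    return CategoryMap(mapping)


def load_discovery_audit() -> FilterAudit:
    """Per-patient filter-cascade counts of the discovery cohort."""
    with resources.as_file(_data_path(_AUDIT)) as path:
        return FilterAudit.from_tsv(path)
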