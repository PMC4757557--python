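"""Binary patient x gene mutation matrix, the common currency of all statistics."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


class MutationMatrix:
    """Binary incidence matrix: entry 1 = patient carries >=1 retained variant in gene.

    Thin wrapper around a patients-in-rows :class:`pandas.DataFrame` that
    enforces binary entries and unique labels.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        if df.index.has_duplicates:
            raise ValueError("duplicate patient labels")
        if df.columns.has_duplicates:
            raise ValueError("duplicate gene labels")
        values = df.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")
        self._df = df.astype(np.int8)
        self._df.index.name = "patient"

    # -- accessors ----------------------------------------------------------

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def patients(self) -> list[str]:
        return list(self._df.index)

    @property
    def genes(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_patients(self) -> int:
        return len(self._df.index)

    def column(self, gene: str) -> np.ndarray:
        if gene not in self._df.columns:
            raise KeyError(f"gene {gene!r} not in matrix")
        return self._df[gene].to_numpy()

    def carrier_counts(self) -> pd.Series:
        """Mutated-patient count per gene."""
        return self._df.sum(axis=0)

    def recurrent_genes(self, min_patients: int = 2) -> list[str]:
        """Genes mutated in at least ``min_patients`` patients."""
        counts = self.carrier_counts()
        return sorted(counts.index[counts >= min_patients])

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MutationMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"MutationMatrix({self.n_patients} patients x {len(self.genes)} genes)"

    # -- I/O ----------------------------------------------------------------

    def to_tsv(self, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
        """Write as TSV, patients in rows; metadata as leading '# key=value' lines."""
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}={value}\n")
            self._df.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        df.index = df.index.astype(str)
        return cls(df)

    @classmethod
    def from_carriers(
        cls,
        carriers: Mapping[str, set[str] | frozenset[str]],
        patients: list[str] | None = None,
        genes: list[str] | None = None,
    ) -> "MutationMatrix":
        """Build from a patient -> mutated-gene-set mapping."""
        patients = list(patients) if patients is not None else sorted(carriers)
        if genes is None:
            genes = sorted({g for gs in carriers.values() for g in gs})
        data = np.zeros((len(patients), len(genes)), dtype=np.int8)
        gene_index = {g: j for j, g in enumerate(genes)}
        for i, patient in enumerate(patients):
            for gene in carriers.get(patient, ()):
                if gene in gene_index:
                    data[i, gene_index[gene]] = 1
        return cls(pd.DataFrame(data, index=patients, columns=genes))
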