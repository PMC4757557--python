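"""Somatic variant filter cascade with an auditable per-stage count report.

The cascade applies, in order:

1. ``Variants detected`` — everything the caller emitted.
2. ``Somatic`` — population-database germline screen: calls whose catalogued
   population carrier frequency reaches ``max_pop_freq`` are removed as
   likely germline.
3. ``Absent in CR`` — matched mode: subtraction of calls still observed in
   the complete-remission (CR) sample; unmatched mode: the germinality
   heuristic removes calls whose allele fraction sits in a germline band
   (heterozygous ~0.5 or homozygous ~1.0).
4. ``High quality`` — site-level quality predicates (depth, call quality,
   strand bias, allele fraction).
5. ``Coding (SNVs+indels)`` — consequence-class filter.
6. ``Deleterious (SNVs+indels)`` — deleteriousness flag, with truncating
   consequences kept regardless of the flag.
7. ``Unknown in dbSNP`` — removal of catalogued known variants.

Each stage's output is a subset of its input, so per-patient audit counts
are non-increasing down the cascade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .calls import CONSEQUENCES, TRUNCATING, SamplePair, VariantCall
from .matrix import MutationMatrix

#: Audit stage labels, in cascade order (report layout).
STAGE_LABELS: tuple[str, ...] = (
    "Variants detected",
    "Somatic",
    "Absent in CR",
    "High quality",
    "Coding (SNVs+indels)",
    "Deleterious (SNVs+indels)",
    "Unknown in dbSNP",
)

#: Consequence classes counted as coding for the cascade.
CODING_CONSEQUENCES = frozenset(
    {"nonsynonymous", "stop_gain", "frameshift", "inframe_indel", "splice_site"}
)

#: Transition base pairs; all other single-base changes are transversions.
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


class UnmatchedModeError(ValueError):
    """Raised when matched-remission subtraction is requested without a
    remission sample; unmatched cohorts go through `germline_heuristic`."""


class ConfigError(ValueError):
    """Invalid filter configuration."""


@dataclass
class FilterConfig:
    """Thresholds for the filter cascade.

    VAF bands and the population-frequency ceiling drive the germinality
    test used when no matched remission sample exists.
    """

    max_pop_freq: float = 0.01
    absence_max_alt_reads: int = 1
    absence_max_vaf: float = 0.02
    min_depth: int = 10
    min_qual: float = 30.0
    max_strand_bias: float = 0.9
    min_vaf: float = 0.05
    coding_keep: frozenset[str] = CODING_CONSEQUENCES
    germline_vaf_bands: tuple[tuple[float, float], ...] = ((0.45, 0.55), (0.95, 1.0))
    matched: bool = True
    allow_mixed: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.coding_keep) - CONSEQUENCES
        if unknown:
            raise ConfigError(f"unknown consequence labels in keep-set: {sorted(unknown)}")
        for name in ("max_pop_freq", "absence_max_vaf", "min_vaf", "max_strand_bias"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.min_depth < 0 or self.absence_max_alt_reads < 0:
            raise ConfigError("count thresholds must be non-negative")


# ---------------------------------------------------------------------------
# Individual filter operations
# ---------------------------------------------------------------------------


def population_screen(
    calls: Iterable[VariantCall], max_pop_freq: float = 0.01
) -> list[VariantCall]:
    """Remove calls catalogued at population carrier frequency >= ``max_pop_freq``.

    Calls with no catalogued frequency are retained.
    """
    return [c for c in calls if c.pop_freq is None or c.pop_freq < max_pop_freq]


def subtract_matched_remission(
    pair: SamplePair,
    absence_max_alt_reads: int = 1,
    absence_max_vaf: float = 0.02,
) -> list[VariantCall]:
    """Retain diagnosis calls absent from the matched remission sample.

    Variant identity is the normalized ``(chrom, pos, ref, alt)`` tuple.  A
    locus observed in remission still counts as absent when its remission
    alt support is at noise level (``alt_depth <= absence_max_alt_reads``
    and ``VAF < absence_max_vaf``); strict zero would be unstable at
    moderate coverage.
    """
    if pair.remission is None:
        raise UnmatchedModeError(
            f"patient {pair.patient_id!r} has no remission sample; use "
            "germline_heuristic for unmatched cohorts"
        )
    if absence_max_alt_reads < 0 or absence_max_vaf < 0:
        raise ValueError("absence thresholds must be non-negative")
    remission_by_key: dict[tuple, VariantCall] = {c.key: c for c in pair.remission}
    retained = []
    for call in pair.diagnosis:
        rem = remission_by_key.get(call.key)
        if rem is None or (
            rem.alt_depth <= absence_max_alt_reads and rem.vaf < absence_max_vaf
        ):
            retained.append(call)
    return retained


def germline_heuristic(
    calls: Iterable[VariantCall],
    max_pop_freq: float = 0.01,
    germline_vaf_bands: Sequence[tuple[float, float]] = ((0.45, 0.55), (0.95, 1.0)),
) -> list[VariantCall]:
    """Germinality test for unmatched cohorts.

    Removes calls catalogued at population frequency >= ``max_pop_freq``
    and calls whose allele fraction lies in a germline band (heterozygous
    ~0.5 or homozygous ~1.0 by default).  Calls with no catalogued
    frequency are retained unless band-excluded.
    """
    retained = []
    for call in calls:
        if call.pop_freq is not None and call.pop_freq >= max_pop_freq:
            continue
        if any(lo <= call.vaf <= hi for lo, hi in germline_vaf_bands):
            continue
        retained.append(call)
    return retained


def apply_site_filters(
    calls: Iterable[VariantCall],
    min_depth: int = 10,
    min_qual: float = 0.0,
    max_strand_bias: float = 1.0,
    min_vaf: float = 0.0,
) -> list[VariantCall]:
    """Retain calls passing all four site-quality predicates."""
    return [
        c
        for c in calls
        if c.depth >= min_depth
        and c.qual >= min_qual
        and c.strand_bias <= max_strand_bias
        and c.vaf >= min_vaf
    ]


def classify_and_filter_consequence(
    calls: Iterable[VariantCall],
    keep: frozenset[str] | set[str] = CODING_CONSEQUENCES,
) -> list[VariantCall]:
    """Retain calls whose consequence class is in ``keep``."""
    unknown = set(keep) - CONSEQUENCES
    if unknown:
        raise ConfigError(f"unknown consequence labels in keep-set: {sorted(unknown)}")
    return [c for c in calls if c.consequence in keep]


def deleterious_filter(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Retain flagged-deleterious calls; truncating consequences always pass."""
    return [c for c in calls if c.deleterious or c.consequence in TRUNCATING]


def unknown_in_dbsnp(calls: Iterable[VariantCall]) -> list[VariantCall]:
    """Retain calls absent from the known-variants catalogue."""
    return [c for c in calls if not c.known]


def ti_tv_ratio(calls: Iterable[VariantCall]) -> float | None:
    """Transition/transversion ratio over SNVs.

    Transitions are A<->G and C<->T; every other single-base change is a
    transversion.  Returns ``None`` (undefined) when there are no
    transversions, rather than raising.
    """
    transitions = transversions = 0
    for call in calls:
        if call.vclass != "SNV":
            continue
        change = (call.ref.upper(), call.alt.upper())
        if change[0] == change[1]:
            continue
        if change in _TRANSITIONS:
            transitions += 1
        else:
            transversions += 1
    if transversions == 0:
        return None
    return transitions / transversions


# ---------------------------------------------------------------------------
# Audit report
# ---------------------------------------------------------------------------


class FilterAudit:
    """Per-stage, per-patient surviving-variant counts for the cascade.

    Serializes as a TSV with stages in rows, patients in columns, and a
    final Total column.
    """

    def __init__(self, counts: pd.DataFrame) -> None:
        if set(counts.index) != set(STAGE_LABELS):
            raise ValueError(
                f"audit stages must be exactly {STAGE_LABELS}, got {list(counts.index)}"
            )
        counts = counts.reindex(list(STAGE_LABELS))
        diffs = counts.diff(axis=0).iloc[1:]
        if (diffs.to_numpy() > 0).any():
            raise ValueError("per-patient audit counts must be non-increasing across stages")
        self._counts = counts.astype(int)

    @property
    def counts(self) -> pd.DataFrame:
        """Stage x patient counts (no Total column)."""
        return self._counts

    @property
    def patients(self) -> list[str]:
        return list(self._counts.columns)

    @property
    def totals(self) -> pd.Series:
        """Per-stage sums over patients (the printed Total column)."""
        return self._counts.sum(axis=1)

    def total(self, stage: str) -> int:
        return int(self.totals[stage])

    def mean_per_patient(self, stage: str) -> float:
        """Mean surviving variants per patient at a stage."""
        return float(self._counts.loc[stage].mean())

    def to_frame(self) -> pd.DataFrame:
        out = self._counts.copy()
        out["Total"] = self.totals
        return out

    def to_tsv(self, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key, value in (metadata or {}).items():
                fh.write(f"# {key}={value}\n")
            frame = self.to_frame()
            frame.index.name = "Filter"
            frame.to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FilterAudit":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        if "Total" in df.columns:
            df = df.drop(columns="Total")
        return cls(df)


# ---------------------------------------------------------------------------
# Cascade
# ---------------------------------------------------------------------------


def run_cascade(
    cohort: Sequence[SamplePair],
    config: FilterConfig | None = None,
) -> tuple[FilterAudit, dict[str, list[VariantCall]]]:
    """Run the seven-stage filter cascade over a cohort.

    Returns the audit report and the retained calls per patient (the
    survivors of the final stage).  Matched and unmatched patients may be
    mixed only when ``config.allow_mixed`` is set.
    """
    config = config or FilterConfig()
    matched_flags = {pair.matched for pair in cohort}
    if len(matched_flags) > 1 and not config.allow_mixed:
        raise ConfigError(
            "cohort mixes matched and unmatched patients; set allow_mixed to permit"
        )
    if not config.allow_mixed and cohort and config.matched != cohort[0].matched:
        raise ConfigError(
            f"config declares matched={config.matched} but cohort is not; "
            "set allow_mixed to permit"
        )

    counts: dict[str, list[int]] = {stage: [] for stage in STAGE_LABELS}
    retained: dict[str, list[VariantCall]] = {}
    for pair in cohort:
        calls = list(pair.diagnosis)
        counts["Variants detected"].append(len(calls))
        calls = population_screen(calls, config.max_pop_freq)
        counts["Somatic"].append(len(calls))
        if pair.matched:
            calls_pair = SamplePair(pair.patient_id, calls, pair.remission)
            calls = subtract_matched_remission(
                calls_pair, config.absence_max_alt_reads, config.absence_max_vaf
            )
        else:
            calls = germline_heuristic(
                calls, config.max_pop_freq, config.germline_vaf_bands
            )
        counts["Absent in CR"].append(len(calls))
        calls = apply_site_filters(
            calls,
            config.min_depth,
            config.min_qual,
            config.max_strand_bias,
            config.min_vaf,
        )
        counts["High quality"].append(len(calls))
        calls = classify_and_filter_consequence(calls, config.coding_keep)
        counts["Coding (SNVs+indels)"].append(len(calls))
        calls = deleterious_filter(calls)
        counts["Deleterious (SNVs+indels)"].append(len(calls))
        calls = unknown_in_dbsnp(calls)
        counts["Unknown in dbSNP"].append(len(calls))
        retained[pair.patient_id] = calls

    audit = FilterAudit(
        pd.DataFrame(
            counts, index=[p.patient_id for p in cohort]
        ).T.reindex(list(STAGE_LABELS))
    )
    return audit, retained


def to_mutation_matrix(
    retained: Mapping[str, Iterable[VariantCall]],
    extra_events: Mapping[str, Iterable[str]] | None = None,
    genes: Sequence[str] | None = None,
) -> MutationMatrix:
    """Collapse retained calls (plus injected gene-level events) to a binary matrix.

    ``extra_events`` lets diagnostics-derived gene hits (fusion partners,
    internal tandem duplications) enter the matrix for patients without a
    sequence-level call in that gene.
    """
    carriers: dict[str, set[str]] = {}
    for patient, calls in retained.items():
        gene_set = set()
        for call in calls:
            if not call.gene:
                raise ValueError(
                    f"retained call {call.chrom}:{call.pos} for patient "
                    f"{patient!r} has no gene symbol"
                )
            gene_set.add(call.gene)
        carriers[patient] = gene_set
    for patient, extra in (extra_events or {}).items():
        carriers.setdefault(patient, set()).update(extra)
    return MutationMatrix.from_carriers(
        carriers,
        patients=list(carriers),
        genes=list(genes) if genes is not None else None,
    )
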