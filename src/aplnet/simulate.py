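"""Synthetic cohorts, reference tables, interactomes and variant fixtures.

Every input the pipeline consumes can be generated here with planted,
labelled structure, so each stage is testable against exact truth:

* cohort mutation matrices — independent Bernoulli gene columns at
  background carrier rates, with planted enriched genes (multiplied rate)
  and planted co-occurring pairs (joint carriers forced in an exact number
  of patients, so the joint count ``a`` is known exactly);
* reference carrier-frequency tables with a stated reference cohort size;
* interactomes — a background random graph with a densified planted
  module;
* matched diagnosis/remission variant-call fixtures in which every variant
  carries a truth tag naming the cascade stage (if any) at which it must
  be removed.

All generation is reproducible from (spec, seed); seeds are recorded in
output metadata.  Default cohort dimensions mirror a small acute-leukemia
resequencing cohort: 25 patients, 72 genes, background carrier rate 0.08.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .calls import SamplePair, VariantCall, write_vcf
from .enrichment import DEFAULT_N_REF, ReferenceFrequencies
from .matrix import MutationMatrix
from .network import Interactome


def default_gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Cohort matrices
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Planted-structure cohort description.

    ``planted_enriched`` maps gene -> rate multiplier (applied to the
    gene's background rate, capped at 1).  ``planted_pairs`` entries are
    (gene1, gene2, joint_carrier_count); the stated number of patients is
    forced to carry both genes and no other patient carries both, so the
    realized joint count is exact.
    """

    n_patients: int = 25
    genes: list[str] = field(default_factory=lambda: default_gene_names(72))
    background_rate: float | Mapping[str, float] = 0.08
    planted_enriched: Mapping[str, float] = field(default_factory=dict)
    planted_pairs: Sequence[tuple[str, str, int]] = field(default_factory=tuple)
    rng_seed: int = 0

    def rate_of(self, gene: str) -> float:
        base = (
            self.background_rate
            if isinstance(self.background_rate, (int, float))
            else self.background_rate.get(gene, 0.0)
        )
        rate = float(base) * self.planted_enriched.get(gene, 1.0)
        return min(rate, 1.0)

    def validate(self) -> None:
        gene_set = set(self.genes)
        if len(gene_set) != len(self.genes):
            raise ValueError("duplicate gene names")
        for gene in self.planted_enriched:
            if gene not in gene_set:
                raise ValueError(f"planted enriched gene {gene!r} not in gene list")
        for g1, g2, count in self.planted_pairs:
            if g1 not in gene_set or g2 not in gene_set:
                raise ValueError(f"planted pair ({g1}, {g2}) not in gene list")
            if count > self.n_patients:
                raise ValueError(
                    f"planted pair ({g1}, {g2}) count {count} exceeds "
                    f"{self.n_patients} patients"
                )
        for gene in self.genes:
            if not 0.0 <= self.rate_of(gene) <= 1.0:
                raise ValueError(f"rate for {gene!r} outside [0, 1]")


@dataclass
class CohortTruth:
    """Planted structure labels carried alongside a generated matrix."""

    enriched: dict[str, float]  # gene -> realized carrier rate used
    pairs: list[tuple[str, str, int]]  # exact joint-carrier counts
    rng_seed: int


def generate_cohort(spec: CohortSpec) -> tuple[MutationMatrix, CohortTruth]:
    """Draw a cohort mutation matrix with the requested planted structure."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    rates = np.array([spec.rate_of(g) for g in spec.genes])
    data = (rng.random((spec.n_patients, len(spec.genes))) < rates).astype(np.int8)
    gene_index = {g: j for j, g in enumerate(spec.genes)}
    for g1, g2, count in spec.planted_pairs:
        j1, j2 = gene_index[g1], gene_index[g2]
        joint = rng.choice(spec.n_patients, size=count, replace=False)
        solo = np.setdiff1d(np.arange(spec.n_patients), joint)
        # clear accidental joint carriers outside the forced set, keep solo hits
        both = solo[(data[solo, j1] == 1) & (data[solo, j2] == 1)]
        half = len(both) // 2
        data[both[:half], j1] = 0
        data[both[half:], j2] = 0
        data[joint, j1] = 1
        data[joint, j2] = 1
    matrix = MutationMatrix(pd.DataFrame(data, index=patients, columns=list(spec.genes)))
    truth = CohortTruth(
        enriched={g: spec.rate_of(g) for g in spec.planted_enriched},
        pairs=[(g1, g2, c) for g1, g2, c in spec.planted_pairs],
        rng_seed=spec.rng_seed,
    )
    return matrix, truth


def generate_reference(
    genes: Sequence[str],
    base_frequencies: float | Mapping[str, float] = 0.01,
    n_ref: int = DEFAULT_N_REF,
) -> ReferenceFrequencies:
    """Reference carrier-frequency table (zero frequencies allowed, to
    exercise the floor rule downstream)."""
    if isinstance(base_frequencies, (int, float)):
        freqs = {g: float(base_frequencies) for g in genes}
    else:
        freqs = {g: float(base_frequencies.get(g, 0.0)) for g in genes}
    return ReferenceFrequencies(freqs, n_ref=n_ref)


# ---------------------------------------------------------------------------
# Interactomes
# ---------------------------------------------------------------------------


@dataclass
class InteractomeSpec:
    """Random interactome with a planted densely connected module."""

    n_nodes: int = 150
    background_p: float = 0.02
    module: Sequence[str] = field(default_factory=tuple)
    module_p: float = 0.6
    node_names: Sequence[str] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.background_p <= 1.0 or not 0.0 <= self.module_p <= 1.0:
            raise ValueError("edge probabilities must be in [0, 1]")
        names = self.resolved_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        missing = set(self.module) - set(names)
        if missing:
            raise ValueError(f"module nodes not among node names: {sorted(missing)}")

    def resolved_names(self) -> list[str]:
        if self.node_names is not None:
            return list(self.node_names)
        names = default_gene_names(self.n_nodes, prefix="N")
        # planted module nodes replace the tail of the default namespace
        module = [m for m in self.module if m not in names]
        return names[: self.n_nodes - len(module)] + module


def generate_interactome(spec: InteractomeSpec) -> Interactome:
    """Background G(n, p) graph densified inside the planted module."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    names = spec.resolved_names()
    module = set(spec.module)
    edges = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = (
                spec.module_p
                if names[i] in module and names[j] in module
                else spec.background_p
            )
            if rng.random() < p:
                edges.append((names[i], names[j]))
    graph = nx.Graph()
    graph.add_nodes_from(names)  # keep isolated nodes in the node set
    graph.add_edges_from(edges)
    return Interactome(graph)


# ---------------------------------------------------------------------------
# Variant-call fixtures for the filter cascade
# ---------------------------------------------------------------------------

#: Cascade stage names accepted as planted failure labels.
FAILURE_STAGES = (
    "Somatic",
    "Absent in CR",
    "High quality",
    "Coding (SNVs+indels)",
    "Deleterious (SNVs+indels)",
    "Unknown in dbSNP",
)

_BASES = ("A", "C", "G", "T")


def _base_call(chrom: str, pos: int, gene: str, rng: np.random.Generator, **overrides):
    ref, alt = "C", "T"
    defaults = dict(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence="nonsynonymous",
        depth=60,
        alt_depth=24,
        qual=60.0,
        strand_bias=float(rng.uniform(0.0, 0.3)),
        known=False,
        pop_freq=None,
        deleterious=True,
    )
    defaults.update(overrides)
    return VariantCall(**defaults)


def generate_variant_fixtures(
    n_patients: int = 5,
    genes: Sequence[str] | None = None,
    somatic_per_patient: int = 8,
    failures_per_stage: Mapping[str, int] | None = None,
    rng_seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[SamplePair], dict[str, dict[tuple[str, int, str, str], str | None]]]:
    """Matched diagnosis/remission pairs with per-variant truth tags.

    Each diagnosis variant either survives the whole cascade (truth tag
    ``None``/"somatic") or is built to fail at exactly one named stage
    (passing every other stage's predicate), so the cascade's per-stage
    removal counts must equal the planted counts.  With ``out_dir`` set,
    ``<patient>.diagnosis.vcf`` / ``<patient>.remission.vcf`` files are
    written with TRUTH tags.
    """
    genes = list(genes) if genes is not None else default_gene_names(50)
    if failures_per_stage is None:
        failures_per_stage = {s: 2 for s in FAILURE_STAGES}
    failures = dict(failures_per_stage)
    unknown = set(failures) - set(FAILURE_STAGES)
    if unknown:
        raise ValueError(f"unknown failure stages: {sorted(unknown)}")
    rng = np.random.default_rng(rng_seed)
    pairs: list[SamplePair] = []
    truth: dict[str, dict[tuple[str, int, str, str], str | None]] = {}

    for i in range(n_patients):
        patient = f"P{i:03d}"
        diagnosis: list[VariantCall] = []
        remission: list[VariantCall] = []
        tags: dict[tuple[str, int, str, str], str | None] = {}
        pos = 1000
        gene_cycle = iter(genes * 1000)

        def add(call: VariantCall, tag: str | None) -> None:
            diagnosis.append(call)
            tags[(call.chrom, call.pos, call.ref, call.alt)] = tag

        for _ in range(somatic_per_patient):
            pos += int(rng.integers(50, 500))
            add(_base_call("1", pos, next(gene_cycle), rng), None)
        for stage, count in failures.items():
            for _ in range(count):
                pos += int(rng.integers(50, 500))
                gene = next(gene_cycle)
                if stage == "Somatic":
                    call = _base_call("1", pos, gene, rng, pop_freq=0.3)
                elif stage == "Absent in CR":
                    call = _base_call("1", pos, gene, rng)
                    remission.append(
                        VariantCall(
                            chrom="1", pos=pos, ref=call.ref, alt=call.alt,
                            gene=gene, consequence=call.consequence,
                            depth=60, alt_depth=27, qual=60.0,
                            strand_bias=0.1, deleterious=call.deleterious,
                        )
                    )
                elif stage == "High quality":
                    call = _base_call("1", pos, gene, rng, depth=6, alt_depth=3)
                elif stage == "Coding (SNVs+indels)":
                    call = _base_call("1", pos, gene, rng, consequence="synonymous",
                                      deleterious=False)
                elif stage == "Deleterious (SNVs+indels)":
                    call = _base_call("1", pos, gene, rng, deleterious=False)
                else:  # Unknown in dbSNP
                    call = _base_call("1", pos, gene, rng, known=True)
                add(call, stage)
        pair = SamplePair(patient, diagnosis, remission)
        pairs.append(pair)
        truth[patient] = tags
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            vcf_tags = {k: (v or "somatic") for k, v in tags.items()}
            write_vcf(out_dir / f"{patient}.diagnosis.vcf", diagnosis, truth_tags=vcf_tags)
            write_vcf(out_dir / f"{patient}.remission.vcf", remission)
    return pairs, truth


def generate_unmatched_calls(
    n_patients: int = 200,
    somatic_per_patient: int = 14,
    germline_per_patient: int = 6,
    catalogued_germline_fraction: float = 0.85,
    homozygous_fraction: float = 0.2,
    depth: int = 60,
    rng_seed: int = 0,
) -> tuple[dict[str, list[VariantCall]], dict[str, set[tuple[str, int, str, str]]]]:
    """Unmatched cohort with a planted germline fraction, for the germinality test.

    Germline variants draw allele fractions from binomial sampling around
    heterozygous (0.5) or homozygous (~1.0) truth at the given depth; most
    carry a catalogued population frequency >= 1%.  Somatic variants sit at
    subclonal fractions (~0.35) and are uncatalogued.  Returns calls per
    patient and the planted germline identity keys.
    """
    rng = np.random.default_rng(rng_seed)
    calls: dict[str, list[VariantCall]] = {}
    germline_keys: dict[str, set[tuple[str, int, str, str]]] = {}
    for i in range(n_patients):
        patient = f"P{i:03d}"
        patient_calls: list[VariantCall] = []
        keys: set[tuple[str, int, str, str]] = set()
        pos = 1000
        for _ in range(somatic_per_patient):
            pos += int(rng.integers(50, 500))
            alt_depth = int(rng.binomial(depth, 0.35))
            patient_calls.append(
                _base_call("1", pos, "GENE", rng, depth=depth,
                           alt_depth=alt_depth, pop_freq=None)
            )
        for _ in range(germline_per_patient):
            pos += int(rng.integers(50, 500))
            true_vaf = 0.99 if rng.random() < homozygous_fraction else 0.5
            alt_depth = int(rng.binomial(depth, true_vaf))
            pop_freq = (
                float(rng.uniform(0.01, 0.5))
                if rng.random() < catalogued_germline_fraction
                else None
            )
            call = _base_call("1", pos, "GENE", rng, depth=depth,
                              alt_depth=alt_depth, pop_freq=pop_freq)
            patient_calls.append(call)
            keys.add((call.chrom, call.pos, call.ref, call.alt))
        calls[patient] = patient_calls
        germline_keys[patient] = keys
    return calls, germline_keys
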