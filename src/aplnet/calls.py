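"""Annotated variant-call records and VCF input/output.

A :class:`VariantCall` is one annotated variant observation in one sample,
carrying the site metrics (depth, allele depth, quality, strand bias) and
annotation fields (gene symbol, consequence class, deleteriousness flag,
known-variant membership, population carrier frequency) that the somatic
filter cascade consumes.  Coordinates are 1-based, VCF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

#: Consequence vocabulary used by the filter cascade.
CONSEQUENCES = frozenset(
    {
        "nonsynonymous",
        "synonymous",
        "stop_gain",
        "frameshift",
        "inframe_indel",
        "splice_site",
        "ncRNA",
        "intergenic",
        "other",
    }
)

#: Truncating consequences, treated as deleterious regardless of the
#: upstream predictor flag.
TRUNCATING = frozenset({"stop_gain", "frameshift", "splice_site"})

#: INFO keys the VCF reader/writer uses, overridable per file via `info_keys`.
DEFAULT_INFO_KEYS: Mapping[str, str] = {
    "gene": "GENE",
    "consequence": "CSQ",
    "depth": "DP",
    "alt_depth": "ALTDP",
    "strand_bias": "SB",
    "known": "KNOWN",
    "pop_freq": "POPFREQ",
    "deleterious": "DELETERIOUS",
    "truth": "TRUTH",
}


class VcfParseError(ValueError):
    """Malformed VCF input; message names the file and record."""


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Normalize an allele pair by trimming shared sequence.

    Trims the shared suffix, then the shared prefix (advancing ``pos``),
    always leaving at least one base in each allele.  This makes variant
    identity ``(chrom, pos, ref, alt)`` robust to redundant padding in the
    caller's representation.  Reference-free: full left-alignment of
    ambiguous indels requires the genome sequence and is not attempted.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant observation in one sample."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    depth: int = 0
    alt_depth: int = 0
    qual: float = 0.0
    strand_bias: float = 0.0
    known: bool = False
    pop_freq: float | None = None
    deleterious: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not 0 <= self.alt_depth <= self.depth:
            raise ValueError(
                f"alt_depth must satisfy 0 <= alt_depth <= depth, "
                f"got {self.alt_depth}/{self.depth}"
            )
        if not 0.0 <= self.strand_bias <= 1.0:
            raise ValueError(f"strand_bias must be in [0, 1], got {self.strand_bias}")
        if self.pop_freq is not None and not 0.0 <= self.pop_freq <= 1.0:
            raise ValueError(f"pop_freq must be in [0, 1], got {self.pop_freq}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def vclass(self) -> str:
        """Variant class: SNV iff both alleles are single bases."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        return "deletion"

    @property
    def vaf(self) -> float:
        """Variant allele fraction; 0 at uncovered sites."""
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity used for subtraction and deduplication."""
        pos, ref, alt = normalize_alleles(self.pos, self.ref, self.alt)
        return (self.chrom, pos, ref, alt)


@dataclass
class SamplePair:
    """Diagnosis calls with an optional matched-remission germline control."""

    patient_id: str
    diagnosis: list[VariantCall] = field(default_factory=list)
    remission: list[VariantCall] | None = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")

    @property
    def matched(self) -> bool:
        return self.remission is not None


# ---------------------------------------------------------------------------
# VCF I/O (pysam).  Single-sample VCFs; site metrics and annotations live in
# INFO under the keys of DEFAULT_INFO_KEYS, quality in the QUAL column.
# ---------------------------------------------------------------------------

_HEADER_INFO = [
    ('##INFO=<ID={gene},Number=1,Type=String,Description="Gene symbol">'),
    ('##INFO=<ID={consequence},Number=1,Type=String,Description="Consequence class">'),
    ('##INFO=<ID={depth},Number=1,Type=Integer,Description="Total read depth">'),
    ('##INFO=<ID={alt_depth},Number=1,Type=Integer,Description="Alt-supporting reads">'),
    ('##INFO=<ID={strand_bias},Number=1,Type=Float,Description="Strand bias in [0,1]">'),
    ('##INFO=<ID={known},Number=0,Type=Flag,Description="Present in known-variant list">'),
    ('##INFO=<ID={pop_freq},Number=1,Type=Float,Description="Population carrier frequency">'),
    ('##INFO=<ID={deleterious},Number=0,Type=Flag,Description="Predicted deleterious">'),
    ('##INFO=<ID={truth},Number=1,Type=String,Description="Planted truth tag (synthetic fixtures)">'),
    ('##INFO=<ID=FILTER_HISTORY,Number=1,Type=String,Description="Cascade stages passed">'),
]


def _build_header(contigs: Sequence[str], info_keys: Mapping[str, str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for line in _HEADER_INFO:
        header.add_line(line.format(**info_keys))
    for contig in contigs:
        header.add_line(f"##contig=<ID={contig}>")
    return header


def write_vcf(
    path: str | Path,
    calls: Iterable[VariantCall],
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
    truth_tags: Mapping[tuple[str, int, str, str], str] | None = None,
    filter_history: str | None = None,
) -> None:
    """Write calls to an uncompressed single-sample VCF.

    ``truth_tags`` optionally maps a call's raw ``(chrom, pos, ref, alt)``
    to a planted-truth label written under the TRUTH key (synthetic
    fixtures); ``filter_history`` is recorded verbatim on every record.
    """
    calls = list(calls)
    contigs = sorted({c.chrom for c in calls})
    header = _build_header(contigs, info_keys)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt)):
            rec = out.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                stop=call.pos - 1 + len(call.ref),
                alleles=(call.ref, call.alt),
            )
            rec.qual = call.qual
            info = rec.info
            if call.gene:
                info[info_keys["gene"]] = call.gene
            info[info_keys["consequence"]] = call.consequence
            info[info_keys["depth"]] = call.depth
            info[info_keys["alt_depth"]] = call.alt_depth
            info[info_keys["strand_bias"]] = call.strand_bias
            if call.known:
                info[info_keys["known"]] = True
            if call.pop_freq is not None:
                info[info_keys["pop_freq"]] = call.pop_freq
            if call.deleterious:
                info[info_keys["deleterious"]] = True
            if truth_tags is not None:
                tag = truth_tags.get((call.chrom, call.pos, call.ref, call.alt))
                if tag is not None:
                    info[info_keys["truth"]] = tag
            if filter_history is not None:
                info["FILTER_HISTORY"] = filter_history
            out.write(rec)


def read_vcf(
    path: str | Path,
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
) -> list[VariantCall]:
    """Read a single-sample VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one call per alternate allele.
    Raises :class:`VcfParseError` naming the file and record on malformed
    input.
    """
    path = str(path)
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"{path}: cannot parse VCF header: {exc}") from exc
    calls: list[VariantCall] = []
    with vcf:
        for i, rec in enumerate(vcf, start=1):
            try:
                info = rec.info
                for alt in rec.alts or ():
                    calls.append(
                        VariantCall(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=info.get(info_keys["gene"], "") or "",
                            consequence=info.get(info_keys["consequence"], "other"),
                            depth=int(info.get(info_keys["depth"], 0)),
                            alt_depth=int(info.get(info_keys["alt_depth"], 0)),
                            # floats round-trip through VCF single precision
                            qual=round(float(rec.qual), 6) if rec.qual is not None else 0.0,
                            strand_bias=round(
                                float(info.get(info_keys["strand_bias"], 0.0)), 6
                            ),
                            known=bool(info.get(info_keys["known"], False)),
                            pop_freq=(
                                round(float(info[info_keys["pop_freq"]]), 6)
                                if info_keys["pop_freq"] in info
                                else None
                            ),
                            deleterious=bool(info.get(info_keys["deleterious"], False)),
                        )
                    )
            except (ValueError, KeyError, TypeError) as exc:
                raise VcfParseError(
                    f"{path}: record {i} ({rec.chrom}:{rec.pos}): {exc}"
                ) from exc
    return calls


def read_truth_tags(
    path: str | Path,
    info_keys: Mapping[str, str] = DEFAULT_INFO_KEYS,
) -> dict[tuple[str, int, str, str], str]:
    """Read planted truth tags from a synthetic fixture VCF."""
    tags: dict[tuple[str, int, str, str], str] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            tag = rec.info.get(info_keys["truth"])
            if tag is not None:
                for alt in rec.alts or ():
                    tags[(rec.chrom, rec.pos, rec.ref, alt)] = str(tag)
    return tags
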