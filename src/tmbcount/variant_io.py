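"""Reading and normalizing per-caller somatic VCFs.

Somatic callers emit the same allele in different shapes: padded,
right-shifted within a repeat, or bundled into a multi-allelic record.
Intersecting caller outputs is only well-defined once every record is
reduced to one canonical representation.  The canonical form used here is
the standard one: multi-allelic records are split, shared prefix/suffix
bases are trimmed down to the mandatory anchor base, and indels are
left-aligned through their homopolymer/repeat context against the
reference.  After normalization two records describe the same allele iff
their ``(contig, pos, ref, alt)`` keys are equal.

Genotype columns are ignored throughout: TMB counting is site-based, so
only allele identity matters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pysam

from .reference_space import GenomeReference, contig_sort_key, normalize_contig

__all__ = [
    "CALLER_ORDER",
    "IMPACTS",
    "NormalizedVariant",
    "CallerVariantSet",
    "classify_variant_type",
    "normalize_variant",
    "decompose_mnv",
    "parse_impact_annotation",
    "read_caller_vcf",
    "write_consensus_vcf",
    "read_consensus_vcf",
]

log = logging.getLogger("tmbcount")

#: Fixed caller precedence used for annotation tie-breaks and CALLERS tags.
CALLER_ORDER: tuple[str, ...] = ("strelka2", "mutect2", "manta")

IMPACTS: frozenset[str] = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})

_BASES = frozenset("ACGT")


def classify_variant_type(ref: str, alt: str) -> str:
    """Variant class of trimmed, normalized alleles.

    SNV if both length 1; INS if alt is longer; DEL if ref is longer; MNV
    for equal lengths > 1.  ``ref == alt`` is a degenerate input and raises.
    """
    if ref == alt:
        raise ValueError(f"degenerate variant: ref == alt == {ref!r}")
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "INS" if len(alt) > len(ref) else "DEL"


@dataclass(frozen=True)
class NormalizedVariant:
    """A left-aligned, fully trimmed, biallelic somatic variant.

    ``pos`` is the 1-based position of the first reference base (VCF
    convention).  ``callers`` records which callers reported the allele.
    ``gene``/``impact``/``effect`` carry the parsed functional annotation
    when present.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    vclass: str
    callers: frozenset[str] = field(default_factory=frozenset)
    gene: str | None = None
    impact: str | None = None
    effect: str | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def sort_key(self) -> tuple[tuple[int, int, str], int, str, str]:
        return (contig_sort_key(self.contig), self.pos, self.ref, self.alt)

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span.

        Deletions and (M)NVs span every deleted/substituted base; an
        insertion spans only its single anchor base.
        """
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def with_callers(self, callers: Iterable[str]) -> "NormalizedVariant":
        return replace(self, callers=frozenset(callers))


def _check_alleles(ref: str, alt: str) -> None:
    if not ref or not alt:
        raise ValueError("empty allele string")
    if set(ref) - _BASES or set(alt) - _BASES:
        raise ValueError(f"non-ACGT allele: ref={ref!r} alt={alt!r}")


def normalize_variant(contig: str, pos: int, ref: str, alt: str,
                      reference: GenomeReference,
                      gene: str | None = None, impact: str | None = None,
                      effect: str | None = None,
                      callers: Iterable[str] = ()) -> NormalizedVariant:
    """Reduce one (contig, pos, ref, alt) record to canonical form.

    Trims the shared suffix, left-aligns through repeat context by
    extending from the reference whenever an allele would become empty,
    then trims the shared prefix down to the single anchor base indels
    require.  Raises if ``ref`` does not match the reference sequence at
    ``pos`` or if ``ref == alt``.
    """
    canon = normalize_contig(contig)
    ref, alt = ref.upper(), alt.upper()
    _check_alleles(ref, alt)
    if ref == alt:
        raise ValueError(f"degenerate variant at {canon}:{pos}: ref == alt == {ref!r}")
    observed = reference.fetch(canon, pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref:
        raise ValueError(
            f"REF mismatch at {canon}:{pos}: expected {observed!r} from reference, "
            f"VCF record says {ref!r}")

    # Right-trim shared suffix; left-extend from the reference whenever an
    # allele empties out (this walks the variant left through repeats).
    while True:
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= 1:
                    raise ValueError(
                        f"cannot left-align variant past the start of contig {canon}")
                pos -= 1
                anchor = reference.base(canon, pos).upper()
                ref, alt = anchor + ref, anchor + alt
        else:
            break
    # Left-trim shared prefix, keeping the mandatory anchor base for indels.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return NormalizedVariant(contig=canon, pos=pos, ref=ref, alt=alt,
                             vclass=classify_variant_type(ref, alt),
                             callers=frozenset(callers),
                             gene=gene, impact=impact, effect=effect)


def decompose_mnv(variant: NormalizedVariant) -> list[NormalizedVariant]:
    """Split an MNV into its constituent SNVs (non-MNVs pass through)."""
    if variant.vclass != "MNV":
        return [variant]
    out = []
    for offset, (r, a) in enumerate(zip(variant.ref, variant.alt)):
        if r != a:
            out.append(replace(variant, pos=variant.pos + offset, ref=r, alt=a,
                               vclass="SNV"))
    return out


def parse_impact_annotation(record) -> tuple[str | None, str | None, str | None]:
    """Extract (gene, impact, effect) from a record's SnpEff-style ANN field.

    Uses the first ANN entry — SnpEff orders most-deleterious first.  A
    record without ANN yields ``(None, None, None)``; a malformed entry is
    logged as a warning and treated as absent (the record is retained).
    """
    ann = None
    try:
        ann = record.info.get("ANN")
    except (AttributeError, KeyError):
        ann = None
    if ann is None:
        return (None, None, None)
    first = ann[0] if isinstance(ann, (tuple, list)) else str(ann).split(",")[0]
    fields = str(first).split("|")
    if len(fields) < 4:
        warnings.warn(f"malformed ANN entry {first!r}: expected >=4 pipe-separated fields",
                      stacklevel=2)
        return (None, None, None)
    effect, impact, gene = fields[1] or None, fields[2] or None, fields[3] or None
    if impact is not None and impact not in IMPACTS:
        warnings.warn(f"unknown SnpEff impact {impact!r} in ANN entry", stacklevel=2)
        impact = None
    return (gene, impact, effect)


@dataclass
class CallerVariantSet:
    """Normalized small variants from one caller's VCF, with read tallies."""

    caller: str
    variants: list[NormalizedVariant]
    source_path: str
    n_records_read: int
    n_records_pass: int
    n_after_normalization: int
    n_symbolic: int = 0

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.variants}


def _is_symbolic(alt: str) -> bool:
    return (alt.startswith("<") or alt == "*" or alt == "." or
            "[" in alt or "]" in alt)


def _passes_filter(record) -> bool:
    keys = list(record.filter.keys())
    return not keys or keys == ["PASS"]


def read_caller_vcf(path: str, caller: str, reference: GenomeReference,
                    decompose_mnvs: bool = True) -> CallerVariantSet:
    """Read one caller's somatic VCF into a normalized variant set.

    Only records with FILTER ``PASS`` or ``.`` are kept; multi-allelic
    records are split one candidate per ALT; symbolic ALTs (``<DEL>``,
    breakends) are tallied separately and excluded from small-variant
    counting.  By default MNVs are decomposed into their constituent SNVs
    to maximize cross-caller matchability.
    """
    if caller not in CALLER_ORDER:
        raise ValueError(f"unknown caller {caller!r}; expected one of {CALLER_ORDER}")
    try:
        vcf = pysam.VariantFile(path)
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc

    n_read = n_pass = n_symbolic = 0
    by_key: dict[tuple[str, int, str, str], NormalizedVariant] = {}
    with vcf:
        for record in vcf:
            n_read += 1
            if not _passes_filter(record):
                continue
            n_pass += 1
            if record.contig is None or normalize_contig(record.contig) not in reference:
                raise KeyError(
                    f"{path}: record contig {record.contig!r} absent from reference")
            gene, impact, effect = parse_impact_annotation(record)
            for alt in (record.alts or ()):
                if _is_symbolic(alt):
                    n_symbolic += 1
                    continue
                try:
                    nv = normalize_variant(record.contig, record.pos, record.ref, alt,
                                           reference, gene=gene, impact=impact,
                                           effect=effect, callers=(caller,))
                except ValueError as exc:
                    raise ValueError(f"{path}: record at {record.contig}:{record.pos}: {exc}") from exc
                for part in (decompose_mnv(nv) if decompose_mnvs else (nv,)):
                    by_key.setdefault(part.key, part)

    variants = sorted(by_key.values(), key=lambda v: v.sort_key)
    return CallerVariantSet(caller=caller, variants=variants, source_path=str(path),
                            n_records_read=n_read, n_records_pass=n_pass,
                            n_after_normalization=len(variants),
                            n_symbolic=n_symbolic)


_CONSENSUS_HEADER = [
    "##fileformat=VCFv4.2",
    "##source=tmbcount",
    '##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers supporting this variant">',
    '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol from first annotated caller">',
    '##INFO=<ID=IMPACT,Number=1,Type=String,Description="SnpEff impact rating">',
    '##INFO=<ID=EFFECT,Number=1,Type=String,Description="SnpEff effect term">',
]


def write_consensus_vcf(consensus, path: str,
                        reference: GenomeReference | None = None) -> None:
    """Write the consensus variant set as deterministic VCF 4.2.

    The header is fixed (no timestamps, no host information) so identical
    inputs always serialize to byte-identical files.  Supporting callers go
    into the ``CALLERS`` INFO tag in fixed caller order.
    """
    variants = sorted(consensus.variants, key=lambda v: v.sort_key)
    lines = list(_CONSENSUS_HEADER)
    if reference is not None:
        for contig in reference.contig_names:
            lines.append(f"##contig=<ID={contig},length={reference.length(contig)}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for v in variants:
        callers = ",".join(c for c in CALLER_ORDER if c in v.callers)
        info = [f"CALLERS={callers}" if callers else "CALLERS=."]
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.impact:
            info.append(f"IMPACT={v.impact}")
        if v.effect:
            info.append(f"EFFECT={v.effect}")
        lines.append(f"{v.contig}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t" + ";".join(info))
    with open(path, "w", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")


def read_consensus_vcf(path: str, reference: GenomeReference) -> list[NormalizedVariant]:
    """Read a consensus VCF written by :func:`write_consensus_vcf`."""
    out: list[NormalizedVariant] = []
    with pysam.VariantFile(path) as vcf:
        for record in vcf:
            callers = record.info.get("CALLERS")
            caller_set = ()
            if callers is not None:
                joined = ",".join(callers) if isinstance(callers, tuple) else str(callers)
                caller_set = tuple(c for c in joined.split(",") if c and c != ".")
            for alt in (record.alts or ()):
                out.append(normalize_variant(
                    record.contig, record.pos, record.ref, alt, reference,
                    gene=record.info.get("GENE"), impact=record.info.get("IMPACT"),
                    effect=record.info.get("EFFECT"), callers=caller_set))
    return out
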