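"""Fixed denominators of TMB estimation.

Tumor mutation burden is a rate: somatic variants per megabase of
*interrogated* genomic space.  This module computes the three interrogated
spaces used downstream:

* the alignable (non-N) size of the counting scope — by default the
  autosomes 1-22 plus X and Y — which is the whole-genome denominator;
* the merged CDS footprint of a gene annotation, the coding and
  protein-modifying denominator;
* the merged CDS footprint restricted to a panel gene list, the
  pseudo-panel denominator.

Footprints are represented as :class:`IntervalSet` — per-contig, sorted,
strictly disjoint 0-based half-open intervals — so every genomic base is
counted exactly once regardless of how many transcripts cover it.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from pyfaidx import Fasta

__all__ = [
    "CANONICAL_SCOPE",
    "normalize_contig",
    "contig_sort_key",
    "GenomeReference",
    "IntervalSet",
    "CountingScope",
    "count_alignable_bases",
    "build_cds_intervals",
    "total_bases",
]

#: Default counting scope: autosomes plus the sex chromosomes, in canonical
#: (alias-normalized) naming.  Mitochondrial, unplaced and alt contigs are
#: deliberately absent.
CANONICAL_SCOPE: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def normalize_contig(name: str, aliases: Mapping[str, str] | None = None) -> str:
    """Map a contig name to its canonical form.

    hg19-style names carry a ``chr`` prefix while Ensembl-style names do
    not; both map to the bare name (``chr1`` -> ``1``).  An explicit alias
    table takes precedence over prefix stripping, which covers edge cases
    such as ``chrM`` vs ``MT``.
    """
    if aliases and name in aliases:
        return aliases[name]
    if name.lower().startswith("chr"):
        stripped = name[3:]
        if aliases and stripped in aliases:
            return aliases[stripped]
        return stripped
    return name


def contig_sort_key(contig: str) -> tuple[int, int, str]:
    """Deterministic contig ordering: numeric contigs first, then lexical."""
    if contig.isdigit():
        return (0, int(contig), "")
    return (1, 0, contig)


class GenomeReference:
    """Read-only view of a reference genome with alias-normalized contigs.

    Backed either by an in-memory mapping (fixtures, tests) or a FASTA file
    opened through :mod:`pyfaidx`.  Coordinates in the accessors are 0-based
    half-open; ``base`` takes the 1-based VCF position.
    """

    def __init__(self, sequences: Mapping[str, str] | Fasta,
                 aliases: Mapping[str, str] | None = None) -> None:
        self._aliases = dict(aliases) if aliases else {}
        self._fasta = sequences if isinstance(sequences, Fasta) else None
        self._seqs: dict[str, str] = {}
        self._names: list[str] = []
        name_source = sequences.keys()
        seen: set[str] = set()
        for raw in name_source:
            canon = normalize_contig(raw, self._aliases)
            if canon in seen:
                raise ValueError(f"duplicate contig after alias normalization: {canon!r}")
            seen.add(canon)
            self._names.append(canon)
            if self._fasta is None:
                self._seqs[canon] = str(sequences[raw])
        self._raw_by_canon = {
            normalize_contig(raw, self._aliases): raw for raw in name_source
        }

    @classmethod
    def from_fasta(cls, path: str, aliases: Mapping[str, str] | None = None) -> "GenomeReference":
        return cls(Fasta(path, as_raw=True, rebuild=True), aliases=aliases)

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str],
                  aliases: Mapping[str, str] | None = None) -> "GenomeReference":
        return cls(dict(sequences), aliases=aliases)

    @property
    def contig_names(self) -> tuple[str, ...]:
        return tuple(self._names)

    def __contains__(self, contig: str) -> bool:
        return normalize_contig(contig, self._aliases) in self._raw_by_canon

    def _resolve(self, contig: str) -> str:
        canon = normalize_contig(contig, self._aliases)
        try:
            return self._raw_by_canon[canon]
        except KeyError:
            raise KeyError(f"contig {contig!r} (canonical {canon!r}) not in reference") from None

    def length(self, contig: str) -> int:
        raw = self._resolve(contig)
        if self._fasta is not None:
            return len(self._fasta[raw])
        return len(self._seqs[normalize_contig(contig, self._aliases)])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence over [start, end), 0-based half-open, original case."""
        raw = self._resolve(contig)
        if start < 0 or end > self.length(contig) or start > end:
            raise ValueError(
                f"fetch window [{start}, {end}) out of bounds for contig "
                f"{contig!r} of length {self.length(contig)}")
        if self._fasta is not None:
            return str(self._fasta[raw][start:end])
        return self._seqs[normalize_contig(contig, self._aliases)][start:end]

    def base(self, contig: str, pos: int) -> str:
        """Single base at 1-based position ``pos``."""
        return self.fetch(contig, pos - 1, pos)


def _merge(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Merge possibly overlapping/adjacent intervals into a disjoint chain."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if end <= start:
            raise ValueError(f"empty or inverted interval ({start}, {end})")
        if out and start <= out[-1][1]:  # overlap or adjacency
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return tuple(out)


@dataclass(frozen=True)
class IntervalSet:
    """Merged, sorted, half-open genomic intervals defining a counting footprint.

    Invariants (enforced by the constructor): within each contig the
    intervals are sorted by start and strictly disjoint and non-adjacent
    (``end_i < start_{i+1}``), and every interval is non-empty.
    """

    intervals: Mapping[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @classmethod
    def from_iter(cls, triples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        """Build from (contig, start, end) triples, merging as needed."""
        raw: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in triples:
            raw.setdefault(contig, []).append((start, end))
        merged = {c: _merge(ivs) for c, ivs in sorted(raw.items(), key=lambda kv: contig_sort_key(kv[0]))}
        return cls(intervals=merged)

    @property
    def total_bases(self) -> int:
        return sum(end - start for ivs in self.intervals.values() for start, end in ivs)

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for contig, ivs in self.intervals.items():
            for start, end in ivs:
                yield contig, start, end

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())

    def overlaps(self, contig: str, start: int, end: int) -> bool:
        """True iff [start, end) covers at least one footprint base of ``contig``."""
        ivs = self.intervals.get(contig)
        if not ivs or end <= start:
            return False
        starts = [iv[0] for iv in ivs]
        i = bisect.bisect_right(starts, start)
        if i > 0 and ivs[i - 1][1] > start:
            return True
        return i < len(ivs) and ivs[i][0] < end

    def merged(self) -> "IntervalSet":
        """Re-merge (idempotent: returns an equal set)."""
        return IntervalSet.from_iter(iter(self))

    def restricted(self, contigs: Sequence[str]) -> "IntervalSet":
        allowed = set(contigs)
        return IntervalSet(intervals={c: ivs for c, ivs in self.intervals.items() if c in allowed})

    def to_bed(self, path: str, name: str = "cds") -> None:
        """Write as 6-column BED (0-based half-open) for inspection."""
        with open(path, "w") as fh:
            for contig, start, end in self:
                fh.write(f"{contig}\t{start}\t{end}\t{name}\t0\t.\n")


def total_bases(intervals: IntervalSet) -> int:
    """Number of distinct genomic positions covered by ``intervals``."""
    return intervals.total_bases


@dataclass(frozen=True)
class CountingScope:
    """The whole-genome counting scope: allowed contigs and their non-N size."""

    allowed_contigs: tuple[str, ...]
    alignable_bases: int

    @classmethod
    def from_reference(cls, reference: GenomeReference,
                       contigs: Sequence[str] | None = None) -> "CountingScope":
        """Build a scope from a reference.

        ``contigs`` defaults to the canonical 1-22,X,Y scope intersected
        with what the reference actually contains (a toy genome may carry
        only a couple of contigs).
        """
        if contigs is None:
            contigs = [c for c in CANONICAL_SCOPE if c in reference]
            if not contigs:
                contigs = list(reference.contig_names)
        canon = tuple(normalize_contig(c) for c in contigs)
        return cls(allowed_contigs=canon,
                   alignable_bases=count_alignable_bases(reference, canon))


def count_alignable_bases(reference: GenomeReference,
                          scope_contigs: Sequence[str]) -> int:
    """Count non-N bases over ``scope_contigs``.

    Lowercase (soft-masked) a/c/g/t count as alignable; only N/n does not.
    Raises on an empty scope or a contig absent from the reference.
    """
    if not scope_contigs:
        raise ValueError("empty contig scope: alignable space undefined")
    seen: set[str] = set()
    n_alignable = 0
    for contig in scope_contigs:
        canon = normalize_contig(contig)
        if canon in seen:
            raise ValueError(f"contig {contig!r} listed twice in scope")
        seen.add(canon)
        if contig not in reference:
            raise KeyError(f"scope contig {contig!r} not present in reference")
        seq = reference.fetch(contig, 0, reference.length(contig)).upper()
        n_alignable += len(seq) - seq.count("N")
    return n_alignable


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    """Permissive GTF2.2 attribute parsing: ``key "value"; key2 "v2";``.

    Unquoted values (``key value``) are tolerated; malformed tokens are
    ignored rather than fatal.
    """
    attrs: dict[str, str] = {}
    for token in attr_field.strip().split(";"):
        token = token.strip()
        if not token:
            continue
        parts = token.split(None, 1)
        if len(parts) != 2:
            continue
        key, value = parts
        attrs[key] = value.strip().strip('"')
    return attrs


def build_cds_intervals(gtf_path: str,
                        scope_contigs: Sequence[str],
                        gene_filter: Iterable[str] | None = None) -> IntervalSet:
    """Merged union of CDS intervals from a GTF, as 0-based half-open intervals.

    Only rows with feature type ``CDS`` are used; overlapping CDS from
    multiple transcripts are merged so each genomic base counts once.
    ``gene_filter`` restricts to the named genes (matched on the
    ``gene_name`` attribute, falling back to ``gene_id``); filter names
    absent from the GTF raise a warning, not an error.
    """
    scope = {normalize_contig(c) for c in scope_contigs}
    wanted = set(gene_filter) if gene_filter is not None else None
    seen_genes: set[str] = set()
    triples: list[tuple[str, int, int]] = []
    any_cds = False
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{gtf_path}:{lineno}: expected 9 tab-separated GTF fields")
            if fields[2] != "CDS":
                continue
            any_cds = True
            contig = normalize_contig(fields[0])
            if contig not in scope:
                continue
            attrs = _parse_gtf_attributes(fields[8])
            gene = attrs.get("gene_name") or attrs.get("gene_id") or ""
            if gene:
                seen_genes.add(gene)
            if wanted is not None and gene not in wanted:
                continue
            start1, end1 = int(fields[3]), int(fields[4])  # 1-based inclusive
            triples.append((contig, start1 - 1, end1))
    if not any_cds:
        raise ValueError(f"no CDS features found in {gtf_path}")
    if wanted is not None:
        missing = sorted(wanted - seen_genes)
        if missing:
            warnings.warn(
                f"gene_filter names absent from {gtf_path}: {', '.join(missing)}",
                stacklevel=2)
    return IntervalSet.from_iter(triples)
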