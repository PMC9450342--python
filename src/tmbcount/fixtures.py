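"""Synthetic, ground-truthed inputs for the whole pipeline.

Real multi-caller TMB inputs come from controlled-access tumor/normal WGS;
nothing here depends on them.  This module builds a toy universe — a small
reference genome with N-runs and homopolymers, a multi-transcript gene
annotation, three caller VCFs with configurable sensitivity and
representation jitter, gene lists and a COSMIC-like site catalogue — and,
crucially, an independently enumerated :class:`GroundTruth`: the expected
consensus under each policy, the expected subset counts, exclusion tallies
and denominators, all derived *by construction* (per-base coverage masks,
explicit membership bookkeeping, exhaustive rule application), never by
running the pipeline under test.

Determinism: every random choice flows from seeded, per-component streams,
and all emitted files carry fixed fake dates, so the same
:class:`FixtureSpec` always produces byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "FixtureSpec", "TruthVariant", "GroundTruth", "Fixture",
    "make_reference", "make_annotation", "make_caller_vcfs",
    "make_panel_inputs", "build_fixture", "generate_fixture",
    "brute_force_canonical", "equivalent_representations",
]

_BASES = "ACGT"
_POLICIES = ("strelka2+mutect2", "all", "k-of-n:2")


@dataclass
class FixtureSpec:
    """Tunable parameters of the synthetic universe.

    Defaults are chosen to resemble a scaled-down tumor/normal WGS
    experiment: caller sensitivities in the low-to-mid 0.9s for the SNV
    callers (typical published somatic benchmarks), a lower value for the
    SV/indel candidate caller, ~4:1 SNV:indel ratio, ~10% of emissions
    failing caller filters, and a quarter of records emitted in a
    non-canonical (padded or repeat-shifted) representation to exercise
    normalization.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 8000
    n_run_fraction: float = 0.05
    n_genes: int = 6
    transcripts_per_gene: int = 2
    cds_per_transcript: int = 3
    n_truth_snvs: int = 120
    n_truth_indels: int = 30
    cds_placement_fraction: float = 0.5
    caller_sensitivity: Mapping[str, float] = field(
        default_factory=lambda: {"strelka2": 0.95, "mutect2": 0.92, "manta": 0.5})
    n_false_positives_per_caller: int = 4
    fraction_nonpass: float = 0.1
    fraction_noncanonical: float = 0.25
    fraction_cosmic: float = 0.3
    n_cosmic_novel: int = 8
    n_panel_genes: int = 3
    n_tsg_genes: int = 2
    impact_distribution: Mapping[str, float] = field(
        default_factory=lambda: {"HIGH": 0.15, "MODERATE": 0.30,
                                 "LOW": 0.25, "MODIFIER": 0.30})
    fraction_stop_gained: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_run_fraction", "cds_placement_fraction", "fraction_nonpass",
                     "fraction_noncanonical", "fraction_cosmic", "fraction_stop_gained"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for caller, sens in self.caller_sensitivity.items():
            if not 0.0 <= sens <= 1.0:
                raise ValueError(f"sensitivity for {caller} must be in [0, 1], got {sens}")
        if sum(self.impact_distribution.values()) <= 0:
            raise ValueError("impact_distribution must have positive mass")
        if self.contig_length < 2000:
            raise ValueError("contig_length too small for requested features (< 2000)")
        if self.n_panel_genes < 1 or self.n_panel_genes > self.n_genes:
            raise ValueError("n_panel_genes must be in [1, n_genes]")

    def rng(self, component: str) -> random.Random:
        """One independent seeded stream per fixture component."""
        return random.Random(f"{self.seed}|{component}")


@dataclass(frozen=True)
class TruthVariant:
    """A ground-truth somatic variant in canonical (left-aligned) form."""

    contig: str
    pos: int            # 1-based
    ref: str
    alt: str
    vclass: str         # SNV | INS | DEL
    gene: str
    impact: str
    effect: str

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def span(self) -> tuple[int, int]:
        """0-based half-open reference span (insertions: anchor base only)."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


# ---------------------------------------------------------------------------
# canonical-form oracle (deliberately independent of variant_io.normalize_variant)


def brute_force_canonical(seq: str, pos: int, ref: str, alt: str,
                          margin: int = 40) -> tuple[int, str, str]:
    """Canonical (leftmost, minimal) representation by string surgery.

    Cuts a window around the edit, applies it, then trims the longest
    common suffix (which pushes the difference leftmost) followed by the
    longest common prefix, backing off one base when an allele would
    empty out (the indel anchor).  Works purely on strings, so it is an
    independent check on the reference-walking normalizer.
    """
    start0 = pos - 1
    ws = max(0, start0 - margin)
    we = min(len(seq), start0 + len(ref) + margin)
    a = seq[ws:we]
    b = seq[ws:start0] + alt + seq[start0 + len(ref):we]
    if a == b:
        raise ValueError(f"degenerate edit at {pos}: ref and alt haplotypes identical")
    q = 0
    while q < min(len(a), len(b)) and a[len(a) - 1 - q] == b[len(b) - 1 - q]:
        q += 1
    a2, b2 = a[:len(a) - q], b[:len(b) - q]
    p = 0
    while p < min(len(a2), len(b2)) and a2[p] == b2[p]:
        p += 1
    if p == len(a2) or p == len(b2):  # indel: keep one anchor base
        p -= 1
    if p < 0:
        raise ValueError("edit extends past the window start; enlarge margin")
    return (ws + p + 1, a2[p:], b2[p:])


def equivalent_representations(seq: str, pos: int, ref: str, alt: str,
                               max_pad: int = 2, margin: int = 40
                               ) -> list[tuple[int, str, str]]:
    """All equivalent (pos, ref, alt) spellings of one edit, by enumeration.

    Includes right/left reference padding up to ``max_pad`` bases and, for
    indels, every repeat-shifted placement inside the window that yields
    the identical alternate haplotype.  The canonical representation is
    included; every entry applied to ``seq`` produces the same string.
    """
    cpos, cref, calt = brute_force_canonical(seq, pos, ref, alt, margin)
    start0 = cpos - 1
    reps: set[tuple[int, str, str]] = {(cpos, cref, calt)}
    # padded spellings
    for k in range(1, max_pad + 1):
        right = seq[start0 + len(cref): start0 + len(cref) + k]
        if len(right) == k:
            reps.add((cpos, cref + right, calt + right))
        if start0 - k >= 0:
            left = seq[start0 - k: start0]
            reps.add((cpos - k, left + cref, left + calt))
    # repeat-shifted spellings for indels
    if len(cref) != len(calt):
        ws = max(0, start0 - margin)
        we = min(len(seq), start0 + len(cref) + margin)
        a = seq[ws:we]
        b = seq[ws:start0] + calt + seq[start0 + len(cref):we]
        d = abs(len(cref) - len(calt))
        for s in range(ws, we - 1):
            if len(cref) > len(calt):  # deletion: drop d bases after anchor s
                if s + 1 + d > len(seq):
                    continue
                ref_c = seq[s: s + 1 + d]
                alt_c = ref_c[0]
                b_c = seq[ws:s] + alt_c + seq[s + 1 + d:we]
            else:  # insertion after anchor s: inserted bases dictated by b
                off = s + 1 - ws
                if off + d > len(b):
                    continue
                ins = b[off: off + d]
                ref_c = seq[s]
                alt_c = ref_c + ins
                b_c = seq[ws: s + 1] + ins + seq[s + 1: we]
            if b_c == b and len(b_c) == len(b):
                reps.add((s + 1, ref_c, alt_c))
    # keep only valid allele strings (a pad could touch an N run)
    return sorted(r for r in reps if set(r[1] + r[2]) <= set(_BASES))


# ---------------------------------------------------------------------------
# reference and annotation


def make_reference(spec: FixtureSpec) -> tuple[dict[str, str], int]:
    """Deterministic toy genome: returns (contig -> sequence, non-N count).

    Homopolymer runs are salted in so indel left-alignment is actually
    exercised; N-runs are contiguous, as in a real assembly, and their
    total per contig is exactly ``round(n_run_fraction * contig_length)``.
    """
    rng = spec.rng("reference")
    contigs: dict[str, str] = {}
    total_alignable = 0
    for ci in range(1, spec.n_contigs + 1):
        length = spec.contig_length
        seq = [rng.choice(_BASES) for _ in range(length)]
        # homopolymer tracts every ~400 bp
        for start in range(200, length - 20, 400):
            base = rng.choice(_BASES)
            run = rng.randint(5, 12)
            seq[start:start + run] = base * run
        n_total = round(spec.n_run_fraction * length)
        placed = 0
        occupied: list[tuple[int, int]] = []
        attempts = 0
        while placed < n_total:
            attempts += 1
            if attempts > 10000:
                raise ValueError("contig_length too small to place requested N runs")
            run = min(n_total - placed, rng.randint(20, 80))
            start = rng.randrange(50, length - run - 50)
            if any(start < e + 10 and s - 10 < start + run for s, e in occupied):
                continue
            seq[start:start + run] = "N" * run
            occupied.append((start, start + run))
            placed += run
        s = "".join(seq)
        contigs[str(ci)] = s
        total_alignable += len(s) - s.count("N")
    return contigs, total_alignable


@dataclass(frozen=True)
class GeneDef:
    name: str
    contig: str
    territory: tuple[int, int]                  # 0-based half-open gene body
    cds: tuple[tuple[str, int, int, int], ...]  # (transcript, start0, end0, exon_index)


def make_annotation(spec: FixtureSpec, contigs: Mapping[str, str]
                    ) -> tuple[str, list[GeneDef], int]:
    """Toy GTF with overlapping transcripts; returns (gtf text, genes, merged CDS total).

    Transcripts of a gene are shifted copies of each other so their CDS
    overlap partially — the merged footprint must therefore be smaller
    than the transcript-summed total.  The merged total is computed from a
    per-base boolean mask, independent of any interval arithmetic in the
    package.
    """
    rng = spec.rng("annotation")
    names = sorted(contigs)
    genes: list[GeneDef] = []
    per_contig = [0] * len(names)
    for g in range(spec.n_genes):
        per_contig[g % len(names)] += 1
    need = spec.cds_per_transcript * 270 + 120
    gi = 0
    for cidx, contig in enumerate(names):
        n_here = per_contig[cidx]
        if n_here == 0:
            continue
        slot = len(contigs[contig]) // n_here
        if slot < need + 100:
            raise ValueError(
                f"contig_length too small: gene slot {slot} < required {need + 100}")
        for k in range(n_here):
            gi += 1
            name = f"GENE{gi:02d}"
            t0 = k * slot + rng.randint(30, 80)
            cds_rows: list[tuple[str, int, int, int]] = []
            for t in range(spec.transcripts_per_gene):
                shift = t * rng.randint(10, 40)
                cursor = t0 + shift
                tx = f"{name}.T{t + 1}"
                for e in range(spec.cds_per_transcript):
                    exon_len = rng.randint(60, 120)
                    cds_rows.append((tx, cursor, cursor + exon_len, e + 1))
                    cursor += exon_len + rng.randint(80, 150)
            t1 = max(end for _, _, end, _ in cds_rows) + 20
            if t1 > (k + 1) * slot:
                raise ValueError("overlapping genes requested beyond contig capacity")
            genes.append(GeneDef(name=name, contig=contig, territory=(t0, t1),
                                 cds=tuple(cds_rows)))
    lines = ["#!genome-build toyref-1"]
    for gene in genes:
        for tx, s0, e0, exon in gene.cds:
            attrs = (f'gene_id "{gene.name}"; transcript_id "{tx}"; '
                     f'gene_name "{gene.name}"; exon_number "{exon}";')
            lines.append("\t".join([gene.contig, "fixture", "CDS", str(s0 + 1),
                                    str(e0), ".", "+", "0", attrs]))
    merged_total = sum(_mask_total(genes, contig, len(contigs[contig]))
                      for contig in names)
    return "\n".join(lines) + "\n", genes, merged_total


def _cds_mask(genes: Sequence[GeneDef], contig: str, length: int,
              gene_filter: set[str] | None = None) -> bytearray:
    mask = bytearray(length)
    for gene in genes:
        if gene.contig != contig:
            continue
        if gene_filter is not None and gene.name not in gene_filter:
            continue
        for _, s0, e0, _ in gene.cds:
            for i in range(s0, e0):
                mask[i] = 1
    return mask


def _mask_total(genes: Sequence[GeneDef], contig: str, length: int,
                gene_filter: set[str] | None = None) -> int:
    return sum(_cds_mask(genes, contig, length, gene_filter))


# ---------------------------------------------------------------------------
# truth variants


class _Allocator:
    """Reserves genomic windows so fixture variants never interfere."""

    def __init__(self, contigs: Mapping[str, str], margin: int = 8) -> None:
        self.blocked = {c: bytearray(len(s)) for c, s in contigs.items()}
        self.margin = margin

    def free(self, contig: str, start0: int, end0: int) -> bool:
        b = self.blocked[contig]
        lo = max(0, start0 - self.margin)
        hi = min(len(b), end0 + self.margin)
        return not any(b[lo:hi])

    def reserve(self, contig: str, start0: int, end0: int) -> None:
        b = self.blocked[contig]
        lo = max(0, start0 - self.margin)
        hi = min(len(b), end0 + self.margin)
        for i in range(lo, hi):
            b[i] = 1


def _sample_impact(rng: random.Random, dist: Mapping[str, float]) -> str:
    items = sorted(dist.items())
    total = sum(w for _, w in items)
    x = rng.random() * total
    acc = 0.0
    for name, w in items:
        acc += w
        if x <= acc:
            return name
    return items[-1][0]


_EFFECTS = {
    ("HIGH", "SNV"): ("stop_gained", "splice_acceptor_variant"),
    ("HIGH", "INS"): ("frameshift_variant",),
    ("HIGH", "DEL"): ("frameshift_variant",),
    ("MODERATE", "SNV"): ("missense_variant",),
    ("MODERATE", "INS"): ("inframe_insertion",),
    ("MODERATE", "DEL"): ("inframe_deletion",),
    ("LOW", "SNV"): ("synonymous_variant",),
    ("LOW", "INS"): ("splice_region_variant",),
    ("LOW", "DEL"): ("splice_region_variant",),
}


def _make_truth_variants(spec: FixtureSpec, contigs: Mapping[str, str],
                         genes: Sequence[GeneDef], alloc: _Allocator
                         ) -> list[TruthVariant]:
    rng = spec.rng("truth")
    names = sorted(contigs)
    masks = {c: _cds_mask(genes, c, len(contigs[c])) for c in names}
    cds_positions = {c: [i for i, m in enumerate(masks[c]) if m] for c in names}

    def place(want_cds: bool, ref_len: int) -> tuple[str, int] | None:
        for attempt in range(800):
            contig = rng.choice(names)
            seq = contigs[contig]
            # fall back to genome-wide placement once the CDS gets crowded
            if want_cds and attempt < 300 and cds_positions[contig]:
                start0 = rng.choice(cds_positions[contig])
            else:
                start0 = rng.randrange(60, len(seq) - 60 - ref_len)
            if start0 < 60 or start0 + ref_len > len(seq) - 60:
                continue
            window = seq[start0 - 1: start0 + ref_len + 1]
            if "N" in window:
                continue
            if not alloc.free(contig, start0, start0 + ref_len):
                continue
            return contig, start0
        return None

    out: list[TruthVariant] = []
    seen: set[tuple] = set()
    plan = (["SNV"] * spec.n_truth_snvs
            + ["INS"] * (spec.n_truth_indels // 2)
            + ["DEL"] * (spec.n_truth_indels - spec.n_truth_indels // 2))
    for vclass in plan:
        placed = None
        for _ in range(60):  # retry canonical-form collisions with a fresh spot
            want_cds = rng.random() < spec.cds_placement_fraction
            ref_len = 1 if vclass != "DEL" else 1 + rng.randint(1, 4)
            spot = place(want_cds, ref_len)
            if spot is None:
                break
            contig, start0 = spot
            seq = contigs[contig]
            if vclass == "SNV":
                ref = seq[start0]
                alt = rng.choice([b for b in _BASES if b != ref])
                pos, cref, calt = start0 + 1, ref, alt
            elif vclass == "INS":
                anchor = seq[start0]
                ins = "".join(rng.choice(_BASES) for _ in range(rng.randint(1, 4)))
                pos, cref, calt = brute_force_canonical(seq, start0 + 1, anchor, anchor + ins)
            else:
                ref = seq[start0: start0 + ref_len]
                pos, cref, calt = brute_force_canonical(seq, start0 + 1, ref, ref[0])
            if set(cref + calt) - set(_BASES):
                continue
            key = (contig, pos, cref, calt)
            if key in seen:
                continue
            span0 = (pos - 1, pos - 1 + len(cref))
            lo = min(span0[0], start0)
            hi = max(span0[1], start0 + ref_len)
            if not alloc.free(contig, lo, hi):
                continue
            placed = (contig, start0, ref_len, pos, cref, calt, span0)
            break
        if placed is None:
            raise ValueError("contig_length too small to place requested truth variants")
        contig, start0, ref_len, pos, cref, calt, span0 = placed
        seq = contigs[contig]
        alloc.reserve(contig, min(span0[0], start0), max(span0[1], start0 + ref_len))
        seen.add((contig, pos, cref, calt))
        # annotation by construction: gene owning a covered CDS base, if any
        mask = masks[contig]
        in_cds = any(mask[i] for i in range(span0[0], span0[1]))
        if in_cds:
            gene = next(g.name for g in genes
                        if g.contig == contig
                        and any(s0 <= i < e0 for _, s0, e0, _ in g.cds
                                for i in range(span0[0], span0[1])))
            impact = _sample_impact(rng, spec.impact_distribution)
            if impact == "MODIFIER":
                effect = "non_coding_transcript_variant"
            else:
                choices = _EFFECTS[(impact, vclass)]
                if impact == "HIGH" and vclass == "SNV":
                    effect = choices[0] if rng.random() < spec.fraction_stop_gained else choices[1]
                else:
                    effect = choices[0]
        else:
            owner = next((g.name for g in genes if g.contig == contig
                          and g.territory[0] <= span0[0] < g.territory[1]), "")
            gene = owner or f"INTERGENIC_{contig}"
            impact, effect = "MODIFIER", ("intron_variant" if owner else "intergenic_region")
        out.append(TruthVariant(contig=contig, pos=pos, ref=cref, alt=calt,
                                vclass=vclass, gene=gene, impact=impact, effect=effect))
    out.sort(key=lambda v: (v.contig, v.pos, v.ref, v.alt))
    return out


# ---------------------------------------------------------------------------
# caller VCFs


_VCF_DATE = "20200101"


def _vcf_header(source: str, contigs: Mapping[str, str]) -> list[str]:
    lines = ["##fileformat=VCFv4.2",
             f"##fileDate={_VCF_DATE}",
             f"##source={source}",
             '##FILTER=<ID=LowQual,Description="Failed caller quality filter">',
             '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
             "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
             "Feature_Type | Feature_ID'\">",
             '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
             '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">']
    for name in sorted(contigs):
        lines.append(f"##contig=<ID={name},length={len(contigs[name])}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    return lines


def _ann_field(alt: str, v: TruthVariant) -> str:
    return (f"ANN={alt}|{v.effect}|{v.impact}|{v.gene}|{v.gene}.id|"
            f"transcript|{v.gene}.T1")


def make_caller_vcfs(spec: FixtureSpec, contigs: Mapping[str, str],
                     truth: Sequence[TruthVariant], alloc: _Allocator
                     ) -> tuple[dict[str, str], dict[str, set], dict[str, list[TruthVariant]]]:
    """Emit one VCF text per caller plus explicit membership bookkeeping.

    Returns ``(vcf_texts, effective_membership, false_positives)`` where
    ``effective_membership[caller]`` is the set of truth/FP keys that
    appear in that caller's VCF *with a passing filter* — recorded at
    generation time so the expected consensus is known by construction.
    """
    rng_mem = spec.rng("membership")
    rng_rep = spec.rng("representation")
    rng_fp = spec.rng("false-positives")
    callers = sorted(spec.caller_sensitivity)

    fps: dict[str, list[TruthVariant]] = {c: [] for c in callers}
    for caller in callers:
        for _ in range(spec.n_false_positives_per_caller):
            for _ in range(200):
                contig = rng_fp.choice(sorted(contigs))
                seq = contigs[contig]
                start0 = rng_fp.randrange(60, len(seq) - 60)
                if seq[start0] == "N" or not alloc.free(contig, start0, start0 + 1):
                    continue
                alloc.reserve(contig, start0, start0 + 1)
                ref = seq[start0]
                alt = rng_fp.choice([b for b in _BASES if b != ref])
                fps[caller].append(TruthVariant(
                    contig=contig, pos=start0 + 1, ref=ref, alt=alt, vclass="SNV",
                    gene=f"INTERGENIC_{contig}", impact="MODIFIER",
                    effect="intergenic_region"))
                break

    texts: dict[str, str] = {}
    effective: dict[str, set] = {c: set() for c in callers}
    for caller in callers:
        sens = spec.caller_sensitivity[caller]
        records: list[tuple[str, int, str, str, str, str]] = []
        for v in truth:
            if rng_mem.random() >= sens:
                continue
            filt = "LowQual" if rng_mem.random() < spec.fraction_nonpass else "PASS"
            pos, ref, alt = v.pos, v.ref, v.alt
            if rng_rep.random() < spec.fraction_noncanonical:
                reps = equivalent_representations(contigs[v.contig], pos, ref, alt)
                others = [r for r in reps if r != (pos, ref, alt)]
                if others:
                    pos, ref, alt = others[rng_rep.randrange(len(others))]
            records.append((v.contig, pos, ref, alt, filt, _ann_field(alt, v)))
            if filt == "PASS":
                effective[caller].add(v.key)
        for v in fps[caller]:
            records.append((v.contig, v.pos, v.ref, v.alt, "PASS", _ann_field(v.alt, v)))
            effective[caller].add(v.key)
        lines = _vcf_header(f"{caller}-fixture", contigs)
        if caller == "manta":  # one symbolic SV record, excluded from small-variant counting
            contig = sorted(contigs)[0]
            mid = len(contigs[contig]) // 2
            anchor = contigs[contig][mid - 1]
            if anchor != "N":
                records.append((contig, mid, anchor, "<DEL>", "PASS",
                                f"SVTYPE=DEL;END={mid + 500}"))
        records.sort(key=lambda r: (r[0], r[1], r[2], r[3]))
        for contig, pos, ref, alt, filt, info in records:
            lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t50\t{filt}\t{info}")
        texts[f"{caller}.vcf"] = "\n".join(lines) + "\n"
    return texts, effective, fps


# ---------------------------------------------------------------------------
# panel inputs and ground truth


def make_panel_inputs(spec: FixtureSpec, contigs: Mapping[str, str],
                      genes: Sequence[GeneDef], truth: Sequence[TruthVariant],
                      alloc: _Allocator
                      ) -> tuple[set[str], set[str], set[tuple], str]:
    """Panel/TSG gene lists and a COSMIC-like VCF.

    COSMIC sites are drawn partly from truth variants inside the panel CDS
    (matching, so exclusion (a) fires) and partly from fresh positions
    (non-matching).  Returns (panel_genes, tsg_genes, cosmic_keys, cosmic_vcf).
    """
    rng = spec.rng("panel")
    gene_names = sorted(g.name for g in genes)
    panel = set(rng.sample(gene_names, spec.n_panel_genes))
    tsg_pool = sorted(panel) + [g for g in gene_names if g not in panel]
    tsg = set(tsg_pool[: spec.n_tsg_genes])

    panel_masks = {c: _cds_mask(genes, c, len(contigs[c]), gene_filter=panel)
                   for c in sorted(contigs)}
    in_panel = [v for v in truth
                if any(panel_masks[v.contig][i] for i in range(*v.span))]
    n_match = round(spec.fraction_cosmic * len(in_panel))
    if n_match > len(truth):
        raise ValueError("requested COSMIC overlap exceeds truth size")
    matched = rng.sample(sorted(in_panel, key=lambda v: v.key), n_match) if n_match else []
    cosmic_keys = {v.key for v in matched}

    novel: list[tuple[str, int, str, str]] = []
    for _ in range(spec.n_cosmic_novel):
        for _ in range(200):
            contig = rng.choice(sorted(contigs))
            seq = contigs[contig]
            start0 = rng.randrange(60, len(seq) - 60)
            if seq[start0] == "N" or not alloc.free(contig, start0, start0 + 1):
                continue
            alloc.reserve(contig, start0, start0 + 1)
            ref = seq[start0]
            novel.append((contig, start0 + 1, ref,
                          rng.choice([b for b in _BASES if b != ref])))
            break

    rows = [(v.contig, v.pos, v.ref, v.alt) for v in matched] + novel
    rows.sort()
    lines = _vcf_header("cosmic-like-fixture", contigs)
    for contig, pos, ref, alt in rows:
        lines.append(f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    return panel, tsg, cosmic_keys, "\n".join(lines) + "\n"


_TSG_IMPACTS = {"HIGH", "MODERATE", "LOW"}


@dataclass
class GroundTruth:
    """Expected pipeline outputs, enumerated at generation time."""

    alignable_bases: int
    cds_total_bases: int
    panel_cds_total_bases: int
    n_truth_snvs: int
    n_truth_indels: int
    consensus_by_policy: dict[str, list[str]]
    subset_counts: dict[str, list[int]]       # subset -> [snv, indel], default policy
    exclusions: dict[str, int]
    tmb: dict[str, float]                     # "<subset>_<class>" -> per-Mb, unrounded

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


def _enumerate_ground_truth(spec: FixtureSpec, contigs: Mapping[str, str],
                            genes: Sequence[GeneDef], truth: Sequence[TruthVariant],
                            fps: Mapping[str, Sequence[TruthVariant]],
                            effective: Mapping[str, set],
                            panel: set[str], tsg: set[str], cosmic: set[tuple],
                            alignable: int, cds_total: int) -> GroundTruth:
    by_key: dict[tuple, TruthVariant] = {v.key: v for v in truth}
    for vs in fps.values():
        for v in vs:
            by_key[v.key] = v

    consensus_by_policy: dict[str, list[str]] = {}
    for policy in _POLICIES:
        if policy == "strelka2+mutect2":
            keys = effective["strelka2"] & effective["mutect2"]
        elif policy == "all":
            keys = set.intersection(*(effective[c] for c in sorted(effective)))
        else:  # k-of-n:2
            keys = {k for k in by_key
                    if sum(k in effective[c] for c in effective) >= 2}
        consensus_by_policy[policy] = sorted(
            f"{k[0]}:{k[1]}:{k[2]}:{k[3]}" for k in keys)

    default_keys = effective["strelka2"] & effective["mutect2"]
    members = [by_key[k] for k in sorted(default_keys)]

    cds_masks = {c: _cds_mask(genes, c, len(contigs[c])) for c in sorted(contigs)}
    panel_masks = {c: _cds_mask(genes, c, len(contigs[c]), gene_filter=panel)
                   for c in sorted(contigs)}

    def tally(vs: Sequence[TruthVariant]) -> list[int]:
        snv = sum(1 for v in vs if v.vclass == "SNV")
        return [snv, len(vs) - snv]

    def overlaps(v: TruthVariant, masks: Mapping[str, bytearray]) -> bool:
        return any(masks[v.contig][i] for i in range(*v.span))

    coding = [v for v in members if overlaps(v, cds_masks)]
    protein = [v for v in members if v.impact in ("HIGH", "MODERATE")]
    in_panel = [v for v in members if overlaps(v, panel_masks)]
    kept, n_cos, n_non, n_tsg = [], 0, 0, 0
    for v in in_panel:
        if v.key in cosmic:
            n_cos += 1
        elif v.vclass == "SNV" and v.effect == "stop_gained":
            n_non += 1
        elif v.gene in tsg and v.impact in _TSG_IMPACTS:
            n_tsg += 1
        else:
            kept.append(v)

    panel_cds_total = sum(sum(m) for m in panel_masks.values())
    counts = {"genome": tally(members), "coding": tally(coding),
              "protein": tally(protein), "panel": tally(kept)}
    denoms = {"genome": alignable, "coding": cds_total,
              "protein": cds_total, "panel": panel_cds_total}
    tmb: dict[str, float] = {}
    for subset, (snv, indel) in counts.items():
        for sel, count in (("snv", snv), ("total", snv + indel)):
            tmb[f"{subset}_{sel}"] = count / (denoms[subset] / 1_000_000)

    return GroundTruth(
        alignable_bases=alignable, cds_total_bases=cds_total,
        panel_cds_total_bases=panel_cds_total,
        n_truth_snvs=spec.n_truth_snvs, n_truth_indels=spec.n_truth_indels,
        consensus_by_policy=consensus_by_policy,
        subset_counts=counts,
        exclusions={"n_in_panel_footprint": len(in_panel),
                    "n_excluded_cosmic": n_cos,
                    "n_excluded_nonsense": n_non,
                    "n_excluded_tsg": n_tsg},
        tmb=tmb)


# ---------------------------------------------------------------------------
# assembly


@dataclass
class Fixture:
    """A fully generated synthetic universe plus its expected outputs."""

    spec: FixtureSpec
    contigs: dict[str, str]
    genes: list[GeneDef]
    truth: list[TruthVariant]
    panel_genes: set[str]
    tsg_genes: set[str]
    cosmic_keys: set[tuple]
    texts: dict[str, str]          # filename -> file content
    ground_truth: GroundTruth


def _fasta_text(contigs: Mapping[str, str]) -> str:
    lines = []
    for name in sorted(contigs):
        lines.append(f">{name}")
        seq = contigs[name]
        for i in range(0, len(seq), 60):
            lines.append(seq[i:i + 60])
    return "\n".join(lines) + "\n"


def build_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate the full fixture in memory (no files touched)."""
    spec = spec if spec is not None else FixtureSpec()
    contigs, alignable = make_reference(spec)
    gtf_text, genes, cds_total = make_annotation(spec, contigs)
    alloc = _Allocator(contigs)
    truth = _make_truth_variants(spec, contigs, genes, alloc)
    vcf_texts, effective, fps = make_caller_vcfs(spec, contigs, truth, alloc)
    panel, tsg, cosmic_keys, cosmic_text = make_panel_inputs(
        spec, contigs, genes, truth, alloc)
    gt = _enumerate_ground_truth(spec, contigs, genes, truth, fps, effective,
                                 panel, tsg, cosmic_keys, alignable, cds_total)
    texts = {
        "ref.fa": _fasta_text(contigs),
        "ann.gtf": gtf_text,
        "panel.txt": "\n".join(sorted(panel)) + "\n",
        "tsg.txt": "\n".join(sorted(tsg)) + "\n",
        "cosmic.vcf": cosmic_text,
        "ground_truth.json": gt.to_json(),
        **vcf_texts,
    }
    return Fixture(spec=spec, contigs=contigs, genes=genes, truth=truth,
                   panel_genes=panel, tsg_genes=tsg, cosmic_keys=cosmic_keys,
                   texts=texts, ground_truth=gt)


def generate_fixture(spec: FixtureSpec | None = None,
                     out_dir: str | Path = "fixture") -> Fixture:
    """Write all fixture files to ``out_dir`` and return the fixture."""
    fixture = build_fixture(spec)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, text in fixture.texts.items():
        (out / name).write_text(text)
    return fixture
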