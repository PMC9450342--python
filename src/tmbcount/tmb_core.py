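"""TMB counting, per-Mb conversion, threshold classification, cohort summary.

Four genomic subsets are reported, each as a per-megabase rate with its own
denominator:

========  ==========================================  ==========================
subset    numerator                                   denominator
========  ==========================================  ==========================
genome    consensus variants on the counting scope    alignable (non-N) bases
coding    variants overlapping the CDS footprint      merged CDS bases
protein   variants with HIGH/MODERATE impact          merged CDS bases
panel     panel-gene CDS variants minus known-driver  merged panel-gene CDS bases
          exclusions (COSMIC sites; nonsense SNVs;
          HIGH/MODERATE/LOW in tumor suppressors)
========  ==========================================  ==========================

The pseudo-panel emulates how a targeted gene-panel assay estimates TMB:
likely drivers (catalogued somatic sites, truncating events in tumor
suppressors) are subtracted because a panel enriches for them, which would
otherwise inflate the burden estimate relative to genome-wide counting.

Every estimate is classified against the clinical threshold (default
10/Mb, boundary inclusive: a value of exactly 10 is *high*) using the
unrounded value; rounding to 4 decimal places happens only at
serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .consensus import ConsensusSet
from .reference_space import CountingScope, GenomeReference, IntervalSet, normalize_contig
from .variant_io import NormalizedVariant, normalize_variant

__all__ = [
    "SUBSETS", "VARIANT_CLASS_SELECTIONS", "DEFAULT_THRESHOLD",
    "PanelConfig", "PanelCounts", "SubsetCounts", "TMBEstimate", "TMBReport",
    "CohortSummary",
    "count_genome", "count_in_footprint", "count_protein_modifying",
    "count_panel", "compute_tmb", "classify_threshold", "build_report",
    "summarize_cohort", "render_report", "load_cosmic_sites", "load_gene_list",
]

SUBSETS: tuple[str, ...] = ("genome", "coding", "protein", "panel")
#: SNV-only counting, and total = SNV + indel counting.
VARIANT_CLASS_SELECTIONS: tuple[str, ...] = ("snv", "total")
DEFAULT_THRESHOLD = 10.0

_PROTEIN_IMPACTS = frozenset({"HIGH", "MODERATE"})
_TSG_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW"})


# ---------------------------------------------------------------------------
# configuration and counting


@dataclass(frozen=True)
class PanelConfig:
    """Inputs of the pseudo-panel exclusion rules.

    ``cosmic_sites`` holds normalized ``(contig, pos, ref, alt)`` keys in
    allele mode, or ``(contig, pos)`` keys in position mode; the keys must
    be normalized with the same rules as the variants they are matched
    against.
    """

    panel_genes: frozenset[str]
    tumor_suppressor_genes: frozenset[str] = frozenset()
    cosmic_sites: frozenset[tuple] = frozenset()
    match_mode: str = "allele"

    def __post_init__(self) -> None:
        if self.match_mode not in ("allele", "position"):
            raise ValueError(f"match_mode must be 'allele' or 'position', got {self.match_mode!r}")
        if not self.panel_genes:
            raise ValueError("empty panel gene list: panel denominator undefined")

    def matches_cosmic(self, v: NormalizedVariant) -> bool:
        key = v.key if self.match_mode == "allele" else (v.contig, v.pos)
        return key in self.cosmic_sites


def _tally(variants: Iterable[NormalizedVariant]) -> tuple[int, int]:
    """(snv_count, indel_count); MNVs (if undecomposed) count with SNVs."""
    snv = indel = 0
    for v in variants:
        if v.vclass in ("SNV", "MNV"):
            snv += 1
        else:
            indel += 1
    return snv, indel


def scope_variants(consensus: ConsensusSet, scope: CountingScope) -> list[NormalizedVariant]:
    """Variants on allowed contigs; off-scope variants (MT, unplaced) are
    dropped from every subset."""
    allowed = set(scope.allowed_contigs)
    return [v for v in consensus.variants if v.contig in allowed]


def count_genome(consensus: ConsensusSet, scope: CountingScope) -> tuple[int, int]:
    """Whole-genome counts over the allowed contigs."""
    return _tally(scope_variants(consensus, scope))


def _in_footprint(v: NormalizedVariant, footprint: IntervalSet) -> bool:
    start, end = v.span
    return footprint.overlaps(v.contig, start, end)


def count_in_footprint(consensus: ConsensusSet | Sequence[NormalizedVariant],
                       footprint: IntervalSet) -> tuple[int, int]:
    """Counts of variants whose reference span covers >= 1 footprint base.

    A deletion or MNV intersects if any deleted/substituted base is in the
    footprint; an insertion intersects iff its anchor base is.
    """
    variants = consensus.variants if isinstance(consensus, ConsensusSet) else consensus
    return _tally(v for v in variants if _in_footprint(v, footprint))


def count_protein_modifying(consensus: ConsensusSet | Sequence[NormalizedVariant]) -> tuple[int, int]:
    """Counts of variants rated HIGH or MODERATE impact; unannotated
    variants are never counted."""
    variants = consensus.variants if isinstance(consensus, ConsensusSet) else consensus
    return _tally(v for v in variants if v.impact in _PROTEIN_IMPACTS)


@dataclass(frozen=True)
class PanelCounts:
    """Pseudo-panel counts plus the exclusion tallies that produced them.

    Each excluded variant is removed exactly once and attributed to the
    first matching rule in fixed order: COSMIC, nonsense SNV, tumor
    suppressor impact.
    """

    snv_count: int
    indel_count: int
    n_in_panel_footprint: int
    n_excluded_cosmic: int
    n_excluded_nonsense: int
    n_excluded_tsg: int

    def __iter__(self):
        return iter((self.snv_count, self.indel_count))


def _is_nonsense_snv(v: NormalizedVariant) -> bool:
    return v.vclass == "SNV" and v.effect == "stop_gained"


def count_panel(consensus: ConsensusSet | Sequence[NormalizedVariant],
                panel_footprint: IntervalSet,
                config: PanelConfig) -> PanelCounts:
    """Pseudo-panel counting: panel-CDS variants minus driver exclusions.

    Starting from variants intersecting the panel footprint, removes (a)
    variants matching the known-somatic-site catalogue under
    ``config.match_mode``, then (b) nonsense SNVs (``stop_gained``)
    panel-wide and any HIGH/MODERATE/LOW-impact variant in a tumor
    suppressor gene.
    """
    variants = consensus.variants if isinstance(consensus, ConsensusSet) else consensus
    in_panel = [v for v in variants if _in_footprint(v, panel_footprint)]
    kept: list[NormalizedVariant] = []
    n_cosmic = n_nonsense = n_tsg = 0
    for v in in_panel:
        if config.matches_cosmic(v):
            n_cosmic += 1
        elif _is_nonsense_snv(v):
            n_nonsense += 1
        elif (v.gene in config.tumor_suppressor_genes
              and v.impact in _TSG_IMPACTS):
            n_tsg += 1
        else:
            kept.append(v)
    snv, indel = _tally(kept)
    return PanelCounts(snv_count=snv, indel_count=indel,
                       n_in_panel_footprint=len(in_panel),
                       n_excluded_cosmic=n_cosmic,
                       n_excluded_nonsense=n_nonsense,
                       n_excluded_tsg=n_tsg)


# ---------------------------------------------------------------------------
# rates, classification, reports


def compute_tmb(count: int, denominator_bases: int) -> float:
    """Per-megabase rate: count / (denominator / 1e6).

    The value is returned unrounded; 4-decimal round-half-even formatting
    is applied only when a report is serialized.
    """
    if denominator_bases <= 0:
        raise ValueError(f"denominator must be positive, got {denominator_bases}")
    if count < 0:
        raise ValueError(f"negative variant count {count}")
    return count / (denominator_bases / 1_000_000)


def classify_threshold(tmb: float, threshold: float = DEFAULT_THRESHOLD) -> str:
    """``high`` iff tmb >= threshold (boundary inclusive), else ``low``."""
    if threshold < 0:
        raise ValueError(f"negative threshold {threshold}")
    if tmb < 0:
        raise ValueError(f"negative TMB {tmb}")
    return "high" if tmb >= threshold else "low"


def _fmt4(x: float) -> str:
    return format(x, ".4f")


@dataclass(frozen=True)
class SubsetCounts:
    """Raw (snv, indel) tallies and denominators for the four subsets."""

    counts: Mapping[str, tuple[int, int]]          # subset -> (snv, indel)
    denominators: Mapping[str, int]                # subset -> bases
    panel_detail: PanelCounts | None = None

    def __post_init__(self) -> None:
        for subset in SUBSETS:
            if subset not in self.counts or subset not in self.denominators:
                raise ValueError(f"missing subset {subset!r}")
        g_snv, g_ind = self.counts["genome"]
        c_snv, c_ind = self.counts["coding"]
        if c_snv > g_snv or c_ind > g_ind:
            raise ValueError("coding counts exceed genome counts")


@dataclass(frozen=True)
class TMBEstimate:
    count: int
    denominator_bases: int
    tmb_per_mb: float
    classification: str


@dataclass(frozen=True)
class TMBReport:
    """Per-subset, per-variant-class TMB estimates for one sample."""

    sample_id: str
    threshold: float
    estimates: Mapping[tuple[str, str], TMBEstimate]  # (subset, class) -> estimate

    def classification_vector(self,
                              selection: Sequence[tuple[str, str]] | None = None
                              ) -> tuple[str, ...]:
        keys = selection if selection is not None else self.estimate_keys()
        return tuple(self.estimates[k].classification for k in keys)

    @staticmethod
    def estimate_keys() -> tuple[tuple[str, str], ...]:
        return tuple((s, c) for s in SUBSETS for c in VARIANT_CLASS_SELECTIONS)


def subset_counts(consensus: ConsensusSet, scope: CountingScope,
                  cds_footprint: IntervalSet, panel_footprint: IntervalSet,
                  panel_config: PanelConfig) -> SubsetCounts:
    """Count all four subsets on the in-scope consensus variants."""
    in_scope = scope_variants(consensus, scope)
    panel = count_panel(in_scope, panel_footprint, panel_config)
    counts = {
        "genome": _tally(in_scope),
        "coding": count_in_footprint(in_scope, cds_footprint),
        "protein": count_protein_modifying(in_scope),
        "panel": (panel.snv_count, panel.indel_count),
    }
    denoms = {
        "genome": scope.alignable_bases,
        "coding": cds_footprint.total_bases,
        "protein": cds_footprint.total_bases,
        "panel": panel_footprint.total_bases,
    }
    return SubsetCounts(counts=counts, denominators=denoms, panel_detail=panel)


def build_report(sample_id: str, consensus: ConsensusSet, scope: CountingScope,
                 cds_footprint: IntervalSet, panel_footprint: IntervalSet,
                 panel_config: PanelConfig,
                 threshold: float = DEFAULT_THRESHOLD) -> TMBReport:
    """Assemble the full per-sample report from a consensus set."""
    sc = subset_counts(consensus, scope, cds_footprint, panel_footprint, panel_config)
    estimates: dict[tuple[str, str], TMBEstimate] = {}
    for subset in SUBSETS:
        snv, indel = sc.counts[subset]
        denom = sc.denominators[subset]
        for vclass_sel, count in (("snv", snv), ("total", snv + indel)):
            tmb = compute_tmb(count, denom)
            estimates[(subset, vclass_sel)] = TMBEstimate(
                count=count, denominator_bases=denom, tmb_per_mb=tmb,
                classification=classify_threshold(tmb, threshold))
    return TMBReport(sample_id=sample_id, threshold=threshold, estimates=estimates)


@dataclass(frozen=True)
class CohortSummary:
    """Threshold-concordance accounting across a cohort.

    A sample is *consistent* when every selected estimate falls on the same
    side of the threshold; otherwise it is discordant in k estimates, where
    k is the size of the minority classification.
    """

    n_samples: int
    n_consistently_high: int
    n_consistently_low: int
    discordant_by_k: Mapping[int, int]
    per_sample: Mapping[str, tuple[str, ...]]
    estimate_selection: tuple[tuple[str, str], ...]
    threshold: float

    @property
    def n_consistent(self) -> int:
        return self.n_consistently_high + self.n_consistently_low


def summarize_cohort(reports: Sequence[TMBReport],
                     selection: Sequence[tuple[str, str]] | None = None) -> CohortSummary:
    """Tally consistent vs discordant samples across the selected estimates."""
    if not reports:
        raise ValueError("empty cohort")
    thresholds = {r.threshold for r in reports}
    if len(thresholds) != 1:
        raise ValueError(f"inconsistent thresholds across reports: {sorted(thresholds)}")
    sel = tuple(selection) if selection is not None else TMBReport.estimate_keys()
    per_sample: dict[str, tuple[str, ...]] = {}
    n_high = n_low = 0
    by_k: dict[int, int] = {}
    for r in reports:
        vec = r.classification_vector(sel)
        per_sample[r.sample_id] = vec
        k = min(vec.count("high"), vec.count("low"))
        if k == 0:
            if vec[0] == "high":
                n_high += 1
            else:
                n_low += 1
        else:
            by_k[k] = by_k.get(k, 0) + 1
    return CohortSummary(n_samples=len(reports), n_consistently_high=n_high,
                         n_consistently_low=n_low, discordant_by_k=dict(sorted(by_k.items())),
                         per_sample=per_sample, estimate_selection=sel,
                         threshold=thresholds.pop())


# ---------------------------------------------------------------------------
# serialization

_REPORT_COLUMNS = ("sample_id", "subset", "variant_classes", "count",
                   "denominator_bases", "tmb_per_mb", "classification", "threshold")


def _report_rows(report: TMBReport) -> list[tuple]:
    rows = []
    for subset in SUBSETS:
        for vclass_sel in VARIANT_CLASS_SELECTIONS:
            e = report.estimates[(subset, vclass_sel)]
            rows.append((report.sample_id, subset, vclass_sel, e.count,
                         e.denominator_bases, _fmt4(e.tmb_per_mb),
                         e.classification, _fmt4(report.threshold)))
    return rows


def render_report(report: "TMBReport | CohortSummary", format: str = "tsv") -> str:
    """Deterministic serialization: fixed column/key order, 4 d.p. floats.

    Identical inputs always produce byte-identical output.
    """
    if format not in ("tsv", "json"):
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'json'")
    if isinstance(report, TMBReport):
        if format == "tsv":
            lines = ["\t".join(_REPORT_COLUMNS)]
            lines += ["\t".join(str(x) for x in row) for row in _report_rows(report)]
            return "\n".join(lines) + "\n"
        payload = {
            "sample_id": report.sample_id,
            "threshold": report.threshold,
            "estimates": {
                f"{subset}_{vclass_sel}": {
                    "count": report.estimates[(subset, vclass_sel)].count,
                    "denominator_bases": report.estimates[(subset, vclass_sel)].denominator_bases,
                    "tmb_per_mb": float(_fmt4(report.estimates[(subset, vclass_sel)].tmb_per_mb)),
                    "classification": report.estimates[(subset, vclass_sel)].classification,
                }
                for subset in SUBSETS for vclass_sel in VARIANT_CLASS_SELECTIONS
            },
        }
        return json.dumps(payload, indent=2) + "\n"
    if isinstance(report, CohortSummary):
        if format == "tsv":
            sel_names = [f"{s}_{c}" for s, c in report.estimate_selection]
            lines = ["\t".join(["sample_id"] + sel_names + ["n_discordant"])]
            for sample in sorted(report.per_sample):
                vec = report.per_sample[sample]
                k = min(vec.count("high"), vec.count("low"))
                lines.append("\t".join([sample, *vec, str(k)]))
            lines.append(f"#n_samples\t{report.n_samples}")
            lines.append(f"#consistently_high\t{report.n_consistently_high}")
            lines.append(f"#consistently_low\t{report.n_consistently_low}")
            for k in sorted(report.discordant_by_k):
                lines.append(f"#discordant_by_{k}\t{report.discordant_by_k[k]}")
            return "\n".join(lines) + "\n"
        payload = {
            "n_samples": report.n_samples,
            "n_consistently_high": report.n_consistently_high,
            "n_consistently_low": report.n_consistently_low,
            "discordant_by_k": {str(k): v for k, v in sorted(report.discordant_by_k.items())},
            "threshold": report.threshold,
            "estimate_selection": [f"{s}_{c}" for s, c in report.estimate_selection],
            "per_sample": {s: list(report.per_sample[s]) for s in sorted(report.per_sample)},
        }
        return json.dumps(payload, indent=2) + "\n"
    raise TypeError(f"cannot render {type(report).__name__}")


# ---------------------------------------------------------------------------
# external inputs


def load_gene_list(path: str) -> frozenset[str]:
    """One gene symbol per line; blank lines and #-comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            name = line.strip()
            if name and not name.startswith("#"):
                genes.add(name)
    return frozenset(genes)


def load_cosmic_sites(path: str, reference: GenomeReference,
                      match_mode: str = "allele") -> frozenset[tuple]:
    """Load a known-somatic-site catalogue from VCF or TSV.

    VCF records are normalized with the same rules as the variants they
    will be matched against.  TSV input needs columns contig, pos[, ref,
    alt] (tab-separated, #-comments ignored).
    """
    sites: set[tuple] = set()

    def add(contig: str, pos: int, ref: str | None, alt: str | None) -> None:
        if ref and alt and ref != alt:
            nv = normalize_variant(contig, pos, ref, alt, reference)
            sites.add(nv.key if match_mode == "allele" else (nv.contig, nv.pos))
        elif match_mode == "position":
            sites.add((normalize_contig(contig), pos))
        else:
            raise ValueError(
                f"site {contig}:{pos} lacks alleles; allele match_mode impossible")

    if path.endswith((".vcf", ".vcf.gz")):
        import pysam
        with pysam.VariantFile(path) as vcf:
            for record in vcf:
                for alt in (record.alts or ()):
                    if not alt.startswith("<") and alt not in (".", "*"):
                        add(record.contig, record.pos, record.ref, alt)
    else:
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                ref = fields[2] if len(fields) > 2 else None
                alt = fields[3] if len(fields) > 3 else None
                add(fields[0], int(fields[1]), ref, alt)
    return frozenset(sites)
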