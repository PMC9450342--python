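# Methods

## Scope and assumptions

`tmbcount` estimates tumor mutation burden from finished somatic VCFs: it
assumes alignment, calling and functional annotation have already
happened. Inputs are per-caller VCF 4.x files (Strelka2-style,
Mutect2-style, optionally Manta), a reference FASTA, a GTF with CDS
features, plain-text gene lists, and an optional known-somatic-site
catalogue (VCF or TSV). Genotype columns are ignored throughout — the
counting is site-based, so only allele identity matters. Tumor-only
calling, germline filtering and allele-frequency modelling are out of
scope.

Contig naming is alias-normalized by stripping a leading `chr`
(`chr1` ≡ `1`), with an explicit alias table available for edge cases
such as `chrM`/`MT`, because references and annotations in the wild mix
the two conventions.

## Variant normalization

Callers spell the same allele differently (padding, repeat placement,
multi-allelic bundling), so intersection is only well-defined on a
canonical form. `normalize_variant` implements the standard
left-align-and-trim algorithm: repeatedly strip a shared terminal base and,
whenever an allele would empty out, extend both alleles leftward with the
reference base (this walks an indel left through its repeat tract); then
strip shared leading bases down to the single anchor base indels require.
The result is fully trimmed, left-aligned and biallelic; normalization is
idempotent, and every equivalent spelling of an allele maps to the same
`(contig, pos, ref, alt)` key.

Records with FILTER other than `PASS`/`.` are dropped before counting
(both SNV callers emit tiered filters; only caller-accepted calls should
enter a burden estimate). Symbolic ALTs (`<DEL>`, breakends) are tallied
separately and never counted as small variants. MNVs are decomposed into
their constituent SNVs by default, because the callers differ in whether
they emit MNVs at all and decomposition maximizes cross-caller
matchability; with decomposition disabled, an MNV is counted with the
SNVs. Degenerate records (`ref == alt`) and reference mismatches are hard
errors, not silent drops.

Functional annotation is taken from the first entry of a SnpEff-style
`ANN` INFO field (SnpEff orders most-deleterious first); a malformed entry
produces a warning and an unannotated — never a discarded — variant.

## Caller intersection

The default membership policy keeps a variant iff both Strelka2 and
Mutect2 report it. Manta's membership is recorded in the output but not
required: its role in this calling ensemble is to supply indel/SV
candidates, and requiring it would zero out the SNV count. `all` and
`k-of-n:K` policies are available where a stricter or looser ensemble is
wanted. Matching is exact on normalized keys — a deliberate simplification
relative to haplotype-aware comparison (rtg vcfeval), which can match
allele sets that compose to the same haplotype through different records;
after left-alignment and trimming the residual disagreement between the
two approaches is confined to rare complex-region representations.

When callers disagree on annotation, fields are taken from the first
caller in the fixed order (strelka2, mutect2, manta) that carries an
impact; determinism requires a total order and this one favours the
caller whose annotations are most often present.

## The four subsets and their denominators

Counts are converted to per-Mb rates with subset-specific denominators:

* **genome** — variants on the counting scope (default: autosomes plus X
  and Y; mitochondrial, unplaced and alt contigs are excluded everywhere)
  over the alignable space, defined literally as the non-N reference
  bases of the scope. Soft-masked lowercase bases are alignable; only
  N/n is not.
* **coding** — variants whose reference span overlaps at least one base
  of the merged CDS footprint, over that footprint's size. "Merged"
  means the union over all transcripts: a per-Mb denominator must count
  each genomic base once, not once per transcript. Insertions intersect
  via their anchor base; deletions and MNVs via any affected base.
* **protein** — variants rated HIGH or MODERATE impact, over the same CDS
  footprint. Unannotated variants never count.
* **panel** — variants in the merged CDS of a cancer-gene panel, minus
  (a) variants matching the known-somatic-site catalogue, (b) nonsense
  (stop-gained) SNVs panel-wide, and (c) HIGH/MODERATE/LOW-impact
  variants in tumor suppressor genes; over the merged panel-gene CDS.
  Each excluded variant is removed exactly once, attributed to the first
  matching rule in the order (a), (b), (c). Catalogue matching defaults
  to exact normalized-allele keys, with a position-only mode for
  catalogues without reliable allele representations. Rule (b)'s
  grammar admits two readings; the implemented one removes nonsense SNVs
  everywhere in the panel and the impact-based exclusion only inside
  tumor suppressors.

The panel denominator is a genuine design choice — panel-style TMB could
also be normalized by the whole-CDS size. Merged panel-gene CDS was
chosen so the panel estimate mirrors the genome/coding pattern (count in
a footprint over that footprint's size); users comparing the panel
estimate against the 10/Mb threshold should be aware the choice matters.

## Threshold and serialization

Classification is `high` iff TMB ≥ threshold (default 10/Mb), boundary
inclusive, computed on the unrounded value. Rounding — 4 decimal places,
round-half-even — is applied only at serialization, so a value of
9.999999/Mb prints as `10.0000` yet classifies `low`. Reports serialize
with fixed column and key order; two runs on identical inputs are
byte-identical, including the consensus VCF, whose header carries no
timestamps. Cohort concordance tallies, per sample, whether all selected
estimates fall on one side of the threshold; a discordant sample is
binned by the size of its minority classification.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `policy` | `strelka2+mutect2` | consensus membership rule (`all`, `k-of-n:K`) |
| `threshold` | 10.0 /Mb | clinical high/low split, boundary inclusive |
| `contigs` | 1–22, X, Y ∩ reference | counting scope |
| `cosmic_match_mode` | `allele` | catalogue matching granularity |
| MNV decomposition | on | decompose MNVs into SNVs before intersection |

## The synthetic-data generator

Real inputs are controlled-access tumor/normal genomes, so the test bed
is `tmbcount.fixtures`: a seeded generator producing a toy genome
(default two contigs of 8 kb, 5 % N in contiguous runs, salted
homopolymer tracts so left-alignment is exercised), a GTF whose genes
carry two shifted transcripts of three CDS exons each (so CDS merging is
exercised), 120 truth SNVs and 30 indels placed half inside CDS, three
caller VCFs, gene lists and a COSMIC-like VCF. Caller sensitivities
default to 0.95/0.92 for the SNV callers and 0.5 for the candidate
caller — in the range published somatic benchmarks report — with 10 % of
emissions failing caller filters, 25 % emitted in a non-canonical
(padded or repeat-shifted) spelling, four private false positives per
caller, and 30 % of panel-CDS truth variants drawn into the catalogue.

Everything downstream is checked against a `GroundTruth` enumerated at
generation time by independent machinery: per-base coverage masks instead
of interval trees, string-surgery canonicalization
(`brute_force_canonical`) instead of the reference-walking normalizer,
and explicit membership bookkeeping instead of VCF re-parsing. Each
component draws from its own seeded stream, so changing one spec field
perturbs only that component, and identical specs yield byte-identical
files.

What the generator does not emulate — and hence what passing tests do not
show about real data: read-level artifacts (strand bias, mapping error),
caller-specific filter behaviour beyond a uniform failure rate,
clustered/hypermutated regions, MNV emission, multi-sample VCF columns,
and realistic genome scale (toy per-Mb rates are thousands, not tens).
The counting arithmetic is scale-free, but performance and
reference-edge behaviour at 3 Gb are only exercised by pointing
`tmbcount refspace` at a real reference.

## Problem sizes and numerical choices

The test suite and acceptance script run the full pipeline on 100+ seeded
universes (seconds in total at the toy scale above), a choice that keeps
the oracle check exhaustive per universe rather than sampled. Property
tests are derandomized. Ties and degenerate inputs are fixed policies:
empty caller input, empty panel gene lists, zero denominators,
inconsistent cohort thresholds and unknown contigs are errors; absent
ANN fields, filter-listed genes missing from the GTF, and malformed ANN
entries are warnings.

## Known limitations

* Exact-key intersection, not haplotype-aware comparison (above).
* No liftover; reference and annotation must share an assembly (modulo
  `chr` aliasing).
* GFF3 is not parsed (GTF2.2 only, attributes read permissively); CDS
  merging includes stop codons only where the annotation marks them CDS.
* The panel estimate's comparability to assay-calibrated panel TMB
  depends on the user-supplied gene lists and catalogue, which are
  stand-ins for proprietary panel definitions.
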