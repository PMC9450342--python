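# tmbcount

Deterministic tumor mutation burden (TMB) estimation from multi-caller
somatic VCFs.

## The problem

TMB — somatic mutations per megabase of interrogated genome — is used
tumor-type-agnostically to select patients for immune checkpoint inhibitor
therapy, with ≥ 10 mutations/Mb a widely adopted eligibility threshold.
For whole-genome data, the largest source of variability in a TMB estimate
is not the assay but the analysis: which callers ran, how their records
were normalized and combined, and which genomic space the count was
divided by. Small analytic differences move patients across the 10/Mb line.

`tmbcount` implements the counting core of such an analysis so that the
same inputs always give byte-identical answers:

1. **Normalize** each caller's VCF (PASS records only, multi-allelics
   split, alleles trimmed and left-aligned) so that every allele has one
   canonical `(contig, pos, ref, alt)` key.
2. **Intersect** callers: by default a variant is kept iff both Strelka2
   and Mutect2 report it (Manta membership is recorded; SV records are
   tallied but never counted).
3. **Count** the consensus over four genomic subsets and convert each to a
   per-Mb rate:

   | subset  | numerator                                       | denominator |
   |---------|-------------------------------------------------|-------------|
   | genome  | variants on contigs 1–22, X, Y                  | alignable (non-N) bases |
   | coding  | variants overlapping the merged CDS footprint   | merged CDS bases |
   | protein | variants with SnpEff impact HIGH or MODERATE    | merged CDS bases |
   | panel   | cancer-gene CDS variants minus driver exclusions| merged panel-gene CDS bases |

   The pseudo-panel emulates a targeted-panel TMB: variants matching a
   COSMIC-like catalogue, nonsense (stop-gained) SNVs, and
   HIGH/MODERATE/LOW-impact variants in tumor suppressor genes are
   subtracted, since a panel's driver enrichment would otherwise inflate
   the rate. Each subset is reported for SNVs only and for SNVs+indels
   ("total"), giving TMB = count / (denominator / 10⁶).
4. **Classify** every estimate against the clinical threshold
   (high iff TMB ≥ 10/Mb, on the unrounded value) and, across a cohort,
   tally how often the subsets agree.

Because real inputs are controlled-access tumor/normal genomes, the
package ships a synthetic-data generator (`tmbcount.fixtures`) that builds
toy references, annotations and caller VCFs with an independently
enumerated ground truth — every count the pipeline should produce is known
by construction.

## Worked example

Generate a synthetic sample and run the pipeline on it:

```bash
tmbcount fixtures --seed 1 --out-dir demo
tmbcount refspace --reference demo/ref.fa --gtf demo/ann.gtf --panel-genes demo/panel.txt
```

```
contigs	1,2
alignable_bases	15200
cds_bases	2326
panel_cds_bases	1173
```

The toy genome has 16,000 bases of which 15,200 are non-N (the genome
denominator); the merged CDS footprint is 2,326 bases and the three panel
genes contribute 1,173 of them.

```bash
tmbcount run --strelka2 demo/strelka2.vcf --mutect2 demo/mutect2.vcf \
    --manta demo/manta.vcf --reference demo/ref.fa --gtf demo/ann.gtf \
    --panel-genes demo/panel.txt --tsg-genes demo/tsg.txt \
    --cosmic demo/cosmic.vcf --out-dir demo_out
cat demo_out/tmb_report.tsv
```

```
sample_id	subset	variant_classes	count	denominator_bases	tmb_per_mb	classification	threshold
sample	genome	snv	82	15200	5394.7368	high	10.0000
sample	genome	total	104	15200	6842.1053	high	10.0000
sample	coding	snv	47	2326	20206.3629	high	10.0000
sample	coding	total	58	2326	24935.5116	high	10.0000
sample	protein	snv	19	2326	8168.5297	high	10.0000
sample	protein	total	27	2326	11607.9106	high	10.0000
sample	panel	snv	11	1173	9377.6641	high	10.0000
sample	panel	total	14	1173	11935.2089	high	10.0000
```

Of the 104 consensus variants (82 SNVs, 22 indels) reported by both SNV
callers, 58 fall in coding sequence, 27 are protein-modifying, and 14
survive the panel exclusions. Dividing each count by its subset's
megabase denominator gives the `tmb_per_mb` column; every estimate here
exceeds 10/Mb, so all classify `high` (toy genomes are tiny, so per-Mb
rates are far larger than real tumors'). Re-running the command
reproduces all three result files byte for byte. Pointed at a real
reference and Ens75-style GTF, `tmbcount refspace` computes the
genome-scale denominators the same way.

Per-sample reports aggregate with
`tmbcount cohort --reports OUT1 --reports OUT2 ... --out cohort.tsv`,
which tallies how many samples every subset calls consistently high or
low at the threshold.

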