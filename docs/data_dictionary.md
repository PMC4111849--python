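# Report data dictionary

All reports are tab-separated with a header row.  Coordinates are
1-based inclusive; position strings are `chrom:start-end` with an
optional trailing strand sign.

## novel_transcripts.tsv (discovery stage)

| column | meaning |
|---|---|
| `id` | assembled transcript identifier |
| `position` | locus span with strand, e.g. `chr2:152934-166829+` |
| `n_exons` | number of exons in the assembled model |
| `class_reference_A` / `class_reference_B` | classification against each reference (`known`, `exonic_overlap`, `intronic`, `intergenic`); calls are reported only when both are `intergenic` |

## novel_exons.tsv (discovery stage)

| column | meaning |
|---|---|
| `id` | sequential call identifier (`NE-1`, `NE-2`, ...) |
| `gene` | host gene whose intron contains the exon |
| `position` | exon span, 1-based inclusive |
| `length` | `end − start + 1` |
| `strand` | host transcript strand |
| `support` | min spliced-read support of the defining junction pair |
| `left_junction` / `right_junction` | `donor-acceptor` coordinates of the two novel junctions |

## enrichment.tsv (enrichment stage)

One row per feature per target tissue.

| column | meaning |
|---|---|
| `id` | feature identifier from the count table |
| `target_group` | tissue tested against all others |
| `p_vs_<group>` | exact NB test p-value for target vs that group |
| `p-value min` / `p-value max` | extremes over the pairwise comparisons |
| `enriched` | True iff every comparison has p < threshold and favours the target |
| `tested` | False for features with zero counts in every sample |

With `adjust=True`, additional `p_vs_<group>_adj` columns carry
Benjamini–Hochberg adjusted values and drive the verdict instead.

## exon_usage.tsv (condition-splicing stage)

| column | meaning |
|---|---|
| `exon_id` / `gene_id` | tested exon and its gene |
| `usage_change` | pooled inclusion proportion, non-baseline minus baseline condition |
| `p_usage` | quasi-binomial p-value for the inclusion change |
| `p_gene` | exact NB p-value for gene-level expression change |
| `gene_fold_change` | non-baseline / baseline normalized gene means |
| `significant` | True iff `p_usage` < threshold |

## consequence.tsv (consequence stage)

| column | meaning |
|---|---|
| `id`, `gene`, `position`, `length` | as in novel_exons.tsv |
| `prediction` | consequence category: `alternative_5utr`, `alternative_3utr`, `n_terminal_change`, `c_terminal_truncation`, `internal_insertion`, `frame_disruption`, `noncoding` |
| `aa_delta` | novel − reference peptide length (blank when noncoding) |
| `uorf_count` | upstream ORFs in the novel isoform's 5′UTR |
| `utr5_g_quadruplexes` | canonical G-quadruplex motifs in the novel 5′UTR |
| `notes` | boundary-case annotations (e.g. C-terminal extension) |

## Count and design inputs

Count tables: first column `feature_id`, remaining columns one per
sample, nonnegative integers.  Design tables: two columns `sample_id`
and `group`.  Junction BED6: columns 2–3 give the intron as 0-based
half-open, score = spliced-read support.
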