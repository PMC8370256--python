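# Methods

## The screening model

The pipeline operates on peptide-level phosphopeptide quantification
tables from a five-condition starvation/restimulation design (NT, SS,
AAS, LeuS, AllS), one pooled sample per condition. There are no
replicates, so no significance testing of individual fold changes is
attempted; the screen is a deterministic fold-change classifier.

**Site assembly.** Records with a reliability score below a threshold
(default 0.75; records without a score are kept) are removed, exact
duplicate records (same condition, peptide, protein, modified positions
and abundance) are collapsed to one, and the survivors are merged to
residue-level sites. The merge statistic is the **sum** of contributing
peptide abundances: summing preserves the total signal attributed to a
site and is the common convention for site-level collapsing
(configurable to the mean). A peptide carrying several phosphosites
contributes its full abundance to each site — sites are counted, not
fractionally occupied. Conflicting residue letters at one
(protein, position) are a hard error rather than a silent vote.

**Normalization.** The method behind "normalized quantitative data" in
such screens is rarely stated; the default here is per-condition
**median scaling** (each column divided by its median positive cell),
which is robust to a handful of very abundant sites, with `total` and
`none` as alternatives. Only ratios between conditions are ever
interpreted; absolute units are arbitrary.

**Frames.** For each contrast (AAS/SS, LeuS/AAS, AllS/AAS) fold changes
are computed over the sites present with positive abundance in *both*
conditions (intersection first; zeros count as absent, so no infinite
ratios arise and nothing is imputed). With thresholds θ_up = 2 and
θ_down = 0.5 (|log2 FC| > 1, strict inequalities — FC exactly 2.0 does
not qualify):

| frame | up-contrast | down-contrast | reading |
|---|---|---|---|
| 1 | AAS/SS | LeuS/AAS | negatively regulated by leucine |
| 2 | LeuS/AAS | AAS/SS | positively regulated by leucine |
| 3 | AAS/SS | AllS/AAS | negatively regulated by amino acids |
| 4 | AllS/AAS | AAS/SS | positively regulated by amino acids |

Frames are not exclusive; a site satisfying two rules belongs to both
(the worked example contains such a site). The strict tier keeps frame
members whose defining fold changes clear 10x in both directions
(|log10 FC| > 1, threshold configurable).

**Percentages** are rounded half-up to two decimals everywhere, so
complementary shares sum to 100 ± 0.02. The worked-example tables
round-trip under this rule with one known exception: a published serine
share of 93.05% where 134/144 = 93.056 rounds to 93.06 under any
consistent half-up convention. The package keeps the consistent rule
and does not replicate that single cell.

## Motif discovery

Windows are 13 residues wide, centered on the phosphosite, padded with
`_` beyond the protein termini; a site whose recorded residue disagrees
with the FASTA sequence is skipped with a warning, never silently
re-anchored. Discovery follows the motif-x strategy, applied separately
per central residue class (S/T/Y):

1. For every unfixed position and residue, count foreground successes
   against the background frequency at that position and compute the
   binomial tail probability P[X ≥ k]. Padded positions contribute
   neither trials nor successes on either side.
2. Greedily fix the smallest-p pair if p ≤ 1e-6 and it has ≥ 20
   foreground occurrences (both configurable); restrict foreground and
   background to matching windows and repeat.
3. When no pair qualifies, emit the motif, remove its matching windows
   from both sets, and restart. Classes are therefore disjoint and
   their proportions (of the original foreground) sum to ≤ 100%.

Motifs are reported in discovery order, i.e. by observed enrichment;
when two planted classes are of similar frequency (19% vs 16% in the
generator's default mixture), chance matches in the remaining
foreground can swap their observed ranks between runs, while the
dominant class reliably ranks first.

The default background is every same-residue-centered window in the
supplied proteome. A residue never seen in the background at a position
is given a pseudo-frequency of 1/(N+1) rather than zero. The
"no motifs when foreground equals background" property holds for any
p-threshold ≤ 0.5 (the binomial median theorem guarantees tail
probabilities ≥ 1/2 at the observed frequency); absurdly permissive
thresholds above 0.5 can of course fix pairs on null data.

## Over-representation and network summaries

Enrichment is the standard one-sided hypergeometric test (scipy) with
Benjamini–Hochberg correction (statsmodels) across all tested terms;
the universe defaults to all quantified proteins. Term databases are
supplied by the user as GMT — no bundled GO/KEGG snapshot, so term
counts are inherently database-version-dependent and are not a
validation surface. Network degree is counted within the queried
protein set over a deduplicated, self-loop-free edge list; a third
edge-list column is treated as a confidence score and thresholded at
0.4 by default.

## The synthetic generator

`synthetic_data.generate` emulates the quantification tables downstream
of database search. Defaults (all configurable through `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| sites per class | 20/20/20 frames 1–3, 200 frame 4, 500 null | mirrors a screen dominated by all-amino-acid-responsive sites |
| planted effect | 16x up, 1/16 down | clears both the 2x and the strict 10x tier |
| noise | multiplicative log-normal, CV 0.2 | typical label-free peptide-level variability |
| baseline | log-normal, median 100, σ_log 0.8 | arbitrary intensity units |
| redundancy | 1–3 peptides per site-condition, Dirichlet split; 10% exact duplicates | exercises merging and deduplication |
| unreliable records | 5% decoys with reliability < 0.7 | exercises the reliability filter |
| dropout | null sites absent from AAS w.p. 0.7, LeuS w.p. 0.9 | emulates the sparse starvation/restimulation coverage |
| residue mix | 90% S, 9% T, 1% Y | typical S/T/Y proportions |
| motif mixture | 45% P at +1, 19% E at +3, 16% D at +2, 20% none | planted serine-kinase context, exact largest-remainder counts |

A planted site is absent from the restimulation condition that does not
define its class (a leucine-responsive site is not observed in AllS and
vice versa); otherwise, e.g., a site down under starvation and back at
baseline under both restimulations would genuinely belong to two frames
and recovery scoring would be ambiguous. Expected frame memberships are
nevertheless recomputed from the planted means at generation time, not
trusted from the class label.

The generator plants **no global between-condition intensity bias**, so
its columns are already on a common scale. Recovery benchmarks
therefore run the screen with `normalization="none"`: median scaling
would actively distort the planted ratios here, because most sites
present in the sparse AAS/LeuS columns are regulated and the column
median is not a stable pivot. This is a property of the simulated
design, not of the pipeline default (for real data, where the
unchanged majority anchors the median, median scaling remains the
default).

What the generator does *not* emulate: spectrum-level effects (charge
states, retention time, missed-cleavage structure), phospho-localization
ambiguity, correlated noise between conditions, and real protein
sequence composition beyond average amino-acid frequencies. Passing
recovery benchmarks therefore demonstrates the correctness of the
screening logic under the stated noise model, not robustness to every
artifact of real acquisitions.

## Problem sizes and determinism

The test suite and the acceptance script use studies of 760 sites on
380 proteins (about 6,000–6,500 peptide records), five independent
seeds for the noisy-recovery benchmark, and 20,000 draws for the
Monte-Carlo check of the hypergeometric tail; these sizes give stable
statistics while keeping a full run to seconds. All randomness flows
from explicit `numpy` generator seeds; identical seed and configuration
reproduce outputs byte-for-byte, and the CLI manifest records the
configuration hash and SHA-256 of every output file.

## Known limitations

* No PSM-level FDR, localization probabilities or occupancy estimation
  — inputs are assumed to be post-search quantification exports.
* The pooled single-sample-per-condition design admits no variance
  estimate; fold-change thresholds are the only evidence.
* Vendor export formats are not parsed directly; inputs follow the
  documented TSV schema.
* Enrichment and network results are only as good as the user-supplied
  annotation and edge lists.
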