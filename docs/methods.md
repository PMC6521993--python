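# Methods

## Phenotype model

Each dog carries ten ordinal airway grades g_c ∈ {1,2,3,4}. The total
airway score is Σ_c w_c·g_c; the clinically used weights are not public, so
the package defaults to unit weights (range 10–40), which preserve the
ordinal monotonicity every downstream stage relies on, and accepts any
non-negative weighting. The overall grade discretises the total at
cutpoints (14, 22, 30] → clear/mild/moderate/severe; these cutpoints are
package conventions, configurable, with boundaries belonging to the lower
grade. The severity ranking sorts dogs descending-lexicographically on the
four components that anchor the association signal (laryngeal saccule >
cartilage position > cricoid oedema > oropharyngeal oedema), breaking ties
by descending total score and then stable input order, so the ordering is a
deterministic total order. The "severe" stratum feeding the fine-mapper is
grade 4 on the top-priority component (configurable).

## Mixed-model association scan

QC removes samples with > 10 % missing genotypes first, then markers with
MAF < 0.05 computed on the retained samples; both cutoffs are strict.
Missing dosages are mean-imputed per marker afterwards. Kinship is the
standardised genomic relationship K = ZZᵀ/m over column-centred,
column-scaled dosages (the centred-only variant is available); zero-variance
markers are excluded with a note.

Each marker is tested in y = Wα + xβ + u + ε with u ~ N(0, σ²g K) and
ε ~ N(0, σ²e I), W holding intercept, age and sex. Writing λ = σ²g/σ²e,
one eigendecomposition K = USUᵀ turns the covariance diagonal; the
restricted likelihood is maximised in λ per marker on a 41-point log grid
over [1e-5, 1e5] with parabolic refinement in log λ, flat stretches and
ties resolving to the smaller ratio (first grid maximum). The grid sweep is
vectorised across markers through the Schur complement of the covariate
block, so the scan is O(grid × n × m). Wald t statistics use the GLS
estimate and σ̂²e = RSS/(n−p) with df = n − p, p counting every
fixed-effect column including the marker; this makes the scan collapse
*exactly* to OLS when K = I, which is the correctness oracle used in the
tests. p-values are computed in log space (`t.logsf`), so perfect signals
report large finite −log10 p rather than zero. The Bonferroni helper
reports α/m and its −log10 to two decimals. LD r² is the squared Pearson
correlation of dosage vectors (composite LD) within a ±50-marker window;
zero-variance pairs are NaN-flagged, never silently 0. PCA of the centred
dosage matrix (thin SVD) supports the substructure check.

## Haplotype fine-mapping

Among the severity-ordered severe dogs' phased chromosomes, the consensus
risk haplotype is the modal full-region allele vector; frequency ties break
toward the chromosome of the highest-ranked dog, then the lowest dog id.
Chromosomes matching the consensus allele at the index marker are walked
outward, left and right independently; the first mismatching marker on a
side is that chromosome's departure — read as one meiotic recombination
event — and a chromosome contributes at most one event per side even if it
re-matches further out (the simplest reading of an event count). The
critical interval's boundary on each side is the last marker strictly
inside the marker where the cumulative departure count reaches
`min_recomb` (default 3); a `--boundary-inclusive` mode takes the departure
marker itself, since which side of the breakpoint carries the boundary is a
convention. Departures are counted per side by default; a total-count mode
(combined tally across both sides, nearest first) is available because the
published rule's sidedness is ambiguous. If a side never accumulates enough
events the interval is truncated at the panel edge and flagged unbounded.
Interval length is reported as end − start, matching the convention by
which 61,166,179–61,579,985 spans 413,806 bp. Chromosomes from the same dog
count as independent events; relatedness deduplication is out of scope.

Diplotype classes count a dog's chromosomes exactly matching the consensus
across the interval: 2 → homozygous-risk, 1 → heterozygous, 0 → non-carrier.

## Variant sieving

Variants are restricted to the interval (1-based inclusive), sites with any
missing call are dropped (only fully genotyped positions are interpretable
for segregation), and one of two schemes applies: *exclusive-to-affected*
keeps variants homozygous-alternate in the affected carrier and not
homozygous-alternate in every other dog; *haplotype-concordant* keeps
variants homozygous-alternate in all risk-haplotype carriers and
homozygous-reference in all non-carriers. "Derived" is operationalised as
the alternate allele of the supplied reference; ancestral-state inference
is not attempted. Complete-LD groups are maximal sets with exact pairwise
r² = 1 (identical or affinely equivalent dosage vectors), found by
union-find. Consequence calls map a genomic SNV through the gene model's
CDS intervals (strand-aware, reverse-complementing alleles on minus-strand
genes), derive the codon as ⌈cds_pos/3⌉, translate reference and alternate
codons by the standard code, and emit c.<pos><ref>><alt> and
p.(<Ref><codon><Alt>) with three-letter residue codes; a variant whose
reference allele contradicts the CDS is an input error, not a silent guess.
Stop-retaining changes are synonymous. Indels are located
(exonic/intronic/intergenic-indel) without protein notation. The
cross-species conservation check declares an alignment column invariant iff
exactly one distinct non-gap residue appears; all-gap columns are flagged
rather than called invariant.

## Reporting

Allele frequency is (2·hom + het)/(2n) from genotype counts. Score
comparisons between genotype classes use a two-sided Mann–Whitney test with
midrank ties: full enumeration of the C(n, nx) group assignments when the
combined size is ≤ 12 (p = probability of |U − nxny/2| at least as large as
observed), and a tie- and continuity-corrected normal approximation above
that; the threshold of 12 keeps enumeration under ~1000 assignments. No
correction is applied across the three pairwise genotype comparisons,
matching raw reporting practice (a Bonferroni option exists). The breeding
rule prohibits dogs whose overall grade strictly exceeds "moderate";
"moderate" itself is permitted. Decision tables report within-stratum
genotype percentages to one decimal, flagging empty strata as undefined.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
the biology of any real genome. Defaults (the package's study conditions):
300 dogs, 1000 markers on one 2-Mb chromosome, 30 founder haplotypes,
Poisson(1.0) crossovers per chromosome copy with uniform breakpoints and no
interference, risk-allele target frequency 0.57 with the causal alternate
allele private to one founder, causal effect β = 2.0 liability SD per
allele copy, polygenic share h² = 0.3, component loadings 1.0 on the four
priority components and 0.6 elsewhere, component noise SD 1.0. β = 2.0 is
chosen so risk-haplotype homozygosity contrasts sharply between severe and
non-severe strata (on the order of the observed 75 % vs 18 % contrast); it
is a working value, not an estimate of the true effect. Grade thresholds
sit at fixed z-offsets (−1, 0.2, 1.2) of each component's theoretical
latent mean/SD, giving roughly 16/34/34/16 % grade frequencies. Age (6–120
months), sex and weight are emitted as covariates with no liability effect
by default; hooks for age/sex effects exist because age-dependent
penetrance is plausible but unparameterised. Realised causal allele
frequency is rejection-controlled to ±0.05 of target. The kinship used to
draw the polygenic term is the realised standardised kinship of the
simulated markers themselves, so the scan's estimated kinship can recover
exactly the structure that generated the confounding.

What the generator does **not** emulate: genotyping error, imputation
artefacts, pedigree loops, allele-frequency spectra shaped by selection,
multi-breed structure, and genome-scale marker density. Passing tests
therefore demonstrate the correctness and calibration of the *methods*
under the stated generative model, not performance guarantees on real
array data.

A note on nulls: on a single simulated chromosome the polygenic term —
drawn from a 30-founder mosaic's kinship — is locally taggable, so some
marker can attain a large realised correlation with the polygenic draw and
reach genome-wide significance even with β = 0 and a correct mixed model;
per-marker REML also legitimately prefers λ → 0 for such a marker (the
marker absorbs the structure as a fixed effect). Genome-wide null
calibration therefore uses multi-chromosome panels (`n_chromosomes`), where
the polygenic background spreads across independently recombining
chromosomes; there the family-wise Bonferroni guarantee holds in ≈ 95 % of
replicate cohorts and per-marker type-I error is within sampling noise
of α.

## Problem sizes

The test suite and acceptance script run simulations at 150–300 dogs and
400–2000 markers, with 50-seed replication for recovery rates and 20-seed
replication for null and inflation properties — sizes chosen to make the
Monte-Carlo bands (e.g. type-I error 0.05 ± 0.015, recovery ≥ 90 %) sharp
enough to detect real defects while keeping a full run of the suite in the
low minutes on one CPU.

## Known limitations

Per-marker REML (rather than a null-model, EMMAX-style approximation) is
faithful to the exact-mixed-model design but, as noted above, can collapse
λ for founder-tagging markers on short synthetic panels. Ordinal grades are
analysed as numeric responses; no ordinal-link model is offered. The
consensus haplotype is a modal full-region vector, which is informative
only while unrecombined copies of the risk background are common — very
long regions with high recombination would need a windowed consensus.
Statistical phasing is out of scope: haplotype input must already be
phased (the simulator emits truth phase).
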