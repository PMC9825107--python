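# Methods

## Model overview

`niptsr` predicts whether a foetus inherited a parent's balanced
chromosomal rearrangement by relative haplotype dosage (RHDO) from
maternal plasma cfDNA.  The quantity of interest is, per parent and
chromosome, the hidden sequence of transmitted haplotypes along the
panel SNPs.  The model assumes:

* plasma cfDNA is a two-component mixture — maternal fraction (1−ff)
  and foetal (placental) fraction ff — with no maternal or placental
  mosaicism;
* read counts at a SNP are binomial in the expected alt fraction θ
  (no overdispersion; see Limitations);
* sequencing errors flip alleles symmetrically at rate ε, so
  θ = θ_raw(1−ε) + (1−θ_raw)ε with θ_raw = (1−ff)m/2 + ff·f/2;
* the transmitted-haplotype process along a chromosome is Markov with
  Haldane-map switch probabilities, i.e. crossovers form a Poisson
  process on the genetic map.

Informative SNPs — one parent heterozygous, the other homozygous — are
the only sites carrying transmission signal, and the two parental
chains are inferred independently: at a maternal-informative SNP the
father is homozygous, so the emission depends only on the maternal
transmission state, and vice versa.  A joint 4-state mother×father
chain would add nothing at these sites and is not implemented.

## Phasing and Hap0/Hap1 orientation

The carrier parent's haplotypes are phased by Mendelian transmission
against one typed relative:

* **Grandparent route** (a parent of the carrier): at carrier-het /
  grandparent-homozygous sites the grandparent's allele must lie on the
  grandparent-derived haplotype.  This assignment is immune to
  recombination in the grandparent's own meiosis, because a homozygote
  transmits the same allele either way; the phased vector is therefore
  a true haplotype of the carrier.
* **Child/sibling route** (an existing child of the couple): at
  parent-het sites where the transmitted allele is unambiguous (other
  parent homozygous, or child homozygous) that allele joins the
  child-transmitted haplotype.  Crossovers in the child's meiosis make
  this vector a mosaic of the carrier's two true haplotypes; the HMM
  absorbs each such phase switch as an extra state change, and the
  evaluation helpers account for them (`expected_switch_points`).
  "Sibling" here means a sibling of the foetus; it is the same phasing
  route as "child".

A grandparent can phase only the carrier parent; a child phases both
parents, which is why the accuracy study defaults to a child reference
(both maternal and paternal chains are then scored).  Ambiguous sites
are left unphased rather than imputed, and Mendelian-impossible sites
are dropped and counted into a reported conflict rate.

Hap0 (rearranged-linked) orientation comes from the reference's
karyotype: a carrier reference shares Hap0 with the carrier parent, a
non-carrier reference shares Hap1.  A missing reference karyotype is a
fatal error — the label is never guessed.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| `maf_min` | 0.3 | frequency | strict floor; high-MAF SNPs maximise informative sites |
| `vif_max` | 1.5 | ratio | redundancy ceiling for panel markers |
| VIF window | 20 retained neighbours | markers | the cohort/window of the original panel design is unpublished; a fixed sliding window with greedy left-to-right retention is deterministic and order-stable |
| `epsilon` | 0.0011 | per-base error | targeted-capture error rate of the assay class |
| `morgans_per_mb` | 0.01 | Morgans/Mb | ~1 cM/Mb genome average; no genetic map is assumed, a per-case override is accepted |
| `ff` | estimated | fraction | opposite-homozygote median estimator (below); `--ff` overrides |
| `flank_bp` | 5,000,000 | bp | breakpoint windows sized so that at the observed ~1.63 informative SNPs/Mb a 10 Mb window expects ≥16 informative SNPs |
| `min_snps` | 8 | SNPs | half the expected count above, rounded down — a loose floor |
| `lor_threshold` | ln 100 ≈ 4.6 | nats | a 100:1 posterior odds requirement per window |

Foetal-fraction estimator: at sites where the parents are homozygous
for opposite alleles the foetus is an obligate heterozygote and the
plasma alt fraction deviates from the maternal expectation by ff/2;
per-site estimates (twice the deviation) are combined by their median,
which is robust to scattered outliers.  Fewer than 10 usable sites is
an error directing the user to supply ff externally.  Estimates outside
the clinically observed 4.6–36.7% range only raise a warning flag.

## HMM numerics

All chain arithmetic is in natural-log space with `logaddexp`; chains
of 2×10⁴ SNPs with deliberately tiny emission likelihoods produce
finite posteriors (tested).  The prior at the first SNP is uniform.
Per-SNP transmitted-allele calls use the forward–backward marginal MAP
(which minimises per-site error); segmentation and crossover intervals
use the Viterbi path under the same emissions and transitions.  Both
decoders are exposed.  Zero-depth sites contribute log-likelihood 0
under both states.  The LOR sign convention is positive ⇒ Hap0.  A
base-10 LOR accessor exists for plotting.

Limiting behaviour (tested): with recombination rate c → 0 the chain
collapses to a single pooled likelihood-ratio decision; with c → ∞
every SNP is classified independently.

Crossovers are reported as the interval between the last SNP of the
old Viterbi state and the first SNP of the new state, with the midpoint
as point estimate.  Resolution is therefore bounded by the local
informative-SNP spacing.

## Karyotype calling

A breakpoint window is `no_call` if it holds fewer than `min_snps`
usable SNPs, if |mean LOR| is below `lor_threshold`, or if a Viterbi
crossover interval overlaps it — a crossover inside the window makes
the transmitted haplotype at the breakpoint itself ambiguous.
Robertsonian windows extend only q-proximally: acrocentric short arms
carry no reliable panel SNPs.  Window calls combine as: all Hap1 ⇒
`normal`; all Hap0 ⇒ `balanced_carrier`; disagreement ⇒
`possible_unbalanced`; any window `no_call` ⇒ overall `no_call`.
`possible_unbalanced` is an extension label: cohorts of the underlying
study design (largely PGT-selected pregnancies) contain only
normal/carrier outcomes, so this label is flagged as non-validated in
reports.

## What the simulator emulates — and what it does not

The generator reproduces the study's information content: a panel with
MAF ~ Uniform(0.3, 0.5) and lognormal neighbour gaps of median 40 kb
(65,172 markers allocated across GRCh38 autosome lengths for the
genome-wide fixture; two 100-Mb chromosomes at the same 21.7 SNPs/Mb
density for the desk-scale scenario); founder haplotypes drawn from the
MAFs; meioses with Poisson crossovers at 0.01 Morgans/Mb (positions
forcible for localisation studies); a typed reference per role, with
offspring references rejection-sampled to be balanced at the
breakpoints (an unbalanced child would not be a usable karyotyped
reference); plasma depth ~ Poisson and alt counts ~ Binomial(depth, θ)
at the true foetal genotype.  The rearrangement is represented purely
as breakpoint-linked haplotype labels — the assay never observes
derivative-chromosome sequence, so none is simulated.

Not emulated: linkage disequilibrium between panel SNPs (founder
alleles are drawn independently, so the simulated panel needs no VIF
pruning), genotyping error in the parents/reference, GC and capture
bias, count overdispersion, placental mosaicism, crossover
interference, and obligate-crossover constraints.  Passing tests
therefore demonstrate correctness of the inference given the stated
mixture model, not robustness to these real-data artefacts.

## Validation studies shipped with the package

* **Allele accuracy**: 20 desk-scale families, depth 100×, ff uniform
  0.05–0.30, ε = 0.0011, child reference, carrier parent alternating;
  the marginal-MAP transmitted allele is compared to truth at every
  usable informative SNP.  The true ff is supplied to the model so the
  measurement isolates haplotype inference.
* **Crossover localisation**: 200 meioses with one forced maternal
  crossover ≥ 10 Mb from chromosome ends, depth 100×, ff 0.15; error is
  the distance from truth to the nearest inferred midpoint.
* **Exactness**: forward–backward marginals against brute-force
  enumeration of all 2ⁿ paths for chains of 1–12 SNPs (|ΔLOR| < 1e−9).
* **Concordance grid**: depth 1000×, ε = 0, ff 0.2, all three
  rearrangement kinds × both carrier parents × all three reference
  roles; foetal meioses are conditioned on zero crossovers so each
  simulated pregnancy has a definitive balanced outcome (mirroring a
  normal/balanced-carrier cohort); the call must equal truth in all 18
  cells.  Crossover handling is exercised separately above.

## Limitations

* No population-based phasing or imputation: a typed relative is
  required; de novo rearrangements are out of scope by design.
* Plain binomial emissions; amplification overdispersion would widen
  posterior intervals and is an explicit extension point.
* A uniform genetic map; hotspot structure will locally distort
  crossover localisation.
* Breakpoints must be supplied as explicit genomic intervals;
  cytogenetic band nomenclature is not parsed (band→coordinate maps
  are assembly-dependent).
* Sex chromosomes are excluded; aneuploidy screening and CNV dosage
  analysis of unbalanced products are out of scope.
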