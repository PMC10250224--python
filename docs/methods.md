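# Methods

`circdimorph` reimplements, at desk scale, the analysis chain used to
discover and classify sex-dimorphic circular RNAs from fractionated
RNA-seq, together with a PAR-CLIP branch that maps an RNA-binding
protein's sites onto circRNA-relative regions.  Every stage is driven by
a seeded synthetic-data generator with planted ground truth, so each
claim the pipeline makes can be checked against what was planted.

## Experimental design being emulated

Six samples (sex F/M × tissue head/body/gonad), each sequenced as three
RNA fractions:

* **polyA** — poly(A)-selected mRNA; unstranded; used only for gene-level
  TPM of the circles' host ("cognate") genes.
* **R−** — rRNA/mRNA-depleted RNA; strand-specific; contains linear
  fragments of all genes, a small rRNA residual, and circle-derived
  fragments.
* **R+** — the R− material after RNase R digestion.  RNase R is a 3'→5'
  exoribonuclease that degrades linear RNA but not covalently closed
  circles, so the R+ fraction is strongly circle-enriched.

A circular RNA is observed through its **back-splice junction (BSJ)**:
the covalent joint between an upstream 3' splice site (the *acceptor*,
genomic start of the circle) and a downstream 5' splice site (the
*donor*, genomic end).  Reads spanning this junction are the circle's
abundance proxy.  Exonic circRNAs sit exactly on annotated exon
boundaries; intronic ciRNAs derive from intron lariats and run from the
intron 5' end to a branch point a few tens of nucleotides upstream of
the intron 3' end.

## BSJ detection (bsjcall)

Instead of chimeric alignment, candidate junctions are enumerated from
the annotation: for each gene's canonical transcript (longest CDS, then
longest exonic length), every ordered exon-boundary pair (i ≤ j, same
gene, span ≤ 100 kb) defines an exonic junction, and every intron a
family of lariat junctions with branch points 15–50 nt (step 5) upstream
of the intron 3' end.  Each junction's *probe* is the last
L = read_length − min_anchor nt of the circle's mature sequence followed
by its first L nt (transcript orientation).  A read is assigned when it
matches a probe with the junction at least `min_anchor` nt (default 10,
the usual chimeric-segment minimum) from both read ends and at most
`max_mm` substitutions (default 1; the upstream protocol is silent on
mismatches, so the allowance is explicit and configurable).

Matching is exact-first (hash lookup of the read against all valid probe
windows), then seed-and-verify: the read is split into `max_mm + 1`
segments, any error-free segment locates the candidate alignment, and
the full overlap is verified by Hamming comparison — by pigeonhole this
is fully sensitive for up to `max_mm` substitutions.  Among candidates
the fewest mismatches wins; ties between junctions, or an equal-quality
contiguous match to the genome itself (both strands), mark the read
non-unique and it is not counted.  Stranded (R−/R+) reads must match in
transcript orientation; polyA reads are scanned in both orientations.

Calls are typed from the annotation: *exonic* iff both boundaries
coincide with exon boundaries of one gene; *ciRNA* iff the interval
starts at an intron 5' end (strand-aware) and ends inside the
branch-point window; otherwise *unassigned* — retained in output but
excluded from all cohort statistics.

## Quantification and normalization (quantnorm)

* **Gene counts**: a read counts toward a gene iff it matches the gene's
  canonical spliced transcript contiguously (same seed-and-verify
  scanner); reads matching ≥ 2 genes are discarded; rRNA-gene reads are
  tallied separately.
* **TPM** uses the canonical transcript's exonic length as effective
  length (reads are fixed-length; no fragment-length correction):
  rate_g = count_g/len_g, TPM_g = rate_g/Σrate × 10⁶.
* **Size factors** for R− BSJ counts: DESeq2-style median-of-ratios
  against a geometric-mean reference over rows nonzero in every sample,
  rescaled to geometric mean 1.  With fewer than 10 such rows the
  estimator is unstable and the implementation falls back to adjusted
  library size (total − mRNA − rRNA reads), recording the method tag.
* **Back-splicing level** = R+ BSJ count / max(cognate TPM, ε) with
  ε = 1 TPM.  The floor keeps the ratio bounded when the host is barely
  expressed; junctions whose host TPM is below ε in *every* sample are
  flagged low-expression and excluded from differential back-splicing.
  R+ counts are deliberately not size-factor scaled before the TPM
  division (a switch exists); only the TPM division is applied.

## Classification (classify)

All rules are threshold rules on one library per condition (the design
has no replicates), with a 0.5 pseudocount making fold changes total:

* **Reliable**: R+ ≥ 2 × R− and R+ ≥ 2 in at least one sample.  The
  count floor decides the zero-denominator case.
* **Differentially expressed** (toward side a of a comparison):
  (R+_a + ½)/(R+_b + ½) ≥ 4 and normalized R−_a > R−_b strictly (same
  direction).
* **Sex-specific**: max R+ over one sex's samples ≥ 15 and zero reads in
  every opposite-sex sample, R+ *and* R− (strictest reading of "not
  detected"; an option relaxes to R+ only).
* **Differentially back-spliced**: the fold rule applied to the
  TPM-normalized level, additionally requiring max(level_a, level_b) ≥ 15.
  Between-sex flags map to a fixed group grid: G1/G2 head F>/M-higher,
  G3/G4 body, G5 testis-higher, G6 ovary-higher.
* **Alternative back-splicing**: per gene, an acceptor shared by ≥ 2
  donors is one alt5 event; a donor shared by ≥ 2 acceptors one alt3
  event; an event is observed in a sample iff ≥ 2 members have an R+
  read there.  The enumeration is verified against an exhaustive
  shared-boundary pairing oracle in the tests.

All flagged sets are monotone in their thresholds, mutually exclusive
per comparison side, and sex-specific ⊆ reliable by construction.

## PAR-CLIP branch (parclip)

Reads are aligned by contiguous scan with ≤ 2 non-T>C mismatches;
a reference-T read as C (transcript orientation) is recorded as a
crosslink-induced conversion, not a mismatch (seeding is done in a
C→T-collapsed alphabet so conversions cannot break seeds); multi-mappers
are discarded.  Candidate peaks are maximal single-strand coverage runs
≥ 5 reads, merged when closer than 10 nt.  Enrichment over the IgG
control is scored as ratio = (n_pd/N_pd)/((n_igg+1)/N_igg) with a
one-sided Poisson tail P-value at mean (n_igg+1)·N_pd/N_igg — the
simplest defensible enrichment null, stated openly (the upstream HMM
peak caller is out of scope).

**CIMS** (crosslink-induced mutation sites): within a peak, every
reference-T position with ≥ 2 conversions is a candidate; its FDR is
estimated by read-level permutation — each read redistributes its
conversions uniformly over the reference-T positions it covers, and
FDR = (mean permuted count of positions with k' ≥ k)/(observed count of
positions with ≥ k), clamped to [0,1].  This is a within-peak,
self-contained variant of the usual genome-wide CIMS procedure.

**Significance** is the two-branch rule: (ratio ≥ 10, P < 10⁻⁴, and a
CIMS site with FDR ≤ 0.3) or (ratio ≥ 100 and P < 10⁻⁴).

Peaks are annotated by midpoint with precedence exon > intron >
intergenic, coding exons sub-labelled 5'UTR/CDS/3'UTR by the canonical
transcript, and densities reported per kb of annotated category length.
Relative to a circle, a peak is *back-spliced exon* (overlaps a chain
exon), *flanking intron* (overlaps the intron immediately outside either
boundary) or *flanking exon* (overlaps the nearest annotated exon
outside the circle); one peak may hold several categories across calls,
so category percentages can sum above 100%.  Motif discovery is replaced
by k-mer z-scores against dinucleotide-preserving (Altschul–Erikson)
shuffles.

## Synthetic-data generator (synthio)

The generator emulates the *structure* of the experiment, not fly
biology: a single random contig with 3–8 exons/gene (80–300 nt), introns
60–2000 nt carrying GT/AG, intergenic gaps ≥ 500 nt, one rRNA gene, a
CDS leaving 20–150 nt UTRs on coding genes.  Planted circles sit exactly
on canonical exon boundaries (ciRNAs use a branch point fixed 25 nt
upstream of the intron 3' end, inside the detector's 15–50 nt window).
Circle classes: null, female/male-biased (rate fold `fold`, default 8,
optionally restricted to given tissues), female/male-specific (rate 0 in
the opposite sex).

Rates are absolute: a circle's R− BSJ read probability is
circ_frac·(R−1)·a_c·eff_c/Σ(a·M) (abundance a, mature length M), so null
circles have identical rates in every condition and fold effects are
exact by construction.  A circle read is junction-spanning with
probability (R−1)/M, with the junction placed uniformly and ≥ 1 nt on
each side.  R+ applies survival thinning (linear sources × 0.02 by
default, circles × 1) and renormalizes to the requested depth; the exact
per-fraction probabilities are exposed (`TruthSet.bsj_rates`) for
binomial oracles.  Renormalization means large planted effects shift R+
library composition between conditions — a real compositional artefact;
study fixtures therefore keep effect-carrying circles a small mass
fraction of the circle pool.

PAR-CLIP: pulldown reads are drawn around site centers with Gaussian
jitter (sd 5 nt) plus uniform background; every pulldown read
overlapping a site converts each covered site T with probability 0.25;
the IgG library is background only.  `clip_enrichment` (default 20) is
the *expected pulldown:control ratio statistic* of a site's peak — the
same quantity the significance rule thresholds — and the per-site signal
budget is solved in closed form from that target.

Defaults that matter (units; rationale): read length 100 nt (merged
single-end; merging is upstream preprocessing), sequencing error 0.1%/nt,
circRNA share of R− 2% (circles are a minor fraction of rRNA-depleted
libraries), rRNA residual 2% (exercises the library-size reduction
path), RNase-R linear survival 2%, abundances log-normal (σ = 0.8,
clipped to [0.25, 8] so no planted circle is undetectably rare),
expression log-normal (σ = 1).  Everything is configurable through a
flat key=value file; identical (config, seed) reproduce every output
byte for byte.

What the generator does **not** model — and hence what passing tests do
not show about real data: alternative isoforms (one canonical transcript
per gene), intronic-complementary-sequence-driven circularization
biology, quality-score and fragment-length distributions, paired-end
reads, PCR duplicates, mapping ambiguity from repeats, EIciRNAs, and
trans-gene circles.

## Validation studies and problem sizes

The `study` module fixes the package's validation experiments (also run
by `scripts/acceptance.py`):

* **Detection exactness** — 40 genes, 150 circles (130 exonic, 20
  ciRNAs), one R+ library of 200 k error-free reads, max_mm 0: junction
  recall and precision must both be 100%, and assignments must equal the
  truth-labelled junction reads whose anchors satisfy the ≥ 10 nt rule
  (the simulator's uniform junction placement makes ~18% of true
  junction reads sub-anchor; they are recorded as such).
* **Reliability** — same genome, R− 60 k / R+ 200 k reads (the enriched
  library sequenced deeper): every circle with ≥ 4 true R+ junction
  reads passes the 2× filter; 10 forged junction reads spiked into R−
  only never produce a reliable call.
* **Size factors** — 500 junctions, planted depth factors {0.5, 1, 2},
  recovery within 5% relative error, geometric mean 1 ± 10⁻⁹.
* **Group recovery** — 70 genes, 20 female-head-biased (8-fold) + 40
  null circles, host TPM pinned at 40, R+ 600 k / R− 100 k / polyA 2.5 M
  reads per sex, 5 independent runs: ≥ 90% of biased circles assigned
  G1, ≤ 5% of null circles grouped.  The biased class is planted at 0.1×
  relative abundance so R+ compositional renormalization compresses the
  8-fold only to ≈ 6×; the depths are sized from a power analysis of
  that compressed fold against the 4-fold threshold, in which the
  host-gene TPM estimate (≈ 90 polyA reads per host at this depth) is
  the dominant noise term.  Biased circles see ≈ 200 R+ junction reads
  even on the male side — far above the ≥ 30-read floor the study
  stipulates.
* **Null calibration** — 150 null circles, equal depths, 10 runs: ≤ 1%
  of reliable circles flagged differential.
* **PAR-CLIP recovery** — 45 genes, one circle per (coding) gene, 100
  sites (25 back-spliced-exon / 25 flanking-intron / 25 flanking-exon /
  15 3'UTR / 10 intergenic), pulldown 20 k / IgG 300 k reads: ≥ 90% of
  sites recovered as significant peaks, ≤ 10% of significant peaks
  unplanted, ≥ 90% of recovered circ-role peaks receive exactly their
  planted category.  Sites are placed ≥ 30 nt inside features ≥ 90 nt so
  a peak (≈ site ± 20 nt at these depths) stays within its feature.
* **CIMS calibration** — a planted 8-conversions-in-10-reads position
  reaches FDR < 0.05; uniformly sprayed conversions give median site
  FDR > 0.3 (1000 permutations).
* **Determinism** — two identical runs of the whole generator byte-match.

## Known limitations

* Canonical-transcript resolution of exon chains is a convention; real
  isoform mixtures can disagree, and ambiguous multi-gene junctions are
  reported with no cognate gene.
* The Poisson enrichment P-value has no multiple-testing correction; the
  two-branch rule's CIMS requirement is what controls false peaks here.
* Seed-and-verify sensitivity is guaranteed only up to the configured
  mismatch budget; indels are not modelled by the scanner (or the
  generator).
* With one library per condition, all classifications are threshold
  rules; no variance model or significance statement attaches to them.
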