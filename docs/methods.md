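# Methods

`enhancerhubs` implements the computational chain used to detect
ligand-induced changes in enhancer interaction hubs from ChIA-PET and
4C-seq data, together with a fully seeded simulator that provides
ground truth for every stage.  This note describes the models, the
parameters that matter, the numerical choices, and what the synthetic
data do and do not establish about real data.

## Coordinate and signal conventions

All coordinates are 0-based half-open `[start, end)`.  Adjacent
intervals `[a, b)` and `[b, c)` are *book-ended*; book-ended anchors
connect interaction clusters during subdomain collapsing.  ChIP-seq
tags are directionally extended to 200 bp (the sequenced fragment
length) before overlap counting; coverage tracks average per-base
overlap over 10 bp bins and conserve mass (`sum(track) * binsize =
n_tags * extension`).  Occupancy and expression are expressed as RPKM
(reads per kilobase per million mapped reads); binding-site intensity
is log2 RPKM with a 0.5-count pseudocount guarding empty regions.

The gene body used for POLII density starts 1 kb downstream of the TSS
(strand-aware, configurable) to exclude the promoter-proximal POLII
peak; a gene is called active when its body density exceeds the median
of the nonzero densities (quantile configurable).  "Distal" means
more than 5 kb from every TSS, measured from the peak midpoint;
the midpoint convention (rather than peak edge) is an explicit choice
— for peak-scale intervals the two differ by at most a few hundred bp.

## ChIA-PET processing

Each single-end read carries 20 bp of genomic DNA on either side of a
36 bp composite linker: `tag_a + half_linker(b1) +
revcomp(half_linker(b2)) + revcomp(tag_b)`.  Half-linkers are 18 bp
with a 4 bp internal barcode (A: `TAAG`, B: `ATGT`).  The splitter
scans every read offset for the best composite match, allowing at most
one mismatch per half-linker *outside* the barcode and none inside it
(barcode integrity determines the chimera accounting), preferring
fewer mismatches, then the leftmost position.  Mixed (AB) barcodes
mark chimeric ligations between unrelated complexes; because AA/BB
chimeras are invisible, the random-ligation rate is estimated as twice
the AB fraction (capped at 1).

Tags are mapped by exact search against the genome (2-bit packed
k-mers, both orientations, unique-hit-only), the simulator-era
replacement for an aligner: on synthetic genomes a tag either matches
exactly once or is ambiguous.  PET span is the distance between the
two tags' 5' positions; categories are `self` (< 5 kb), `intra_inter`
(5 kb – 1 Mb inclusive), `distal_intra` (> 1 Mb) and `trans`
(different chromosomes).  Exactly 5 kb counts as inter-ligation and
exactly 1 Mb is retained, matching the "between 5 and 1000 kb"
convention.  PETs with identical coordinate pairs are de-duplicated by
default (configurable); each tag is assigned to the binding-site
anchor that its 200 bp extension overlaps (anchor optionally grown by
a window), larger overlap winning and ties going to the smaller
coordinate.

## Interaction calling

Candidate clusters are unordered anchor pairs of inter-ligation PETs
(AB-barcode PETs are excluded from calling — they only inform the
noise estimate).  Significance against non-specific ligation noise is
the hypergeometric tail: with library total N, anchor degrees n_a and
n_b (each supporting iPET counted once per anchor over the *whole*
library, not just the call set), the null count for a pair is
Hypergeometric(N, n_a, n_b) and p = P(X >= k).  Benjamini–Hochberg
q-values are computed over all candidates; high-confidence clusters
require k >= 2 (use 3 for POLII-type libraries), q < 0.05, and span in
[5 kb, 1 Mb].  A permutation alternative (shuffle the second anchor
across PETs, empirical tail) is available as a model-misspecification
cross-check but is never the default path.  Trans clusters are not
produced by the default caller; the hub analysis is intra-chromosomal.

## Subdomains (hubs) and annotations

Clusters whose anchors overlap (>= 1 bp) or book-end belong to one
subdomain; subdomains are connected components of that relation,
computed by merging anchor intervals into adjacency groups and
union-finding clusters through shared groups (equivalent to, and
tested against, pairwise-graph connected components).  The footprint
runs from the smallest anchor start to the largest anchor end; width =
footprint length.  Singleton clusters form singleton subdomains; they
participate in interaction-type statistics but are removed from the
differential analysis by the >= 5-peak gate.  Subdomain membership of
a site or gene is midpoint-in-footprint; because split components can
nest, membership uses the smallest containing footprint.

Annotations: anchors within 5 kb of a TSS are promoter anchors, else
DBS; cluster types are the unordered label pairs, with proportions
over all clusters.  Two subdomain sets (e.g. P300 vs POLII) are
*shared* when footprints overlap >= 1 bp (book-ended footprints are
separate); the anchor-share percentage of a shared pair is the number
of reciprocally overlapping anchors over the union.  Domain
containment reports the fraction of clusters with both anchors inside
a single externally supplied domain (replication-timing domains in the
motivating study); whether sites outside any footprint belong in
denominators is ambiguous in general, so both the all-sites and
inside-only proportions are reported.

## Dynamic sites and the differential hub comparison

Per-site delta = treated − vehicle log2 RPKM.  With population median
m and MAD = median(|delta − m|) (no Gaussian consistency constant),
sites with delta > m + 2·MAD are induced, delta < m − 2·MAD reduced,
else constitutive — strict inequalities, so boundary values are
constitutive.  Fewer than 5 sites or MAD = 0 is an error.  An
empirical two-sided p (fraction of sites at least as far from the
median) is reported per site for transparency; the ±2·MAD cut itself
is the classification rule, and no second test is invented.

Subdomain concentration per condition is the mean member-site log2
RPKM (the linear RPKM sum is also emitted; the mean-of-log2 version is
the one coherent with a log-scale concentration gate).  The
differential comparison keeps subdomains with >= 5 member sites and
−0.3 < dC < 0.3 (strict), splits them into the group with >= 1
induced site versus the group with only constitutive sites (subdomains
containing reduced sites are set aside and reported), and compares
per-subdomain interaction ratios r = treated/vehicle cluster count
with a one-sided Mann–Whitney U (induced stochastically greater).
Zero vehicle counts get a pseudocount of 1 on both numerator and
denominator (flagged) — it preserves ordering without discarding
subdomains.  The U test is exact (full null distribution by the
classic counting recursion) when combined n <= 20 and there are no
ties, otherwise a tie-corrected normal approximation with continuity
correction; a zero-variance configuration returns p = 0.5.

Because the |dC| gate matches only the *change* in concentration, not
its level, the comparison is additionally repeated within density
quantile bins (default terciles of the condition-averaged
concentration), each bin tested on its own; both the pooled and the
per-bin results are reported.  How many bins to use is genuinely open
— terciles keep at least a handful of hubs per bin at realistic hub
counts.

Expression linkage: genes are linked to DBSs through DBS–promoter
clusters (the linked gene is the one whose TSS is nearest the promoter
anchor, within 5 kb).  DBSs sorted by delta are split into 10
nearly-equal bins — earlier bins take the remainder, so the partition
is deterministic — and each bin reports the mean log2 expression
change of its linked genes.  Group-wise expression change of genes
inside induced vs constitutive subdomain footprints uses the same
one-sided Mann–Whitney machinery.

## 4C-seq

The reduced genome holds, for every GATC occurrence, the 30 bases
immediately 3' of the site on each strand (the site itself excluded;
including it is a configuration flag).  Sites too close to a contig
edge for a full flank are dropped and counted.  An end is mappable iff
its sequence occurs exactly once among all end sequences and their
reverse complements — note that two sites exactly (motif + flank) bp
apart produce reverse-complement flank collisions and are genuinely
unmappable, which real reduced-genome pipelines also discard.  Reads
are parsed by the bait-primer prefix and matched to mappable ends
exactly (an optional 1-mismatch mode enumerates single mutants and
discards ambiguous hits).  The signal at end i sums counts within
±5 kb of its site, normalized to reads per million assigned; the
binned track averages end signals per 10 kb bin, and delta-4C is the
per-bin treated − vehicle difference (sign convention: positive means
gained upon treatment).  Mismatched bin grids are an error, never a
silent zero-fill.  The viewpoint site and ±2 flanking sites are masked
by default (self-ligation and undigested artifacts dominate there);
replicates are merged by summing counts before normalization, which
equals the count-weighted average of per-replicate signals.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not real genome sequence.  Genomes are i.i.d. uniform nucleotides with
GATC injected every ~2 kb (±0.5 kb jitter) plus one site 150 bp
upstream of every peak, guaranteeing each peak a fragment end within
1 kb; random sequence also contains natural GATCs every ~256 bp, which
is harmless and adds realism to the reduced genome.  Subdomains are
disjoint genomic blocks (default 128 blocks of ~140 kb over 4 × 4.5 Mb
chromosomes) each holding 10 peaks ~12 kb apart, giving hub footprints
of ~110 kb, the scale reported for co-factor interaction subdomains.
Edge truth connects all intra-subdomain peak pairs with weight
proportional to the geometric mean of the linear occupancies times a
1/distance decay; treated-condition weights on edges touching induced
peaks are multiplied by rho (`interaction_enrichment`, default 2;
rho = 1 is the null).

Occupancy: vehicle log2 occupancy is Normal(3, 1) per peak; treated =
vehicle + Uniform(−w, w) drift (w = `condition_wobble` = 0.2) plus
`induction_effect` at induced peaks (default fraction 0.12, matching
the ~10–12 % of ligand-bound distal sites that acquire the co-factor
de novo in the motivating system).  The bounded drift is a deliberate
choice: the median ± 2·MAD rule flags a *fixed* ~17.7 % of any
Gaussian-tailed null (2·MAD = 1.35 sigma), so a generator with normal
condition noise can never satisfy a 5 % false-positive calibration;
with a bounded drift, 2·MAD sits at the support edge and only
measurement (Poisson-count) noise leaks across, giving a ~2–4 %
realized false-positive rate at the default depth
(`chip_count_scale` = 2000 expected tags per unit occupancy, i.e.
~20 M tags per library).  The realized MAD of the delta population at
these settings is ~0.11; recovery experiments use an induction effect
of ~4× that (0.455) and recover >= 95 % of induced peaks.

ChIA-PET reads: a fraction `chimeric_rate` (0.10) carry mixed barcodes
and join random anchor pairs; of the rest, `self_pet_fraction` (0.15)
are self-ligations around single peaks with span |Normal(0, 1 kb)|;
remaining inter-ligations are drawn from edge weights except a
`noise_rate` (0.05) fraction from random anchor pairs.  Tags are
placed Normal(0, 150 bp) around peak midpoints with the strand facing
the peak, so 200 bp extensions reach the anchor.  Default depths
(10–20 k PETs per condition against ~5 800 true edges) keep 1–3 iPETs
per edge — the sparse regime in which cluster-count differences carry
the treatment signal; saturated designs (every edge called in both
conditions) have ratio 1 everywhere and no power, which is a property
of count-based differential interaction analysis generally.

4C reads: capture probability per cis site is d^(−1) (distance floored
at 1 kb) plus an additive spike (0.5) at sites nearest to
edge-connected peaks, times rho for induced edges under treatment;
each read is the bait primer plus the captured fragment-end sequence.
Genes: two per subdomain, TSS 0.5–3 kb from a member peak; the
expected treated/vehicle gene-body density ratio is
1 + 0.5 × (mean log2 occupancy gain of the connected enhancers)
(`expression_coupling`), a deliberately simple monotone coupling — the
motivating observation is a monotone relation without a stated
functional form.

Everything derives from one seed through independent named streams, so
changing the requested depth of one output does not perturb any other.

### What the simulations do not show

The generator has no sequencing errors, PCR duplicates, mappability
structure, copy-number variation, GC bias, or realistic sequence
composition; anchors are the true peaks, so peak-calling error is out
of frame.  Passing calibration and recovery on these data shows the
*chain of statistics* is implemented correctly and calibrated under
its own assumptions — not that those assumptions hold in any real
library.  In particular the bounded-drift null is a model: with
heavier-tailed biological variability the ±2·MAD rule will flag more
than 5 % of sites, as it does on any Gaussian population.

## Problem sizes used in the test suite

Unit tests run on 2 × 0.6 Mb landscapes (~24 peaks).  Calibration uses
50 seeds at 10 000 PETs/condition under the null; recovery uses 20
seeds at 20 000 PETs/condition with a rho sweep {1, 1.5, 2, 3} sharing
one landscape and genome index per seed.  These sizes give binomial
standard errors of 1–3 % on the reported rates.

## Known limitations

* Exact string mapping is only meaningful on synthetic genomes; real
  libraries need an aligner upstream, after which the same PET tables
  flow through unchanged.
* The exact Mann–Whitney path requires tie-free data; tied small
  samples fall back to the tie-corrected normal approximation, which
  is anticonservative below n ≈ 8 with heavy ties.
* The hypergeometric noise model conditions on anchor degrees and is
  known to be permissive for sparse anchor pairs; the k >= 2 count
  gate, not the FDR, does most of the work against singleton noise —
  the permutation cross-check exists for exactly this reason.
* Subdomain sharing and anchor-share percentages are quadratic in the
  number of shared pairs; fine at hub counts, not built for Hi-C scale.
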