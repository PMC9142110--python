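# Methods

This note documents the models, conventions, numerical choices and known
limitations behind `mitoprofile`. It describes what the code computes; every
empirical number quoted here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Scope and data model

The package profiles an annotated circular mitochondrial genome — the
canonical insect layout of 13 protein-coding genes (PCGs), 22 tRNAs, 2 rRNAs
and a control region (CR) — and infers a concatenated-PCG maximum-likelihood
phylogeny under GTR+I+G. Coordinates are 1-based inclusive everywhere (the
GenBank convention), converted exactly once at the I/O boundary; a feature
with `start > end` wraps the circular origin. Strands are J (majority) and N
(minority); `+`/`-` are accepted as synonyms on input. Sequences are stored
as uppercase DNA with U mapped to T on read.

The packaged data files under `src/mitoprofile/data/` transcribe the
published annotation, composition and codon-count tables of the *Malenka
flexura* mitogenome (GenBank ON411527). They are inputs for the replication
checks, never hard-coded answers: all derived columns (sizes, intergenic
nucleotides, skews, RSCU) are recomputed from the primary columns at run
time. The transcription keeps two printed anticodon-position typos verbatim
(tRNA-Asn `6174-6172` descending, tRNA-Val garbled) because the reader is
required to flag, not crash on, such values.

## Organization statistics

Feature size is `end − start + 1`, or `L − start + 1 + end` over the origin.
The signed intergenic nucleotide count (IGN) of a junction is
`downstream.start − upstream.end − 1`; negative values are overlaps. The
closing CR→first-gene junction is reported but excluded from gene-to-gene
totals. These definitions satisfy an exact conservation identity on a
circular genome — Σ(feature sizes) + Σ(signed IGN over all junctions,
closing included) = genome length — which the tests check on the published
table (it holds exactly at 15,744 bp) and on every synthetic genome.

Two cells of the published IGN column (ND3, ND6) contradict the table's own
printed coordinates; the coordinate-derived values (0 and 1, not 3 and 0)
are the ones that satisfy the conservation identity, so the package reports
those and the tests document the two discrepancies. By coordinates the
genome has 51 bp of overlap in 16 junctions (longest 8 bp) and 224 bp of
spacers in 10 junctions.

Start codons are classified into ATN / GTG / TTG / other; stop codons into
TAA / TAG / the incomplete `T-` (length mod 3 = 1, final T) and `TA-`
(mod 3 = 2, final TA) completed to TAA by post-transcriptional
polyadenylation, or "other". Classification is total for any CDS of at
least one codon.

## Composition and skews

Percent composition excludes N from numerator and denominator. AT-skew is
(A−T)/(A+T) and GC-skew is (G−C)/(G+C); zero denominators yield NaN rather
than an error. Reports round percentages to 1 decimal and skews to 3,
keeping unrounded values internally.

Strand-split rows ("PCGs N-strand" etc.) are computed on the genes' own
coding strands by default; a `own_strand=False` flag gives the
majority-strand reading instead, since the published table does not state
its convention. Reverse-complementing a sequence negates both skews, so the
two conventions differ only in sign for pure-N classes.

When comparing skews recomputed from *rounded* printed percentages against
printed skews, the correct tolerance is the rounding-propagation bound: each
percentage carries ±0.05, and |∂skew/∂x| + |∂skew/∂y| = 2/(x+y), so the
worst-case error is 0.1/(sum of the two percentages) (+0.0005 for the
skew's own printed rounding). For typical rows this is ≈0.0015–0.003; for
the GC-poor control region (G+C = 14.8%) it is ≈0.007. All 22 published
skew cells fall within this bound; two of them (PCGs-N GC, CR GC) exceed a
naive blanket ±0.002, which is why the bound matters. Similarly, the printed
A+T column can differ from the sum of the printed A and T by one unit in
the last digit (two rows do), because the components were rounded
independently.

## Codon usage and RSCU

The genetic code is NCBI translation table 5 (invertebrate mitochondrial):
AGA/AGG = Ser (8-codon family with TCN), ATA = Met, TGA = Trp. Synonymous
families group codons by encoded amino acid, taken from the code object, not
a hard-coded 61-codon table. (The published codon table prints AUA under
(I); under table 5 it belongs to the Met family, and the AGA/AGG=(S) rows in
the same table confirm table 5 was in use — the package follows the code.)

Codons are consecutive non-overlapping triplets from position 1 of each
coding-strand CDS; a trailing incomplete codon (the `T-`/`TA-` stop) is
dropped, as is a terminal complete stop codon; codons containing N are
excluded and counted. Start codons are counted as their literal triplet
(no Met-recoding). RSCU of codon c in a family of size k is
`count(c) · k / Σ family counts`; a family with zero usage is flagged and
reported as 0. The family mean of RSCU is exactly 1 for every used family,
and RSCU is invariant under duplicating every gene.

## tRNA cloverleaf statistics

`pair_stats` is the load-bearing operation: given a structure (arm pair
lists over the gene sequence), it classifies each pair as Watson–Crick
(A-T/G-C), weak G-U (G-T in DNA), or a typed mismatch (U-U, A-G, U-C, A-C,
…, named with RNA letters in a fixed canonical order). The "unmatched"
tally of a tRNA set is G-U plus true mismatches. Structures may be supplied
externally (TSV sidecar with dot-bracket and arm spans).

`fold_cloverleaf` is a versioned constraint heuristic, not a thermodynamic
folder: acceptor stem fixed at 7 pairs with one 3′ discriminator base;
anticodon stem 5 pairs around a 7-nt loop centered on the given anticodon;
TΨC stem 4–5 pairs (loop 3–9) anchored against the acceptor 3′ arm; DHU
stem 3–4 pairs (loop 3–11) in the window between the acceptor and anticodon
5′ arms. An arm is accepted when at most one position fails to pair (floor
of 3 true pairs); candidate ties prefer higher score, larger stem, then the
template-anchored position. If no DHU candidate passes, the arm is declared
absent — the metazoan tRNA-Ser(AGN) situation. On generator-built template
tRNAs the folder recovers all arms exactly for ≈88% of tRNAs (misplacements
concentrate in arms that carry planted mismatches, which lower the true
arm's score) and calls DHU presence correctly in >99.7% of cases; it never
hard-fails on template tRNAs. Exact pair accounting therefore runs on truth
structures, with the folder checked separately.

## Control-region scanners

All scanners take an `origin` parameter and report 1-based inclusive
coordinates in that frame, making them shift-equivariant by construction.

* **Poly-N runs**: maximal single-base runs ≥ 7 bp (configurable).
* **Microsatellites**: maximal perfect repeats of primitive units 1–6 bp
  with ≥ 5 complete copies; period-1 runs are left to the poly-run scanner
  by default; output is irredundant (an (AT)8 is never also an (ATAT)4).
* **Tandem repeats**: bespoke period enumeration (units 7–200 bp) with
  adjacent-copy Hamming identity ≥ 0.85; fractional copy number =
  array length / unit length including a trailing partial copy; array
  boundaries are anchored on matching positions so calls do not creep into
  flanking sequence. Two specificity filters: a minimum array length of
  30 bp (two near-identical copies of a very short unit arise constantly by
  chance), and rejection of consensus units that are ≥80% a repetition of a
  period ≤ 6 (those belong to the microsatellite scanner). Overlapping
  calls are resolved greedily by copies × identity, ties to smaller units.
* **Stem-loops**: pure inverted-repeat scanning (Watson–Crick + G-T
  wobble), stems ≥ 10 pairs with ≤ 2 internal mismatches around loops of
  3–30 nt; no thermodynamics. The 3′ flank is scanned for the
  replication-associated G(A)nT motif and classified exact / modified
  ("GTA") / absent. Calls are ranked by net pairs, then fewer mismatches,
  then smaller loops.

False-positive behavior differs by scanner. On uniform random 300-mers the
tandem-repeat scanner is empty in ≥95% of seeds (tested over 200 seeds) and
the microsatellite scanner almost always. Poly-run and stem-loop scanners
do fire on A+T-rich random sequence — a ≥7 bp homopolymer or a partially
complementary inverted repeat in 85% A+T DNA is a real feature of the
sequence, not a detector error — so their validation is plant-and-recover
(exactness of planted calls), not a false-positive rate.

The five-part partition report merges adjacent tandem arrays into blocks
and labels lead / blocks / spacers / tail; segment lengths always sum to
the CR length.

## Synthetic mitogenome generator

The generator is first-class, tested code: it is the ground-truth harness
for every scanner and statistic. The default layout reuses the published
37-gene + CR coordinate skeleton, so the planted overlaps (including both
7-nt ATGNTAA junctions), start/stop codon classes, and the 63–71 bp tRNA
size range match the real genome's organization exactly; the truth record
carries every plant.

Generation runs in two passes over a genome canvas. A constraint pre-pass
writes every PCG start codon and stop tail (strand-aware) so overlapping
neighbors see them as fixed bases; generation then proceeds in genome
order: PCG interiors are drawn codon-wise from the published codon-count
distribution (stops excluded, in-frame stops re-drawn where unconstrained),
tRNAs are built from a parameterized cloverleaf template honoring forced
bases (overlaps only ever touch acceptor-tail positions in this layout)
with planted G-U/mismatch pairs, rRNAs and intergenic filler come from
per-class base distributions defaulting to the published composition rows
(whole-genome 68.6% A+T, CR 85.2%), and the CR is assembled from an
explicit plan. Conflicting constraints raise a configuration error before
any sequence is emitted.

The default CR plan mirrors the published five-part structure: a 360 bp
lead containing an 18-pair perfect hairpin with an 8-nt loop and a "GTA"
(modified) 3′ flank; a 75 bp block of a 19 bp unit × 3 plus an 18 bp
partial copy; a 23 bp spacer; a 44 bp block of a 16 bp unit × 2.75; and a
233 bp tail containing two 9 bp poly runs (A and T) and an (AT)8
microsatellite. (The published part lengths print as 360/75/23/44/231,
which sums to 733, two short of the printed 735 bp CR; the default tail is
233 bp so the plan tiles the CR exactly.) Planted elements are flanked by
guard bases chosen so chance sequence cannot extend a run, repeat array or
stem — this is what makes exact plant-and-recover a meaningful test rather
than a coin flip. Filler homopolymer runs are capped at 6 bp for the same
reason. Consequences worth knowing: guard bases and codon-driven PCG
interiors mean realized class compositions differ from the configured
targets by design; the truth record stores the realized values.

What the generator does not emulate: sequencing error, heteroplasmy,
within-genome composition gradients, rRNA secondary structure, indels, and
annotation error. Passing plant-and-recover therefore demonstrates scanner
correctness at the stated thresholds, not robustness to noisy annotation.

## Phylogeny: GTR+I+G maximum likelihood

The substitution model is GTR with stationary frequencies π, six
exchangeabilities (GT ≡ 1 for identifiability), a proportion of invariant
sites p_inv, and gamma rate heterogeneity discretized into k = 4
equal-probability categories represented by their category means
(computed from regularized incomplete gamma functions). The rate matrix is
scaled so the expected rate over the whole I+G mixture is 1: variable-site
category rates are multiplied by 1/(1−p_inv). Branch lengths are therefore
expected substitutions per site.

Likelihood is Felsenstein pruning over unique site patterns with
per-pattern rescaling (max-normalization per node, log-accumulated), so
deep trees cannot underflow; gaps and N are missing data (leaf partials of
ones). The invariant-site term of a pattern is π of its shared observed
state (1 for all-missing, 0 for polymorphic patterns), combined on the log
scale via logaddexp. Transition matrices come from the eigendecomposition
of the π-symmetrized generator. The tests verify pruning against explicit
enumeration over all internal-state assignments and categories (4 taxa,
30 sites, agreement to 1e−8 — in practice ~1e−14) and the α→∞, p_inv = 0
limit against a single-rate GTR likelihood (1e−6).

Fitting is coordinate ascent on a fixed topology: bounded Brent line
searches per branch (lengths in [1e−8, 10]), then Nelder–Mead on
(log α, logit p_inv), then Nelder–Mead on the five free log
exchangeabilities; a step is only accepted if it does not decrease the
log-likelihood, and convergence is declared when a full round gains less
than 1e−4. Stationary frequencies are empirical (+F, the common default in
ML phylogenetics) rather than free parameters — with AT-rich
mitochondrial data the empirical estimator is accurate and removes three
parameters from a search that coordinate ascent traverses many times. On
5,000-site simulations with α = 0.5 truth, α̂ lands in [0.35, 0.70]
(observed spread ≈0.40–0.68 over 20 replicates) and p̂_inv < 0.05 when the
truth has no invariant fraction; α and p_inv estimates are mildly
correlated upward, the well-known I+G ridge.

Tree search is neighbor joining on Jukes–Cantor distances (pairwise
deletion; mismatch fractions ≥ 0.75 receive a fixed saturation distance of
5 substitutions/site; negative NJ branch lengths are clamped to zero)
followed by NNI hill climbing: every internal edge proposes its two
rearrangements, each scored after re-optimizing only the central edge, and
the best improving move is applied until a sweep gains < 1e−3. Internal
branches optimized to ≤ 1e−7 are collapsed, so an identical-sequence
alignment yields a star tree, which downstream consumers flag instead of
decorating with meaningless supports.

Nonparametric bootstrap resamples alignment columns with replacement,
re-runs NJ + NNI per replicate, and reports, for each internal split of the
reference ML tree, the percentage of replicates containing it. The default
is B = 100 (a desk-scale default; the flag raises it). Identical seeds give
identical supports.

Problem sizes used by the validation study: a 14-taxon truth tree shaped
like the published Amphinemurinae phylogeny (two to three species per
genus, internal branches 0.03–0.08, terminals 0.07–0.16), GTR+I+G truth
with AT-rich frequencies, α = 0.5, p_inv = 0.2, supermatrices of 5,000
sites split over 13 gene blocks, 20 replicates, and one B = 100 bootstrap;
per-replicate inference uses two coordinate-ascent rounds before the NNI
climb, which is where the likelihood surface stops changing the topology
ranking. Observed: 20/20 replicates recover the generating topology and
all 11 true splits average 100% support.

## Known limitations

* The GenBank reader handles single records with CDS/tRNA/rRNA/D-loop (or
  "control region" misc_features) and origin-spanning `join()`s; it is not
  a general-purpose location-grammar implementation.
* The tandem-repeat detector is deliberately small-scale (exact Hamming
  identity, no indels within arrays, no alignment-based consensus
  refinement) and is tuned for CR-sized sequences, not chromosomes.
* The stem-loop scanner has no thermodynamics; on A+T-rich sequence it
  reports every qualifying inverted repeat, by design.
* The ML stack is single-partition; per-gene partitioned models, model
  selection, dating and Bayesian inference are out of scope.
* NNI from an NJ start can in principle stop in a local optimum; the
  validation study shows this does not occur at the study's signal level,
  but pathological data can defeat any hill climber.
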