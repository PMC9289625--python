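# Methods

`ltrdomains` implements a desk-scale, fully testable pipeline for discovering
non-canonical protein domains that have become fixed in plant LTR
retrotransposons, and for the quantitative analytics used to validate a
retrotransposon-encoded m6A RNA demethylase (a 2-oxoglutarate/Fe(II)-dependent
dioxygenase, 2-ODD, of the AlkB family). This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data do
and do not show.

## Discovery model

The pipeline anchors discovery on the reverse-transcriptase (RT) domain, the
most conserved marker of LTR retrotransposons:

1. **Translated profile search.** Each genome is translated in six frames
   (standard code; codons containing N translate to X, stops to `*`) and
   scanned with amino-acid position-specific scoring matrices (PSSMs). A
   profile is a length × 20 log-odds matrix in bits: the master residue of a
   column carries probability 0.7, the rest of the mass is uniform over the
   other 19 residues, and odds are taken against a uniform 1/20 background
   (so a master column scores log2(0.7/0.05) ≈ 3.81 bits). Windows scoring at
   least 1.5 bits per column become hits; overlapping hits are merged keeping
   the maximum score. The 1.5 bits/column default puts the cutoff roughly 30
   standard deviations above the random-window score distribution — the
   empirical false-discovery rate on element-free genomes is zero (tested
   over 10 seeds) — while still detecting cassettes diverged by >25% at the
   amino-acid level.
2. **Size filter.** Merged RT spans must fall in 520–840 bp, bounds
   inclusive.
3. **Identity clustering.** Per species, RT sequences are clustered greedily
   at 95% global identity (length-descending insertion order, lexicographic
   tie-breaks); each cluster contributes at most 50 sequences downstream.
   Global identity is identities / alignment length under Needleman–Wunsch
   with match 1 / mismatch −1 / gap open −5 / extend −1 (gap columns count
   against identity); the pairwise engine is `Bio.Align.PairwiseAligner`.
4. **Locus extension.** RT hits grow by 5 kb per side (clamped at contig
   ends); minus-strand loci are reverse-complemented into element
   orientation.
5. **Locus clustering.** A locus joins a representative when their best
   local alignment covers ≥ 0.5 of the shorter sequence at ≥ 0.8 identity.
   The identity floor is a deliberate addition: a coverage threshold alone
   under-specifies cluster tightness. Loci longer than 15 kb are not
   admitted. Clear decisions are fast-pathed by a seed-chain estimate
   (exact 11-mer matches bucketed by diagonal; the k-th root of the hit rate
   estimates identity); only borderline pairs reach the exact local aligner.
6. **Consensus.** Clusters with ≥ 5 members are aligned with a progressive
   aligner: k-mer (k = 8) cosine-distance guide tree joined by UPGMA,
   profile–profile Needleman–Wunsch with affine gaps (open −5, extend −1),
   banded around the proportional diagonal (half-width 512, widened by any
   length difference) once the profile-pair table exceeds 4·10⁶ cells. A
   column is a match column iff its non-gap fraction is ≥ 0.5 (boundary
   inclusive); the consensus emits the most frequent non-gap residue per
   match column (ties alphabetical) and drops non-match columns. Majority
   vote denoises: on a family at divergence d ≤ 0.05 the consensus is
   ≥ (1 − d)-identical to the family master.

Because loci are RT ± 5 kb, elements much longer than ~11 kb reconstruct
truncated — the package reproduces this artifact deliberately (a 25.5 kb
family yields a < 12 kb consensus), which is why full-length characterization
is a separate stage.

## Domain annotation and the fixation filter

Consensuses are scanned with the full profile library (same engine); hits in
the canonical families {Gag, protease, RT, RNaseH, integrase, Chromo} are
filtered out; redundant hits against homologous profiles can be collapsed to
one representative per family. A non-canonical domain counts as *fixed* in a
species only when detected in at least `min_consensuses` (default 5) distinct
consensuses of that species. One family yields one consensus, so the filter
is effectively a subfamily count: a lineage must have speciated into several
consensus-yielding subfamilies before its extra domain is reported. The
unfiltered matrix is always computed alongside (the no-filter view is the
same code path).

Superfamily classification takes the translated RT region of a consensus
(max-score hit), aligns it locally (BLOSUM62, open −11 / extend −1) against a
labeled RT reference library and returns the label of the best score; a
margin under 1 is flagged ambiguous rather than silently resolved; no RT
region means `unclassified`.

Motif scanners report the demethylase cofactor motifs — H-x-D/E with a
distal H 30–90 residues downstream of the motif start (covers the documented
His→His spacing of the human AlkB-family demethylase fold), R-x(5)-R, YNF,
and the 2-OG-stabilizing N/Y pair when a reference alignment block is
supplied — plus K/R-rich basic patches (sliding 25-residue windows at ≥ 0.4
K/R, merged), a proxy for disordered RNA-binding regions.

## Full-length element structure

LTR pairs are found by exact 20-mer seeding between positions whose offset
lies in [5,000, 20,000] (the offset is between repeat *start* positions),
grouping seeds by offset (±30 for indel drift, split when runs are separated
by more than one repeat length), X-drop extension (+1 match / −2 mismatch,
drop 25) and a maximum-likelihood changepoint refinement of each terminus
(match weight +1.28, mismatch −2.04, i.e. log-likelihood ratios for ~90%
repeat identity vs 25% background match) with a soft bonus (+3 both copies,
+1.2 one copy) for the canonical TG…CA termini. Repeats must be 100–3,000 bp
(cap configurable; the giant Ogre-like worked example needs 7,000) at ≥ 0.85
identity; overlapping candidates resolve by identity × length. Measured
accuracy against generator truth at 5% per-copy divergence: ≥ 90% of
boundaries within ±5 nt, all within ±15 nt over 20 replicates; at zero
divergence boundaries are exact unless the flanks continue matching by
chance — the changepoint estimator's information-theoretic limit, which no
local boundary rule can beat.

An LTR pair carries no strand information, so both orientations of the
internal region are annotated and the orientation with the stronger PBS/PPT
evidence is kept. The PBS is the reverse complement of the 3'-terminal
12–18 nt of a library tRNA within 30 nt of the 5' LTR (longest match, then
closest); the PPT is the highest-purine-fraction run of ≥ 10 nt within 50 nt
of the 3' LTR (≥ 0.85 purines). ORFs are maximal ATG→stop spans (≥ 300 aa by
default; `any_start` relaxes the ATG requirement); dual RNase H is the count
of non-overlapping RNase H profile hits on the polyprotein. Masking uses
13-mer seed-and-extend local alignments; divergence is mismatches /
alignment length (no CpG-adjusted correction), alignments above 20%
divergence are rejected, and coverage is reported both over total assembly
length and excluding N runs.

## Phylogenetics

Domain regions are extracted via their profile hit, and placement uses
Poisson-corrected amino-acid distances, d = −(19/20)·ln(1 − 20p/19) with p
the mismatch fraction over mutually ungapped columns (saturated pairs capped
at 5.0 and flagged), canonical neighbor joining (Q-matrix ties to the
smallest label pair; the final three nodes join by the three-point formulas)
and column-resampling bootstrap (default 100 replicates) counting recovery
of the point-estimate tree's bipartitions. This is a deliberate desk-scale
substitute for maximum-likelihood inference: the package's claims are about
pipeline mechanics and qualitative placement (which reference group contains
the query, relative to a user-declared outgroup), not likelihoods. NJ is
exact on additive matrices (property-tested) and cross-checked against
scikit-bio's implementation.

## Biochemical estimators

EMSA lanes give fraction bound θ = 1 − free/total. The Hill transformation
log10(θ/(1−θ)) = n·log10(c) − n·log10(Kd) is fitted by unweighted ordinary
least squares on replicate means; the slope is the Hill coefficient and
Kd = 10^(−intercept/slope). Lanes with θ outside (0, 0.999) or non-positive
concentration are excluded and reported, never silently dropped; a
non-positive slope raises (non-binding data). Protein mass converts to
concentration by c [μM] = ng / (kDa · μL); the molecular weight is a required
user input. Noise-free recovery is exact to numerical precision; with 2%
Gaussian noise on θ the median recovered Kd over 1,000 replicates stays
within 5% of truth.

Chromatogram analysis integrates baseline-subtracted intensity trapezoidally
in non-overlapping retention-time windows (baseline = median of the
out-of-window trace), or sums discrete peak areas by window. The m6A/A ratio
is the area ratio, and demethylation is 100·(1 − ratio_sample/ratio_control),
invariant to common rescaling of both chromatograms.

## The synthetic-data generator

The generator is first-class, tested code; its defaults define the study
conditions:

* **Elements.** Master elements have identical LTRs with TG…CA terminal
  inverted repeats (default 5 nt), a PBS that is the reverse complement of
  the 3'-terminal 14 nt of a named tRNA (configurable 12–18; the literature
  states only the tRNA identity) placed immediately inside the 5' LTR, a
  ≥ 12 nt pure-purine PPT immediately ahead of the 3' LTR, and stop-free
  ORFs built by codon-level sampling (never post-hoc patching) that embed
  amino-acid domain cassettes sampled from the profile masters with 2%
  residue noise. An in-frame stop is written directly ahead of each ORF so
  the designed ATG is the true ORF start. The Ogre-like default carries a
  gag-pol polyprotein with a dual RNase H plus a separate 2-ODD ORF with an
  N-terminal K/R patch; the Copia-like default has a single polyprotein with
  integrase ahead of RT and no extra ORF. The worked-example element uses
  the published dimensions: 25,510 bp, 6,425 bp LTRs, ORFs of 2,640 and
  565 aa.
* **Genomes.** Background is iid at a specified GC with no repeats beyond
  the implanted elements, so ground truth is unambiguous. Copies diverge by
  iid substitutions (default 2%, exposed as a parameter — the real
  within-family distribution is not asserted); indels are opt-in and never
  placed in LTRs. Strand is random per copy; N runs are written last and may
  not overlap implanted copies (error, never silent clipping). Everything is
  deterministic given the spec seed.
* **Lineages.** Subfamily masters derive from a common founder at a chosen
  divergence (default 16% — old enough that subfamilies do not co-cluster at
  the 0.8 identity floor, young enough that one RT profile finds all of
  them). Inside ORFs the lineage mutation is codon-level and stop-free,
  modeling purifying selection on families that retained coding capacity;
  outside ORFs and in LTRs it is plain nucleotide substitution. The default
  discovery scenario implants five 6-copy 2-ODD-bearing Gypsy subfamilies
  plus one 6-copy plain Copia family, the minimal configuration in which a
  non-canonical domain passes the fixation filter.
* **Biochemistry.** Binding series follow θ(P) = Pⁿ/(Kdⁿ + Pⁿ) with
  truncated Gaussian noise and always include a zero-protein lane;
  chromatograms emit Gaussian peaks for G, A and m6A at fixed retention
  times (3.2, 4.5, 6.0 min; σ = 0.04 min) with areas realizing the requested
  m6A/A ratio.

**What passing tests show — and do not show.** The generator emulates the
statistical structure the pipeline assumes (multi-copy families, controlled
divergence, LTR architecture, extra ORFs) but not nested or fragmented
insertions, solo LTRs, low-complexity or satellite background, sequencing or
assembly error, or realistic codon usage. Passing tests demonstrate that the
pipeline's logic is correct under those assumptions, not that its thresholds
are optimal for real assemblies.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale inputs chosen as the smallest sizes
that exercise every code path: genomes of 20–560 kb, families of 4–6 copies,
five-subfamily lineages, alignments of ≤ 50 × 15 kb, 100 bootstrap
replicates, 1,000 Monte-Carlo replicates for estimator bias. Determinism is
end-to-end: every stochastic routine takes a seed, and fixed-seed CLI runs
are byte-reproducible. Degenerate inputs are defined, not special-cased:
empty genomes scan to empty hit lists, all-gap alignments give empty
consensuses, single sequences align trivially, saturated distances cap at
5.0, and infeasible element packings raise sizing errors.

## Known limitations

* The MSA is progressive with no iterative refinement or consensus
  polishing by remapping.
* The LTR detector's distance constraint follows the repeat-start-offset
  convention; elements whose LTRs exceed the configured cap are invisible
  until the cap is raised (the worked example documents this deliberately).
* No E-value statistics: profile scans use bit thresholds only.
* Masking divergence is raw mismatch fraction, not a substitution-model
  corrected distance.
* No TSD detection, insertion-age estimation, nested-element resolution, or
  solo-LTR simulation.
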