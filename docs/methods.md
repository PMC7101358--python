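# Methods

This note documents the models, numerical choices and limitations behind
`saltlnc`. Coordinates are 0-based half-open on the forward strand
internally; report files are 1-based inclusive.

## Ungapped local alignment and significance

All homology rules run through one engine (`saltlnc.align`): exact words
(default length 11, minimum 8) seed ungapped extensions in both directions
with an X-drop of 20 score units; overlapping extensions on one diagonal
are merged and one maximal-scoring window per seeded diagonal is reported.
Scores use match +1 / mismatch −2; N never matches anything. Significance
is a Karlin–Altschul-style e-value E = K·m·n·e^(−λS) with λ = 1.28,
K = 0.46 for this scoring scheme, where m is the query length and n the
*total* reference-set length (the usual search-space convention). These
constants mimic, but do not reproduce, BLASTn; externally produced
alignments can be imported through the 12-column tabular dialect, where
rows with gap openings are retained but flagged and excluded from the
ungapped-only NAT rule.

Two desk-scale consequences are worth naming. First, gapped alignment is
not implemented: the decisive NAT rule forbids gap openings, and the
identity-dominated classification rules lose little without it; users with
gapped aligners use the import path. Second, with references thousands —
not millions — of nucleotides long, a chance exact ~12-mer can satisfy
(identity ≥ 0.90, E ≤ 0.1). This is a property of the e-value at small
m·n, not a bug; the synthetic generator accounts for it (below).

The translated (protein) search uses the same seed-and-extend machinery on
six-frame translations with 4-residue seed words, identity scoring and the
same e-value form, thresholded at 10⁻⁵. It is a deliberately simple
stand-in for a protein aligner: adequate for near-exact matches (which is
what the generator plants and what a within-species protein set yields),
not for remote homology.

## Coding potential

The union rule marks a transcript coding if it has a protein hit at
E ≤ 10⁻⁵, OR a complete ORF of ≥ 100 codons (a common long-ORF
convention), OR a positive mean hexamer log-odds over its longest complete
ORF. The hexamer model scores s(h) = log₂((f_cod(h)+c)/(f_bg(h)+c)) with
pseudocount c = 1; coding frequencies are computed over in-frame hexamers
of training ORFs and background frequencies over all-frame hexamers, so
the model captures both codon usage and frame structure. Because the two
frequency fields are computed differently, identical training sets yield
zero scores only for frame-invariant sequences (e.g. homopolymers) — the
symmetry is in the formula, not in the featureization. The hexamer term is
applied only when a trained model is supplied; the default pipeline runs
on the protein-homology and long-ORF terms, which is the robust
configuration when no curated training split exists.

## Classification order and rescue

Decision order per transcript: (1) length < 200 nt → too short (the
"longer than 200 bp" convention is implemented inclusively at 200, and is
configurable); (2) coding; (3) miRNA-hairpin homology; (4)
conserved-lncRNA homology; (5) known-ncRNA homology → excluded as a known
small RNA; (6) novel lncRNA. Running (3)–(4) before (5) implements the
rescue of probable precursors and conserved lncRNAs from the ncRNA
exclusion; the final lncRNA reference is the union of (3), (4) and (6).
The ncRNA exclusion reuses the (0.90, 0.1) thresholds of the other
homology rules, an assumption the configuration exposes. Redundancy
removal is a greedy longest-first clustering (join when identity ≥ 0.90
over ≥ 80% of the member's length), a simplification of CD-HIT-EST that is
exact for the well-separated clusters it is used on here.

## SSR scanning

Perfect tandem repeats of primitive 2–6-nt motifs at minimum repeat counts
6/5/5/4/4. Reported runs are maximal in whole periods; non-primitive
motifs are never considered, which is also what suppresses sub-period
re-descriptions ((AT)₆ is not re-reported as (ATAT)₃). Canonical classes
take the lexicographically smallest rotation over the motif and its
reverse complement, printed "AG/CT"-style. Mononucleotide runs and
compound/interrupted SSRs are out of scope. A maximal run may begin up to
one period before a planted tract when a chance flank base extends it;
consumers comparing to planted coordinates should compare runs, not start
offsets.

## Replicate-free differential expression

With one library per condition the dispersion is not estimable, so the
test assumes one. `nb_exact_test(y_a, y_b, L_a, L_b, φ)` conditions on
s = y_a + y_b, places NB(s·p_a, φ) and NB(s·(1−p_a), φ) masses on the two
sides with p_a = L_a/(L_a+L_b), normalizes over the s+1 splits, and sums
the probabilities of all splits no more probable than the observed one
(two-sided). At φ = 0 this is exactly Binomial(s, p_a). φ is the squared
biological coefficient of variation (edgeR's "dispersion"); the module
default 0.4 is deliberately conservative for field-collected material,
and synthetic-study runs set φ = 0.1 to match the generator's order of
magnitude — the assumed dispersion is a declared analysis input, not an
estimate. Fold changes are CPM-style: log₂((y_a+0.5)/L_a) −
log₂((y_b+0.5)/L_b); TMM-style composition correction is out of scope, so
the generator keeps planted signal a small share of library mass (below).
q-values are Benjamini–Hochberg step-up with monotone enforcement, and a
transcript is called at |log₂FC| ≥ 2 and q < 0.01 ("log fold change ≥ 2"
is read as a two-sided magnitude rule, since both directions are
reported). The Pfaffl ratio E_t^ΔCt_t / E_ref^ΔCt_ref is provided for
qPCR relative quantification.

Calibration, measured by the tests: on 2000 matched-dispersion null pairs
(mean 100, φ = 0.4) the raw rejection rate at α = 0.05 falls in
[0.03, 0.07] (the conditional discrete test is slightly conservative).
Power is measured on a planted-only matrix (200 transcripts, mirrored
up/down 8-fold shifts at mean 500, φ = 0.1) where recall of the full
calling rule is ≥ 0.9; the binding constraint is the |log₂FC| ≥ 2 margin
itself, whose pass probability at a true fold change of 8 and φ = 0.1 is
≈ 0.94 per transcript. The mirrored design (up: 500→4000, down: 4000→500)
keeps the two library totals exchangeable, isolating test power from
normalization composition bias.

## NAT pairs and hybridization

Candidates require an ungapped match ≥ 150 nt (inclusive) at ≥ 90%
identity between a salt-responsive lncRNA and a salt-responsive coding
transcript; both orientations are searched and stored. Confirmation
slides the shorter sequence along the reverse of the longer at every
offset and sums per-position duplex energies — G:C −3.0, A:U −2.0, G:U
−1.0 kcal/mol, anything else +1.0 — returning the offset with minimal
total ΔG; ndG = ΔG/L over the overlap length L, confirmed at
ndG ≤ −0.1. The constants follow the published normalized-free-energy
convention in spirit; they are documented defaults, not fitted values, and
the scorer is gap-free (no bulges or loops), consistent with the ungapped
candidate rule. Concordance percentages (similar = up/up + down/down) are
reported to one decimal over confirmed pairs whose two members both have a
DE direction.

One empirical property matters for target counting: for *unrelated*
transcripts of typical composition the best-offset ndG is itself ≈ −0.3
to −0.4, because one quarter to one third of random juxtapositions pair
and the optimizer picks the best of hundreds of offsets. The −0.1 cutoff
is therefore meaningful only downstream of the 150-nt/90% prefilter (its
role in NAT confirmation). The target-count ranking of the
expression-filtered lncRNAs, which has no such prefilter, uses a stricter
cutoff (−0.7 by default, configurable) that unrelated pairs essentially
never reach while planted complementary islands clear it with margin.

## miRNA precursor, family, hairpin and targets

Precursor annotation is hairpin homology at (0.90, 0.1) on both strands;
the precursor name is the subject name with any species prefix stripped;
the family strips arm suffixes and trailing variant letters, keeping
"mir<number>". Distinct-precursor counts key on precursor names, not
lncRNA ids (two lncRNAs may carry the same precursor). The hairpin check
is a documented stand-in for structure-based webservers: Nussinov
maximum base pairing (G:C/A:U/G:U, minimum hairpin loop 3) with a
stem-favouring traceback, passing when the longest stacked stem has ≥ 15
pairs and ≥ 30% of bases pair, on sequences of 40–400 nt. A pass means
"plausible hairpin", nothing stronger. Target prediction follows the
plant expectation-score convention: gap-free sliding of the 18–24-nt
mature sequence, penalties 1.0 per mismatch and 0.5 per G:U wobble,
doubled within seed positions 2–13, best site per transcript reported at
E ≤ 5. Regulator patterns: a down-regulated miRNA with > 50% up-regulated
targets is a positive regulator of tolerance; an up-regulated miRNA with
≤ 50% target up-regulation a negative one. The pipeline evaluates every
annotated family (flagging which are contrast-specific by set difference)
rather than only the specific ones, since specificity is an outcome, not
an input.

The packaged differential miRNA–lncRNA table ships as a TSV fixture. Its
three-column layout was reconstructed from a flattened text rendering
under the jointly sufficient constraints of the per-contrast counts
(9/8/10 precursors, 7/7/8 families), the pooled counts (14 precursors, 11
families) and the genotype-specific family narrative; the pooled counts
are insensitive to the column assignment.

## Synthetic data: what it emulates, and what it does not

`saltlnc.simulate` builds a 200-transcript default study: 60 coding
transcripts (UTRs + a planted 120–200-codon ORF at GC ≈ 0.40, whose
translations form the mock protein set), 90 plain lncRNAs (GC ≈ 0.36,
250–700 nt), 12 hairpin-embedding pre-miRNA lncRNAs, 10 conserved-segment
lncRNAs, 12 near-copies of mock ncRNAs, 16 sub-200-nt fragments; 8
antisense NAT pairs (200-nt overlap at exactly 93% identity, planted into
coding 3′ UTRs), 15 SSR tracts, 8 transposon-fragment carriers, 6
triple-response lncRNAs carrying complementary target islands (140 nt —
deliberately below the 150-nt NAT rule) in a descending number of coding
hosts, and mature-miRNA sites for two down-regulated precursor families.
Counts are negative binomial (default φ_gen = 0.05, probing robustness
against the φ = 0.1 analysis setting) with planted fold changes of 2⁴ for
feature-carrying transcripts and 2^±[2.5,4] for ordinary responders;
library-size factors are drawn within ×2 of each other.

Two generator policies make the planted truth exact rather than merely
likely. First, background transcripts are rejection-sampled until they
carry no chance SSR, no ≥ 100-codon ORF and no (0.90, 0.1) homology to any
mock reference set — honoring the desk-scale e-value property above — and
the mock reference sets themselves are cross-screened against each other
at a looser margin so no reference entry can deadlock the sampling.
Second, expression planting controls library composition: up- and
down-regulation alternate and background means are drawn log-uniformly up
to 2×10⁴, so the planted signal stays a small share of library mass and
CPM normalization remains nearly unbiased, as in real libraries.
Triple-response lncRNAs are chosen among hosts ≤ 450 nt so their target
islands dominate the normalized duplex energy.

What passing the recovery suite does **not** show: performance on real
assemblies with fragmented isoforms, sequencing error, shared domains
between coding genes, repeat families with internal structure, remote
(gapped, low-identity) homology, or dispersion misspecification beyond the
probed factor of two. The generator plants clean, well-separated signal at
generous margins by design; it validates the logic and the wiring of every
stage, not field accuracy.

## Pipeline mechanics

A run directory holds plain-text inputs (`transcripts.fasta`,
`counts.tsv`, `refs/`) and one output per stage; each stage is a pure
function of saved files plus the resolved configuration, so single-stage
reruns are byte-identical and full reruns with equal seeds produce
identical manifests (modulo timestamps). The resolved configuration is
written next to the outputs; unknown keys are rejected. Defaults follow
the study's thresholds wherever one is stated (min length 200, homology
0.90/0.1, protein 10⁻⁵, SSR 6/5/5/4/4, DE τ = 2 / α = 0.01, NAT 150/0.90,
ndG −0.1); everything else is ours and documented here. Top-k selection
by target count breaks ties deterministically (count descending, then id
ascending). The `--threads` flag is accepted for interface compatibility;
results are independent of it.

## Problem sizes used by the test and acceptance runs

The default synthetic study is 200 transcripts × 5 samples; oracle suites
use 50 alignment pairs ≤ 300 nt, 100 × 5-kb SSR sequences, 100 folding
sequences ≤ 12 nt and 50 hybridization pairs; calibration uses 2000 null
pairs and a 200-transcript power matrix. These sizes were chosen so each
engine's oracle check is exhaustive at small n while the end-to-end run
remains a desk-scale computation.
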