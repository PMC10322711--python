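# Methods

`trarep` models and analyses the formation of T-cell receptor α (TRA)
repertoires in which the outcome of V(D)J recombination is largely dictated
by germline sequence: short terminal microhomologies at the ends of V and J
elements — plausibly remnants of the target-site duplication (TSD) of the
founding transposon insertion — template the non-homologous end joining
(NHEJ) of the coding ends, so that a large part of the repertoire is
predictable from the germline alone. The package has two halves: a
synthetic-data generator that produces germline loci, rearranged clones and
UMI-tagged reads with complete ground truth, and an analysis pipeline
(extraction, junction annotation, entropy decomposition, genome scanning,
cohort statistics) that must recover that ground truth. This note records
the model, the defaults, and the design decisions taken where the design
was genuinely open.

## Germline templates

**V elements.** Each V coding sequence ends in the conserved 14-nt terminus
`TGTGCTCTGAGGCC`, position 1 being the first nucleotide of the conserved
Cys codon (TGT); the recombination signal sequence (RSS, heptamer
`CACAGTG` + 23-nt spacer + nonamer `ACAAAAACC`) begins at position 15.
A configurable fraction of elements (`v_rss_phase_fraction`, default
0.992) carries this canonical geometry; the remainder carry one extra
nucleotide between the Cys codon and the microhomology block, displacing
the RSS to position 16. The displacement is placed *upstream* of the
microhomology block because the block is physically adjacent to the RSS:
microhomology joins on displaced elements therefore shift by one
nucleotide and fall out of frame, which is the behaviour observed for
natural "rogue" elements and for engineered single-base RSS displacements.

**J elements.** Each J exon opens with `TGCC` (the mirrored microhomology
block), places the Phe of the FGXG tetrad so that its reading-frame phase
relative to the RSS boundary is 2 ("primordial"; `j_primordial_fraction`,
default 134/137), and ends 33 exonic nucleotides after (and including) the
Phe nucleotide, followed by the GT splice donor. We report the
tetrad-to-donor distance as the inclusive count from the Phe nucleotide to
the donor G, which makes the canonical value 34. Five J length classes
(Phe codon at exon positions 12, 15, 18, 21 or 24, drawn uniformly) give
CDR3-side J contributions of 14–26 nt, all ≡ 2 (mod 3). The exon tail also
realises the degenerate nucleotide signature used by the genomic Jα
scanner (see below), with the tetrad Phe at signature offset 5 — the only
register in which the signature's fixed TT/GG/GG/AC dinucleotides coincide
with the F-G-X-G-T codon structure.

**Microhomology patterns.** Four default patterns:

| id | V motif (from Cys) | J motif (from coding start) | CDR3 length |
|----|--------------------|------------------------------|-------------|
| 1  | TG at 8–9          | TG at 1–2                    | 7 + lenJ    |
| 2  | G at 12            | G at 2                       | 10 + lenJ   |
| 3  | C at 13            | C at 3                       | 10 + lenJ   |
| 4  | C at 14            | C at 4                       | 10 + lenJ   |

V positions are anchored to the RSS boundary and J positions to the coding
start, so phase-displaced elements displace their joins. Patterns 2 and 3
yield equal lengths by construction. We chose P4's coordinates so that all
four patterns are in frame on canonical-phase segments (lenJ ≡ 2 mod 3);
the alternative single-C placements that would create a third distinct
dominant length per V–J pair (13 + lenJ) require a C at J position 1,
which conflicts with the TG block. A consequence of shared templates is
that patterns 2–4 produce byte-identical junctions on the same V–J pair;
the simulator therefore records, besides the drawn pattern, the
*canonical* pattern id (lowest id producing the same sequence), which is
the only identity inferable from sequence and the one used in recovery
checks.

## Recombination model

Each clone draws a V and a J (uniform usage by default; real usage
distributions are unpublished) and one join mechanism:

* **Microhomology** (probability `mh_join_prob`, default 0.65): a pattern
  drawn from `pattern_weights` (default 0.50/0.20/0.15/0.15) renormalised
  over the patterns applicable to the chosen pair; the join keeps the V up
  to the motif and the J beyond it, the motif itself being attributable to
  either end. If no pattern applies the draw falls back to the trimming
  branch (logged).
* Among non-microhomology joins: **P-nucleotide** joins (`p_nuc_prob`,
  default 0.15 of the non-MH mass) keep both ends untrimmed and add the
  reverse complement of 1–2 terminal nucleotides of one end (hairpin
  opening); **blunt** joins (`blunt_prob`, 0.10) ligate the untrimmed ends
  directly; the remainder are **trim(+TdT)** joins with independent
  geometric trims per end (p = 0.4, capped at 10 nt — the cap also keeps
  the Cys and tetrad anchors intact) and, when `tdt_rate` > 0, a geometric
  number of random non-templated nucleotides with that mean. TdT is off by
  default (the TRA-like regime); `tdt_rate = 4` gives the TRB/mouse-like
  regime.

Clone sizes are drawn from a discrete power law (Zipf, exponent
`clone_alpha`, default 2.0) truncated so that sizes sum exactly to
`n_cells` (default 200,000 T cells, the scale of an adult zebrafish).
Note that for a discrete power law the log-log *rank–size* slope is
−1/(α−1), not −α; parameter recovery is therefore asserted on the
maximum-likelihood exponent, with the rank–frequency slope reported as a
diagnostic only.

Frame arithmetic of the model, useful when reading results: with lenJ ≡ 2
(mod 3) and the 14-nt V terminus, all four microhomology joins are in
frame on canonical-phase segments; blunt joins are structurally *out* of
frame (14 + lenJ ≡ 1); P joins are in frame only for 2-nt additions;
geometric trims give ≈ 34.8% in-frame. The default zebrafish-like mix
hence yields ≈ 76.7% in-frame junctions on an all-canonical locus and
74.6–74.8% on the full-size default locus (124 V × 137 J), where the
displaced elements (1 V, 3 J) cost 0.65 × 2.97% ≈ 1.9 points under
uniform usage. Observed repertoires sit above 75%, suggesting the rogue
elements are used below uniform frequency; since usage is unpublished we
keep uniform usage and state both numbers. The TdT-driven regime (no MH,
geometric insertions of mean 4) gives 33.2% in-frame, indistinguishable
at our sample sizes from the 1/3 of unconstrained junctions.

## Read simulation and extraction

Each molecule is a clone copy with a unique random UMI (12 nt, emitted as
a read prefix), Poisson-distributed reads (mean 3, minimum 1), and
per-base substitution (10⁻³) and insertion (2×10⁻⁴) errors; all errors
also hit the UMI, which is what the corrections must handle. Reads are
parsed by exact-substring (fast path) or edlib infix alignment: J by its
invariant exon suffix (≤ 2 edits), V by the expressed-V dictionary entry
ending at the Cys codon (≤ 5 edits, ties treated as ambiguous and
dropped); the CDR3 is delimited Cys codon through FGXG Phe codon
inclusive, so in-frame means length ≡ 0 (mod 3). Molecules are
(UMI, V, CDR3, J) combinations with at least `min_reads` reads (default
2). Stage-1 correction connects molecules of equal CDR3 length with UMIs
at Hamming ≤ 1 and CDR3s at Hamming ≤ 2 and keeps one member per
connected component (highest reads, ties to the lexicographically
smallest UMI, reads summed — so stage 1 conserves total reads); stage 2
resolves UMIs still carrying several CDR3s, keeping only sequences
pairwise more than Levenshtein 3 apart (most-read wins a conflict;
absorbed reads are discarded, so stage 2 does not conserve reads). Both
stages are idempotent. At 0.5% substitution error and 10⁴ molecules,
≥ 99% of surviving molecules match a true simulated molecule; recall is
substantially lower (~70%) because matching is precision-oriented — an
acceptable trade for repertoire statistics, which are molecule-weighted.

The allele classifier translates the constant-region opener in its own
frame; an in-frame stop marks the transcript as coming from the
non-selectable (frameshifted) allele. Only this computation is modelled;
no thymic selection is applied anywhere, so simulated in-frame fractions
correspond to unselected repertoires.

## Junction annotation

`annotate_junction` takes the longest CDR3 prefix matching the germline V
and the longest suffix matching the germline J. Overlap = microhomology
('A' labels, attributable to either end — never greedily assigned); gap =
non-templated ('N' labels), with palindromic openings of ≤ 2 nt per
untrimmed end flagged as P nucleotides (longer inverted repeats count as
ordinary N). `n_len` counts all N labels; the TdT-attributable count is
`n_len − p_len`, and a junction is TdT-free iff that is zero. Join classes
follow the precedence MH > P > BLUNT > N_INS; "blunt" here means *no
unexplained nucleotides*, so a trimmed join without insertions is also
BLUNT — mechanism identity beyond the sequence is unknowable. The
maximal-attribution rule is verified against a brute-force enumerator of
all decompositions on small alphabets. Because maximal attribution is
inference, trimmed joins whose flanks share homology by chance annotate as
microhomology joins; on the default templates the annotator reports 2–3
ambiguous nucleotides for pattern joins and ≤ 4 in virtually all cases.

## Entropy decomposition

Repertoire sequence entropy is decomposed as H(S) = H(L) + Σ_l p(l)·H(S|L=l)
(H(L|S) = 0 because a sequence determines its length), with

H(S|L=l) = Σ_n [H(CDR3_n|l) − max(I(CDR3_n;V|l), I(CDR3_n;J|l))] + H(V,J|l).

All frequencies are molecule-weighted plug-in estimates in bits, with no
small-sample bias correction; (nucleotide, gene) cells under 5 molecules
are flagged. Taking the larger of the V- and J-information instead of the
(V,J)-pair information needs far shallower sampling and can only
under-estimate the explained information, so the resulting H(S) upper
bounds the pair-based estimate; with pair information and deterministic
CDR3s the decomposition reproduces the direct clonotype-frequency entropy
exactly (tested). An amino-acid alphabet variant translates in-frame
CDR3s only.

## Genome scanning

Constant-region exons are located by six-frame translation and the
peptide signatures `CL.TD(F|.F)` (TRA) and `CL...F.P` (TRD). Jα elements
are located with the degenerate donor-anchored signature
`T N4 TT N GG N4 GG N AC N5 T N5 N8 gt`, filtered by the
`FGXGTX[LV]X[VI]` tetrad pattern in the induced frame (rightmost match
taken, i.e. the tetrad nearest the donor; variant tetrads such as FAKG are
thereby excluded), and restricted to the trdc→trac interval per strand
when both anchors are found. The signature has 12 fully fixed positions
including the donor GT, i.e. a chance rate of 4⁻¹² per offset per strand
under uniform bases (`pattern_match_probability` reports the closed form
for any IUPAC pattern, and the scanner's chance-hit rate is tested against
it on random sequence).

RSS positions are found iteratively: score every offset of every flank
with a position weight matrix (log-odds vs uniform background,
pseudocount 0.5), take the per-sequence argmax (ties to the smallest
offset), rebuild the matrix from the chosen sites, repeat for 5 cycles.
Two seed matrices are packaged — both encode heptamer + 23-nt spacer +
nonamer, with column sharpness 0.70 ("zebrafish") and 0.55 ("mouse") —
so seed-convergence is a meaningful check. Phase reports count V elements
by RSS start position (primordial: 15) and J elements by frame phase
(primordial: 2).

## Cohort statistics

Publicity is molecule-weighted: p_shared[k] is the probability that a
randomly picked molecule's (V, CDR3, J) occurs in exactly k individuals.
The generation-probability table enumerates the deterministic
microhomology assemblies: p_gen = P(V)·P(J)·mh_join_prob·w(pattern |
applicable), aggregating sequence-degenerate patterns, and
p_present = 1 − (1 − p_gen)^n_cells treats the n_cells recombination
events of an individual as independent draws — an assumption, documented
here and cross-checked by Monte-Carlo simulation in the tests. The
power-law fit is a discrete maximum-likelihood estimator with
Hurwitz-zeta normalisation and KS-based x_min selection.

## What the generator does and does not emulate

The generator reproduces: fixed RSS phases with rare displaced elements,
TSD-like terminal motifs and the four-pattern microhomology repertoire,
TdT-on/off regimes, five J length classes (hence multi-peaked CDR3
length distributions), power-law clone sizes, UMI structure and
sequencing noise, and a two-allele constant-region marker. It does not
emulate: thymic selection or MHC restriction (simulated in-frame
fractions are pre-selection), non-uniform V/J usage, D segments and
three-way junctions, somatic hypermutation, paired-end artefacts, or
base-quality structure. Passing tests therefore demonstrate correctness
of the algorithms on data with the stated statistical structure, not
performance on any particular real dataset.

## Problem sizes and numerics

Desk-scale defaults used by the tests and the acceptance script: loci of
30 V × 15 J (4 V × 20 J for scanner checks), 50,000–100,000 assemblies
for frame/annotation rates, 500 flanks for RSS recovery, 10⁴ molecules
(~3×10⁴ reads) for extraction recovery. At 30 × 15 the displaced-element
fractions (0.8% of V, 2.2% of J) round to zero elements, so those runs
are all-canonical; the full-size behaviour is quantified above. Entropies
use log₂ throughout; 0·log 0 ≡ 0; mutual information is clipped at 0
against floating-point cancellation. All randomness derives from
`SimConfig.seed` (numpy Generator); equal configurations produce
byte-identical FASTA/FASTQ output.
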