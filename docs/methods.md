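# Methods

This note documents the models, estimators and numerical choices behind
`charkit`, what the synthetic-data generators do and do not emulate, and the
known limitations. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and formats

All feature coordinates are 0-based half-open with strand ∈ {+, −}
internally. GenBank and GFF3 use 1-based inclusive coordinates; the
conversion happens only at the I/O boundary (Biopython / gffutils readers
and writers), and a write-then-read round trip reproduces coordinates
exactly (tested).

## Genome statistics

**GC content** is 100·(G+C)/(A+C+G+T). `N` and IUPAC ambiguity codes are
excluded from numerator *and* denominator; a sequence with no unambiguous
base is an error rather than 0/0. This matches common practice but is a
documented choice — tools differ in how they treat ambiguity codes.

**Direct terminal repeats.** Linear phage genomes assembled with the
terminal repeat present at both ends show the repeat as an exact
prefix == suffix border. `detect_dtr` returns the longest k ≤ ⌊n/2⌋ with
`seq[:k] == seq[-k:]`, computed in O(n) from the Knuth–Morris–Pratt prefix
function (the borders of a string form the chain π[n−1], π[π[n−1]−1], …).
Exact matching only: this is a border detector on a deposited assembly, not
a read-coverage terminus predictor, and an assembly deposited with the
repeat collapsed to one copy legitimately yields `found = False`. The
degenerate homopolymer case returns the maximal allowed k = ⌊n/2⌋, by
construction of the definition.

**ORF extraction** reports, per stop-anchored frame on both strands, the
maximal ORF from the leftmost allowed start codon ({ATG, GTG, TTG}) to the
first in-frame stop, protein length ≥ `min_aa`. Choosing the leftmost start
makes the output deterministic and the longest plausible product; CDS
lengths that are not multiples of three are legal elsewhere in the package
because frameshifted loci exist.

## Alignment and conservation

The pairwise core is Needleman–Wunsch with linear gap penalties (default
match 1, mismatch −1, gap −2) and a pinned traceback tie-break: diagonal,
then the move consuming the first sequence, then the second. The multiple
aligner is center-star: the center maximizes its summed pairwise score
(ties to input order) and other sequences are merged by gap propagation
("once a gap, always a gap"). These primitives are written out rather than
delegated because reproducibility of the alignment — identical output on
identical input, no external binaries, exhaustive-oracle testability — is
the requirement here; a production MSA tool (e.g. Muscle) would give
different (often better) alignments, so alignment-derived statistics such
as invariant-site fractions are *alignment-dependent* and are not treated
as comparable across aligners.

Percent identity of two gapped rows counts matching non-gap columns over
columns where at least one row is non-gap; columns gapped in both are
excluded. An invariant column has one unique symbol and no gaps across all
rows. Both definitions vary across tools and are therefore stated
explicitly rather than assumed.

## −1 PRF scanning

Tail assembly chaperones are produced as a short (TAC-N) and long (TAC-NC)
isoform, the latter via a −1 programmed ribosomal frameshift near the 3′
end of the TAC-N frame. The scanner models the slippery element as the
exact hexamer GTTTTT and searches the final `window_nt` (default 60 nt,
"near the 3′ end" made concrete) of the annotated ORF, stop codon included.
`offset_from_stop` records the nucleotides between the end of the motif and
the 3′ end of the ORF: a motif immediately preceding the stop codon has
offset 3.

The recoding event is applied immediately after the motif's last base: the
ribosome moves back one nucleotide, so the −1 frame starts at
`motif_end − 1`. The exact recoding nucleotide is not observable from
sequence alone; alternatives shift the measured extension by at most 3 nt,
which the ≥ 200 nt pass threshold absorbs. A −1 frame stop codon starting
strictly before the original frame-0 stop is a premature stop (the locus
fails); otherwise the extension is measured from the start of the original
stop codon to the end of the first −1 frame stop at or beyond it, in
nucleotides. Scanning gives up `scan_limit_nt` (default 3000 nt) past the
ORF end and flags the result unterminated rather than looping over a
genome. Locus identification is annotation-driven (ORF id or coordinates);
de novo recognition of TAC loci from tail-gene synteny is out of scope.

Minus-strand loci are reverse-complemented before scanning; the measured
extension is strand-invariant (tested).

## Kinetics estimators

**Integration endpoint.** The virulence window T defaults to the onset of
stationary phase in the phage-free control, detected as the first time
after the point of maximum slope at which the forward difference falls
below 5% of that maximum; if growth never flattens the final time point is
used. T is user-overridable, and only the ladder → index step (which does
not involve T) is treated as exactly reproducible against published
numbers.

**Local virulence** is clamped below at 0: a phage-exposed culture that
outgrows the control (pathological or strongly resistant inputs) reports
v = 0 rather than a negative virulence. The index integrates v against
log₁₀ MOI by the trapezoid rule and divides by the full-suppression area,
so it is invariant to the ordering of inputs and bounded in [0, 1].

**One-step growth.** The baseline is the t₀ titer. The first sustained
crossing of `rise_factor` × baseline (default 1.5; a single spiked point is
not sustained) marks the rise; the latent period is the previous sample
time, i.e. the estimate is grid-resolution-limited exactly like the bench
protocol it mirrors (10-min sampling ⇒ latent reported to 10 min). The
plateau is the first maximal run of ≥ 2 consecutive post-rise points over
which growth has ceased — each next point within (1 + `plateau_tol`),
default 1.10, of the run's running maximum — so a second burst
(another rise_factor-scale jump) ends the run while ~10% multiplicative
measurement noise does not. This envelope formulation was chosen over a
strict pairwise-spread rule after simulation showed the strict rule fails
to find any qualifying pair in a material fraction of realistically noisy
series; on noiseless data the two rules coincide. Burst size uses the
phage input at t₀ as the denominator (infective centers as defined by the
assay), not post-adsorption centers.

**Adsorption.** Percent adsorbed is 100·(1 − P/P₀). When a cell density is
supplied, the rate constant comes from a least-squares fit of −ln(P/P₀)
against N·t constrained through the origin (the model has no intercept at
t = 0 by construction); points at or below zero titer are excluded from
the log.

**Biofilm inhibition** is the crystal-violet reduction
100·(mean control − mean treated)/mean control. Negative values (biofilm
enhancement) are reported as-is, not clamped — the standard formula is
symmetric and hiding enhancement would be misleading.

**Stability.** Log-reduction is log₁₀(ref) − log₁₀(max(treated, LOD)); a
treated titer below the limit of detection is censored: the value is a
lower bound ("complete inactivation"). Uncensored log-reductions are
additive along a chain of conditions (tested).

## Enrichment screen

With both margins of a 2×2 table fixed, the focal-group-and-present count
follows a hypergeometric distribution. The two-sided p-value sums the
probabilities of all same-margin tables whose point probability does not
exceed the observed one, with the conventional 1 + 10⁻⁷ relative tolerance
guarding ties against floating-point loss; probabilities are computed from
log-gamma (scipy) and the implementation is verified against exact integer
enumeration for every table with total ≤ 40 and against the scipy reference
implementation. Sidedness is a documented choice: two-sided, the default of
standard implementations. The odds ratio is the sample cross-product ratio
(ad/bc, infinite when bc = 0 and ad > 0) and is reported for ranking, not
inference. Benjamini–Hochberg is applied per screen, across the systems of
one group comparison; q-values are the step-up minima, capped at 1,
returned in input order.

## Synthetic data

The generators exist to provide inputs with known ground truth; every
parameter-recovery, sensitivity/specificity and calibration test consumes
only generator output plus its truth table.

**Infection simulator.** A forward-Euler (dt ≤ 0.5 min) compartment model:
susceptible cells grow logistically (r = 0.03 /min ≈ 23 min doubling,
carrying capacity K = 1.0 OD with 10⁹ cells/mL per OD unit, inoculum 10⁷
cells/mL) and are adsorbed at rate k_ads·B·P (default k_ads = 5×10⁻¹⁰
mL·cell⁻¹·min⁻¹); infected cells lyse after the latent period (default
20 min) releasing `burst` phage (default 60); an optional resistant
subpopulation grows unexposed, producing the late regrowth seen in killing
assays. The OD proxy is total cells over the OD calibration; per-step
adsorption is capped at the susceptible pool so no compartment goes
negative. Latent period, burst and the order of magnitude of k_ads are
anchored to the characterized phage (20 min, 59 ± 11, and the observed
~76% adsorption in 5 min respectively). Noise is multiplicative lognormal
(positivity-preserving), one seeded RNG stream per call; identical seeds
give bit-identical output.

*Limitation:* a deterministic mass-action model lets even 1 phage/mL
amplify within a 6.5 h window, so simulated low-MOI killing is stronger
than real plate assays, where stochastic and spatial effects delay the
crash. The simulator is therefore used for ordering and recovery tests
(e.g. the virulence index increases with k_ads), never to reproduce a
published ladder, and passing tests say nothing about absolute low-MOI
virulence of real data.

**One-step curves** are piecewise (baseline to `latent_min`, linear rise
over 10 min to n₀·burst, plateau, optional slower second burst), matching
how the estimator's quantities are defined rather than simulating
intracellular kinetics; the compartment model is deliberately not reused
here so that estimator failures cannot be masked by a shared model.
**Adsorption curves** are exact exponentials with noise.

**PRF genomes.** Each genome set descends from one ancestral locus built at
codon level: ATG + random non-stop codons + GTTTTT (codon-aligned) + 30 nt
spacer + TAA, with the −1 frame after the slip stop-free through a planted
−1 TAA at least `extension_len` (default 300 nt) past the frame-0 stop.
Negatives are local edits of the ancestor — motif replaced by a neutral
hexamer, or the two bases after the slip set to give a premature −1 stop —
so that with divergence 0 all positive alleles are identical. Per-site
substitutions are applied at the requested divergence and individually
reverted if they would break the frame-0 frame, the motif placement, or
the planted −1 stop structure (validated by an independent structural
checker, not by the scanner under test). Optional terminal repeats of a
requested length are planted verbatim at both ends. The generator emulates
locus structure only: no codon-usage bias, no indels, no recombination —
so conservation statistics on synthetic alleles exercise the machinery but
do not imitate real divergence patterns.

**Defense tables.** Group labels are Bernoulli(group_frac); system presence
is Bernoulli with baseline log-odds logit(prevalence), shifted by ln(OR) in
the focal group for designated systems. Under OR = 1 everywhere this is an
exact null for calibration of the screen.

## Test-suite design notes

The Fisher implementation is checked against exhaustive same-margin
enumeration in exact integer arithmetic for *all* tables with total ≤ 40.
The aligner is checked against brute-force enumeration of all alignments
for all two-letter pairs up to length 4 and a seeded sample of 200 longer
pairs (up to length 8) — the full cross of length-8 pairs would require
~10¹⁰ enumeration steps and adds no coverage beyond the sample. The PRF
scanner is checked against a translation-based oracle (Biopython) on every
synthetic locus. Two acceptance checks require the deposited genome
(accession PV469300, fetched once and cached); they fail cleanly when the
record is unavailable offline, and all other tests are independent of it.

## Known limitations

- The aligner is O(nm) per pair with linear gaps; it is meant for locus
  alleles (hundreds of nt), not genomes.
- Alignment-derived conservation figures are not comparable across
  aligners (see above).
- The DTR detector requires exact repeats; sequencing errors at the
  termini shorten the reported border.
- The enrichment screen assumes one 2×2 per system with a shared, fixed
  grouping; stratified or matched designs are out of scope.
- The infection simulator is a test harness, not a fitted model of any
  particular phage–host pair.
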