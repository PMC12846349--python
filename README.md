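# charkit — phage characterization toolkit

`charkit` re-implements, as a tested and reusable Python package, the bench
computations used to characterize a lytic bacteriophage: killing-curve
virulence quantification, one-step-growth / adsorption / biofilm / stability
estimators, a −1 programmed ribosomal frameshift (PRF) conservation scanner
for tail-assembly-chaperone (TAC) loci, and a defense-system enrichment
screen. A seeded synthetic-data module generates every input the pipeline
consumes with known ground truth, so the whole analysis runs and is testable
with no downloads.

It is written for phage biologists and bioinformaticians who have plate-reader
OD time series, titration series, genome records and strain × defense-system
tables, and who want the bespoke numbers of a phage characterization study —
virulence index, burst size, adsorption constant, log-reductions, frameshift
read-through, enrichment q-values — from auditable, unit-tested code.

## The statistics at the core

**Local virulence and virulence index** (Storms-style). At one MOI,

> v(MOI) = 1 − A_phage / A_control,

where A is the trapezoidal area under the OD curve from infection onset to
the integration endpoint T (by default the detected onset of stationary
phase in the phage-free control). The virulence index integrates v over
log₁₀ MOI and normalizes by the area of v ≡ 1, giving a number in [0, 1].

**One-step growth.** The latent period is the last pre-rise sample time,
the plateau is the first post-rise run where burst-scale growth has ceased,
and burst size = plateau titer × volume / phage input at t₀.

**Adsorption.** The first-order model P(t) = P₀·exp(−k·N·t) is fitted as
the least-squares slope of −ln(P/P₀) against N·t through the origin.

**−1 PRF scan.** For an annotated TAC ORF the scanner locates the slippery
hexamer (GTTTTT) in a 3′-terminal window, shifts the reading frame back one
nucleotide after the motif, and requires a stop-free −1 frame that extends
the reading past the original stop codon by ≥ 200 nt with no premature stop
— the genomic signature of a programmed ribosomal frameshift producing the
long TAC isoform. Allele sets are deduplicated, aligned with a
deterministic center-star aligner (Needleman–Wunsch pairwise core), and
summarized as invariant-site fraction and minimum pairwise identity.

**Enrichment screen.** Each defense system is tested for association with a
two-level strain grouping by a two-sided Fisher exact test assembled from
the hypergeometric distribution, with Benjamini–Hochberg control of the
false discovery rate across systems (α = 0.05).

## Worked example

```python
import numpy as np
from charkit import synthetic_data as sd, kinetics as kin, prf_scanner as ps
from charkit.kinetics import LocalVirulence, virulence_index

# 1) virulence index from a measured eight-MOI local-virulence ladder
mois = [10.0**e for e in range(-7, 1)]
vs = [0.17, 0.16, 0.20, 0.25, 0.68, 0.97, 0.92, 0.97]
virulence_index([LocalVirulence(m, v) for m, v in zip(mois, vs)])
# 0.536  -> a moderately virulent phage (0 = harmless, 1 = total suppression)

# 2) one-step growth analysis of a simulated titer curve (truth: 20 min / 60)
params = sd.InfectionModelParams(latent_min=20, burst=60, noise_sd=0.05, seed=7)
series, truth = sd.simulate_one_step(params, np.arange(0, 70.1, 10.0),
                                     second_burst=True)
kin.one_step(series)
# latent=20 min, rise=10 min, plateau=5.77e5 PFU/mL, burst=57.7

# 3) PRF survey of ten synthetic genomes (one motif-scrambled negative)
spec = sd.PrfGenomeSpec(n_genomes=10, negatives={4: "scramble_motif"},
                        divergence=0.1, dtr_len=1165, seed=11)
genomes, tr = sd.make_prf_genomes(spec)
survey = ps.survey_locus(genomes, dict(zip(tr.genome_id, tr.orf_id)))
sum(r.passes for r in survey.per_genome)          # 9 of 10 pass
survey.n_unique_alleles                           # 10 alleles
survey.conservation.min_pairwise_identity         # 75.6 %
```

The burst estimate 57.7 differs from the programmed 60 only through the 5%
multiplicative measurement noise; the genome that fails the PRF test is
exactly the planted motif-scrambled negative.

A CLI mirrors the library (`charkit genome stats`, `charkit align msa`,
`charkit prf scan`, `charkit kinetics {virulence,onestep,adsorption}`,
`charkit enrich`, `charkit simulate ...`); every command reads and writes
plain TSV/FASTA/GenBank.

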