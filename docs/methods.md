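# Methods

## Scope and coordinate conventions

All computation happens in transcript coordinate space: each mRNA is its own
reference, 0-based and half-open everywhere internally.  BED is consumed
natively; GFF3 (1-based inclusive) and SAM (1-based POS, reference span from
the CIGAR) are converted at the boundary.  Genomic strand and exon count
survive only as metadata — every in-scope analysis is anchored at the start
codon, so transcript space loses nothing while removing strand/splice
bookkeeping.  Genome-space projection, alignment itself and FASTQ handling
are out of scope.

## Translation model

One mRNA carries a main ORF (and optionally short upstream ORFs).  Ribosome
dynamics are a Markov jump process:

* **Initiation** is Poisson with a piecewise-constant rate α(t)
  (default 6 initiations/min per transcript).  With probability
  `uorf_initiation_fraction` an initiation targets a uniformly chosen uORF
  instead of the main ORF.
* **Elongation** advances one codon at a time with exponential waiting times
  at rate v (default 6 codons/s).  All codons are kinetically identical: no
  dwell-time, tRNA-availability or rare-codon model.  Ribosomes reaching the
  stop codon terminate and leave.
* **Drug uptake** is single-compartment first-order:
  `c_in(t) = c_out·(1 − exp(−k_uptake·(t − t_drug)))`.  The default
  `k_uptake = ln(20)/2 ≈ 1.498 min⁻¹` places 95% equilibration at exactly
  2 min after drug addition, the diffusion timing the model is calibrated to.
* **Arrest** is an absorbing state entered, at each attempted elongation
  step, with probability `p = c_in/(c_in + k_i)` (default `k_i = 5 μg/ml`,
  giving ~95% per-step inhibition at the 100 μg/ml reference dose).  The
  Michaelis-type form encodes gradual, concentration-dependent inhibition;
  arrest is permanent (the drug is never removed).
* **Initiation is not inhibited by the drug.**  Ribosomes keep loading at
  the start codon throughout the harvest window.  A permanently arrested (or
  queued) ribosome occupying the first 10 codons of an ORF occludes its
  start site: later initiation attempts on that mRNA are lost.  Transiently
  elongating ribosomes do not block — a momentary delay at a moving queue
  renames initiation events rather than destroying them, and folding it into
  α keeps the drug-free process an exact Poisson pipeline (the stationary
  ribosome count obeys Little's law, E[N] = α·L/(60·v), exactly).  Without
  this occlusion the start-codon pile would grow linearly with harvest time
  at *every* dose and the peak area would no longer discriminate between
  concentrations, contradicting the concentration dependence the simulator
  exists to reproduce.
* **Queued pool.**  Acute stress collapses initiation; the model represents
  the resulting excess of initiation-competent complexes as Q ribosomes
  queued at the start codon at drug-addition time, each committing to
  elongation after an exponential delay (rate β, default 1/min — chosen so
  the queue drains on the 5-min harvest timescale).  Stress otherwise enters
  only through the α schedule; elongation is deliberately untouched by
  stress.
* **Steric exclusion** (footprint of 10 codons between elongating
  ribosomes) is available but off by default; run-on dynamics do not require
  it away from the start site.

Harvest is a single snapshot at `t_harvest` (default `t_drug + 5 min`, the
time it takes to collect cells by filtration); a per-cell uniform harvest
window is available (`harvest_spread`).  The default drug-free equilibration
(`t_burnin`, 6 min) covers twice the traversal time of ORFs up to ~1000
codons; callers simulating longer ORFs should extend it.

## Samplers

The default sampler is an exact counting-process decomposition: attempted
steps form a Poisson process at rate 60·v per minute; marking each attempt
"arrest" with probability p(t) splits it into an inhomogeneous arrest
process with rate `60·v·p(t)` and an advance process with rate
`60·v·(1−p(t))`.  Each ribosome's arrest time is drawn by inverting the
cumulative arrest hazard (tabulated on a log-spaced grid after drug addition
so that doses from 1.56 to 10,000 μg/ml are all resolved), and its codon
position is a Poisson count of the advance measure up to
min(arrest, harvest); counts reaching the ORF length mean the ribosome
terminated and left.  Start-site occlusion is applied afterwards: the
occlusion time of an ORF is the earliest qualifying arrest among its
walkers, which no later-starting walker can precede, so no sequential sweep
is needed.  This vectorizes over all ribosomes of all cells.

An explicit event-driven simulation (heap of initiation/step events) is kept
alongside: it is the implementation used when steric exclusion is enabled
and serves as an independent cross-check — the test suite verifies by
chi-square that both samplers draw positions from the same law.  Both are
bit-reproducible given a seed; libraries over many transcripts and cells
derive per-transcript generators from a seed tree, so results do not depend
on iteration order.

## Footprints

A ribosome with P-site at codon j of an ORF starting at `orf_start` yields a
footprint with 5′ end `orf_start + 3j − 12` and a length drawn from the
library's length distribution (default uniform on 27–31 nt), clipped to the
transcript; clipped fragments shorter than 20 nt are dropped as they would
not survive size selection.  rRNA-class contamination reads are appended so
their expected library share matches the requested fraction; they reference
18S/25S rRNA ids outside the mRNA annotation, as real contamination does.
An optional scenario knob emits short (25–27 nt) start-proximal reads to
mimic small-subunit footprints; this is a re-labeling device, not a model of
40S scanning.

Because footprint 5′ ends sit at a fixed codon phase, nucleotide-level
coverage carries an intrinsic ~±3% three-nucleotide ripple (the 27–31 nt
kernel covers the three frame positions unevenly).  Real Ribo-seq data shows
the same reading-frame periodicity; flatness claims about simulated
profiles are therefore read at codon resolution.

## Metagene analysis

Coverage is computed per nucleotide from entire footprints (`full`), or from
5′/3′ ends only.  Expression is rpkm with the transcript length (not CDS) as
the kilobase denominator and footprint-class reads only in the per-million
denominator; reads are assigned to genes by their 5′-end nucleotide.  The
profile takes single-exon genes with length > 1000 nt (strict) and
rpkm > 30 (strict), aligns them at the start codon, averages coverage over
genes across positions −50..+999, and normalizes by the mean over positions
+700..+999 — the last 300 positions *of the window*, so the plateau of the
normalized profile is exactly 1.0 by construction.  Genes whose 5′UTR is
shorter than 50 nt or whose CDS is shorter than 1000 nt are dropped with a
logged count rather than padded, which would bias the tail mean.
`peak_area` sums the normalized profile's excess above 1.0 over +0..+299.

## 5′-end analyses

5′UTR and uORF membership are decided by the inferred P-site (5′ end +
12 nt): a ribosome whose P-site is the start codon is an initiating ribosome
on the main ORF even though its footprint physically overhangs the UTR, so a
library with no uORF initiation has a 5′UTR share of exactly zero.  The raw
5′-end rule is available (`assign="end5"`) for comparison with end-based
pipelines; it counts start-codon ribosomes as UTR signal.  uORF intervals
are half-open.  The cumulative start profile sums unnormalized full-read
coverage of *all* genes (no filters) over −50..+299, each gene contributing
whatever part of the window it covers.

## What the synthetic data does and does not emulate

The fixture generator produces single- and multi-exon genes with ≥50 nt
5′UTRs, optional uORFs, and a library with a 100-fold log-uniform spread of
per-gene depth.  Simulated libraries reproduce: stationary uniform coverage
without drug, the dose-dependent 5′ run-on peak, queued-pool amplification
of that peak, uORF occupancy under drug, rRNA contamination shares, and
footprint-length mixtures.  They do not contain: sequence-dependent dwell
times, biased nuclease digestion, ligation bias, multimapping, overlapping
genes, splice isoforms, or genuine 40S scanning.  Passing tests therefore
validate the analysis machinery and the kinetic mechanism, not any claim
about a particular organism's parameter values.

## Numerical choices and degenerate inputs

Hazard tables use trapezoidal integration on a log-spaced grid (6000 points
after drug addition); interpolation error is far below sampling noise at
every dose.  Zero elongation with nonzero initiation is rejected (unbounded
queue).  An empty alignment set is an error for expression and class-share
computations; an empty uORF table is returned, not raised.  A zero tail
mean (no 3′ coverage) is an error since normalization is undefined.  All
reductions are arithmetic means; gene order never affects results, and
select_genes returns ids lexicographically.

## Desk-scale study sizes

The simulation-backed tests run 200 single-exon genes × 50 cells per
library and 10 seeds per condition, with conditions at 1/16×, 1×, and 100×
of the 100 μg/ml reference dose and queued pools of 0/5/20 — sizes chosen so
that the concentration and queued-pool orderings of the peak area are
resolved far beyond their sampling noise while a full study completes in
about a minute.

## Known limitations

* Arrest is irreversible; drug washout cannot be simulated.
* The queued-pool realization of stress is one admissible mechanism for the
  initiating/elongating imbalance, not a quantitative claim; simulated
  stress magnitudes should not be read as reproductions of any particular
  measured stress response.
* rpkm on short features (uORFs) is noisy in real data; the per-uORF table
  reports raw counts and densities and leaves significance to the caller.
* The 40S-fraction analyses operate on re-labeled footprints; no scanning
  kinetics are modeled.
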