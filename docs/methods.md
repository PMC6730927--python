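# Methods

This note documents the models, estimators, parameter choices and known
limitations of `asmob`. All thresholds live in
`asmob.pipeline.PipelineConfig` and are serialized (with a SHA-256 config
hash) next to every run's outputs.

## Homology screen

Queries are aligned to every member of each target family with
Smith–Waterman local alignment under BLOSUM62 and affine gaps
(open 11, extend 1; a gap of length *g* costs 11 + *g*). Raw scores are
converted to E-values with the Karlin–Altschul formula

    E = K · m · n · exp(−λ·S),

where *m* is the query length and *n* the summed residue count of the
family searched. For the default gapped scheme the published constants
λ = 0.267, *K* = 0.041 are used; `calibrate_lambda` solves the ungapped
equation Σᵢⱼ pᵢpⱼ e^{λsᵢⱼ} = 1 by bisection (to |f| < 1e−9) for arbitrary
matrices and is verified against the closed-form match/mismatch solution
λ = ln 3. A protein matches a family when its best member alignment has
E ≤ 1e−40; only that best hit is kept per (protein, family) pair, because
the downstream decision is binary presence. Deviations from BLAST: no
heuristic seeding (scores are exact optima, so the screen is strictly more
sensitive), no effective-length correction and no composition-based
statistics — at a 1e−40 gate neither correction can flip a decision at the
lengths involved. Residue X scores 0 against everything; U/O are read as
C/K.

The dynamic programming runs as a numba kernel with deterministic
traceback (tie order: diagonal, then gap-in-subject, then gap-in-query;
gap runs close as early as possible). An exhaustive pure-Python DP and
Biopython's `PairwiseAligner` serve as independent oracles in the tests.

## Molybdopterin disambiguation

ArrA and AioA sit in the molybdopterin oxidoreductase superfamily, whose
members (NapA, DMSO reductase, …) cross-react under any E-value gate, so
family membership is decided on a tree, not a score. Candidates are
combined with the arrA/aioA references, decoy families and an outgroup
family (DMSO-reductase set by default — clades are undefined on unrooted
trees, and rooting on the most distant reference family is the
conventional choice):

1. **Progressive alignment**: UPGMA guide tree on 3-mer cosine distances,
   profile–profile merges by global Needleman–Wunsch with affine gaps on
   column-frequency score expectations. Deterministic and seed-free.
2. **Gap trimming**: columns with a gap fraction ≥ 0.95 are removed
   ("at least 95% gaps" read literally as remove-at-threshold). Trimming
   deletes the minority residues in removed columns, so ungapped rows are
   subsequences of their inputs afterwards; before trimming they are
   identical to the inputs.
3. **Distances**: pairwise-deletion p-distance (optionally Poisson
   corrected, −ln(1−p)).
4. **Neighbor joining** (Saitou–Nei): Q-matrix ties break on the
   lexicographic pair of cluster labels; negative branch lengths are
   clamped to zero with the deficit moved to the sibling branch (lengths
   are not used by the clade test). Additive matrices are reproduced
   exactly (path distances to 1e−9).
5. **Clade test**: after outgroup rooting, a query is accepted for family
   F iff it lies in the leafset under the MRCA of F's references and that
   leafset contains no reference of any other family. A contaminated
   reference clade aborts the run ("reference clade not recovered") —
   the method refuses to guess when the references themselves do not
   separate.

This replaces a maximum-likelihood workflow (MUSCLE + model-selected
RAxML with bootstraps). The tree is used purely as a binary clade
classifier; on synthetic truth NJ reproduces the classification, and the
MRCA-purity rule is one mechanical formalization of what is otherwise a
manual tree-inspection step. Bootstrap support is out of scope.

## Multiheme cytochrome inventory

A CXXCH (Cys-X-X-Cys-His) motif is one covalent heme attachment site.
`scan_motifs` counts motifs left-to-right greedily non-overlapping
(successive starts ≥ 5 apart): two counted motifs may not share a
cysteine, since that would double-count hemes. An overlapping mode is
available. Proteins with ≥ 3 motifs are candidates.

Candidates plus seed references (metal-active: *Geobacter*/*Shewanella*-style
seeds; non-metal: NapC/NirT, NrfA, HAO-style seeds) form a similarity
network with an edge whenever the pairwise Smith–Waterman bitscore is
≥ 67; clusters are connected components labelled by smallest member id.
The published network service computes its own alignment-significance
score; here the same numeric cutoff is applied to bitscores, and the
cutoff is configurable. Filters fire in a fixed order per candidate —
below-threshold, denylisted annotation, non-metal cluster (component
contains a non-metal seed and no metal seed), cytoplasm-only
localization — and the retained set is order-independent because each
criterion is a property of the candidate itself; the recorded status
only names the first filter that fired. Unknown or missing localization
retains (only confident cytoplasm-only calls remove). Per-MAG motif
totals over retained MHCs are reported, flagged when strictly above
50 motifs per genome.

## Abundance

RPKM(g) = count(g) / ((len(g)/1000) · (total_mapped/1e6)), with
total_mapped counted over all mapped reads in the sample (not only reads
in genes — "mapped reads in the assembly" read literally). Two counting
modes: `start_in` (default; a read belongs to a gene iff its leftmost
position lies inside) and `overlap`. Multi-mapped reads are counted once
at their primary alignment; the SAM subset retained carries no secondary
flags. CIGAR strings are ignored (read length from SEQ), which RPKM and
window coverage never need. Family panels sum RPKM per marker family
(arrA/aioA post-disambiguation); the cytochrome panel sums retained-MHC
RPKM in CXXCH-count bins 3–5, 6–10, 11–20, 21+ (configurable).

## Replication estimation (iRep-style)

A replicating population over-represents origin-proximal DNA, so read
coverage decays from origin to terminus; the peak-to-trough ratio (PTR)
of that gradient indexes replication. Per contig, mean coverage is
computed in 5,000 bp windows sliding by 100 bp (fully-inside windows
only); windows are pooled across contigs — contig order and orientation
relative to the origin are unknown, and the estimator sorts windows, so
order is irrelevant by construction. MAGs qualify at completeness ≥ 75%
and contamination < 3% (the stricter 2% gate is available via
`max_contamination`).

The estimator sorts pooled windows, drops the lowest and highest 5%, and
fits log2 coverage against rank by OLS. Two design points matter:

* **Ranks keep their global quantile positions** after trimming
  (i/(n−1) over the untrimmed count). Renormalizing ranks to the
  trimmed set would shrink every slope by exactly (1 − 2q) — a 10%
  systematic underestimate at the default trim — which a noise-free
  exponential profile exposes immediately.
* **Sampling-noise bias correction.** Sorting embeds the noise quantile
  shape into the curve: a non-replicating genome (flat coverage) at 50×
  read-sampled depth would otherwise report irep ≈ 1.06, not 1.0. The
  window-scale noise SD σ is estimated from the genomic-order profile as
  MAD/0.6745/√2 of log2 differences at a lag of one full window
  (independent sampling noise, near-identical signal; robust to pooled
  contig boundaries), and the fitted slope is corrected by variance
  decomposition, slope² → max(slope_obs² − (k·σ)², 0), where k is the
  closed-form OLS slope of the standard-normal quantile function over
  the trimmed rank range. The correction is scale-invariant (log-space)
  and vanishes as depth grows. Exactly flat profiles return irep 1.0
  with r² = 1 by definition.

On a 2 Mb genome at 50× with 100 bp reads the estimator recovers
PTR ∈ {1.0, 1.5, 2.0} with median absolute relative error well under 1%
(the tests gate at 5%). The estimate is defined on genomic-order
profiles (the noise estimator differences neighbours), and is invariant
to contig orientation reversal. Not reproduced from the published tool:
GC-bias correction, its specific window-filter heuristics, and
origin/terminus localization; fragment-level (paired-end) coverage is out
of scope. `r²` of the sorted fit is reported with a 0.90 reliability
flag, but note that sorted curves are optimistic — the flag marks
obviously bad fits rather than certifying good ones. Reported log(iRep)
uses the natural log, recorded in the output metadata.

## MAG quality

From a per-MAG single-copy marker copy table: completeness = 100 ·
(markers present ≥ once)/|universe|, contamination = 100 · Σ max(0,
copies − 1)/|universe|. Tiers: high iff completeness > 90 and
contamination < 5; medium iff completeness ≥ 50 and contamination < 10;
else low. This is deliberately not a CheckM reimplementation (no
lineage-specific marker sets, no collocation corrections) — the pipeline
needs the gate decisions, and externally computed tables can be ingested
directly. A bundled 43-gene bacterial marker list (ribosomal proteins
plus universal housekeeping genes) serves as the default universe. The
analysis set is MAGs of tier ≥ medium with an rps3 homology hit and at
least one function of interest; rps3 detection reuses the homology
screen with an rps3 reference family.

## Synthetic data

The generator emulates exactly the statistical structure the analysis
assumes, with a truth table for every decision:

* **Families.** Reference members diverge from a family seed protein by
  exact-count point substitutions (realized identity equals the target up
  to rounding) at 80% identity; planted environmental genes descend from
  a randomly chosen *reference member* at 90%, so true members nest
  inside the reference radiation on the tree — the geometry the clade
  test assumes about references spanning known diversity. The four
  molybdopterin families (arrA, aioA, NapA decoy, DMSO outgroup) share a
  common ancestor at 60% seed-to-ancestor identity, putting
  between-family identity near 40% and making decoy cross-hits pass the
  E-value gate — the situation that forces disambiguation. Family
  lengths: arsB 430, arsC 140, dsrD 100, rps3 220, molybdopterin 400 aa.
* **Cytochromes.** A motif-free core (300 aa, diverged from a metal or
  non-metal seed core at 80%) plus a tail of exactly k CXXCH motifs with
  random-length (8–20) random-composition spacers. Long variable spacers
  stop the shared CXXCH pattern itself from bridging unrelated families
  at the 67-bit cutoff (only the heme-binding residues are conserved
  across real families); measured cross-family scores sit ≥ 15 bits
  below the cutoff while within-family scores are in the hundreds.
  Accidental motifs in cores are destroyed; the generator verifies the
  greedy scan returns exactly k and refuses otherwise.
* **Genomes and reads.** Genes are reverse-translated (seeded uniform
  synonymous codon choice — nucleotide realism is irrelevant downstream)
  and packed first-fit onto fixed-length contigs with random intergenic
  spacers. Reads are emitted pre-mapped as SAM from truth coordinates
  (mapping is outside the scope; truth coordinates make coverage tests
  exact), with start density ∝ ptr^(1−x) along each MAG's concatenated
  coordinate (origin at x = 0) via inverse-CDF sampling, 1% substitution
  errors, and 2% unmapped decoy reads. Marker tables realize requested
  completeness/contamination exactly; unrepresentable percentages are
  rejected naming the nearest feasible pair.
* **Default community.** Six MAGs, two samples, depths 10–30×: a
  high-quality arsenate reducer rich in MHCs (PTR 2.0, > 50 motifs), an
  arsenite oxidizer (PTR 1.5) with a cytoplasmic and a below-threshold
  cytochrome, a sulfate reducer with mixed metal/non-metal/denylisted
  cytochromes (contamination 4.7% — iRep-ineligible), a NapA-decoy
  carrier without rps3 (PTR 1.0), a function-free medium-quality bin,
  and a low-quality bin whose arrA is excluded by the tier gate. The
  22 kb genomes keep the end-to-end run in seconds; their 5 kb windows
  smooth the coverage gradient, so end-to-end replication estimates are
  attenuated toward 1 and the exact-recovery claims are made on 2 Mb
  single-genome simulations instead.

What the generator does not emulate — indel evolution, horizontal
transfer, chimeric bins, strain mixtures, sequencer error profiles,
alignment ambiguity (reads are pre-mapped) — bounds what passing tests
show: the pipeline's decisions are correct when its modelling
assumptions hold, not that the screens are robust to assembly and
mapping artifacts in real data.

## Determinism

Every stochastic step takes a numpy `Generator` seeded from a single
integer; the generator is byte-identical per seed, and a pipeline rerun
with identical config and inputs reproduces `report.json` byte for byte.
NJ ties, network cluster labels, traceback paths and file orderings are
all fixed deterministically.
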