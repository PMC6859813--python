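# Methods

## The problem

Mixotrophic ciliates such as *Mesodinium* keep stolen prey organelles — and
a transcriptionally active stolen prey nucleus (the kleptokaryon) — so an
RNA-Seq library from a host culture is dominated by prey-derived
transcripts (80–90% of a mixed library can be prey). Including those
transcripts under the host's name in a phylogenomic supermatrix misplaces
the host, an artefact compounded by the host clade's elevated evolutionary
rate (long-branch attraction). A second, independent trap is the genetic
code: *Mesodinium* reads TAA and TAG as tyrosine, so protein prediction
with the standard code truncates host proteins at the first in-frame
TAA/TAG while leaving prey proteins (standard code) intact — any
longest-protein heuristic then systematically prefers prey sequences.

`ciliovet` implements the decontamination workflow end to end and, because
the real libraries are not reproducible at desk scale, ships a
synthetic-data generator with full ground truth so that every stage can be
scored exactly.

## Pipeline stages and their operating parameters

1. **ORF recall** (`genetic_codes`). Maximal stop-to-stop codon runs on all
   six frames (EMBOSS getorf, find=0 semantics), minimum 150 nt, under a
   chosen code: standard, ciliate table 6 (TAA/TAG→Q) or Mesodinium
   (TAA/TAG→Y, TGA stop). Stop-to-stop rather than ATG-anchored because
   assembled transcript 5′ ends are routinely truncated. `code_gain`
   tabulates, per contig, the longest-ORF length difference between two
   codes; contigs gaining ≥100 aa flag code misassignment.
2. **Subtraction screen** (`subtraction`). A host-library protein is
   removed when a pure-prey protein matches at ≥80% identity (identities /
   length of the shorter sequence, the cd-hit-2d convention) *and* the host
   protein is at most 150 aa longer. The length slack is asymmetric (a
   longer prey sequence never blocks removal) and measured on full
   sequence lengths, not aligned spans. Candidate pairs come from a
   permissive similarity search (E ≤ 1e-4). Two failure modes are inherent
   and deliberate: hosts >150 aa longer than their best prey match are
   retained even at perfect identity, and prey transcripts from genes the
   pure culture does not express (kleptokaryon-only) cannot be matched at
   all. The module therefore reports its leakage rate rather than
   pretending completeness — removal of the leaked sequences is the next
   stage's job.
3. **Family building** (`families`). Proteins grouped by a KO-style
   annotation key (consumed as a TSV; best score wins per sequence).
   Composition filters: stage 1 requires ≥1 host-group member, ≥1 curated
   ciliate and ≥1 outgroup; stage 2 requires ≥24 core sequences
   (host + curated ciliates), ≥1 SRA-derived ciliate and ≥4 outgroups at
   the published defaults. Families larger than 200 members are dropped (a
   reproducible stand-in for "too many homologs to inspect"). A seed-based
   constructor (top-6 hits per database at E ≤ 1e-30) covers the other
   published route to families.
4. **Vetting** (`vetting`). Per family: drop rows shorter than 50% of the
   median length (proxy for manual removal of short/spurious sequences),
   align (internal progressive aligner), build an NJ tree from model
   distances, root with the outgroup, extract all maximal all-ciliate
   clades, and keep the one containing a genome anchor with the greatest
   taxonomic representation (ties: more sequences, then smallest leaf id).
   In-paralog sets that recover the same relationships collapse to one;
   conflicting sets are dropped and logged; within the kept clade, the
   longest sequence per taxon wins when its copies form a taxon-pure
   subclade. Up to four nearest outgroup sequences (edge count, then path
   length) accompany the clade into round 2, which realigns and re-extracts.
   Verdicts: `kept`; `rejected_no_anchor_clade`; `rejected_host_with_prey`
   (host-group sequences were present but none survived inside the vetted
   clade — the signature of a family whose "host" sequences were prey);
   `rejected_unstable` (ciliate membership changed by >25% between rounds —
   a quantitative proxy for "placement too uncertain to consider", which
   the source procedure left informal).
5. **Supermatrix** (`supermatrix`). Per-gene occupancy trimming (keep
   columns with ≥60% non-gap rows; boundary inclusive), concatenation with
   1-based inclusive partition spans, per-taxon missing fractions,
   parsimony-informative counts (≥2 states each in ≥2 taxa),
   coverage-based gene reduction (strictly >80% of ciliate taxa; note
   29/36 ≈ 0.806 passes the strict rule even though the published count
   starts at 30 — the strict reading of ">80%" is kept), and fast-site
   removal at rate thresholds 2, 1 and 0.8 (≥ threshold drops the site).
6. **Tree engine** (`model`, `likelihood`, `treebuild`). See below.
7. **Topology tests** (`topotests`). RELL resampling (10,000 draws by
   default): one index multiset per replicate applied to every tree's
   site log-likelihood vector, no re-optimisation. bp-RELL splits exact
   ties equally. KH is the signed one-sided test for a pre-specified pair
   (see *Numerical and statistical choices*). SH uses the centred
   max-statistic null over the whole tree set. AU fits the multiscale
   bootstrap (scales 0.5–1.4, step 0.1, 2,000 draws per scale) by weighted
   least squares on the probit scale, p = 1 − Φ(d − c). Scales whose win
   proportion is exactly 0 or 1 carry no curvature information and would
   bias the fit through clipping, so they are excluded; a tree with fewer
   than two informative scales gets p clamped to 0/1 with a flag, and
   singular fits return NaN with a flag, never silently.

## Substitution model

Likelihood calculations use a reversible amino-acid model: exchangeability
matrix + equilibrium frequencies, scaled to one expected substitution per
unit branch length, with discrete-gamma rate variation (4 categories,
category means, mean 1) and an optional invariant-site class. The shipped
default is the **Poisson model** (equal exchangeabilities), optionally with
observed frequencies ("+F"); its transition probabilities have the exact
F81-style closed form P_ij(t) = π_j + (δ_ij − π_j)e^(−βt). Empirical
matrices in PAML .dat format (LG, WAG, …) can be loaded with
`model.load_paml_dat` and run through the same eigendecomposition path.

The Poisson default is a deliberate design choice, not an approximation
claim: the synthetic generator simulates under the same process, so every
validation experiment is model-matched, and the pipeline's logic
(monophyly extraction, site-rate ranking, RELL tests) is independent of
which empirical matrix supplies the exchangeabilities. Free-rate and
profile-mixture models are out of scope; a single sound likelihood is the
design point. For real data an LG-class matrix file should be supplied.

Machinery: Felsenstein pruning with per-node scaling and log-space category
combination (gaps and X are missing data — partial likelihood 1);
branch-length optimisation by per-branch Brent iterations on cached
inside/outside messages in the model's eigenbasis, refreshed once per
sweep, with a sweep accepted only if the total log-likelihood improved
(stops at <1e-4 improvement or 20 sweeps); empirical-Bayes posterior-mean
site rates; two-sequence ML distances (closed-form sufficient statistic
under the uniform-frequency Poisson model, scalar optimisation otherwise,
with a capped corrected p-distance fallback flagged on saturation);
standard NJ with negative branch lengths clamped to zero and the deficit
moved to the sibling; and nonparametric column-resampling bootstrap
support. Hypothesis placement of the host clade is evaluated with NJ on
model distances of the concatenated matrix — full ML topology search is a
non-goal.

## Progressive aligner

Plumbing for realignment after clade extraction: NJ guide tree on k-mer
distances (k=3), midpoint-rooted; profile–profile global alignment with
affine gaps (BLOSUM62 expected column scores, occupancy-scaled gap
penalties); one round of leave-one-out refinement accepting only
sum-of-pairs improvements. On small benchmark instances the refined result
matches or beats a centre-star baseline, but as a greedy method it carries
no optimality guarantee; the synthetic generator's indel-free genes (the
true alignment is emitted alongside) keep vetting validation independent
of aligner quality.

## Synthetic data: what it emulates, and what it does not

The generator draws a species tree with `n_ingroup_classes` ciliate
classes (3 taxa each by default: one genome anchor, one SRA-derived
library, one curated/MMETSP-like), an outgroup radiation containing the
prey taxon, and a host clade sister to the first class whose branch
lengths are multiplied by `host_rate_multiplier` (default 2 — the
long-branch host). Genes evolve site-wise under the Poisson process with
gamma(0.8) site rates on the species tree with log-normal branch jitter
(σ=0.15, mean 1: gene/species concordance is assumed, as the vetting
procedure itself assumes); amino acids are back-translated with uniform
synonymous codon choice under each taxon's genetic code, so host genes
carry in-frame TAA/TAG sense codons.

The mixed library holds one host transcript per gene plus isoform-jittered
prey transcripts (1% amino-acid jitter, resampled codons) in the ratio set
by `contamination_fraction` (default 0.85); a `kleptokaryon_unique_fraction`
(default 0.10) of prey transcripts come from genes withheld from the
pure-prey reference entirely. In-paralogs arise per gene and taxon with
probability 0.05, carrying at least one substitution. Defaults are the
study conditions; experiments that need other sizes say so explicitly.

Problem sizes: decontamination experiments use 60 genes × 120 codons over
50 seeds; end-to-end placement uses 100 genes, 12 ingroup taxa and 20
seeds; code-gain experiments use 400-codon genes (typical protein length —
at ~120 codons a reverse-strand frame can be stop-free by chance, masking
the forward read-through gain); topology-test recovery uses 13 taxa ×
2,400 sites. The reproduction script (`scripts/acceptance.py`) runs the
same experiments at moderately reduced seed counts.

What the generator does **not** emulate — hence what passing tests do not
show about real data: sequencing error, assembly fragmentation and
chimerism, indels (off by default), expression-level variation,
gene-tree/species-tree discordance from incomplete lineage sorting or HGT,
codon-usage bias, and compositional heterogeneity across lineages. The
validation demonstrates that the *procedure* is sound when its assumptions
hold, not that any particular real dataset satisfies them.

## The naive baseline

The placement experiment contrasts the vetted pipeline with a "naive" run
modelling an uncurated workflow: standard-code ORF recall (host proteins
truncate at the first in-frame TAA/TAG), no subtraction, no vetting, and
the longest sequence per taxon per family. Because prey transcripts are
both more numerous and — under the wrong code — longer than the host's,
the mixed-culture taxon's supermatrix rows become predominantly
prey-derived and the taxon is pulled toward the prey lineage, away from
its class. This is the artefact the decontamination exists to prevent.

## Numerical and statistical choices

- KH is implemented as the signed one-sided test for a pre-specified pair
  (p = fraction of centred resampled sums ≥ the observed signed
  difference). An absolute-value variant is either degenerate when two
  fits coincide or roughly doubles the type-I error on a symmetric null;
  the signed form is calibrated (measured type-I 0.05–0.06 at α=0.05).
- The calibration null is a balanced per-site mixture of two symmetric
  four-taxon topologies evaluated with fixed true branch lengths. A
  star-tree null with per-tree branch-length optimisation is degenerate:
  both resolutions collapse to the same fit and the statistic is
  identically zero.
- Identity in the subtraction screen is short-sequence-relative; a
  per-aligned-column identity is recorded alongside for diagnostics.
  E-values use fixed ungapped Karlin–Altschul parameters (λ=0.267,
  K=0.041) and serve only the published cutoffs, not database statistics.
  The k-mer prefilter (k=5) only ever skips pairs sharing zero k-mers.
- Boundary semantics follow the stated rules literally: occupancy "60% or
  more" is ≥, gene coverage ">80%" is strict >, fast-site removal
  "rate ≥ threshold" drops the site.
- Rooting with a non-monophyletic outgroup picks the edge whose split
  disagrees least with the outgroup/ingroup partition (ties: smaller
  clade); an all-outgroup tree is midpoint-rooted.
- Degenerate inputs raise rather than guess: empty supermatrices, ragged
  alignments, zero-overlap sequence pairs, site filters that would empty
  the matrix, families below four members.

## Known limitations

- NJ placement (not ML search) dates the final tree; with the strong
  concatenated signal of the validation datasets this is sufficient, but
  marginal real placements would warrant an external ML search on the
  exported PHYLIP + partition files.
- The two-round stability rule (25% membership change) quantifies an
  informal judgement; families near the threshold deserve inspection.
- The aligner is adequate for the moderately diverged, mostly indel-free
  families vetting handles, not a general replacement for MAFFT.
- Karlin–Altschul parameters are ungapped approximations; absolute
  E-values are not comparable to BLAST's, only the relative ordering and
  the cutoffs are meaningful.
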