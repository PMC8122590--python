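# Methods

## TF identification and classification

A gene is called a TF when, after redundancy removal, its protein carries
at least one DNA-binding-domain (DBD) hit from the rule set that passes
its family's e-value threshold. The shipped rule set maps 85 Pfam
accessions to 78 family labels (the 76 census families plus BTB, used only
by the compound ZBTB rule, and zf-CCCH, a family the engine must tolerate
with zero members). Thresholds follow the conventions of the animal TF
databases: 1e-4 by default, 1e-2 for bHLH, 1e-3 for HMG_box, Homeodomain,
zf-BED and zf-C2H2, and 1e-20 for zf-CCCH. Because the analysis consumes
hmmscan's per-domain tabular output rather than shelling out to HMMER, the
package stays runnable with no external binary; Pfam accession version
suffixes are stripped on read so release drift cannot break the rule join.

Decisions the underlying study leaves open, fixed here deterministically:

* **e-value field** — the full-sequence e-value is screened (matching the
  screening style of the databases the thresholds come from); the
  per-domain independent e-value is available via `use_full_seq=False`.
* **boundary** — inclusive: a hit exactly at its threshold passes.
* **multi-DBD genes** — compound rules are evaluated first (all required
  families passing → host family + subtype); otherwise the family of the
  smallest-e-value hit wins, ties broken by larger bit score, then
  alphabetical family name. All passing families are kept in
  `candidate_families` for audit.
* **redundancy removal** — CD-HIT is replaced by keeping the longest
  isoform per gene (ties: lexicographically smallest protein id), which
  preserves the one-TF-per-gene accounting deterministically.

## Comparative census

All set algebra works on family *presence* (count > 0) at family level;
superfamily labels (bZIP, NF-Y, ETS, bHLH, Homeobox, IRF, STAT, zinc
finger, Nuclear Receptor, MH1) are metadata only. Percentages are exact
rationals rounded half-up to two decimals only at the reporting layer.
The packaged 76 × 9 count table reproduces every printed comparative
number exactly (totals, fractions, expansions, shared and exclusive sets,
orphans); the 61 × 9 family-by-module table keeps one internally
inconsistent printed row (PBC: cells sum to 1, printed total 0) as printed
and flags it rather than correcting it.

## Co-expression modules

FPKM is normalized as log10(FPKM + 1); replicate libraries (7 stages × 3
replicates by default) are collapsed by mean before correlating. The
network is unsigned by default, $a_{ij} = |c_{ij}|^{\beta}$ with
$\beta = 12$; a signed variant $((1+c_{ij})/2)^{\beta}$ is available.
Zero-variance genes (sd below 1e-12 of the profile scale) get correlation
0 to all others and are flagged. The topological overlap matrix is
computed vectorized and verified in tests against an independent
double-loop evaluation to 1e-10.

Module detection is average-linkage hierarchical clustering on
$1-\mathrm{TOM}$ with a **static** cut at `cut_height` × (maximum merge
height), followed by a minimum-size filter (sub-minimum clusters are
relabeled grey) — the limiting, least-aggressive behavior of dynamic tree
cutting with deep splitting off; the `deep_split` flag is reserved but
unimplemented. Surviving modules are colored by descending size
(turquoise, blue, brown, …), ties broken by earliest member index, so the
partition is fully deterministic.

**Choosing the cut height.** The default 0.99 is appropriate for sparse
genome-scale networks, where between-module dissimilarity hugs 1.0 and the
cut only trims the unclustered canopy. In small, densely planted networks
(a few hundred genes, all in modules) between-module average dissimilarity
sits visibly below 1 (≈0.97–0.98 at within-module r = 0.8, β = 12, while
within-module merges complete by ≈0.8), so recovery runs on synthetic
matrices use `cut_height = 0.9` with `min_module_size = 30` — the middle
of the wide band separating the two merge regimes; recovery is insensitive
across cuts 0.8–0.95.

Developmental groups are assigned from each module's **mean**
log-normalized profile: argmax stage in {2–8 cells, gast, neu} → Group I,
tb → Group II, {hsl, trl, mj} → Group III, ties resolved toward the
earlier stage. The module eigengene (first principal component of the
standardized submatrix, sign-oriented along the mean profile) is exposed
for diagnostics only, since the mean profile is simpler and has no sign
ambiguity. Two "expressed" notions are kept distinct and configurable:
network inclusion (FPKM > 0 in ≥ 1 stage) and the expressed call
(FPKM > 10 at a stage).

Module counts are input- and parameter-dependent: the published nine-module
partition came from a genome-wide network from which TF memberships were
read off, so running on a TF-only matrix need not yield nine modules, and
no such count is asserted anywhere.

## Hox collinearity

Expression onset is formalized as the earliest canonical stage with
FPKM > 10 (the same cutoff as the expressed call; configurable, since the
study never defines "initially expressed" numerically). Collinearity uses
Kendall τ-b, the tie-corrected variant, because onset stages are heavily
tied ordinal data; a fully tied onset vector returns τ = 0. STC windows
are genomically contiguous runs of ≥ 3 genes, all with onsets, with
τ = ±1; only windows no qualifying window strictly contains are reported.
Paralog-group assignment is an input (phylogenetics is out of scope).
Cluster-arrangement comparison treats an exact reversal of the shared
paralog-group order as the same order, and "same linkage" means both
clusters are single-chromosome.

## Enrichment and qPCR

Enrichment is the one-sided hypergeometric upper tail
$P(X \ge k)$ for $X \sim \mathrm{Hypergeom}(N, K, n)$, with
Benjamini–Hochberg adjustment over exactly the terms annotated in at
least one background gene (that count is the BH *m*). The original study
used a web tool without naming the test; this is the standard such tools
wrap. Annotations are used as supplied — no ontology-graph propagation.
Relative qPCR expression is 2^−ΔΔCt with ΔCt = Ct(target) − Ct(reference)
per condition.

## Synthetic data

Generators are pure functions of their arguments including the seed; the
same call yields byte-identical files.

* **Domain tables** — planted TF genes draw a family from a mix shaped
  like an ascidian TF complement and get a hit 1–10 decades below their
  family threshold; compound genes get passing BTB and zf-C2H2 hits;
  decoys get hits 1–4 decades *above* threshold (≥ 10× margin, so
  boundary-inclusivity choices cannot flip them). Each gene has 1–4
  isoforms with only the longest carrying the hits.
* **Expression** — module genes share a Gaussian-bump latent profile
  (amplitude 2 on the log10 scale, i.e. peak FPKM ≈ 100; width one stage)
  centred on the module's peak stage, plus independent per-gene noise
  scaled to achieve the stated expected within-module Pearson correlation
  across stages, plus small replicate-level noise (sd 0.05). FPKM is
  10^x − 1 clipped at 0, so normalization recovers the latent structure
  exactly up to clipping. Background genes are flat low-level noise.
* **Hox clusters** — genes placed in order on one chromosome; forward and
  reverse orientations use strictly monotone onset stages; shuffled
  rejection-samples an arrangement with no monotone window of length 3.
* **Annotations** — one planted term over-represented in the target set at
  a stated fold over a 0.1 base rate; decoy terms independent of
  membership.

What passing recovery tests show — and do not: the generators emulate the
*structure* of the real inputs (hit/threshold geometry, stage-peaked
profiles, replicate noise, collinear onsets), not their full biological
messiness (no overlapping module membership, no count-noise model for
FPKM, no correlated decoy architectures, random protein sequences).
Recovery on these fixtures validates the algorithms and their
determinism, not re-derivation of the study's genome-specific counts,
which require the deposited data.

## Problem sizes in tests and the acceptance script

Fixture checks are exact and instantaneous. Recovery runs use 120 planted
TFs + 80 decoys (12 compound), 150-gene noiseless and 300-gene noisy
expression matrices (4 modules of 70 at within-module r = 0.8, 20 seeded
replicates, median adjusted Rand reported), 3–8-gene Hox clusters, and a
500-gene annotation universe with 51 terms — sizes at which every
algorithmic regime (threshold boundaries, compound rules, module merging,
window maximality, BH adjustment) is exercised while the whole suite runs
in seconds.
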