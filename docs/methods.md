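# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the `metabias` pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic communities

The generator produces data with the structure the comparison assumes, not a
mechanistic model of a sequencer.

**Species tree.** Pure-birth (Yule) process with birth rate λ (default 1,
arbitrary time units). Simulation starts at the root split with two
lineages; the waiting time while k lineages exist is Exp(λk), and after the
(n−1)-th split one further Exp(λn) interval runs to the present, so the
expected root height is Σ_{k=2..n} 1/(λk). This closed form is used as the
test oracle.

**Within-species trees.** Each species tip is replaced by a Kingman
coalescent of `within_species_n` tips. θ is the standard pairwise
coalescent scale: the time during which j lineages remain is
Exp(j(j−1)/(2θ)), so the expected subtree height for 4 tips is 1.5 θ. The
subtree height is constrained below the species' terminal branch by
resampling (bounded retries, then an error); grafted trees therefore remain
ultrametric and species stay monophyletic. Note the constraint conditions
the coalescent slightly toward shallower clusters on short branches.

**Sequences.** Jukes–Cantor evolution along branches, independently per
region, with region-specific rates; the per-branch substitution probability
is ¾(1 − e^(−4rt/3)), which gives the closed-form expected identity
¼ + ¾·e^(−4rd/3) between tips at patristic distance d — used directly as a
test oracle. Jukes–Cantor is deliberately the whole model: no rate
heterogeneity, no indels, no chimeras. Default regions: a 300 bp V1–V2-like
region at rate 0.1 substitutions/site/unit time flanked by the EukF/SR7
primers, and a 130 bp V9-like region at rate 0.3 flanked by the
Illumina_Euk_1391f/EukBr primers. The 3× rate ratio encodes the premise
that the V9 region diverges faster; the absolute values were chosen once so
that within-phylum identities fall in the 0.6–0.9 range typical of 18S
comparisons at these scales.

**Surveys.** True incidence is Bernoulli(occupancy) per species × site,
resampled so every species occupies ≥1 site. A present species is detected
by a method with probability p(phylum, method); detections emit
1 + Poisson(depth − 1) reads (so a detection always yields at least one
read) copied from a random individual of the species with i.i.d.
substitution errors. The per-phylum detection probabilities shipped with the
examples (0.95 baseline, 0.3 for the depressed phylum×method cell) are
illustrative: the study design motivates their *structure* — phyla respond
unevenly to the survey method — but no quantitative values exist to copy.
Survey size defaults to 19 sites, matching the field design the comparison
emulates.

What passing tests on these data do **not** show: robustness to PCR/primer
amplification bias, rRNA copy-number variation, chimeras, indel errors, or
abundance-calibrated read counts. The generator treats read counts as
sampling artifacts, never as ecological abundance.

## Unit delimitation

**Sequence variants.** Exact dereplication, then an abundance-ratio merge:
a unique sequence with abundance < `min_abundance` (default 2) within
`max_err_links` (default 1) substitutions of a ≥10×-more-abundant sequence
is merged into the most abundant such neighbour (quietest first, so chains
resolve toward the abundant end); remaining low-abundance sequences are
dropped. This is a fully specified stand-in for learned-error-model
denoisers; it requires equal-length reads and preserves per-site counts
through merges. On simulated data with within-species variation but low
error rates, variant counts can *exceed* 99% OTU counts (the OTU threshold
collapses intraspecific variants); the opposite ordering reported for
error-dominated field data is a property of those error processes, which
this generator does not emulate.

**Greedy clustering.** Centroid clustering in decreasing-abundance order
(ties: lexicographic id), assigning each sequence to the first centroid
reaching the identity threshold (default 0.99), with reverse-strand
matches. Identity is global Needleman–Wunsch (match 1, mismatch −1, gap
−2) with identity = matches / aligned columns (gap–base columns count;
gap–gap cannot occur pairwise). Pinning the aligner and the denominator is
what makes "99%" well-defined. `cluster_reads` dereplicates first and
expands afterwards — identical output, far fewer alignments.

**GMYC.** Single-threshold formulation: for a candidate threshold age T,
branching events older than T are speciation, younger ones coalescence.
Every internode interval is an exponential waiting time under the combined
intensity b(t) = λ₁·n_sp(t) + λ₂·Σⱼ C(nⱼ(t), 2), where n_sp(t) is the
number of species-level lineages (all lineages above T; constant and equal
to the number of clusters below T — i.e. speciation is censored, not
switched off, down to the present) and nⱼ(t) counts the lineages of cluster
j (coalescent intensity is zero above T). The final interval to the present
is censored. λ₁ and λ₂ are maximized by Nelder–Mead in log space from three
starts (the log-likelihood is concave in the rates, so this is belt and
braces); candidate thresholds are the midpoints between consecutive
distinct node ages plus T = 0, at which the model reduces exactly to the
single-process null — guaranteeing LR ≥ 0. Tied node ages are broken by a
seeded jitter of 10⁻⁹ × tree height. The LR is tested against χ² with 2
degrees of freedom (one extra rate plus the threshold). Entities are the
tip sets of subtrees whose stem crosses the best T, singletons included.

A separable variant of this likelihood (class-attributed event factors with
closed-form profiled rates) was implemented first and rejected: on
simulated 5-species trees it systematically merges clusters, because
merging inflates the per-event lineage-pair factors at almost no
survival-probability cost. The combined-intensity form above is
substantially better calibrated but still inherits the well-known
small-sample lumping tendency of GMYC: on 20-tip trees with coalescent
scale 0.01 × tree height it recovers the true species count in roughly
60–70% of replicates, and under those simulation settings a correct global
threshold does not even exist in ~18% of replicates (the youngest
speciation time, ~Exp(5λ), overlaps the coalescent depths). The
delimitation is deterministic given the tree and seed.

## Taxonomy assignment

The hit filter applies the span rule first (span strictly > 120 bp), then
the identity window (≥ top − 0.5), then truncates to five hits; rank
ceilings are strict (>97/>93/>90). Consensus is the lowest common lineage
prefix across retained hits, capped by the ceiling — the only
order-independent reading of "best consensus taxonomy". Clade rescue
examines exactly the *smallest* ancestral clade with support ≥ 0.95
(default; configurable) and requires ≥5 other tips, all assigned, all one
phylum; rescued labels do not feed later rescues, so the result is
independent of tip order. The internal `naive_search` aligns every query
against every reference — adequate for synthetic scales; it is a stand-in
interface, not a fast search tool. Synthetic references have no real family
rank, so the phylum name doubles as a pseudo-family (documented in the
docstring).

## Diversity descriptors

Chao2 uses the classic form S + ((m−1)/m)·Q₁²/(2Q₂) and switches to the
bias-corrected S + ((m−1)/m)·Q₁(Q₁−1)/2 only at Q₂ = 0 (logged). Faith's
PD sums the edges of the minimal subtree connecting the tip set *below*
their MRCA: the MRCA's stem and the root edge are excluded and PD of a
single tip is 0. This convention is pinned because SES comparisons are
convention-sensitive. MPD/MNTD use patristic distances; the SES null
shuffles tip labels uniformly (999 draws by default, seeded); a null whose
standard deviation is zero (e.g. the tip set is all tips) flags the SES as
undefined (NaN) rather than reporting 0.

## Community statistics

Jaccard dissimilarity is computed on per-site unit sets; a pair of empty
sites has distance 0 by convention (logged). PERMANOVA Gower-centers the
squared distance matrix and partitions it by sequential (Type-I) projection
— term order matters, as in the standard distance-based implementations;
the permutation p-value counts the observed statistic in numerator and
denominator, so p is never 0; an exact mode enumerates all permutations for
≤8 sites. The implementation was verified against the R vegan
implementation (adonis2) on fixed inputs; those oracle values are frozen in
the test suite.

The cross-method harness replaces mixed-model richness regression with
site-stratified sign-flip permutation tests of paired per-site richness
differences, Holm-corrected across contrasts — the same null (no method
effect within sites), fully specifiable, and exact under exchangeability.
Per-phylum contrasts require phylum labels on units; in synthetic runs
these come from the ground truth (majority over member reads).

## Marker-region comparison

Primers are matched ungapped by Hamming distance with IUPAC expansion
(default ≤2 mismatches), on both strands; the reverse primer is sought as
its reverse complement downstream of the forward primer, and minus-strand
hits are mapped to forward coordinates. The extracted region excludes the
primer sites (the between-primer interval); an `include_primers` option
exists and makes extraction idempotent on its own output. Identity profiles
average pairwise global-alignment identity within each phylum × region cell
directly, rather than reading it off a multiple alignment; the comparison
of interest is ordinal (V9 versus V1–V2), which is insensitive to this
choice.

## Problem sizes and determinism

The shipped analyses use a 21-species, 19-site community with ~600 reads
per method, 50 replicates for the GMYC-recovery and deficit-detection
rates, 1000 null datasets × 199 permutations for the PERMANOVA
calibration, and 3 replicates × 7 phyla for the region ordering. Every
stochastic step takes an explicit seed and is bit-reproducible; the
acceptance script derives all its seeds from `--seed`.

## Known limitations

* GMYC: single threshold only, no scaling exponents, χ² reference
  distribution rather than a simulated null; small trees lump (see above).
* The denoiser does not model quality scores, chimeras or indels.
* `naive_search` is O(queries × references) alignments.
* PERMANOVA assumes exchangeable sites under the null; no strata support
  beyond the covariate design, and no turnover/nestedness decomposition.
* The generator's detection probabilities are illustrative, and synthetic
  phyla are contiguous clades, which makes clade rescue easier than on
  real para-/polyphyletic reference libraries.
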