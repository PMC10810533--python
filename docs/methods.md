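# Methods

This note documents the models, procedures, defaults and numerical choices
behind the package, and what the synthetic-data experiments do and do not
demonstrate.

## Scientific setting

Ciliates divide somatic and germline functions between two nuclei, and
their somatic genomes fall into strikingly different architectures:
extensive fragmenters (EF) with gene-sized somatic chromosomes,
non-extensive fragmenters (NEF) with multi-gene chromosomes, the highly
polyploid Heterotrichea (HE) and the paradiploid Karyorelictea (KA).  The
pipeline asks how these architectures relate to the birth, sharing and
selection regimes of *lineage-specific gene families* (LSGFs): families
restricted to ciliates and present in at least two ciliate genera.  Because
most ciliate data are transcriptomes, the pipeline is built around
aggressive curation (ORF calling under the correct genetic code, allelic
collapse, composition screening) and loss-insensitive inference (Dollo
gains only; reconciliation duplications only).

## ORF curation

ORFs are called per transcript in all six frames under a configurable
genetic code.  Ciliate stop-codon usage varies: the default is NCBI table 6
(TAA/TAG = Gln, used by most ciliate classes), with table 1 and table 10
(TGA = Cys, *Euplotes*) built in and custom 64-line tables loadable.
"Largest complete ORF" is read as one ORF per transcript requiring both an
ATG start and an in-frame stop; the terminal stop is excluded so the CDS
length is exactly 3x the protein length.  A `complete_only=False` mode
drops the ATG requirement (stop-to-stop), since it is genuinely unknown
which behaviour a given ORF caller used; the default is the stricter
reading.  ORFs under 200 aa are discarded (configurable; the desk-scale
synthetic runs lower this because they simulate 100–250-codon genes).

Allelic variants are collapsed by greedy longest-first clustering at >= 97%
nucleotide identity over the full shorter sequence.  This reproduces the
semantics of CD-HIT-EST's `-G 0 -c 0.97 -aS 1.00` without its word-filter
heuristics: at desk scale an exact pairwise pass (edlib infix alignment,
identity = 1 − edit distance / shorter length, gaps and ambiguity codes
counting as mismatches) is affordable and deterministic given the
length-then-id ordering.

## Composition statistics and filtering

GC3s is the G+C fraction at third positions of codons in four-fold
degenerate quartets *of the active code* (the same eight quartets under
tables 1 and 6).  ENc is Wright's effective number of codons generalised to
arbitrary codes: per amino acid `a` with `n >= 2` observations,
`F_a = (n Σ p_i² − 1)/(n − 1)`; `F̄_k` averages over observed amino acids of
degeneracy `k`; `ENc = N_1 + Σ_k N_k / F̄_k`, clamped to the sense-codon
count (61/63/62 under tables 1/6/10).  Degeneracy classes are recomputed
per code — under table 6, Gln is four-fold.  Unobserved classes are imputed
from the flanking observed classes (Wright's convention); families with
`n < 2` or `F <= 0` are treated as missing.  ENc is computed on the full
CDS; the four-fold restriction applies to GC3s only.

The lineage-specific candidates are filtered against the GC3s values of a
conserved-gene reference set: candidates inside the closed
[10th, 90th]-percentile interval (linear-interpolation percentiles, the
common default) are retained.  The reference is a plain one-value-per-line
input, so any conserved-family set can be supplied; the synthetic module
generates one.  ENc is computed and reported but not filtered on by
default, since the retention rule is stated on GC3s; an optional ENc band
exists.  The band is pooled across taxa by default.

## Family refinement and sharing

Refinement applies, in order: (1) a length band — the mean protein length
is computed once over the initial membership and members outside
[50%, 150%] of it are dropped (a single pass, not iterated); (2) on the
survivors, ciliate proportion >= 95%, member count >= 5, and >= 2 distinct
ciliate genera (genus from the taxon metadata table, never parsed from
sequence ids).  Rejections carry machine-readable reasons
(`ciliate_proportion`, `min_members`, `min_genera`).  Whether the
proportion should be evaluated before the length drop is ambiguous; the
default is after, with `proportion_before_band=True` to flip.

Sharing summaries project families onto a families-by-taxa count matrix and
report upset-style intersection counts over architecture categories,
per-category family counts and mean/median sizes, and per-taxon counts.  A
single-linkage protein-identity clustering is included purely so synthetic
runs are end-to-end; real analyses should supply an orthology-derived
membership map.

## Dollo dating and reconciliation

Under Dollo parsimony a family is gained once and lost arbitrarily often,
so the birth maps to the MRCA of the presence leaves and the gain is
tallied on the branch subtending it (root gains on the root).  Minimal loss
counts (one per maximal absent subtree below the birth) are computed for
validation but excluded from reports: with transcriptome-dominated
sampling, absence is weak evidence.  All-absent families are skipped with a
warning.

Duplications are mapped by fixed-topology LCA reconciliation: postorder
mapping of each gene-tree node to the LCA of its children's images, with a
duplication wherever a node maps to the same species node as one of its
children.  This is the major deviation from a full DL reconciliation with
topology search (no SPR correction of gene trees); the package trusts its
input gene trees.  Unrooted inputs can be midpoint- or outgroup-rooted.
Losses are counted internally by the usual depth-difference bookkeeping and
likewise excluded from reports.

## Codon model and selection tests

The substitution model is MG94 x GTR over the sense codons of the active
code: single-nucleotide codon changes at rate (exchangeability x target
frequency), multiplied by omega for nonsynonymous changes; multi-nucleotide
changes are forbidden.  Codon frequencies come from the F3x4 convention
with a 0.5 pseudocount.  The generator is scaled so branch length 1 = one
expected substitution per codon at omega = 1.  Random effects are at the
branch-site level: each (branch, site) draws omega independently from the
branch's 3-category discrete distribution, so the per-branch transition
matrix is the category-weighted mixture and the likelihood factorises over
sites.  Likelihoods use pruning over the codon state space with
per-node rescaling; transition matrices come from the symmetrised
eigendecomposition that reversibility affords.

Branches are labeled EF/NEF/HE/KA/unclassified: terminal branches by their
taxon's category, internal branches labeled `c` iff every branch below is
labeled `c`.  Groups with fewer than two labeled branches are folded into
the nuisance (unclassified) class for fitting.  A partition is testable
when at least two groups have two or more branches; the reference is EF if
present, else NEF, else HE, else KA.

**RELAX-style intensity test.**  Null: one shared reference omega
distribution, all `K_G = 1`.  Alternative: a free exponent `K_G` per
non-reference group, applied as `omega_ref^K` with shared weights (`K < 1`
relaxation, `K > 1` intensification).  Unclassified branches carry an
independent nuisance distribution in both models.  LRT = 2 delta lnL
against chi-square with |G| − 1 degrees of freedom; BH-FDR across families.
A partitioned descriptive model (free distribution per group) is also
fitted, and the "good fit" check compares the RELAX alternative against it
by small-sample-corrected AIC (AICc with n = number of codons) — the
criterion behind the published fit check is unspecified, so this documented
information-criterion rule stands in.  K is bounded to [1e-3, 50]; bound
hits and alt-below-null refits are flagged in `warnings`.  Wald confidence
intervals for K come from the finite-difference curvature of the profile in
log K.

**BUSTED[S]-style EDS screen.**  Per group: unconstrained model (free
distribution per group, omega_3 unbounded) versus the tested group
constrained to omega <= 1.  The LRT null is the conservative 50:50 mixture
of chi2_0 and chi2_2 (boundary handling; the degrees of freedom are not
stated in the source analysis).  Synonymous site-to-site rate variation is
implemented as an optional 3-category mean-1 branch-length multiplier mixed
at the site level and is OFF by default — with it off the screen is plain
BUSTED; the LRT contract is unchanged.  Detection rates are binned by
floor(labeled branches / 5) at q <= 0.1.

**Optimisation.**  Two-stage: branch lengths (a single scale factor on the
input lengths, by default) and nucleotide rates (HKY kappa by default, full
GTR optional) are estimated once under a shared single-omega model and held
fixed across tests.  Omega distributions are fitted by L-BFGS-B on
unconstrained transforms (log-increment values, softmax weights; for the
constrained model a product-of-sigmoids chain keeps omegas in (0,1)),
ftol 1e-9, with two starts per model: a data-informed/neutral pair for the
null, and for the alternative the null solution with K = 1 (which
guarantees LRT >= 0 by nesting) plus a jittered start.  Two starts rather
than three-or-more proved sufficient on the synthetic scales used here;
the count is a parameter (`n_starts`).

## Synthetic data

The generator defines the study conditions for every experiment:

* **Species tree** — categories assigned clade-wise and monophyletic,
  nested (KA,(HE,(NEF,EF))) to mirror ciliate taxonomy, with random-join
  clade topologies and exponential branch lengths (mean 0.2
  substitutions/codon); `cladewise=False` shuffles labels for stress tests.
  Category proportions are apportioned exactly (largest remainder).
* **Family histories** — one birth per family on a length-weighted random
  branch (a virtual root branch of mean branch length allows root births;
  length weighting puts most births near the tips, matching the expected
  shape since no empirical birth/loss/duplication magnitudes exist to
  calibrate against — the defaults, loss 0.3 and duplication 0.1 per unit
  branch length, are documented as arbitrary).  Losses kill whole subtrees
  at branch granularity and apply to every gene copy passing through;
  duplication copies evolve independently below a uniform point on their
  branch and do not replay later duplication events.  Fully-lost families
  are flagged, not dropped.
* **Alignments** — root sequence from pi; per-branch-site omega draws from
  the group distribution (`omega_ref^K_G`; K defaults to 1 per group).
  Stop codons cannot arise (sense-codon state space).  Reference
  distribution default: omega (0.05, 0.35, 1.2) with weights
  (0.6, 0.35, 0.05) — mostly purifying with a small nearly-neutral-plus
  class, a realistic regime for young gene families.
* **Transcriptomes** — each CDS is wrapped as AT-rich flank + stop + ATG +
  CDS + stop + flank.  floor(rate x n) records get allelic variants (1.5%
  point mutations, stop-avoiding, hence >= 97% identity to source);
  round(fraction x n) contaminant ORFs are drawn at the contaminant GC3s
  target (0.25 vs the ciliate 0.70) from the same code's sense codons.
  Truth tables record every record's class and family.
* **Conserved reference** — each of 200 reference genes draws its own GC3
  target from Normal(0.70, 0.06) before sampling 300 codons, emulating the
  between-family compositional variance of real conserved families; with
  zero spread the 10–90 band would be unrealistically narrow.

What the synthetic data do *not* emulate: assembly errors and fragmented
transcripts, rRNA contamination, genuine alignment uncertainty (alignments
are simulated aligned), gene conversion between duplicates, within-branch
rate variation beyond the omega mixture, and non-monophyletic architecture
categories (the real EF group is polyphyletic; the clade-wise default is a
simplification, with leaf-wise shuffling available).  Passing the recovery
experiments therefore shows the *procedures* are implemented correctly and
calibrated under the stated model, not that they are robust to all real
ciliate data pathologies.

## Validation experiments and problem sizes

`scripts/acceptance.py` (and the mirror tests in
`tests/test_acceptance.py`) recompute, from scratch at each run:

* ORF caller vs exhaustive (frame, start, stop) enumeration: 100 random
  5–10 kb sequences x 3 codes.
* ENc limits: uniform usage -> 61 (standard code), one codon per amino
  acid -> exactly 20.
* Composition recovery: 8 taxa, 60 families, 250 codons, 25% contaminants;
  >= 90% contaminants discarded and >= 90% genuine retained.
* Family filter: the {100,100,100,100,400} hand case (rejected,
  `min_members`) and threshold-tightening monotonicity over 200 random
  families.
* Dollo vs exhaustive loss-subset enumeration: 500 random instances up to
  8 leaves; plus birth recovery on simulations (exact without losses,
  descendant-or-equal with).
* Reconciliation vs brute-force duplication minimisation: exhaustive over
  all gene trees up to 4 leaves on a 4-species tree (all topologies x all
  labelings) plus 400 sampled 5–6-leaf trees — full enumeration at 6
  leaves (~43M reconciliations) is out of desk-scale reach; the
  two-species-tree-copies construction must give exactly one root
  duplication.
* Codon likelihood vs exhaustive ancestral-state summation (scipy expm,
  independent Q construction): 3–4 taxon, 3–10 codon instances, 1e-8
  relative tolerance; zero-length limit = sum log pi.
* RELAX calibration: 24 null replicates at 16 taxa / 300 codons (EF vs HE
  clades), rejection rate inside the exact binomial 95% band around 0.05,
  LRT never negative.  K recovery: 12 replicates each at K_true = 0.3 and
  2.0, median on the correct side of 1.
* BUSTED screen: 20 all-omega<=1 replicates (rejection <= 0.075 under the
  conservative boundary null) and 10 replicates with a planted omega_3 = 4,
  weight 0.1 class (power strictly above the null rate), 12 taxa / 300
  codons, single-group trees.
* BH-FDR worked example {0.01..0.04} -> all 0.04; q >= p on random input.
* Pipeline determinism: the 8-taxon / 30-family / 100-codon synthetic run,
  executed twice, must produce byte-identical output trees.

Replicate counts are the package's desk-scale defaults, chosen so the whole
suite completes comfortably on one CPU; they are parameters of the
experiment functions.

## Known limitations

* The clustering stand-in is naive single linkage on global identity; it
  exists for end-to-end synthetic runs only.
* LCA reconciliation inherits every error in the input gene trees; with
  losses present, inferred duplication counts are not guaranteed to bound
  the truth in either direction, so the synthetic recovery test asserts
  exact recovery only in the loss-free case.
* The two-stage optimisation (fixed branch lengths/rates during the omega
  fits) trades a small amount of statistical efficiency for large runtime
  savings; `baseline_mode="gtr"` and per-test refitting are available but
  slow.
* Confidence intervals for K are Wald intervals on log K from local
  curvature; they are unreliable when K sits at its bounds (flagged).
* The tiny pipeline preset filters aggressively at 100 codons because GC3s
  is noisy on short ORFs; this is a scale artifact of the smoke
  configuration, not of the method.
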