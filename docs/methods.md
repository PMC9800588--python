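# Methods

This note documents the statistical models, default parameters, and design
choices behind `estrocycle`, and what the synthetic-data results do and do
not establish about real data.

## Study design being modelled

The pipeline targets a two-phase, multi-tissue bulk RNA-seq comparison of
the rodent estrous cycle: for each of up to 15 tissues, three biological
replicates are profiled in estrus (estrogen-dominant, peri-ovulatory) and
three in diestrus (progesterone-dominant). All inference contrasts estrus
against diestrus within a tissue, then compares tissues.

## Differential expression (`deg`)

Counts are pooled across replicates per gene and phase. With pooled count
K and total library size N per phase, the fold-change estimator is

    log2FC = log2( ((K_A + c) / N_A) / ((K_B + c) / N_B) ),   c = 1

and significance comes from the two-proportion z-test on the pooled rates:

    p̂ = (K_A + K_B) / (N_A + N_B)
    z  = (K_A/N_A − K_B/N_B) / sqrt( p̂ (1 − p̂) (1/N_A + 1/N_B) )

with a two-sided normal p-value, Benjamini–Hochberg adjustment per tissue,
and the inclusive call rule |log2FC| ≥ 1 and q ≤ 0.05. Genes with zero
pooled counts in both phases are removed before testing (undefined fold
change); the pseudocount enters the estimate only, never the test.

This estimator treats replicate variation as read-sampling (Poisson)
noise. That is a deliberate modelling choice — it matches the class of
pooled-count DE methods appropriate when only three replicates are
available — and it has a known consequence: **under biological
overdispersion the test is anti-conservative**. All null-calibration
checks therefore run the generator in its Poisson limit
(`nb_dispersion = 0`), where the test's stated level is the right
benchmark. DEG counts from overdispersed data should be read as a ranking,
not as an FDR-calibrated list; a replicate-level NB GLM is out of scope.

Trends encode each DEG as +1 (up in estrus) or −1 (down). Tissue
similarity is the cosine of two trend vectors restricted to the genes
called in **both** tissues — for ±1 vectors this is the mean elementwise
product — with NaN marking pairs sharing no DEG. The top-k tissues by DEG
count (default k = 6, ties broken lexicographically) are prioritised as
estrous-cycle target tissues (ECTTs).

## Over-representation (`enrich`)

One-sided Fisher exact (hypergeometric upper tail) tests of the up, down,
and combined DEG sets per tissue against each GMT term. The universe is
the set of genes actually tested for DE in that tissue — the standard
background correction; genome-wide universes overstate enrichment. BH runs
within each tissue × collection × direction family (the three directions
are distinct hypothesis families, mirroring the three-column reporting of
up/down/both). Cross-tissue reporting keeps terms significant in ≥ 5
tissues and links term pairs sharing ≥ 25% of contributing DEGs, with
|A∩B| / min(|A|,|B|) as the (symmetric, nested-set-conservative) overlap
fraction. Links internal to a named collection can be suppressed in
reports (default: the disease-association collection, which is link-dense).

## Network hubness (`netcent`)

Centrality on the directed signaling network: total (in+out) degree;
betweenness on unweighted shortest paths normalised by (N−1)(N−2);
PageRank with damping 0.85, uniform teleport, dangling mass redistributed
uniformly, iterated to an L1 tolerance tighter than 1e−10. Hubness is a
one-sided Wilcoxon rank-sum test of DEG-node centralities against all
remaining network nodes (the question is positional: where do DEGs sit
*within* the network), tested in both directions since DEG sets can sit
significantly below background. Small tie-free pooled samples (n+m ≤ 12)
use exact enumeration; otherwise the normal approximation with tie and
continuity corrections. A constant pooled sample is degenerate and
reported as p = 1.

## TF activity (`tfact`)

A regulon is a TF's signed target set; sign 0 means direction-unknown
regulation. For a hypothesised direction d ∈ {up = +1, down = −1} the
consistency statistic over measured targets is

    S = Σ_signed  [trend == d·sign] − [trend == −d·sign]  +  #unsigned-measured

i.e. correct minus incorrect predictions, with unsigned edges contributing
responsiveness evidence only. Significance is a one-sided permutation
test: trend labels are permuted over the measured-gene universe B times
(default 1000) with the regulon fixed, p = (1 + #{S_perm ≥ S_obs})/(B+1) —
the permutation null automatically absorbs any up/down imbalance of the
global trend. BH runs across all (TF, direction) pairs per tissue; each TF
then keeps its better direction (smaller q, then larger |S|), so no TF is
reported active in both directions. The activity score is the signed,
shrunk significance ±min(−log10 q, 16); the 1e−16 floor keeps scores
finite and ranking-stable. Online platforms for causal TF inference keep
their consistency statistics partly unpublished; the
correct-minus-incorrect score with a permutation null is this package's
own fully specified statistic for the same inference contract
(directional consistency, one-sided q ≤ 0.05).

Key TFs are those significant in ≥ 4 ECTTs (direction may differ by
tissue). The expression–activity check pools all significant (TF, tissue)
pairs and reports the Spearman correlation between TF log2FC and signed
activity score.

## Signature comparison and PTSP (`tascomp`)

A transcriptomic alteration signature (TAS) is the gene-indexed log2FC
vector of one experiment vs its control, built with the same pooled-rate
estimator as the DE stage. The estrus-induced TAS of a tissue is matched
against a same-tissue library of labelled signatures by Spearman
correlation over the gene intersection of each pair (zero-filling the
union would manufacture rank ties); pairs sharing < 100 genes are skipped.
P-values use the t approximation t = SCC·sqrt((n−2)/(1−SCC²)), standard at
transcriptome-scale n. The library is first de-duplicated by a greedy
single pass in curation order, removing members with SCC ≥ 0.5 against any
already-retained same-tissue member — deterministic, and order-faithful to
how curated libraries grow; pairs below the overlap floor cannot be
assessed and are kept. Matches are significant at |SCC| ≥ 0.1 (inclusive).

Each significant labelled match votes on the protective phase: a positive
correlation with a beneficial state, or negative with a deleterious state,
is evidence that estrus protects the tissue; the converse favours
diestrus. The verdict is the majority, with a two-sided exact binomial
sign test against an even split; ties and unlabelled-only matches are
indeterminate. Ovary and uterus are excluded from verdicts by default:
their deleterious-labelled matches can reflect normal cycle physiology
(luteinisation, decidualisation) rather than harm. Label paths
(outcome / experiment type / subtype) are aggregated as counts per path
prefix for positive hits, negative hits, and the whole-library background.

## Synthetic data (`synthdata`)

The generator plants known truth for every stage. Defaults are the
modelled study conditions: 3 replicates per tissue-phase group, 15
tissues, replicate depth 1e6 expected reads (sequencing-scale depth scaled
down ~20× for tractability), planted effect |log2FC| = 2, NB dispersion
0.05 (mild overdispersion typical of inbred-line bulk RNA-seq), 10% of
genes differential, per-tissue library of 84 signatures (a realistically
sized curation effort of ~1,300 signatures across 15 tissues) with half
correlated at |ρ_S| = 0.3.

* **Counts**: per-gene baselines are log-normal (σ = 1.5) rescaled to the
  target depth; counts are gamma-Poisson with variance μ + φμ²; planted
  DEGs multiply the estrus mean by 2^(±2).
* **Libraries**: correlated members use a Gaussian copula — query values
  are rank-transformed to normal scores z and members are
  s·ρ_P·z + sqrt(1−ρ_P²)·ε with ρ_P = 2·sin(πρ_S/6), the exact Pearson
  counterpart of the target Spearman under bivariate normality. The sign s
  couples to the outcome label through a planted protective phase, so the
  PTSP verdict has a known right answer. Labels live in a fixed 3-level
  hierarchy (outcome / {disease, chemical treatment, lifestyle} /
  subtype).
* **Networks**: preferential-attachment growth with random edge
  orientation; planted hubs (drawn from the DEG set) receive extra edges
  until their total degree clears the 95th percentile of the background
  with margin.
* **Regulons**: planted active TFs are DEG genes whose own trend matches
  their activity direction; a fraction `tf_consistency` (default 0.9) of
  their 20 targets get the consistent edge sign. Inactive TFs sample
  targets uniformly from the measured genes with random signs.
* **Study bundle**: tissues share a global planted sign map, each keeping
  a random 80% subset, with four tissues (aorta, brown adipose, kidney,
  skeletal muscle) sign-flipped — producing the two-module cross-tissue
  trend structure the cosine map should recover, and giving key-TF sharing
  across ECTTs a planted basis.

Every generator is a pure function of (config, seed); a single user seed
derives independent per-stage substreams by hashing stage names, so adding
a stage never perturbs another.

What the generator does **not** emulate: read-level artefacts (GC bias,
mapping ambiguity), batch effects, correlated gene-gene expression beyond
the planted signature structure, heavy-tailed library-size variation, and
real curation biases in signature libraries (different platforms and
dimensionalities). Passing recovery tests therefore demonstrates that the
inference machinery is correct and calibrated under its stated model, not
that the model captures every property of real tissue panels.

## Problem sizes and numerical choices

Unit tests run at reduced scale (hundreds of genes, 4–8 tissues,
B = 150–500); the acceptance checks use the stated recovery conditions
(e.g. ρ = 0.3 at 10,000 genes; TF consistency 0.9 with 20 targets at
B = 1000 over 50 seeds; 100 simulated tissues for PTSP; 100 networks for
hub detection) and the bundled demo defaults to 2,000 genes × 15 tissues.
Ties in Spearman use midranks throughout; all decision thresholds are
inclusive at their boundary; ECTT and pruning ties resolve
deterministically (lexicographic / input order); permutation p-values are
computed with the +1 correction so p ∈ (0, 1].

## Known limitations

* The DE test is anti-conservative under biological overdispersion (see
  above); DEG lists from pooled-count methods are also
  implementation-sensitive, so identical counts should not be expected
  across tools.
* SCC thresholds compare signatures of differing dimensionality on a
  common scale; the overlap floor mitigates but does not remove the
  resulting bias.
* The TF statistic is this package's stand-in for an unpublished platform
  statistic; q-values agree in contract (one-sided, BH, ≤ 0.05) but not
  necessarily numerically.
* PTSP verdicts are label-majority votes; they inherit any curation bias
  in the outcome labels of the library.
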