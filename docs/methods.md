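# Methods

## Problem and model

`comopath` implements a comparative, network-based analysis for two complex
diseases that are suspected to share etiology. The premise is pleiotropy:
some genes or proteins influence both phenotypes, either by sitting on
pathways enriched for both diseases' susceptibility genes or by physically
interacting with susceptibility proteins of both. Three linked computations
operationalise this:

1. **Two-cluster pathway over-representation.** The two disease lists are
   merged into one query and each pathway receives a single hypergeometric
   upper-tail p-value `P(X ≥ k)` for `X ~ Hypergeometric(N, K, n)` — the
   probability of drawing at least `k` annotated genes in `n` query genes
   from an `N`-gene universe containing `K` annotated genes. The tail is
   inclusive of `k` (plain upper tail; no mid-p or two-sided variant).
   Benjamini–Hochberg step-up adjustment runs across all tested pathways as
   one family, including when several GMT files are merged, because the
   downstream interpretation treats the merged annotation as one screen.
   Pathways with zero query overlap are excluded *before* the family is
   formed: they are untestable and would only dilute the adjustment.
2. **Specificity classification.** Each significant pathway's mapped genes
   split into `u₁` (cluster 1 only), `u₂` (cluster 2 only) and `c` (both
   lists). The pathway is specific to cluster *i* iff
   `(uᵢ + c)/total > τ` strictly, for that cluster alone; otherwise it is
   shared. Genes on both lists count toward both fractions — discarding
   them would throw away exactly the genes most relevant to comorbidity.
   Published two-cluster tables of this kind are not all consistent with any
   single counting convention, so both τ and the strict inequality are
   exposed as configuration rather than silently fitted.
3. **Kappa crosstalk network.** For each significant pathway pair, Cohen's
   kappa of the two membership indicator vectors is computed over the
   *mapped query genes* (every susceptibility gene that appears in at least
   one tested pathway), not over the full annotation universe. The mapped
   domain is what the overlaid gene layer displays, and agreement over
   genes that neither pathway could contain is uninformative; the
   full-universe domain remains selectable. Edges require κ ≥ θ.
4. **Guilt-by-association candidate inference.** The PPI network is cleaned
   (self-interactions removed, duplicate unordered pairs collapsed
   first-wins, degree-0 nodes dropped), susceptibility proteins are mapped
   in (unmapped symbols are dropped and counted), and the analysis network
   is the induced subgraph on susceptibility proteins plus their first
   neighbours. A neighbour is a candidate when it has ≥ `min_each` distinct
   susceptibility partners from each disease; with ≥ h from each it is a
   hub. Proteins on both disease lists count toward both partner tallies,
   and susceptibility proteins are never themselves candidates. The
   candidate sub-network uses induced-subgraph semantics, so
   susceptibility–susceptibility and candidate–candidate adjacencies among
   retained nodes are kept.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | BH-adjusted significance cut for pathways |
| `tau` | 0.66 | strict fraction for cluster specificity, in (0.5, 1) |
| `theta` | 0.4 | kappa threshold for a crosstalk edge, in (0, 1] |
| `min_each` | 1 | distinct partners per disease for a candidate (≥ 2 gives the stricter reading of "multiple partners") |
| `hub_threshold` | 5 | partners per disease for a hub, boundary inclusive |

The background universe defaults to the union of all pathway members in the
loaded GMT files; a user-supplied background list overrides it. This is the
annotation's own gene space — the conventional default when the true
testing background is unreported.

## Numerical choices

- The hypergeometric tail is `scipy.stats.hypergeom.sf(k-1, N, K, n)`; BH is
  `statsmodels.multipletests(method="fdr_bh")`. Both are validated in the
  test suite against independent oracles (exhaustive draw enumeration for
  all universes N ≤ 12 at 1e-12; a naive sort-and-cumulative-min step-up on
  1,000 random vectors).
- Kappa is computed from the 2×2 table in closed form. The degenerate case
  `Pe = 1` (both indicator vectors constant over the domain) returns 1.0
  when the vectors are identical and 0.0 otherwise — a continuity
  convention, exercised explicitly in the tests.
- Ties in adjusted p sort by pathway id; candidate lists sort by
  min(deg1, deg2), then total partners, then symbol. All outputs are
  deterministic functions of their inputs.
- Gene symbols are normalized by uppercasing and whitespace-stripping only;
  no alias or ortholog mapping, so identity is deterministic and
  dependency-free. Symbols that do not match between inputs simply drop out
  (with logged counts) rather than being guessed.

## The synthetic generator

The generator emulates the study conditions the pipeline is designed for,
with every random draw flowing from one integer seed:

- **Gene lists**: 196 and 200 symbols from a 2,000-gene universe with
  exactly 14 shared (union 382). Symbols are neutral tokens (`G0001`…), so
  fixtures never make accidental biological claims.
- **Pathways**: 10 cluster-1-specific, 11 cluster-2-specific and 7 shared
  planted pathways of size 20, each drawing 75% of members from its target
  cluster(s) (shared pathways split the draw evenly between the two
  exclusive strata) and the rest uniformly from the remaining universe,
  plus 50 size-20 null pathways drawn uniformly. Within each
  cluster-specific group, the first two pathway pairs share 60% of their
  target members so the kappa layer has planted crosstalk edges to find.
  Two shared genes are additionally planted into 12 and 4 enriched pathways
  respectively, emulating a gene shared by many significant pathways; they
  are excluded from all random draws so their membership degree is exact.
- **PPI**: 20 planted candidate proteins wired *exactly* — partners sampled
  without replacement from each disease's exclusive susceptibility proteins
  — to (deg1, deg2) targets of which 9 meet the (≥5, ≥5) hub rule. Decoy
  nodes (200) split into two helper pools, each attaching only to one
  disease's exclusive proteins (1 + Poisson(1) attachments each), so no
  decoy can satisfy the dual rule; shared susceptibility proteins anchor to
  exclusive susceptibility proteins only, for the same reason. A coverage
  pass guarantees every susceptibility protein maps into the network.
  Decoy–decoy background is Erdős–Rényi (p = 0.02) by default, with a
  preferential-attachment alternative; candidate inference depends only on
  local wiring, so the background topology is nuisance structure.

`recount_truth` re-reads the emitted files with the ordinary readers and
recounts every planted quantity against the stored truth, so tampering with
any file is detectable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: GWAS noise and false-positive susceptibility
genes; incomplete and biased pathway annotations; study-bias and
false-negative edges in literature-curated interactomes; real gene-symbol
ambiguity. The planted-recovery results certify the pipeline's correctness,
not the biological validity of any particular input.

## Problem sizes used in tests and the acceptance script

The acceptance checks run the full default-condition pipeline once for the
arithmetic identities, exhaustively enumerate hypergeometric draws up to
N = 12 and all subset pairs of a 5-element kappa domain, and repeat the
generate–enrich–infer cycle over 200 seeds for the recovery rates. At the
default sizes one full cycle takes well under a second, so the whole suite
completes in well under a minute on one core.

## Known limitations

- One merged-query test per pathway; per-cluster testing (two families) is
  a documented alternative the package does not currently perform.
- Kappa uses plain pairwise agreement; no term-grouping or seeded fusion of
  pathway clusters.
- The PPI stage treats the interactome as static and unweighted; no
  confidence scores, no propagation/random-walk scoring, no literature
  mining of candidates.
- No identifier-mapping services: inputs must share a symbol namespace.
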