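# Methods

This note documents the models, parameters and design choices behind
`helhunt`, and what the synthetic-data tests do and do not demonstrate.

## Element model

A non-autonomous Hel-2-class Helitron is modelled as a ~250–340 bp element
with: a 5′-TC (or TCC) terminus; a 3′-CTRR terminus (R ∈ {A, G}; CTAG in
the family this package targets); flanking A/T bases from integration
between AT/TT dinucleotides with no target-site duplication; a stem-loop
within 100 bp upstream of the 3′ terminus; a 5′-IR (both arms in the first
60 bp); an SIR (one arm in each 120 bp subterminal window); and a (CTGT)n
or (GTTT)n microsatellite. Window sizes are configuration
(`AnnotationConfig`), since no canonical values exist; the defaults above
reflect the published layout of the family.

Confidence tiers are a deterministic function of the features found:
`full` = both canonical termini + a reported hairpin; `partial` = one
terminus + hairpin, or both termini without hairpin (copies whose termini
have eroded or whose hairpin mutated away); `structural_only` = hairpin or
SIR without a canonical terminus; `rejected` otherwise.

## Homology scanning

Candidate copies are found by affine-gap Smith–Waterman (match +2,
mismatch −3, gap open 5 / extend 2 — blastn-like), both strands, with
greedy suboptimal-hit extraction: the optimal hit's subject span is masked
and the DP re-run, down to a score floor equal to the score of a 50 bp,
65%-identity gap-free alignment (12.5 with the defaults). Because that
floor sits below the random-score ceiling of kilobase-scale subjects,
extraction is additionally capped at `max_hits` (default 25) per strand;
the E-value filter removes the noise hits downstream.

E-values use the Karlin–Altschul form E = K·m·n·exp(−λS). λ = 0.625
nats/unit and K = 0.41 are the ungapped-theory values for +2/−3 at uniform
base composition (λ solves Σ πᵢπⱼ e^{λ sᵢⱼ} = 1); they are configuration
constants, not estimated, because desk-scale reproducibility matters more
here than statistical sharpness.

Retention requires identity ≥ 65%, E ≤ 1e−5, and full query coverage or a
≥ 50 bp alignment anchored at the query 5′ or 3′ end. Identity is
computed over aligned columns with gap columns counted as non-matches
(the common report convention); an ungapped-denominator variant is
available in the alignment module. **Full-length end slack is 20 bp**
(config-exposed): a local alignment trims mutated element ends whose
partial score is negative, and at the filter's divergence tolerance this
trim routinely exceeds a few bases, so a 5 bp slack would demote genuine
full-length copies; 20 bp covers the observed trim tail while remaining
far shorter than the 50 bp terminal-anchor requirement. Hits anchored at
neither end are classed `internal` and never retained.

## Hairpin energy model

Hairpin stability uses unified nearest-neighbor DNA stacking free energies
(37 °C, 1 M NaCl), a linear hairpin-loop penalty ΔG_loop = 3.0 + 0.3·(L−3)
kcal/mol, and a flat +1.0 kcal/mol per stem mismatch; mismatches interrupt
stacking; bulges and internal loops are not modelled. Stems need ≥ 4
pairs with Watson–Crick outermost/innermost pairs and ≤ 2 mismatches;
loops ≥ 3 nt; hairpins are reported only below −3.0 kcal/mol. The model
is deliberately minimal so that the minimum-free-energy search can be
verified against exhaustive enumeration of every stem-loop on short
windows — the tests do exactly that on 500 random ≤ 30 nt windows. The
trade-off: reported ΔG values are comparable within this package, not
interchangeable with full secondary-structure predictors.

## Alignment

Pairwise global alignment scores match +1 / mismatch 0 with affine gap
penalties open 10 / extend 0.2 (the parameterisation conventionally used
for nucleotide ClustalW-style alignment of these elements); progressive
multiple alignment uses a neighbor-joining guide tree on fractional
common-k-mer distances (k = 4) and profile–profile merges under gap open
10.0. DP traceback ties break diagonal > up > left, so output is
platform-deterministic. "Identity" is reported in both the all-columns
and ungapped-columns conventions because published similarity figures do
not always state which was used; `complete_deletion` (drop every column
containing any gap) precedes all distance and likelihood computation.

## Phylogenetics

The substitution model is Tamura's three-parameter model (T92): base
frequencies π_A = π_T = (1−θ)/2, π_G = π_C = θ/2, transition/transversion
rate ratio κ (default 2.0 — the matrix needs a κ even though the distance
estimator does not, since the latter conditions on observed P and Q), and
discrete-gamma rate variation with 4 categories at equal-probability slice
means, shape 2.249 by default (appropriate for moderately heterogeneous
element families; config-exposed). θ defaults to the alignment's
empirical GC, as T3P defines it from data. Distances use the closed-form
estimator (gamma-transformed when rate variation is on); saturated pairs
are flagged NaN rather than clamped.

Trees are built by neighbor joining (negative branch lengths clamped to
zero with the deficit moved to the sibling edge; ties break on
lexicographic representative labels), optionally polished by
nearest-neighbor-interchange hill climbing scored with a
Felsenstein-pruning log-likelihood; a full maximum-likelihood tree search
is out of scope, and NJ(+NNI) under the same model family is the
documented stand-in. Support comes from nonparametric bootstrap (column
resampling) with ≥ 50% majority-rule consensus; replicate distances that
saturate fall back to 1.5× the replicate's largest finite distance.
Robinson–Foulds distance against a reference species tree quantifies
incongruence.

## HTT screen

The primary flag is the raw inequality Δ = TE identity − host-marker
identity > 0 per species pair — the comparative-divergence criterion
itself — never replaced by the significance test. The permutation
p-value is an added strengthening: taxon labels of the **TE** matrix are
jointly permuted and Δ recomputed for the focal pair,
p = (1 + #{Δ_null ≥ Δ_obs}) / (1 + N). Two design points:

* **The TE matrix is the one permuted.** The transfer signal lives in the
  TE identities; permuting the host matrix cannot detect an elevated TE
  value when host identities carry no information about the focal pair
  (exactly the exchangeable case below), so that variant has no power.
* **Permutations fixing the focal pair are excluded from the null
  ensemble.** Such permutations reproduce the observed value identically;
  with n taxa they are 2(n−2)!/n! of all permutations (1/15 at n = 6), so
  including them bounds the attainable p at ≈ 0.067 and no 6-taxon screen
  could ever reach p ≤ 0.05. Excluding them restores the usual
  permutation-test resolution while keeping the +1-smoothed estimator.
  When the remaining ensemble is small (always below 4 taxa, or whenever
  n! ≤ N), it is enumerated exhaustively instead of sampled.

A per-pair label-permutation null is exactly calibrated only when pairs
are exchangeable — i.e. on a star-like species history. The default
simulation scenario therefore uses a six-tip star tree (a rapid
radiation) with equal tip branches; on resolved trees the per-pair
p-values inherit the tree structure and should be read as descriptive.
The calibration test draws one random focal pair per replicate, because
the 15 pair tests within a replicate share both matrices and are far from
independent; the binomial reference distribution is only valid at one
test per replicate. At 6 taxa the null flag rate at α = 0.05 is the
pair-orbit atom 1/15 ≈ 0.067 (p-values are granular in the orbit rank),
which lies inside the central 95% binomial band around 0.05 at 100–200
replicates.

## Synthetic data

`render_template` lays the features out deterministically (termini at the
ends, IR/SIR/microsatellite in the 5′ half, a GC-only 8 bp stem + 4 nt
loop hairpin ending 8 bp before the 3′ terminus) over random background of
configurable GC (default 0.40, an insect-like composition), and returns
exact feature coordinates. A GC-only stem guarantees the hairpin clears
the −3.0 kcal/mol reporting ceiling at zero divergence.

`plant_elements` inserts copies between the two bases of uniformly chosen
AT/TT dinucleotides of the *original* host (all sites chosen before any
insertion), so copies never nest within one another and coordinate truth
stays exact; flanks read …A|element|T… or …T|element|T…. Removing each
element at its truth coordinates reconstructs the host byte-exactly (the
no-TSD contract).

`evolve` applies the T92 process per site via the matrix exponential
(per-site gamma rate categories when configured); indels are **not**
simulated, keeping homologous columns exactly mapped. `simulate_scenario`
evolves one element lineage and one marker lineage down the species tree
at separate clocks (defaults 1.0 and 1.0 — no published clock ratio
exists, so equal clocks are the stated assumption); an HTT event (donor,
recipient, age) snapshots the donor lineage at `age` before the present
and evolves the copy independently in the recipient for the remaining
time. Default scenario sizes — 6 taxa, 300 bp element, 500 bp marker,
0.1 substitutions/site tip branches, 3 copies per 4 kb genome — keep every
simulation-based check comfortably inside interactive runtimes while
leaving the statistics well resolved.

What passing these tests shows: the scanner, annotator, distance/tree
machinery and screen recover exactly what was planted under a
substitution-only, indel-free, single-family model with clean element
boundaries. What they do not show: robustness to indels and tandem
expansions inside elements, nested insertions of other TEs, assembly
artefacts, or multi-family interference — real-genome performance on
those axes is untested by construction.

## Numerical and degenerate-input conventions

* All DP tie-breaks and NJ tie-breaks are deterministic and documented.
* `percent_identity` returns NaN (never raises) on an empty denominator;
  `complete_deletion` of an all-gapped alignment returns a 0-column
  alignment with a warning.
* Saturated distances are NaN and listed by `DistanceMatrixT.undefined_pairs`;
  `nj_tree` refuses them, `bootstrap_consensus` substitutes a finite
  ceiling per replicate (see above).
* Ambiguity codes (N etc.) are preserved end-to-end: they score as
  mismatches in scanning, never pair in hairpins, are skipped in distance
  site counts, and are treated as fully ambiguous states in the
  likelihood.
* Seeds: every stochastic routine takes a seed or Generator;
  `simulate_scenario` fans a single seed into per-operation streams by
  `SeedSequence.spawn` in a fixed order, so one integer reproduces a whole
  dataset byte-identically.

## Known limitations

* The hairpin model's absolute ΔG values are internally consistent but not
  comparable to full folding servers (no bulges, linear loop penalty).
* Karlin–Altschul parameters for *gapped* +2/−3 alignment are approximated
  by the ungapped-theory values; E-values are therefore conservative
  rankings rather than calibrated tail probabilities.
* The ML tree is approximated by NJ + NNI under the same model; for large
  families a dedicated ML package will search more thoroughly.
* Per-pair permutation p-values on resolved (non-star) species trees are
  descriptive, not exactly calibrated (see HTT screen above).
* An element interrupted by a nested insertion is recoverable only as two
  terminal-anchored partial hits; no joined "interrupted element" call is
  produced.
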