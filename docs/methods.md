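# Methods

## Model and assumptions

The pipeline treats drug repurposing as signature reversal constrained
to pathway topology. Its assumptions, in order of appearance:

* **Pathway union.** Pathways are signed directed edge lists over gene
  symbols; merging them is a plain node/edge union. When two pathways
  assert opposite signs for the same ordered pair, the edge is kept
  with sign +1 and the pair recorded in `conflict_edges`: scoring uses
  connectivity only, so the sign matters solely for reporting, and a
  logged conflict is more useful than a dropped edge. Gene identifiers
  are case-sensitive symbols; no alias mapping is attempted. Note the
  stored convention is +1 = activation, −1 = suppression; prose
  descriptions of such matrices sometimes enumerate the values in the
  opposite order, so the convention is stated here explicitly.
* **Shortest paths.** Drug–disease networks union the nodes of *all*
  minimum-hop paths per gene pair (a node v qualifies iff
  d(s,v) + d(v,t) = d(s,t)), eliminating tie-break nondeterminism.
  Traversal is undirected by default — subnetworks connect drug and
  disease genes without an obvious orientation — with a directed mode
  available. Unreachable pairs contribute only their endpoints, so
  every mapped drug and disease gene is always scored. Distances come
  from unweighted BFS (scipy.sparse.csgraph) cached as a full
  all-pairs matrix; this favours repeated queries on graphs up to a
  few thousand genes, the intended regime.
* **Candidate genes.** The aberration screen is a transparent G-score
  surrogate — frequency × mean |log-ratio| above an amplitude
  threshold (default 0.5, a single copy gain/loss on log2-ratio
  arrays) — with significance from the named two-sided Fisher's exact
  test rather than a full peak-finding pipeline (no segmentation or
  arm-level modelling). Amplification and deletion are pooled via the
  absolute log-ratio. Multiple testing uses Benjamini–Hochberg at
  α = 0.05 (raw-p mode via `adjust="none"`). Membership additionally
  requires the in-subtype aberration frequency to exceed the
  out-of-subtype frequency: a two-sided Fisher test also flags
  *depletion*, which is not a subtype aberration. Expression ranking
  discretises each gene into equal-frequency bins (default 3) and
  ranks by the Pearson chi-square statistic of the bins × subtype
  table — a deliberate simplification of iterative merge-based
  discretisation, since the statistic is used only to rank. The
  expression top-N uses per-subtype N = |aberration set|; ties break
  by statistic then gene symbol. One-vs-rest (e.g. triple-negative)
  analyses collapse labels to {subtype, rest} via
  `CohortMatrices.collapse_one_vs_rest`.
* **Disease signature.** z = (median_in − median_out) /
  (1.4826 × MAD_out), clipped to [−10, 10], with the denominator
  floored at 1e-6 × the gene's dynamic range. This is a documented
  stand-in chosen to be robust, sign-interpretable (positive = higher
  in the subtype) and bounded like the drug-side z-scores.
* **Condition selection.** Per drug: lowest and highest dose, 24 h
  preferred; if a chosen dose lacks 24 h, the drug's most frequent
  time point (smallest on ties) stands in as its default.
* **Scoring.** Pearson r over DDN genes present in both the profile
  and the signature; genes missing either value are dropped (no
  imputation). Scores with fewer than 3 genes or zero variance in
  either array are *undefined* and excluded from rankings rather than
  set to 0, to avoid fake neutrality. A gene that is both drug and
  disease gene is counted once (role "both"), making
  N = G_dr + G_di + G_i an upper bound.
* **Pairs.** Combined z is the plain sum on shared genes and is *not*
  re-clipped — additivity is the stated model. Pairs of two
  conditions of the same drug are excluded. k for combined profiles
  defaults to the same 50 as singles. Interaction filtering is
  post-verification: pairs are scored first and removed afterwards if
  listed at a blocked severity (default: minor, moderate and major all
  block), so an updated interaction table never forces a re-screen.
  Higher-order combinations are not enumerated (combinatorial cost);
  the additive machinery generalises if needed.

## Synthetic study conditions

The generators emulate input *structure*, not pharmacology: no
dose–response relationships, no correlated gene modules beyond the
planted signals, and no attempt to match real marginal distributions —
so passing tests demonstrate that the machinery recovers known planted
signal under realistic noise, not performance on real cohorts.

Defaults, chosen once as a plausible desk-scale study: a 200-gene
universe; 12 pathways of ~40 edges (covering most of the universe);
cohorts of 120 samples in 3 balanced subtypes; 12 driver genes planted
in the first subtype with a ±1.0 copy-number log-ratio shift (noise
sd 0.15 around 0) and a correlated ±8 sd expression shift — strong
subtype markers whose signature z-scores approach the ±10 clip, as
saturating markers do in bounded-z data; 5 decoy CNV genes with a
fixed ±1.0 aberration but *no* expression shift, listed in the
common-variant set together with 10 null genes. Drug libraries share
one measured gene universe (signature genes plus 20% extra genes
absent from the pathway graph, to exercise unmapped-gene handling);
background drugs are clipped Gaussian noise (sd 2.0), the planted
reversal drug is −signature + noise (sd 0.5), and the planted pair
splits the signature genes into two |z|-balanced halves, each member
reversing one half. Every drug is emitted at doses 0.04 and 10.0 μmol
and 24 h/6 h time points. All randomness flows from one seed;
identical parameters give byte-identical files.

Pair-screen experiments generate their library with
`plant_reversal=False`: "beats the best single drug" is relative to
the screened library, and a planted *perfect* reversal single would
make that comparison a coin flip against the planted pair by
construction. The single-drug screen uses 200 drugs; the pair screen
uses 40 (≈3.4k condition pairs), keeping the full 10-seed test battery
under a minute while leaving the planted-signal margins wide.

## Numerical choices

* All orderings (gene lists, rankings, pair enumeration) break ties
  lexicographically for determinism; rankings tie-break on profile key.
* Fisher p-values come from `scipy.stats.fisher_exact`; the test suite
  checks them to 1e-12 against an independent exact-Fraction
  hypergeometric enumeration for margins ≤ 30.
* Degenerate inputs are values, not crashes: a constant gene scores
  chi-square 0; an empty candidate set is returned with a warning;
  fully unmapped drug or disease genes yield a degenerate network
  whose score is undefined.
* Rankings operate on profile keys (one entry per condition); callers
  wanting one row per drug can collapse to each drug's best condition.

## Known limitations

* The G-score surrogate does not reproduce peak-based aberration
  callers on real array data; it is faithful to the
  frequency × amplitude + exact-test description, not to any specific
  implementation.
* The disease-signature formula is a principled stand-in; cohorts
  normalised differently upstream will shift absolute score values
  (rank orderings are less sensitive).
* The dense all-pairs distance cache trades memory for speed and is
  not suited to graphs far beyond ~10⁴ nodes.
* Probe-to-gene collapsing, real-data download/parsing (perturbation
  archives, cohort archives, pathway releases, variant catalogues,
  interaction services) and clinical interpretation are out of scope;
  file readers expect the gene-level TSV dialects documented in the
  module docstrings.
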