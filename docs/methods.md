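# Methods

## Model

A reaction `R` with substrate set `A` and product set `B` is first
aggregated into *units*: one per distinct compound and side, with
stoichiometric multiples folded into the unit weight (two L-isoleucine
molecules act as a single unit of twice the weight). An *element of the
Cartesian product* (ECP) is a pairing `(a, b)` of a non-empty subset of
the left units with a non-empty subset of the right units; the pairing
of both full sides is always excluded — for a mass-balanced equation it
would have `d = 0` and absorb everything.

The **balance rule** scores each ECP by the normalised weight
difference `d_ab = |W_a − W_b| / max(W_a, W_b) ∈ [0, 1]` and selects the
minimum. The **count rule** fires only when several ECPs tie at the
minimum within `tie_tol`: it selects the tied ECP with the highest
network-wide frequency, where the frequency index counts, per canonical
ECP key, in how many reactions that ECP occurs as a candidate. Keys are
side-agnostic sorted compound-id multisets, so `frequency(ATP→ADP) =
frequency(ADP→ATP)`, and each reaction contributes at most once per
key. Remaining frequency ties break on the lexicographically smallest
key, making construction fully deterministic.

Tree construction recurses on sub-problems in substrate/product
orientation:

1. one unit vs one unit → a pair tip (substrate printed first);
2. a single unit with the other side empty → a loner tip;
3. several units with the other side empty → the lightest unit peels
   off as a left loner (balance marker) and the rest recurses;
4. otherwise the selected ECP becomes the **right** child and the
   remainder the **left** child; a selected multi-compound ECP becomes
   its own sub-problem with its full pairing excluded again, so tips
   are always single pairs or loners.

Every compound of the reaction appears in exactly one tip; trees of
filtered (non-1:1) reactions have at least two tips.

## Serialization and clustering

RSF (reaction string format): `>` root, internal node `(marker child
child)` with `!` = balance and `!!` = count, pair tip `(Ca_Cb)`, loner
tip `(Ca_)` / `(_Ca)` by side. Pattern mode replaces ids with `C` and
drops loner side markers; the verbose `root(balance(...)(...))` form is
accepted on input, the compact form is canonical on output. Equal
patterns ⇔ identical topology and rule markers, so clustering is an
exact partition by pattern string, ranked by descending size with
lexicographic tie-break, ids `CTS-1, CTS-2, ...`.

## Validation

Pair tips are matched unordered against the reaction's curated
reactant-pair annotations; loner tips never match (water and similar
leftovers carry no pair annotation). Reactions are EPP (all pairs
matched), FP (none) or MP (mixed; pairs labelled MPP/MFP). Precision
for a scope with `y` hits out of `n` pairs is summarised by the
2.5%/97.5% quantiles of a beta posterior:

- `table` parameterization (default): `Beta(y, n − y)`. This is the
  form that reproduces published per-cluster interval tables digit for
  digit (for a cluster with 11 hits / 1 fail the quantiles equal the
  closed form `p^(1/11)` of Beta(11, 1)); it falls back to the `methods`
  form whenever a shape parameter would be zero.
- `methods` parameterization: `Beta(y + 1, n − y + 1)`, the standard
  uniform-prior binomial posterior with mean `(y + 1)/(n + 2)`.

The *interval average* is the arithmetic mean of the two quantiles (not
the posterior mean); it assigns clusters to high (≥ 0.8), medium
(≥ 0.6) and low bands. Per-cluster estimates are only emitted for
clusters with at least `min_reactions = 10` members that have predicted
pairs. The class crosstab counts pairs over annotation class ×
EPP/MPP/MFP/FP label × band; an unmatched pair borrows the class of any
same-reaction annotation sharing a compound, else `unknown`.

## Enrichment

At EC level `k ∈ {1,2,3}` a reaction contributes one assignment per
distinct EC prefix (ECs undefined at that level are skipped; reactions
without ECs are excluded). For each cluster with ≥ 10 assigned
reactions and each observed class, the 2×2 table (in/out of cluster ×
of/not of class) is tested with the two-sided Fisher exact test (sum of
hypergeometric probabilities not exceeding the observed table's);
p-values are BH-adjusted across all tests at the level. The odds ratio
is `(a/b)/(c/d)` with a +0.5 correction applied to all cells exactly
when some cell is zero; the log is natural by default (base 10
available). A record is flagged enriched when FDR < 0.05 and log odds
≥ 0.5.

## Synthetic benchmark

The generator emulates the structural features the rules exploit: a
heavy redox couple (weights ~663/665, Δ = 2.016) that barely changes, a
handful of pool species (water 18.015, phosphate 97.977, an NTP
analogue at 500.0 with an NDP partner at 420.0), and main compounds
drawn uniformly from 250–400 g/mol. Four templates cover the archetypal
tree shapes: `A + Cox <=> B + Cred` (two pairs), `A <=> B + H2O` (pair
+ loner), `A + H2O <=> B + Pi` (pair + two loners, nested), and
`NTP + A <=> NDP + B` with the product weight set exactly equal to the
NDP weight so the balance rule ties and the count rule must fire.
Products are derived by mass balance, so every synthetic reaction is
balanced to machine precision.

A **separation guarantee** is validated before generation: each
cofactor couple's relative weight difference must be strictly below the
smallest main-pair relative difference any template can produce
(`main_min_delta / max_main_weight`). Under that guarantee the
minimum-d selection provably recovers every planted pair, so 100%
recovery on the benchmark is a correctness check, not an empirical
accuracy claim. What the benchmark does *not* emulate: real chemical
formulas, unbalanced or ill-defined equations, glycan participants,
multi-step transferase chemistry, or annotation noise — passing it says
the machinery is sound, not that real-database precision would be high.
Default conditions: seed 42, 500 reactions, one cofactor couple, three
pool species, the four templates cycled round-robin.

## Numerical choices and defaults

- `tie_tol = 1e-9` (absolute, on the dimensionless d): formula-identical
  weights tie exactly regardless; the tolerance only guards float noise.
- Count-index subset size capped at 4 per side (bounds enumeration;
  larger ECPs are never frequent), tree-side enumeration guarded at
  2×10⁶ candidates.
- Compound weights: `MOL_WEIGHT` preferred, `EXACT_MASS` fallback;
  entries without a numeric weight are kept in the catalog but their
  reactions are dropped by the missing-weight filter.
- Dataset filters (defaults on): symbolic coefficients, glycan
  participants, one-compound-per-side reactions, missing weights; the
  mass-balance filter is off by default with a 1% relative tolerance.
- Equations are taken as written (left = substrates); reversibility is
  ignored.
- Reactions without EC numbers are kept for tree building and excluded
  only from enrichment.
- Reference weights of the bundled examples are computed from chemical
  formulas with conventional IUPAC atomic weights, so ADP and dGDP
  (same formula) tie exactly.

## Design decisions taken where the design was open

- Recursion into selected multi-compound ECPs (required for tips to be
  only pairs and loners, and for the nested hydrolysis shape).
- Whole-pairing exclusion is re-applied inside recursive sub-problems
  (otherwise a balanced selection would trivially re-select itself).
- One-sided remainders peel the lightest unit first; any fixed order
  works, lightest-first keeps heavy cores together longest.
- The `table` beta parameterization is the default because it is the
  one that reproduces published interval tables; the textbook
  uniform-prior form is kept behind a flag.
- Cluster ties at equal size break lexicographically by pattern.
- CLI exit codes follow click conventions (0 success, 2 usage error,
  1 data/runtime error).

## Problem sizes used in the checks

The test suite and the acceptance script run the bundled six-reaction
fixture set, a 500-reaction benchmark for recovery/validation/output
shapes, a 1000-reaction benchmark for tip-coverage and optimality
scans, exhaustive Fisher enumeration for all 2×2 tables with N ≤ 14
plus a seeded sample up to N = 40, and a few hundred property-test
cases each for round trips and interval bracketing. Everything
completes in well under a minute on one CPU.

## Known limitations

- Weights are the only chemical signal: reactions whose true pair has a
  large weight change (hexosyl/pentosyl transfer, multi-step group
  transfer) can be split against the curated mapping.
- The count index is corpus-dependent: frequencies computed on a small
  reaction set can be too flat to resolve ties meaningfully.
- Symbolic stoichiometry (`n`, `n+1`) is rejected rather than modelled.
- The Fisher test treats EC assignments as independent; reactions with
  several ECs of one class still count once per class.
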