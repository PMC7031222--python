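# Methods

## Problem and model

The package ranks candidate compounds for repositioning by matching a panel
of transcriptional signatures — here, per-timepoint contrasts of an injury /
regeneration time course — against a database of drug-perturbation
expression profiles (a Connectivity-Map-style resource: treatment
*instances* of compound × cell line, each summarised as a complete ranking
of `n` genes, rank 1 = most up-regulated).

The scoring statistic throughout is the **rank product**. For `k` query
genes at ranks `r_1..r_k` inside a ranked list of `n` genes,

    RP = r_1 · r_2 · … · r_k.

Under the null model the ranks are i.i.d. uniform on `{1..n}`
(*with-replacement* null). This model admits exact tail evaluation by
lattice-point counting:

    P(RP ≤ x) = T(k, n, x) / n^k,
    T(k, n, x) = #{ (r_1..r_k) ∈ {1..n}^k : Π r_i ≤ x }.

The with-replacement null is the standard choice in the rank-product
literature; the true sampling model (ranks drawn without replacement from a
permutation) differs at order `k²/n`, negligible for the signature sizes and
universes used here. The without-replacement distribution is retained only
as a brute-force oracle in tests at tiny `n`.

### Exact counting

`T` is evaluated with exact integer arithmetic by the recursion

    T(k, x) = Σ_{r=1}^{min(n,x)} T(k−1, ⌊x/r⌋),   T(0, x) = [x ≥ 1],

memoized on the distinct values of `⌊x/d⌋` and with runs of `r` sharing a
quotient taken in blocks. Three implementation tiers keep this fast:

* closed forms for `k ≤ 1`; compiled (numba) blocking loops for `k = 2, 3`;
* a compiled bottom-up "quotient ladder" for `k ≥ 4`: the reachable
  arguments are exactly the distinct values of `⌊x/d⌋` (about `2√x` of
  them, closed under further division), tabulated level by level in two
  int64 arrays;
* an arbitrary-precision recursive fallback whenever int64 could overflow.
  Safety is decided a priori from the rigorous bound
  `D_j(v) ≤ v·(1 + ln v)^(j−1)` on intermediate counts.

The final p-value is formed as an exact rational `T/n^k` and converted to a
float once. Cost is governed by `√min(x, n^k)`, so exactness is cheap
precisely in the decision-relevant left tail and infeasible in the bulk of
the distribution for large `k`.

### Gamma tail approximation and dispatch

For instances outside the exact-feasible region the continuous
approximation is used: with `U_i = r_i/n` uniform on (0,1],
`s = Σ ln(n/r_i)` is Gamma(k, 1), giving `p ≈ Q(k, s)` (regularized upper
incomplete gamma). A `(r_i − 0.5)/n` midpoint variant is available behind a
flag but is not the default.

`method="auto"` (the default everywhere) chooses the exact count when the
a-priori state estimate `2·√min(x, n^k)·k` stays below the budget
(default `10^7`), else the gamma tail; results record `method_used`.

**Accuracy regime, stated plainly.** The gamma tail is excellent in the
bulk (relative error `< 10^-2` at rank fractions `r/n ≳ 0.1` for small
`k`), but its *relative* error grows without bound in the far tail: its
leading term is `(x/n^k)·s^(k−1)/(k−1)!` whereas the true discrete count
follows the Piltz divisor asymptotics `x·(ln x)^(k−1)/(k−1)!/n^k`, and
`s = ln(n^k/x) ≫ ln x` deep in the tail. At `k = 5`, `n = 10⁴`,
ranks (3, 17, 41, 200, 995) the exact p is 2.0955e-08 while the gamma tail
gives 9.578e-08 — a 4.6-fold overestimate (conservative, never
anti-conservative in the tail). Two consequences matter for the pipeline:

1. within one signature (fixed `k`, `n`), the gamma p is a strictly
   monotone transform of the rank product, so compound *rankings* are
   identical under either method;
2. far-tail p-values that drive final calls are computed exactly whenever
   the auto-budget admits them, which is exactly where the exact count is
   cheapest.

## Connectivity scoring

Conventions: rank 1 = most up-regulated; the reflected rank
`r̃ = n + 1 − r` expresses down-regulation. A signature's positive match
against an instance pools `{r(g) : g ∈ up}` with `{r̃(g) : g ∈ down}` into
one rank list (`k = k_up + k_down`) and takes its rank-product tail; the
negative match swaps the roles. Pooling keeps the whole score inside the
exact rank-product framework; combining the two sub-signatures as separate
tails via Fisher's method is available as a non-default switch. An empty
direction simply reduces `k`. Ranks are sorted canonically before the
log-sum so that `p_pos(sig, profile)` and `p_neg(sig, reversed profile)`
are bit-identical, not merely equal in exact arithmetic.

Instances of one compound are combined per signature with Fisher's method
(`−2 Σ ln p ~ χ²_{2m}`), treating instances as independent — the simplest
defensible choice where no aggregation scheme is prescribed by the source
material. Per-cell-line stratified aggregation is available as an option.

## Integration across the panel

For each signature the `m` compounds are ranked by the direction's
aggregated p (ties broken by compound id). A compound's meta rank product
is `Π_s ρ_s` over the `S` signatures, and its integrated p-value reuses the
same exact machinery at the meta level (`n → m`, `k → S`). Positive and
negative lists are computed independently and BH-adjusted separately
(step-up with running-minimum, via statsmodels). The final list is sorted
by integrated p, then meta statistic, then compound id — fully
deterministic. Fisher combination of the per-signature p-values is a
configurable alternative integration.

## Signature derivation and translation

Signature extraction replaces any expert curation with explicit,
reproducible thresholds: up = `log2FC ≥ lfc_min` and `p_adj ≤ q_max`
(down mirrored), with defaults `lfc_min = 1.0`, `q_max = 0.05`,
`min_size = 10`, `max_size = 500` — chosen so signatures land in the
few-dozen-to-hundreds range typical of connectivity queries. Oversized
signatures keep the largest-|log2FC| genes (ties by gene id).

Cross-species translation applies an ortholog map under a one-to-many
policy (default `expand`; `drop_ambiguous` and `first` selectable). A
target gene reached from both directions is removed from both: direction is
the signal, ambiguity is noise. Gene matching is exact and case-sensitive.

## Synthetic data

The generator emulates a desk-scale screen: a 2000-gene universe, 100
compounds × 2 instances, a 3-signature panel of 40 genes each (20 up / 20
down) — the default study conditions for calibration and power checks. It
produces per-timepoint DE tables (planted differential genes with
`|log2FC| ≥ lfc_effect`, `p_adj < 0.05` over small-noise background), an
ortholog map with controllable one-to-many and unmapped fractions, and
ranked profile matrices.

Non-planted instances are uniform random permutations. Planting works
directly in rank space: a fraction φ of the panel's up genes gets its rank
redrawn as `max(1, ⌈u(1−δ)n⌉)` and down genes mirrored toward `n`
(negative planting swaps sides); collisions bump to the nearest free rank
and all remaining genes backfill in random order, so every column remains a
permutation. `δ = 0` is byte-identical to the null; `δ = 1, φ = 1` pins
affected genes to the extreme ranks. Genes with conflicting directions
across panel signatures are left at the null. One global seed fans out to
per-component streams by stable hashing of `(seed, component)`.

What the generator does **not** model: microarray/RNA-seq noise structure,
cell-line covariance between instances, batch effects, correlated gene
modules, or dose–response ordering. Passing calibration and recovery tests
therefore demonstrates the statistical machinery under its stated null and
a controllable alternative — not performance on real perturbation data.

## Numerical choices

* p-values are clamped into `(0, 1]`; the lower clamp is the smallest
  positive double (only reachable through extreme gamma underflow).
* All tie-breaks (rank ties, compound ties, signature order) are
  lexicographic, for bitwise reproducibility of every output file.
* Exact p-values are exact rationals converted to float once; min/max
  statistics therefore hit `n^-k` and `1` exactly.
* The auto-dispatch budget counts memoization states, not seconds; the
  default `10^7` keeps a single exact evaluation under a few seconds.

## Problem sizes used in the checks

Exhaustive-enumeration oracles run at `k ≤ 3, n ≤ 12` (every achievable
threshold) and spot-check the compiled ladder at `k = 4, 5`. Gamma–exact
agreement is checked on uniform rank draws at `n = 10⁴` for `k ∈ {2, 3}`,
where the exact count covers the full product range; for `k ≥ 4` the
exact-feasible and gamma-accurate regimes no longer overlap (see the
accuracy discussion above), which is a property of the approximation, not
of the implementation. Calibration and recovery studies use 20 null and 50
planted replicates of the default screen. These sizes are the package's
chosen study conditions; all are regenerated from seeds at test time.

## Known limitations

* The with-replacement null slightly overweights tied ranks; exactness is
  relative to that null, not to permutation sampling.
* Fisher aggregation assumes instance independence; replicate instances of
  one compound in the same cell line violate this mildly.
* The gamma fallback is conservative in the far tail; integrated p-values
  that had to fall back can overstate (never understate) the evidence
  threshold needed.
* Real ortholog maps are many-to-many with paralog structure richer than
  the simulated fractions.
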