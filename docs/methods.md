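# Methods

## The inference problem

A crime stain has profile `G_c`.  The population of potential sources
is closed and of known size `N`; person `i` is the source with prior
probability `π_i` (uniform `1/N` unless stated otherwise).  Persons
1..n have their profiles in a database; person 1 is the suspect, found
because his profile corresponds to the stain.  The random match
probability `γ` is the chance that a person *other than the true
source* exhibits the profile, assumed identical and independent across
individuals.

Standing assumptions, shared by all models in the package:

* profiling is perfectly accurate — no typing or clerical error, so
  the true source matches with certainty;
* individuals are unrelated, so match events are independent given the
  source;
* the population is closed: exactly one of the `N` people is the source;
* `γ` is known, not estimated; no subpopulation (θ) correction.

Evidence comes in two pieces: `M1`, the suspect's profile corresponds;
and `X2 & … & Xn`, none of the other n−1 database members' profiles
corresponds.

## The three networks

All networks are discrete, tiny, and queried by exact enumeration of
the joint distribution (see *Numerical choices*).

**Island network** (no database).  `H ∈ {H1, not-H1}` with prior
`(π₁, 1−π₁)`; child `M1 ∈ {match, no-match}` with
`P(match | H1) = 1`, `P(match | not-H1) = γ`.  Conditioning on the
match gives

```
π₁′ = π₁ / (π₁ + γ(1−π₁)).
```

**Two-member database network** (n = 2).  `H ∈ {H1, H2, H3_N}` with
prior `(π₁, π₂, Σ_{i>2} π_i)`; `X2 ∈ {no-match, match}` with
`P(no-match | H2) = 0` and `1−γ` otherwise; `M1` as above with `γ`
under both alternatives.  The `no-match` state is listed first because
the exclusion variable is *defined* as non-correspondence.

**General database network** (any 1 ≤ n ≤ N).  `H ∈ {H1, H2_n,
Hn+1_N}` with prior `(π₁, Σ₂..ₙ π_i, Σₙ₊₁..N π_i)`.  The n−1 individual
exclusions are aggregated into one node `X2..Xn ∈ {no-match-all,
some-match}` with

```
P(no-match-all | H1) = P(no-match-all | Hn+1_N) = (1−γ)^(n−1),
P(no-match-all | H2_n) = 0,
```

since under `H2_n` the true source sits inside the database and
matches with certainty.  For n = 1 the conjunction is empty and the
node is vacuous (probability 1 in every column).  `M1` is as in the
island model.  Aggregation is exact: the individual-level oracle model
(below) reproduces the grouped posteriors to 1e-12.

An optional **summary node** `H1 ∈ {H1, not-H1}` is a deterministic
child of `H` collapsing the three-way proposition to "suspect is / is
not the source".  Conditioning on `not-H1` redistributes mass
proportionally over `H2_n` and `Hn+1_N` — the network reading of the
likelihood-ratio denominator.

Conditioning on both pieces of evidence gives the posterior

```
π₁′ = π₁ / (π₁ + γ Σ_{i=n+1..N} π_i),
```

the `(1−γ)^(n−1)` factor cancelling between numerator and denominator.
Conditioning on the exclusions alone renormalizes the prior over the
survivors, `π₁* = π₁ / (π₁ + Σ_{i>n} π_i)` — with uniform priors,
`1/(N−n+1)`.  The likelihood ratio attached to the exclusion evidence
is

```
LR_DB = (1−γ)^(n−1) / [(1−γ)^(n−1) · Σ_{i>n} π_i / Σ_{i>1} π_i]
      = (N−1)/(N−n)   (uniform priors),
```

independent of γ, equal to 1 for n = 1, unbounded for n = N.

## Parameters

| parameter | meaning | domain | default |
|---|---|---|---|
| `N` | population of potential sources | integer ≥ 1 | required |
| `n` | database size, suspect included | 1 ≤ n ≤ N | 1 |
| `gamma` | random match probability | [0, 1] | required |
| `priors` | `π_i`, i = 1..N | non-negative, sums to 1 | uniform 1/N |

Non-uniform priors are aggregated as `π₁`, `Σ₂..ₙ`, `Σₙ₊₁..N` for the
three `H` states; the exclusion-only posterior then renormalizes over
the surviving individuals rather than using the `1/(N−n+1)` shortcut.

Root values `N`, `n`, `γ` are folded into the CPTs by default.  With
`explicit_roots=True` the builders instead materialize them as
discrete root nodes carrying a small menu of illustrative values with
all prior mass on the scenario's own value; both representations give
identical posteriors (tested to 1e-12).  The menu exists because every
node is required to have at least two states, which keeps validation
uniform across builders.

## The individual-level oracle

`dbsearch.oracle` models each of the N persons as a distinct source
hypothesis and enumerates the match outcome of each profiled
individual explicitly: a table of N·2ⁿ rows with probability
`π_i · Π_j P(match_j | source=i)`, where `P(match_j | source=j) = 1`
and `γ` otherwise.  Outcomes of unprofiled individuals are never
observed and marginalize out exactly, so they are not enumerated.  Any
posterior is a ratio of row sums; summing indices {1}, {2..n},
{n+1..N} reproduces the grouped network.  A cap (default N, n ≤ 12)
guards against accidental exponential blow-up and can be raised
explicitly.

## Scenario fixtures

`generate_fixtures(seed, count)` draws scenarios with N uniform on
2..12, n uniform on 1..N, γ from {0.5, 0.1, 0.01, 0.001}, and a
Dirichlet(1,…,1) prior vector on roughly a quarter of the draws.  The
ranges keep every fixture within the oracle's reach so that all three
computation routes can be compared exactly; γ values span the rare-
profile regime of interest and the strong-adventitious-match regime
where disagreements between routes would be most visible.  These are
synthetic parameter sets, not data: passing the equivalence suite
shows the implementations agree with each other and with the algebra,
not that any particular γ or prior describes a real population or a
real database's error processes.

## Numerical choices

* **Inference is exact enumeration.**  The networks have at most six
  nodes with two or three states, so the joint is summed directly;
  zero-probability branches are pruned.  No approximate or message-
  passing algorithm is involved.
* **Tolerances.**  CPT columns and reported distributions must be
  normalized to 1e-9; agreement between computation routes (formula vs
  network vs oracle) is asserted at 1e-12; the CLI's dual-path audit
  refuses to report when the routes differ by more than 1e-9.
* **Rounding** happens only at the presentation layer (4–6 decimals,
  Python's round-half-even); all internal math is double precision.
* **Degenerate states are kept, not dropped.**  For n = N the
  `Hn+1_N` state keeps prior 0 so CPT shapes are scenario-independent;
  CPT rows reachable only under zero-prior parents are filled with a
  uniform vector so validation never depends on the priors.
* **Impossible evidence raises**, carrying the conflicting
  assignments; a zero-probability evidence set is never silently
  renormalized.
* **Unbounded likelihood ratio.**  At n = N the denominator is 0; the
  report flags `finite=False` with an infinite ratio instead of
  raising, since total exclusion of the alternatives is a meaningful
  limiting case, not an error.  (For N = n = 1 the "not the suspect"
  proposition has prior zero and the same flag applies.)
* **Evidence marginals of zero** make conditional predictive queries
  undefined; these raise rather than return NaN.

## Limitations

* No laboratory or clerical error: a reported non-match is a true
  exclusion.  Real casework must fold in typing-error probabilities
  before these numbers apply.
* No relatedness or population substructure; γ is a single exchangeable
  match probability.
* The closed-population assumption does the heavy lifting in
  `LR_DB = (N−1)/(N−n)`; when N is itself uncertain the ratio is too.
* Priors are assumed unaffected by *how* the suspect entered the
  database; search-dependent priors are out of scope.
* The oracle's cost is N·2ⁿ; it is a verification instrument for small
  scenarios, not a production path (the grouped network is exact at
  any size).
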