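# dbsearch

**Bayesian evaluation of forensic database-search evidence.**

When a suspect is found by trawling a DNA database rather than by
independent investigation, how strong is the resulting "hit"?  This
package answers that question quantitatively for the idealized but
canonical setting: a closed population of `N` potential sources, a
database holding the profiles of `n` of them (person 1, the suspect,
plus persons 2..n), and a random match probability `γ` — the chance
that someone other than the true source exhibits the crime-stain
profile.  It is written for forensic statisticians, legal scholars and
teachers who want the numbers *and* a transparent model behind them.

Every quantity is computed twice, by two independent routes that must
agree to 1e-9 before a report is produced:

1. **Bayesian networks** — tiny discrete networks (source proposition
   `H`, the suspect's match `M1`, the aggregated exclusions `X2..Xn`,
   an optional binary summary node) with exact inference by full
   enumeration;
2. **closed forms** — the equivalent algebra, e.g. the posterior after
   the suspect's match and the exclusion of the other n−1 database
   members,

   ```
   π₁′ = π₁ / (π₁ + γ · Σᵢ₌ₙ₊₁..N πᵢ)
   ```

   and the database-search likelihood ratio for the exclusion evidence,

   ```
   LR_DB = P(X₂&…&Xₙ | H₁) / P(X₂&…&Xₙ | H̄₁) = (N−1)/(N−n)
   ```

   which is independent of γ, equals 1 for n = 1 and is unbounded when
   the database covers the whole population (n = N).

A third, individual-level brute-force model (every person a separate
hypothesis, every profiled individual's match outcome enumerated
explicitly) serves as an oracle that validates both routes on small
scenarios.

The central — and famously counter-intuitive — result these models
make tangible: *a database search strengthens the case against a
matching suspect*, because every other database member who fails to
match is eliminated as an alternative source.

## Worked example

A population of 1,000, a database of 100 profiles, a profile frequency
of 1%.  The suspect matches; the other 99 database members do not:

```
$ dbsearch --mode db --N 1000 --n 100 --gamma 0.01
posterior_suspect.formula                     0.1
posterior_suspect.network                     0.1
network_posterior.H1                          0.1
network_posterior.H2_n                        0
network_posterior.Hn+1_N                      0.9
```

The suspect's posterior rises from the prior 1/1000 to 0.1; the other
database members are certainly excluded (`H2_n = 0`); the remaining
0.9 sits on the 900 unprofiled people.  The weight of the exclusion
evidence alone:

```
$ dbsearch --mode lr --N 1000 --n 100 --gamma 0.01
likelihood_ratio.numerator.formula            0.36973
likelihood_ratio.denominator.formula          0.33309
likelihood_ratio.ratio.formula                1.11
```

The numerator is (1−γ)⁹⁹ = 0.3697, the probability that all 99 others
are excluded if the suspect is the source; the denominator, 0.3331, is
the same probability if he is not; their ratio (N−1)/(N−n) = 999/900 =
1.11 favours the suspect — modestly here, but it grows without bound
as the database approaches the whole population.

Smaller textbook cases (`--mode island --N 100 --gamma 0.01` → posterior
0.5025; `--mode db --N 100 --n 2` → 0.5051) print the same way, and
`--percent` displays probabilities as percentages.  The library API
mirrors the CLI: `Scenario`, `build_island_network`,
`build_general_db_network`, `infer_posterior`, `db_likelihood_ratio`,
etc. — see `docs/methods.md` for the model details.

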