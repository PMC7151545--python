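# Methods

## Model and assumptions

We consider `n = (1/2) f g` functional diploid sites in a genome of `g` base
pairs with functional fraction `f` (the 1/2 because a diploid site spans two
homologous base pairs). At each site a wild-type allele A mutates to a
deleterious allele M at rate `u` per generation; back mutation is neglected,
as are all terms of order `u^2` relative to the leading terms. The mutant
homozygote's fitness is reduced by `1 - s`; the heterozygote by `1 - s/2`
(additive scheme), `1` (recessive), or `1 - hs` (general dominance `h`).
Every site shares the same `u` and `s`, fitness is multiplicative across
sites, and sites are in linkage equilibrium, so an individual's genome is
summarized by the counts `(x, y, z)` of wild-type homozygous, heterozygous,
and mutant homozygous sites, jointly multinomial over `n`.

Per-site fitnesses are normalized so that mean per-site fitness is exactly 1
(a long-run constant-population-size assumption). The balance allele
frequency of M is `2u/s` (additive), `sqrt(u/s)` (recessive), or `u/(hs)`
(partial dominance); genotype frequencies are Hardy-Weinberg in that
frequency, stored in their truncated forms (e.g. additive MM frequency
`(2u/s)^2`) because the downstream closed forms rely on exactly these
expressions. The recessive scheme is a separate code path, not the `h -> 0`
limit: `u/(hs)` diverges there while the true recessive equilibrium is
`sqrt(u/s)`.

## Parameters

| symbol | meaning | default | note |
|---|---|---|---|
| `g` | diploid genome size (bp) | `6.4e9` | recent human estimate |
| `f` | functional fraction | `0.05` | the quantity under study; 0.05 is the running example used for worked numbers |
| `v` | per-base mutation rate | `1.2e-8` | empirical human rate |
| `p` | P(mutation deleterious) | `0.4` | |
| `u` | deleterious rate per site | `5e-9` | canonical rounded value; `v*p` (=4.8e-9) is derived only when `v` or `p` is overridden without `u`, because every headline number assumes the rounded rate |
| `s` | selection coefficient | `1e-2` | human estimates span `1e-4`–`1e-1`; results are reported over that range |
| `h` | dominance coefficient | `0.5` | 0.5 = additive |
| `N` | reproducing population size | `1e9` | deliberately conservative (large) |

`n` is kept as a real number; only the population sampler rounds it to an
integer. The product `nus` is the central quantity: it is the variance of
log fitness at equilibrium.

## Distribution of whole-genome fitness

With the multinomial genotype counts, `E[W] = 1` exactly (additive and
recessive) and the exact variance is
`mean(W)^2 * [(1 + v1/m1^2)^n - 1]` with `m1`, `v1` the per-site mean and
variance of raw fitness. Ignoring `u^2` terms this is `e^(nus) - 1`
(`e^(2nuhs) - 1` under dominance `h`). Since `log W` is a sum of `n` i.i.d.
per-site terms, it is asymptotically normal; matching the mean 1 and the
variance of `W` gives `sigma^2 = nus`, `mu = -nus/2`. A discrete spectrum of
mutation classes `(u_i, s_i)` generalizes `nus` to `n * sum_i u_i s_i`,
i.e. an effective selection coefficient `s_bar = sum u_i s_i / sum u_i`.

Central-range probabilities (e.g. `P(0.5 < W < 2)`, which is 97% at a
per-genome deleterious rate `nu = 10` with `s = 0.01`) are evaluated from
the normal CDF of `log W`. Probabilities are returned as probabilities;
percent formatting is a display concern.

## Extreme fitness

The per-individual count of heterozygous sites (additive; mean `m = 4nu/s`)
or mutant homozygous sites (recessive; mean `k = nu/s`) is Poisson to order
`u^2`; mutant homozygotes are ignored in the additive extreme calculation
because their expected count `n(2u/s)^2` is order `u^2`. By the normal
approximation to the Poisson, the least-burdened of `N` individuals sits
about `r = c*sqrt(mean)` counts below the mean. The working multiplier is
`c = 5` for `N = 1e9` — deliberately conservative, since the exact normal
quantile at `1 - 1/N` is ≈ 6.0 (`extreme_multiplier(N, mode="quantile")`
exposes the quantile as an extension, and the desk-scale simulation check
uses it). The resulting fitness is returned in two forms:

- exact product, e.g. additive `(1-2u)^-n (1-s/2)^(m-r)`, evaluated in log
  space;
- asymptote `e^(c*sqrt(nus))` (identical for additive and recessive;
  `e^(c*sqrt(2nuhs))` under dominance).

The asymptote drops terms of relative size ~`r*s` (from `log(1-s/2)` vs
`-s/2`), so the two agree to ~1% at the canonical working point
(`f = 0.05`, `s = 0.01`) and for all `f` at `s <= 1e-3`, but the asymptote
overestimates by up to several percent in the `s = 0.01`, `f >= 0.25`
corner (7% at `f = 1`). The reference grid reports the asymptotic form, as
published.

The idealized optimum — wild-type at every site — has fitness
`(1-2u)^-n ≈ e^(2nu)` (additive; `(1-u)^-n ≈ e^(nu)` recessive), tens of
standard deviations above the mean; the log probability that such an
individual exists is reported instead of the underflowing probability. The
Crow load `L = (w_max - w̄)/w_max` is parameterized by *which* maximum it
uses — the contrast between the two choices is the package's central point —
while the Haldane load `1 - e^(-2nu)` always refers to the idealized
optimum.

Known published-value discrepancy: the reference grid's idealized cell at
`f = 0.10` is printed as 24.45 in the source table, but the stated formula
gives `e^3.2 = 24.53`; we compute the formula.

## Population sampler

Individuals are i.i.d. draws of `(y, z)` — heterozygous and mutant
homozygous site counts — from the equilibrium frequencies; no per-site
genome is represented (under linkage equilibrium the counts are sufficient,
and `n ~ 1e8` sites per individual is tractable only this way, which also
means per-site features such as linkage or site-specific `s` are outside
the sampler's scope). The default draws `y` and `z` as independent Poissons
with means `n*p_AM` and `n*p_MM` (valid since both frequencies are ≪ 1, and
the same approximation the analytic argument makes); exact multinomial
sampling is available for `n <= 1e6` as a cross-check. Mutant homozygotes
are simulated even where the analytic extreme calculation neglects them, so
the simulation independently validates that neglect. Fitness is assembled
in log space and exponentiated.

Randomness: one root seed; substreams are derived by counter through
`numpy.random.SeedSequence` feeding PCG64, so every sample is reproducible
bit-for-bit for a given (params, M, seed, method).

What passing the simulation checks shows: the lognormal and extreme-value
approximations are self-consistent with the equilibrium model at the stated
parameters. What it does not show: anything about real genomes — the
sampler inherits every idealization above (no linkage, shared `u` and `s`,
equilibrium, no drift, no offspring-number stochasticity).

Simulation problem sizes: moment and normality checks use `M = 1e5` and
`M = 1e4` individuals; the empirical-maximum check uses 50 replicates of
`N' = 1e6` individuals with `c = Phi^-1(1 - 1/N')`, declaring agreement
when the analytic product form lies within the interquartile range of the
replicate maxima. Histograms use 200 fixed-width bins on
`[0, max(3, 1.2 * e^(5*sqrt(nus)))]` so TSV outputs are comparable across
runs; the simulated-distribution figure uses `f = 0.25` with
`s ∈ {1e-4, 1e-3, 1e-2}`.

## Numerical choices

- Everything that would overflow/underflow (`(1-2u)^-n`, `e^-320`, …) is
  computed via `log1p`/`expm1` accumulation; probabilities of
  nonexistence are *returned* as natural logs.
- The exact per-site mean excess over the normalizer is evaluated from
  closed forms (`0` additive/recessive; `(2 - 1/h) u^2/(hs)` under
  dominance, verified symbolically in the tests) rather than by summing
  O(1) genotype terms: floating-point cancellation noise (~1e-16) would be
  amplified `n`-fold downstream.
- Reference-grid formatting: two decimals below `1e3`, two-significant-digit
  scientific notation above, matching the published mixed style.
- `table1_grid` values are strictly increasing along both axes; degenerate
  inputs (`u = 0`: no variance, extreme fitness 1, z-score undefined and
  raised as an error) are handled explicitly.

## Scope and limitations

Out of scope by design: finite-`N` stochastic corrections to the mean
mutant-homozygote count, offspring-number stochasticity, substitutional and
segregational loads, linkage and epistasis, demography and non-random
mating, and any estimation of `f`, `v`, `p` or `s` from data. The
general-dominance scheme requires `h > 0`; `h = 0` is directed to the
recessive scheme.
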