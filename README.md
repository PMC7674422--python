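# cladecal

Fossil-based clade-age calibration densities and Bayesian node dating on
fixed tree topologies, for molecular-clock studies that calibrate against
the fossil record — including clades whose *first* fossil record is
ambiguous because two candidate fossils compete for that status.

## The problem and the model

Divergence-time estimation needs prior densities for the ages of calibrated
clades. Instead of hand-picked lognormal or uniform distributions, the
CladeAge framework derives the prior from the fossilization process itself:
given a clade's oldest fossil and estimates of the net diversification rate
*d* = λ − μ, the turnover ε = μ/λ, and the fossil sampling rate ψ (per
lineage per Myr), the probability density that the clade originated *t*
time units before its first record is

    f(t) = E[ ψ N e^(−ψ S(t)) | N ≥ 1 ]

where *N* is the number of species of the clade extant at the time of
fossilization, *S(t)* is the summed duration of all the clade's lineages
between clade origin and fossilization, and the expectation runs over
birth–death lineage histories conditioned on the clade having survived to
the fossilization time. `cladecal` evaluates this expectation by exact
(Gillespie) Monte-Carlo simulation, marginalizing uniform stratigraphic age
intervals and rate ranges inside the simulation loop.

When two fossils with ages t_younger < t_older are both plausible first
records, with assignment probabilities p_younger + p_older = 1, the
calibration density becomes the weighted mixture

    f(t) = p_younger f_younger(t)                      t < t_older
    f(t) = p_younger f_younger(t) + p_older f_older(t) t ≥ t_older

which is unimodal or bimodal depending on the fossils' separation. A
Metropolis–Hastings sampler then dates internal nodes on a fixed rooted
topology under the birth–death node-age prior times these calibration
densities, optionally with a strict-clock GTR+Γ sequence likelihood
(Felsenstein pruning). A deterministic filter cascade for phylogenomic
marker selection (bitscore / dN/dS / missing-data / entropy / GC /
gene-structure rules over precomputed metric tables) rounds out the
pipeline, with per-step audit reports.

## Worked example

The teleost order Tetraodontiformes has two candidate first records:
†*Cretatriacanthus guidottii* (89.8–83.0 Ma) and †*Plectocretacicus clarae*
(100.3–98.0 Ma), with twice the weight on the younger fossil's assignment:

```python
import numpy as np
import cladecal as cc

bd = cc.BDParams(
    net_diversification=(0.041, 0.081),   # per lineage per Myr
    turnover=(0.0011, 0.37),
    sampling_rate=(0.0066, 0.01806),
)
younger = cc.FossilRecord("Cretatriacanthus", 83.0, 89.8, weight=2/3)
older = cc.FossilRecord("Plectocretacicus", 98.0, 100.3, weight=1/3)
density = cc.mixture_calibration_density(younger, older, bd,
                                         n_reps=100_000, seed=1)
print(f"support: {density.support[0]:.1f}-{density.support[1]:.1f} Ma")
print(f"integral: {np.trapezoid(density.density_values, density.age_grid):.3f}")
print(f"mean clade age: {density.mean():.1f} Ma")
print(f"95% interval: {density.quantile(0.025):.1f}-{density.quantile(0.975):.1f} Ma")
print(f"modes: {[round(m, 1) for m in density.modes()]}")
```

prints

```
support: 83.0-288.4 Ma
integral: 1.000
mean clade age: 118.9 Ma
95% interval: 89.0-167.0 Ma
modes: [110.4]
```

The density is zero below the younger fossil's minimum age (a clade cannot
be younger than its own fossil), integrates to 1, and places the clade's
origin most plausibly ~20 Myr before the older candidate record; with these
rate ranges and fossil ages the two mixture components merge into a single
mode. The same density object plugs directly into the sampler
(`cc.sample_prior` / `cc.sample_posterior`) as a node calibration, and can
be exported as a two-column TSV via `cladecal.io.write_density_tsv`.

A command-line surface wraps the same functions:

```sh
cladecal density --constraints clades.yaml --clade Tetraodontiformes --out dens.tsv
cladecal sample-prior --tree fixed.nwk --constraints clades.yaml --out trace.tsv
cladecal date --tree fixed.nwk --alignment markers.fasta --constraints clades.yaml --out trace.tsv
cladecal filter-markers --exon-table exons.tsv --out filtered.tsv
cladecal validate-bimodality --out report.tsv
```

## Layout

- `cladecal.bd_process` — birth–death simulation with fossil-sampling
  bookkeeping; node-age prior on fixed topologies
- `cladecal.calibration` — single-fossil and two-fossil mixture calibration
  densities with evaluate/CDF/quantile/sample contracts
- `cladecal.dating_mcmc` — Metropolis–Hastings node dating, ESS and HPD
  trace summaries
- `cladecal.seq_likelihood` — strict-clock GTR+Γ pruning likelihood and
  alignment simulator
- `cladecal.marker_filter` — ortholog/alignment/gene-set filter cascade
  with audit reports
- `cladecal.fixtures` — synthetic-data generators and the bimodality
  experiment
- `cladecal.io`, `cladecal.cli` — Newick/NEXUS/FASTA/TSV/YAML i/o and the
  command-line interface

See `docs/methods.md` for the modeling assumptions, estimator definitions,
operator design and known limitations.
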