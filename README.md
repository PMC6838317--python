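# subsidydiet

Quantitative diet analysis for free-ranging predators subsidized by people,
built around the case of domestic cats (*Felis catus*) on a small subtropical
island where they prey on endangered endemic mammals while living mostly on
human-provided food. The package reimplements, as a tested and reusable
pipeline, the full chain of analyses that supports that conclusion:

1. **Fecal analysis** — frequency of occurrence (FO) and minimum number of
   individuals (NI) per prey taxon, and each taxon's contribution to the
   predator's daily consumed biomass (DCB):

   `contribution = 100 · (W_prey · NI / n) / mean DCB`,

   with DCB predicted allometrically from predator weight,
   `DCB = 3.358 · W^0.813 · 2.86/18` (g, W in g), prey weight capped at the
   maximum DCB, and one scat per cat-day assumed. Taxa contributing > 3%
   become candidate sources for the isotope model.
2. **Trophic enrichment factors (TEF)** — nonlinear least-squares fit of the
   asymptotic exponential `Δδ(t) = A·e^{B·t} + C` to diet-switch series of
   sheltered cats; the asymptote C is the TEF per isotope.
3. **Bayesian mixing model** — a three-source, two-isotope (δ13C, δ15N)
   model with Dirichlet(1,…,1) priors on diet proportions,
   `x_ij ~ N(Σ_k p_k(μ_jk + c_jk), Σ_k p_k²(ω_jk² + τ_jk²) + σ_j²)`,
   sampled by adaptive random-walk Metropolis, with 95% highest-density
   regions (HDR) summarising dependence on forest animals, farmland animals
   and artificial resources per cat group.
4. **Landscape GLMs** — land-use coverage in 100/200/500 m buffers around
   capture sites, collapsed to two oblique factors (ML extraction, Promax
   rotation, parallel analysis), spatial autocorrelation absorbed by Moran's
   eigenvector maps from a Delaunay neighbour graph, and all-subsets
   Gaussian GLMs ranked by AICc with full model averaging over ΔAICc < 2.
5. **Synthetic data** — seeded generators for every input table, calibrated
   to the published marginals, so the whole pipeline is testable offline.

It is aimed at trophic ecologists and conservation practitioners who have
scat tables, hair isotope values and capture coordinates, and want the whole
fecal + isotope + spatial workflow in one place.

## Worked example

```python
from subsidydiet import fecal, simulate, mixing

# deterministic fixture reproducing the published fecal-table marginals
taxa, scats, cats = simulate.table1_fixture(seed=0)
dcb = fecal.mean_dcb(cats)                   # mean DCB: 379 g (range 147-629 g)

ni = {t.name: sum(c for s in scats for n, c in s.items if n == t.name) for t in taxa}
table = fecal.category_contributions(taxa, ni, n_scats=len(scats),
                                     mean_dcb=dcb["mean"], max_dcb=dcb["max"],
                                     scats=scats, cats=cats)
fecal.select_sources(table, threshold=3.0)   # the taxa worth isotope-modelling

cfg = simulate.ScenarioConfig(seed=101)      # published group summaries as truth
consumers = [c for c in simulate.gen_consumer_isotopes(cfg) if c.group == "feral"]
post = mixing.run_mixing_mcmc(consumers, simulate.tokunoshima_sources(),
                              mixing.MCMCConfig(50_000, 5_000, 10, seed=102))
print(post.summary_table())
```

Output:

```text
group               source  mean  hdr_low  hdr_high
feral       forest animals 0.171    0.143     0.200
feral     farmland animals 0.120    0.076     0.169
feral artificial resources 0.710    0.660     0.761
```

The contribution table scores the two endangered forest mammals at 7.7% and
6.7% of daily consumed biomass and the black rat at 6.9%, so these three
taxa clear the 3% source-selection threshold. The mixing model then says the
short-term fecal picture is misleading about energy budgets: roughly 70% of
the feral cats' long-term diet is artificial food, with forest animals near
17% — predation on endangered species coexisting with heavy human
subsidy.

A command-line interface mirrors the library:
`subsidydiet {fecal|tef|mix|glm|simulate|all}`, e.g.

```sh
subsidydiet simulate --seed 1 --out fixtures/
subsidydiet fecal --taxa fixtures/taxa.csv --scats fixtures/scats.csv \
    --cats fixtures/cats.csv --threshold 3.0 --out out/
subsidydiet all --seed 1 --out out/
```

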