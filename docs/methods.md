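# Methods

## Problem and scope

`oralgut` re-implements, as a tested library + CLI, the computational core of
an oral-to-gut microbial invasion analysis in a two-compartment in vitro
colon: a continuous luminal fermenter vessel coupled to a mucin-bead
compartment that models the mucus-associated microbiota. The pipeline starts
at gene-level abundance tables (reads mapped against a gut and an oral gene
catalogue); read QC and mapping are upstream tools whose output the
synthetic-data module emulates. The analysis chain is

1. **MSP quantification** — metagenomic species pangenome (MSP) abundance
   per sample from marker genes;
2. **merge** — one species-level table from the two catalogue-specific ones;
3. **normalization, richness, mapping rates**;
4. **niche assignment** — gut / oral / not-determined (ND) labels from the
   two baseline samples (stool, raw saliva);
5. **invasion analytics** — niche-split richness/abundance series, the
   oral-invader detection matrix per compartment and day, Bray-Curtis
   dissimilarities, taxonomic rank compositions, and the Spearman
   correlation between invader abundance in enriched saliva and mucosa.

## Quantification rules

The abundance of an MSP in a sample is the arithmetic mean over **all** of
its marker genes (default 100 per MSP), zeros included, reported only when
at least `ceil(min_marker_fraction * n_markers)` markers have strictly
positive abundance (default 10%, boundary inclusive: 10 of 100 detected
markers is a detection). Averaging over all markers rather than only the
detected ones keeps the estimator monotone in the underlying species
abundance; gene counts are used as-is (a `length_normalize` toggle divides
by the catalogue length weights for pipelines that emit length-normalized
profiles).

Merging drops, for each declared overlap pair, the oral-catalogue member
and keeps the gut identifier with the per-sample elementwise **max** of the
pair. Max avoids double counting the same species while never discarding
signal when one catalogue's markers capture it better; `merge_tables`
also accepts `'gut'` (keep gut values) and `'sum'`. Normalization divides
each sample column by its own sum, after merging; richness counts MSPs
with positive abundance on the merged table.

Downsampling to a fixed depth is a multivariate hypergeometric draw
(without replacement) over the sample's gene rows plus its unassigned
pool, matching read-subsampling semantics; column totals equal the
requested depth exactly.

## Niche assignment and invaders

Each merged MSP is labelled from its strict occurrence in the donor's two
baseline samples: detected (> `detection_floor`, default 0) only in
baseline stool → **gut**; only in baseline raw saliva → **oral**; in both
or in neither → **ND**. The rule forces zero oral-niche richness in the
baseline stool and zero gut-niche richness in the baseline saliva. Oral
invaders are oral-niche MSPs detected in at least one luminal or mucosal
sample; those already detected before the first injection day (default 9)
are flagged pre-existing rather than excluded. ND species are never
counted as invaders. Multi-donor tables are processed per donor.

The invader correlation (enriched saliva vs a mucosal sample, over the
detected invaders) uses Spearman's rank correlation with average ranks for
ties and a two-sided t-approximation p-value; an exact permutation p-value
is available for n ≤ 10. The default report correlates each enriched-saliva
sample against the latest mucosal sample; note that under the simulator's
event ordering the day-10 culture is injected at the instant the day-10
mucosa is sampled, so only the day-9 culture has had colonization time —
the acceptance script therefore reports the day-9 correlation.

## The simulator

### Dynamics

Per-species biomass follows a deterministic discrete-time logistic
chemostat; with lumen vector `x`, mucosa vector `m`, total luminal biomass
`X` and time step `dt` (days):

    x_i <- x_i * exp([g_i (1 - X/K) - D] dt)
    m_i <- m_i + dt (a_i x_i - delta_i m_i),   clipped at 0

The physical set-points fix the washout: a 24-h mean retention time gives
`D = 1/day`. Growth rates `g_i` are lognormal (median 0.8/day, sd-log 0.5),
so roughly half the community declines under washout — reproducing the
richness loss and day-5-ish stabilization seen in such fermenters.
Adhesion `a_i` (default 0.1/day) is multiplied by `oral_mucosal_affinity`
(default 5) for oral-niche species, encoding their preference for mucosal
resources; detachment `delta_i` defaults to 0.5/day. Mucin beads are
replaced every 2 days keeping `bead_retention_fraction = 0.2` of mucosal
biomass; the mucosa is sampled before the swap. `K = 10` (relative biomass
units; the inoculum totals 1) only sets the scale at which growth
saturates — the analyses all run on relative abundances.

Timeline: day 1 is batch amplification (`D = 0`), continuous fermentation
follows to day 11. Luminal samples are taken daily (days 1–11), mucosal
every 2 days (2–10). On each injection day (9, 10) the enriched saliva is
added twice, at `t = day` and `t = day + 1/3` (morning / late afternoon),
each dose a fraction `saliva_dose = 0.033` of the current luminal biomass —
the 10 mL-into-300 mL volume ratio. Events at a shared instant are ordered
injection → sampling → bead swap, i.e. a morning injection precedes that
day's sampling.

### Communities and enrichment

Baseline stool holds the gut-only + shared species, baseline saliva the
oral-only + shared species, each drawn from a Dirichlet. Niche-exclusive
species use concentration 0.5 (a realistic long-tailed community); shared
species use concentration 5. The shared (planted-ND) class represents taxa
genuinely resident in both habitats — operationally the class is *defined*
by detection in both baselines, so the generator plants them at abundances
where a 100k-read sample actually detects them; planting them routinely
below the detection limit would contradict the class definition. A
consequence is that shared species carry a larger biomass share than in
the real study, which flattens the simulated cross-catalogue mapping
rates (see limitations).

The 9-h saliva enrichment keeps each species independently with
probability `enrichment_dropout = 0.7` (a survival probability, chosen to
reproduce the ~70% richness retention the protocol achieves); survivors
grow exponentially at their per-day rate for 9 h and the result is
renormalized. Each injection day gets an independent enrichment culture.

### Sequencing

Each sample of the 20-sample grid (11 luminal + 5 mucosal + 2 enriched
saliva + 2 baselines) is sequenced by a multinomial draw of
`sequencing_depth = 100000` reads over the genes of both catalogues, with
read probability proportional to species weight × gene length weight
(length weights uniform on [0.5, 1.5]). A Binomial fraction of the depth
is set aside as unassigned (host/unknown): 5% for fecal-origin samples,
50% for salivary ones, mirroring the much higher host-DNA load of saliva.
Assigned + unassigned reads always equal the depth exactly. Shared species
have one MSP per catalogue (declared in an overlap pair), so their reads
split between the two catalogues' gene copies; the per-marker expectation,
and hence the MSP estimate, is unaffected.

All randomness flows from one root seed through named substreams
(`catalogue`, `rates`, `communities`, `enrichment_day{d}`,
`sequencing:{sample}`), so identical configs give byte-identical outputs
and stages can be re-run independently.

## Numerical and design choices

- Euler stepping at `dt = 0.01` day; the dynamics tests check the lumen
  washout closed form and the mucosal ODE equilibrium (`a x / delta`) to
  1% at this step size.
- Detection thresholds use `ceil` with an inclusive boundary.
- The baseline raw-saliva sample carries no day (it is collected once,
  late in the run) but serves as the initial-time niche reference together
  with the day-0 stool; niche assignment is insensitive to its collection
  day because the saliva community is not itself simulated over time.
- Bray-Curtis requires normalized input by design (the statistic is only
  comparable across samples on relative abundances).
- Zero-abundance columns are errors in `normalize` (a sample with no
  detected MSP has no composition), as are tables normalized twice.
- Compartment contrast: mucosal vs luminal oral-invader counts are
  compared per day via the report's `invader_summary`; under the default
  schedule day 10 is the only post-injection day with both compartments
  sampled.
- Test and acceptance problem sizes: oracle equivalence runs on 100
  random micro-catalogues (10 MSPs × 100 markers); end-to-end recovery
  uses the full default scenario (330 species, 100k reads/sample) over 25
  seeds, which completes in well under a minute.

## What the simulator does and does not emulate

Emulated: donor-specific stool/saliva communities with disjoint, shared
and absent species; luminal washout and mucosal retention; bead swaps;
the 9-h enrichment with species dropout; twice-daily spike-ins on days
9–10; multinomial read sampling with an unassigned fraction; the full
sampling grid.

Not emulated: strain-level variation; reads mapping to *both* catalogues
(a real read from a shared species maps in both; here it is assigned to
exactly one gene, so simulated per-catalogue mapping rates are lower and
flatter than the >80%/~5% fecal and >79%/<40% salivary splits reported
for real data); pH/gas/short-chain fatty-acid chemistry; abundance-
dependent enrichment dropout; interspecies interactions beyond shared
logistic saturation; sequencing error or gene-length-dependent coverage
bias beyond the static length weights. Passing recovery tests therefore
shows the *analysis rules* are implemented correctly and are robust to
multinomial counting noise at realistic depth — not that the model
captures every ecological mechanism of a real bioreactor.

## Known limitations

- The deterministic chemostat has no demographic stochasticity: an
  injected species never truly washes out to zero, so "planted invader"
  status is read off the sampled trajectory, and exact-zero mucosal
  support is affinity-independent (contrasts are assessed at a
  detectability threshold instead).
- With heterogeneous growth rates the lumen slowly excludes all but the
  fastest growers; the 11-day horizon is short enough that this matches
  the observed richness decline, but much longer horizons would collapse
  the community.
- Spearman p-values for large invader sets rely on the t-approximation;
  the exact permutation option is exponential in n and capped at n = 10.
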