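# oralgut

Metagenomic species (MSP) quantification and oral-to-gut invasion analytics
for two-compartment in vitro colon experiments — with a ground-truth
bioreactor + sequencing simulator so the whole pipeline runs, and can be
validated, without any external data.

## The problem

Oral bacteria show up in the gut of patients with Crohn's disease, liver
cirrhosis and other dysbioses, but *how* they invade — and whether they
prefer the free luminal medium or the mucus layer — is hard to study in
humans. In vitro colon models such as the Mucosal ARtificial COLon
(M-ARCOL) address this: a continuous fermenter vessel (the **lumen**,
24-h mean retention) coupled to a mucin-bead compartment (the **mucosa**),
inoculated with a donor's stool and then challenged with enriched saliva
from the same donor. Shotgun metagenomics of the time course then tracks
which oral species invade which compartment.

`oralgut` is the analysis side of such an experiment, for microbiome
bioinformaticians: it starts from gene-level count tables (reads mapped
against a gut and an oral gene catalogue) and produces species-level
abundance tables, ecological-niche labels, and compartment-resolved
invader reports.

## The method

**Quantification.** Each MSP (metagenomic species pangenome — a cluster of
co-abundant catalogue genes standing in for a species) is quantified per
sample as the mean abundance of its 100 marker genes,

    a(msp, s) = (1/100) Σ_g c(g, s),   detected iff #{g : c(g, s) > 0} ≥ 10,

i.e. the arithmetic mean over *all* markers, reported only when at least
10% of them are present (boundary inclusive); otherwise 0. Gut- and
oral-catalogue tables are merged into one species table (overlapping
species keep the gut identifier with the per-sample max), then normalized
per sample.

**Niche assignment.** A species detected only in the baseline stool is
**gut**; only in the baseline raw saliva, **oral**; in both or neither,
**ND**. Oral invaders are oral-niche species detected in any luminal or
mucosal bioreactor sample; richness and abundance series are split by
niche, community turnover is measured with Bray-Curtis dissimilarity
`BC(x, y) = 1 − 2 Σ min(x_i, y_i) / (Σ x_i + Σ y_i)`, and invader
composition in enriched saliva vs mucosa is compared with Spearman's rank
correlation.

**Simulator.** A deterministic logistic chemostat with linear mucosal
adhesion/detachment (oral species get a 5× adhesion affinity), bead swaps
every 2 days, a 9-h saliva enrichment with ~70% species retention, and
twice-daily saliva injections on days 9–10; sequencing is multinomial read
sampling over miniature paired catalogues with a host/unassigned read
fraction. Every run returns the planted truth (niche labels, invader set,
compositions), so recovery can be scored exactly. See `docs/methods.md`.

## Worked example

Run the full pipeline on a simulated default scenario (330 species,
100k reads/sample, 20 samples):

```bash
oralgut e2e --out demo --seed 42
cat demo/summary.txt
```

```
oral invader MSPs detected: 23
  luminal day 8: 0 oral MSPs (pre-invasion)
  luminal day 9: 3 oral MSPs (post-invasion)
  luminal day 10: 8 oral MSPs (post-invasion)
  luminal day 11: 8 oral MSPs (post-invasion)
  mucosal day 8: 0 oral MSPs (pre-invasion)
  mucosal day 10: 21 oral MSPs (post-invasion)
day 10: mucosal 21 vs luminal 8 oral MSPs
Spearman rho 0.83 (p=7.7e-07, n=23) between S1_enriched_saliva_d09 and S1_mucosal_d10
Spearman rho 0.22 (p=0.3, n=23) between S1_enriched_saliva_d10 and S1_mucosal_d10
```

(abridged; the full summary lists every sampled day). Reading this: no
oral-niche species is detected anywhere before the day-9 injection; after
it, far more oral invaders establish in the mucosal compartment (21) than
survive the luminal washout (8) — the mucus-preference signal this kind of
experiment is designed to expose. The day-9 enriched culture, which had a
full day to colonize, correlates strongly with the day-10 mucosal invader
profile (ρ = 0.83), while the culture injected at the sampling instant
does not (ρ = 0.22).

The run directory also contains the raw/normalized merged MSP tables,
per-sample richness, mapping rates, niche assignments, the invader matrix,
the Bray-Curtis matrix, phylum compositions, the planted ground truth and
a manifest with sha256 digests (two runs with the same seed are
byte-identical).

The same stages are available as library functions
(`quantify_msp`, `merge_tables`, `normalize`, `assign_niches`,
`build_invasion_report`, `simulate_dataset`, ...) and as separate
`oralgut simulate | quantify | invasion` subcommands for real gene tables.

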