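# vinotyper

Genotype and VINOtype calling for two-allele hybridization genotyping
arrays, with a synthetic intensity simulator for end-to-end testing.

## The problem

SNP genotyping arrays measure the hybridization of genomic DNA to
allele-specific probes and convert the two allele intensities (A, B)
into discrete calls by clustering samples in the contrast dimension,
c = (A − B)/(A + B).  When a sample's genomic target carries an
*off-target variant* (OTV) — an uncharacterized variant in the probe's
target sequence or in a flanking restriction site used for genome-wide
amplification — hybridization weakens, the contrast collapses or
reverses, and contrast-only callers emit wrong heterozygous calls or
no-calls.  Probe sets showing a reproducible low-average-intensity
sample cluster are *variable intensity oligonucleotides* (VINOs).
Recognizing that cluster as its own call class (V) recovers probes
that would otherwise be filtered out and counteracts the ascertainment
bias against genetically divergent samples.

`vinotyper` is for anyone who has per-probe-set summarized A/B
intensities (from mouse diversity panels, other Affymetrix-style
arrays, or the bundled simulator) and wants five-class calls
{AA, AB, BB, V, N} plus the quality-control, event-classification and
concordance reports around them.

## The algorithm

Per probe set, with samples as points in (contrast, average) space
(contrast optionally CCS-compressed, `asinh(k·c)/asinh(k)`; average
`log2((A+B)/2)`):

1. **Mixture stage** — 1-, 2- and 3-component Gaussian mixtures are
   fitted to the contrast by EM (fixed initialization at the observed
   min/center/max); the component count is chosen by the silhouette of
   the hard assignment.  Samples whose posterior clears a per-group
   median threshold are assigned; components map to genotypes by
   contrast ordering.
2. **Friends-of-friends** — remaining samples are attached one at a
   time to the cluster of their nearest assigned neighbour in the full
   2D space, so gaps between clusters separate groups even where the
   mixture's variances cannot.
3. **Confidence** — each genotype group gets a robust 2D center and
   scatter (one-step Tukey biweight); a sample's confidence is the
   χ²₂ upper-tail probability of its squared Mahalanobis distance,
   `exp(−d²/2)`; calls below a threshold (default 0.005) become N.
4. **VINO stage** — the VINO score is
   `(1 − confidence) · Φ((μ_avg − avg)/σ_avg)`: far from the group
   *and* low in intensity.  Scores above 0.9999 seed a V cluster,
   which is expanded by a second friends-of-friends pass over all
   samples below the mean average intensity.  Vinotypes equal
   genotypes everywhere except the V substitutions.

Around the caller: cubic-spline (5 df) correction of C+G and
restriction-fragment-length intensity trends plus single-array
quantile normalization to a reference distribution; probe/strand QC
filters; OTV event classification (central/edge OTV by the 3-bp edge
rule, RFLP bins split at 1 kb and 1.5 kb, cut-in-probe); cross-tab
concordance statistics; and NEXUS export of VINO presence/absence
characters (C = V, G otherwise) for phylogenetics.

## Worked example

```python
from vinotyper import SimulationConfig, simulate_dataset
from vinotyper.vino import VinotypeCaller

cfg = SimulationConfig(n_probes=200, n_samples=96, seed=1,
                       het_sample_fraction=0.0)   # inbred panel
probe_table, truth, intensities = simulate_dataset(cfg)

caller = VinotypeCaller().fit(intensities)
v = caller.vinotypes_.to_numpy()

hom = (truth.otv_state.to_numpy() == "hom")
print("V calls:", (v == "V").sum())
print("hom-OTV cells called V:", (v[hom] == "V").mean().round(3))
```

prints

```
V calls: 259
hom-OTV cells called V: 0.558
```

259 cells (of 19 200) land in low-intensity clusters and are called V.
The 56% overall recovery splits sharply by event class: every
homozygous carrier of a central OTV or a within-probe cut site is
called V (253/253 in this run), while edge OTVs and moderate
fragment-length events — whose intensity deficit sits below the
stringent V threshold — are deliberately left as ordinary genotype
calls.
The same pipeline is available from the shell:

```
vinotyper simulate --seed 1 --out-prefix sim
vinotyper genotype --in sim.intensities.tsv --vinotype --out calls
vinotyper concord --a calls.vinotypes.tsv --b sim.genotypes.tsv
```

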