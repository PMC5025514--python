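# polyarray

Toolkit for designing single-locus SNP genotyping assays in an allopolyploid
genome and for analysing the resulting array data. It targets the situation
found in *Brassica napus* (A + C subgenomes) and similar allopolyploids:
near-identical homoeologous sequence causes short hybridisation probes to
bind several loci at once, turning what looks like allelic variation into
unresolvable multi-cluster signal. The package implements the design funnel
that limits assays to effectively single-copy loci, the theta-space cluster
analysis that classifies and rescues the resulting intensity patterns, and
the genetic/physical map reconciliation used to validate marker identity —
plus a simulator that generates every input with known truth.

## What it computes

**Design funnel.** Per-genotype variant calls (VCF) and coverage (BED) over a
combined subgenome reference are aggregated into a site × genotype call
matrix (calls: missing / reference / het / homozygous-variant, with platform
depth minima 3× for long-read 454-type data and 8× for short-read Illumina
data). Candidates then pass a five-step cascade — clean 60-bp flank on at
least one side, ≤ 2 alleles, confidence (missing ≤ 70 %, heterozygous ≤ 40 %,
panel allele frequency within [0.2, 0.8]), external design score ≥ 0.6, and
removal of two-bead (A/T, C/G) SNPs — producing an attrition report.
For each survivor, the 50-bp probe adjacent to the SNP is matched genome-wide:
a locus counts as a match when it shares ≥ 35 consecutive identical bases
with the probe on either strand. SNPs with the fewest probe matches are
selected first (default cap: two matches).

**Cluster engine.** Two-colour intensities are normalised to
θ = (2/π)·arctan(Y/X) ∈ [0, 1] and R = X + Y. Per SNP, a 1-D Gaussian
mixture over θ (K ≤ 5, BIC-selected) is classified into the pattern taxonomy
seen on allopolyploid arrays: genome-specific (extreme clusters separated by
Δθ > 0.6), multi-cluster unresolvable (≥ 4 clusters or an inflated
heterozygote cloud), shifted (clusters compressed into one half of θ space by
a monomorphic co-hybridising homoeolog — automatically rescued by
relabelling to AAAA/AAAB/AABB), presence/absence (one silent allele,
split by R), monomorphic, and failed (low intensity). Genotypes are called
by component responsibility with a no-call confidence threshold of 0.05,
and per-species cluster files can be derived for the diploid ancestors.

**Map reconciliation.** Doubled-haploid genotype matrices give recombinant
fractions r = discordant/jointly-typed lines, converted with the Kosambi
function d = 25·ln((1+2r)/(1−2r)) cM; co-segregating markers collapse into
bins. Markers are anchored physically from alignment hits (best hit at
≥ 85 % identity), density statistics (markers/cM, cM/marker, Kb/marker) and
gap lists (≥ 9 cM genetic, > 500 Kb physical) are tabulated, each marker is
labelled concordant / homoeologous / discordant against a chromosome
correspondence and homoeology table, and runs of markers anchored to one
wrong chromosome are reported as rearranged segments.

## Worked example

```python
import polyarray as pa
from polyarray.filters import attach_design_scores
from polyarray.probes import count_matches_for_candidates

cfg = pa.SimConfig(seed=11, n_snps=400, chromosome_length=150_000)
ref, _ = pa.simulate_allotetraploid(cfg)
sets, truth, scores = pa.simulate_variant_panel(ref, cfg)

matrix = pa.aggregate_panel(sets, ref)            # 480 candidate sites
cands = pa.annotate_flanks(matrix, ref)
attach_design_scores(cands, scores)
report, survivors = pa.run_cascade(cands)
print(report.to_frame().to_string(index=False))
```

```
        step  excluded  remaining
        none         0        480
    flanking        40        440
multiallelic        20        420
  confidence        60        360
design_score        20        340
transversion        20        320
```

The report reads top to bottom as the assay-design funnel: of 480 candidate
sites (400 primary + 80 planted flank-contaminating partners), 40 lose both
flanks to nearby variants, 20 are multi-allelic, 60 fail the confidence
screen, 20 have a low design score and 20 are two-bead A/T or C/G SNPs,
leaving 320 designable candidates — matching the simulator's planted failure
modes exactly. Probe matching then ranks the survivors:

```python
assays = [p for c in survivors for p in pa.extract_probes(c, ref)]
count_matches_for_candidates(assays, ref)
selected = pa.rank_and_select(assays, pa.SelectionPolicy(max_match_count=2))
# 320 selected: 223 unique probes, 97 matching twice (divergence 0.03)
```

At the default 3 % homoeolog divergence, about 70 % of probes are already
subgenome-specific (unique); the rest also hybridise the homoeologous copy.
The same session also gives the classic map-function check:

```python
pa.kosambi(0.25)                 # 27.465307216702744 cM
pa.published_density_stats()[1]  # {'markers_per_cm': 11.99,
                                 #  'cm_per_marker': 0.08,
                                 #  'kb_per_marker': 14.59}
```

The published-map totals are recomputed from the printed per-linkage-group
inputs (21,766 mapped loci over 1,814.9 cM; 49,744 positioned loci over
725,833 Kb) and reproduce the printed densities at two decimals.

A `polyarray` console script exposes the same stages
(`simulate-* | aggregate | filter | probes | select | cluster-fit |
cluster-call | map-stats | concordance`); run `polyarray --help`.

## Layout

```
src/polyarray/
  aggregate.py   cross-panel SNP summary matrix from VCF + BED
  filters.py     five-step design-filter cascade + attrition report
  probes.py      probe extraction, 35-bp match counting, selection
  clusters.py    theta/R normalisation, mixture fits, pattern taxonomy,
                 shifted-cluster rescue, genotype calling, cluster files
  mapping.py     DH bins, Kosambi distances, physical anchoring,
                 density statistics, concordance, segment detection
  simulate.py    truth-emitting generators for every input format
  cli.py         command-line interface
docs/methods.md  model and design notes
```
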