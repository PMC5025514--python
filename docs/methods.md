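# Methods

## Problem setting

An allotetraploid genome carries two homoeologous subgenomes whose sequences
are typically only a few percent diverged. An Infinium-style SNP assay reads
a single 50-bp probe hybridised next to the target base, so a probe designed
against one subgenome will usually also bind the homoeologous locus, and the
two-colour signal becomes a superposition of two loci. The package models the
complete workflow that copes with this: selecting candidate SNPs whose local
sequence context is effectively single-copy, recognising and (where
possible) rescuing the compressed cluster patterns that co-hybridisation
produces, and cross-validating marker identity by comparing genetic map
position against physical anchor.

## Call aggregation

Each genotype contributes variant records (chromosome, position, reference
and alternate allele, read depth, alternate-read fraction) and covered
intervals. A site in a genotype is:

* **MISSING** — uncovered, or a variant observation below the platform depth
  minimum (3× for long-read 454-type data, 8× for short-read Illumina data;
  these minima reflect the platforms' error profiles);
* **REFERENCE** — covered with no variant record, or an alternate fraction
  below the within-genotype heterozygote band;
* **HET** — alternate fraction inside [0.2, 0.8] (inclusive);
* **HOM_VARIANT** — alternate fraction above the band.

The heterozygote band is a package convention (upstream variant callers
differ in how they annotate within-genotype heterozygosity); it is
configurable on `DepthThresholds`. Panel statistics per site are the missing
fraction, the heterozygote fraction among non-missing calls, and the
alternate-allele frequency among non-missing calls with HET counted as half
an alternate allele (the weight is configurable; ½ is the gene-dosage
reading). A row whose stated reference allele disagrees with the reference
genome is kept with a warning flag rather than rejected, because merged
panels from mixed pipelines routinely contain such rows. Internally all
coordinates are 0-based half-open; VCF positions are converted only at I/O.

## Filter cascade

Five independent predicates, applied in a canonical order (flanking →
multi-allele → confidence → design score → transversion) but valid in any
permutation — the survivor set is order-invariant, only the attribution of a
failure to its *first* failing step depends on order, and the attrition
report's telescoping identity (remaining(k) = remaining(k−1) − excluded(k))
holds by construction. All threshold comparisons are strict in the excluding
direction ("greater than 70 %" excludes, so exactly 70 % survives): boundary
candidates pass. A flank side is *clean* when its full 60-bp window fits on
the chromosome, contains no N, and contains no other candidate site from the
complete pre-filter panel; one clean side suffices. The confidence step
excludes sites with missing > 0.70, heterozygous > 0.40, or panel allele
frequency outside [0.2, 0.8]; a site with no non-missing calls (undefined
frequency) is excluded here. The design score is consumed as an opaque
external column in [0, 1] (threshold 0.6, absent score fails by default); no
attempt is made to re-create any proprietary scorer. The transversion step
defaults to removing only A/T and C/G pairs — the pairs that force two-bead
Infinium I assays — with a literal `ALL_TRANSVERSIONS` mode available; the
default reflects how small the step's published attrition is relative to
what removing all transversions would produce.

## Probe matching

The probe is the 50 bp adjacent to the SNP on a clean side, excluding the
SNP base itself (single-base extension interrogates the base 3′ of the
probe); downstream probes are reverse-complemented so the 3′ end abuts the
SNP. A genomic locus *matches* a probe when the two share an exact, gapless,
mismatch-free common substring of ≥ 35 bp on either strand. Overlapping hit
windows merge into one locus, and coincident hits on opposite strands count
once. The count includes the source locus, so every designable probe has
count ≥ 1. Exact matching is a deliberate simplification of
alignment-tool behaviour (which can tolerate scattered mismatches inside a
"fully aligned" run); the implementation is a probe k-mer set scanned along
the genome, and its contract is exact equivalence with a brute-force
all-windows oracle, which the test suite enforces on genomes up to 200 kb
with planted 34/35/36-bp repeats. Per SNP the match count is the minimum
over its candidate probes (design picks the most specific side; a
conservative maximum mode exists). Selection sorts ascending by match count
with ties broken by higher design score then lexicographic id, applies a
match-count cap (default 2), and optional per-class quotas.

## Cluster engine

Normalisation is the polar transform θ = (2/π)·arctan(Y/X), R = X + Y, with
X = Y = 0 treated as a no-signal sentinel. The per-SNP model is a
one-dimensional Gaussian mixture over θ fitted to samples with effective
signal (R ≥ 0.2 by default), K ∈ 1..5 selected by BIC, spherical
covariances, fixed seed. Fitting in θ only — with R reserved for the
low-intensity and presence/absence decisions — keeps the model identifiable
on panels as small as tens of samples; 2-D fitting is a possible extension.

Because BIC occasionally shaves one boundary-compressed cloud into two
near-coincident components, all taxonomy decisions and genotype labels
operate on *merged cluster groups*: fitted components whose θ means lie
within `merge_tol` (default 0.1) of their neighbour act as a single cluster.
Genotype-call confidences likewise aggregate responsibilities per label, so
two slivers of one cloud never compete against each other.

Classification applies a fixed precedence (the taxonomy is a description,
not an algorithm, so an order had to be chosen; this one resolves every
overlap in favour of the more conservative label):

1. **FAILED_LOW_INTENSITY** — more than half the samples below the R floor;
2. **PRESENCE_ABSENCE** — ≥ 10 % (but not a majority) of samples without
   signal while the signal clusters sit at a single θ position;
3. **MULTI_CLUSTER_UNRESOLVABLE** — ≥ 4 effective clusters, or 3 clusters
   with middle weight > 0.6 (the excess-heterozygote signature of two
   segregating homoeologs);
4. **GENOME_SPECIFIC** — 2–3 clusters whose extreme means are separated by
   more than 0.6. Applying the rule to the extreme clusters (not requiring
   three) lets doubled-haploid panels, which lack an AB cloud, qualify;
5. **SHIFTED** — ≥ 2 clusters all confined to one half of θ space, the
   signature of a monomorphic co-hybridising homoeolog;
6. **MONOMORPHIC** — one cluster with signal.

Shifted models with 2–3 effective clusters are rescued automatically:
extreme clusters are relabelled AA/BB (middle AB), sample-to-component
responsibilities untouched (bit-identical before and after), pattern set to
SHIFTED_RESCUED and the SNP becomes scorable. This automates what an
operator does manually when editing cluster positions of such assays.

Calling assigns each sample the label with the highest aggregated
responsibility; the confidence score is the margin between the best and
second-best label posterior, and calls with margin below the no-call
threshold (default 0.05) or nearest an unlabelled component are suppressed.
The margin construction makes the call rate provably monotone in the
threshold and sends responsibility ties to NO_CALL, matching the intended
semantics of a no-call confidence band. It is an analog of, not a clone of,
proprietary calling scores. Presence/absence assays are the one exception:
a no-signal sample is called as the silent homozygote.

Cluster files serialise per-SNP components, labels, pattern and flags to
JSON and round-trip exactly. Diploid cluster files are derived by refitting
each SNP on the diploid samples only: assays specific to the other subgenome
collapse to no signal and are marked failed, the rest are reclassified (the
formerly compressed patterns typically widen once the co-hybridising
homoeolog is absent), and scorable/polymorphic counts are reported.

## Genetic maps and concordance

Doubled-haploid lines are fully homozygous, so markers are binary vectors
and the recombinant fraction between two markers is the discordant fraction
among jointly typed lines (values > 0.5 are flagged unlinked; zero jointly
typed lines give a NaN sentinel). Distances use the Kosambi function
d = 25·ln((1+2r)/(1−2r)) cM with inverse r = tanh(d/50)/2; the pair
round-trips to 1e-12 over the full domain. Adjacent markers merge into a bin
iff they agree on every jointly non-missing line *and* at least one line is
jointly typed — missing cells are wildcards but cannot carry a merge by
themselves, which prevents vacuous merges through all-missing markers.
Marker order is an input (from an external ordering tool or simulation
truth); the package validates and measures an order, it does not search
order space.

Physical anchoring keeps the best alignment hit per marker at ≥ 85 %
identity; co-optimal best hits on different chromosomes mark the marker
ambiguous, no qualifying hit leaves it unanchored. Density statistics
(markers/cM, cM/marker, Kb/marker) are rounded half-up to two decimals, the
presentation convention of the published table they mirror; the packaged
printed per-linkage-group inputs reproduce the published totals exactly.
Gap lists flag genetic intervals ≥ 9 cM and physical intervals > 500 Kb.
Concordance compares each marker's linkage group (via a user-supplied
LG↔chromosome correspondence) with its anchor chromosome: CONCORDANT,
HOMOEOLOGOUS (anchor's homoeolog per a symmetric, user-supplied table —
numbered A↔C pairs by default, since true homoeology is block-level and
block-interval tables can be substituted), DISCORDANT, or UNANCHORED.
Rearranged segments are maximal runs of ≥ 3 consecutive non-concordant
markers sharing one alternate chromosome, reported with genetic and physical
extents.

## Simulator

The simulator defines the study conditions for all tests:

* **Genome** — subgenome A uniform-random (default two chromosomes of
  100 kb), subgenome C derived by per-base substitution at divergence
  d = 0.03, within the range typical of recently hybridised allopolyploid
  subgenome pairs; optional planted exact repeats.
* **Variant panel** — 12 genotypes by default, alternating platform tags.
  Failure modes (flank contamination 10 %, multi-allelic 5 %, high-missing,
  high-het, out-of-band frequency 5 % each, low design score 5 %, two-bead
  pairs 5 %) are injected by *composing* per-genotype call counts, not by
  iid sampling, so each site's statistics land deterministically on the
  intended side of every filter band and the attrition report can be checked
  against truth exactly. Primary sites are spaced ≥ 150 bp apart and flank
  contaminators planted at ±40 bp of their victims, so no site fails the
  flank screen by accident.
* **Intensities** — 200 samples; each SNP draws a pattern class (60 %
  genome-specific, 15 % shifted, 10 % multi-cluster, 5 % each
  presence/absence, monomorphic, failed — proportions of the same order as
  those reported for a real allopolyploid array) and emits θ/R clouds with
  Gaussian noise (sd 0.03 default). Boundary noise is folded back into
  [0, 1] rather than clipped: the polar transform compresses clouds against
  the rails, and a hard clip would plant artificial point masses. Cluster
  geometries (genome-specific extremes at 0.03/0.97, shifted clusters
  compressed into one half of θ space, five-component multi patterns with an
  inflated middle) are conventions chosen to mimic the canonical published
  pattern gallery, not measured facts. Genome-specific assays carry a target
  subgenome; samples tagged as the other diploid species lose all signal.
* **DH population** — 124 lines by default. Crossovers are placed without
  interference: the allele flips between adjacent markers with probability
  equal to the inverse Kosambi of the true interval. (The distance scale is
  Kosambi because that is the reporting convention; crossover placement
  itself assumes no interference, a documented mismatch absorbed by the
  sampling tolerances of the recovery tests.) Homoeologous swaps move a
  configurable fraction of anchors to the homoeologous chromosome;
  translocated blocks move runs of four adjacent markers to an unrelated
  chromosome. The generator records which intervals actually recombined in
  at least one line, so bin recovery is checked against realised crossovers
  rather than expectations.

What the simulator does **not** emulate: read-level errors and mapping
artefacts (variant calls are taken as given), linkage disequilibrium
structure among genotypes, crossover interference, realistic repeat
landscapes, batch effects or dye bias in intensities. Passing tests
therefore demonstrate the correctness of the algorithms under their stated
models, not robustness to every artefact of real array data.

## Numerical choices and limitations

* Mixture fits use spherical 1-D Gaussians, `reg_covar` 1e-6, three
  initialisations per K, fixed seed: results are deterministic given
  (data, seed).
* BIC ties (within 1e-9) resolve to the smaller K.
* Density statistics round half-up at two decimals; all other outputs are
  full precision.
* Degenerate inputs return sentinels, not exceptions: all-missing sites
  (NaN frequency), zero-length linkage groups (NaN densities), zero jointly
  typed marker pairs (NaN r).
* Problem sizes in the test and acceptance runs (1,000-SNP panels, 600-SNP
  intensity sets, 100 match-counting genomes up to 200 kb, 124-line DH
  populations) are the package's chosen study scale: large enough for the
  stochastic recovery criteria to be stable at their stated thresholds.
* The match counter is exact-substring only; probes that would match with
  internal mismatches under a real aligner are counted as unique here.
* Headline counts of any specific published array (total manufactured
  assays, scorable-marker counts) are not reproduced: they require the
  original multi-hundred-gigabase sequencing panel and proprietary intensity
  data, which are out of scope. The acceptance values are instead the
  worked-example density statistics and the truth-recovery rates above.
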