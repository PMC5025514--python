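"""Synthetic data with known truth for every pipeline stage.

Generates (a) an allotetraploid reference — subgenome A drawn uniformly at
random, subgenome C derived from it by per-base substitution at a configured
divergence, mimicking the homoeologous near-identity that makes probe design
hard; (b) a multi-genotype variant panel with assay-design failure modes
(contaminated flanks, multi-allelic sites, excess missingness or
heterozygosity, out-of-band allele frequency, low design score, two-bead
allele pairs) injected with exact per-site truth labels; (c) two-colour
intensity panels realising each cluster-pattern class; and (d) doubled-haploid
populations with crossovers placed without interference at per-interval
recombination fractions given by the inverse Kosambi function, plus planted
homoeologous swaps and translocated blocks.

Every generator is deterministic given its seed and emits a truth record
consumed by the recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import (
    DepthThresholds,
    GenotypeVariantSet,
    Platform,
    ReferenceGenome,
    VariantRecord,
)
from .clusters import IntensityMatrix, Pattern
from .mapping import (
    DHGenotypeMatrix,
    GeneticMap,
    HomoeologyTable,
    PhysicalAnchor,
    kosambi_inverse,
)

BASES = np.array(list("ACGT"))
# transition partner per base (keeps injected alleles clear of the
# transversion filter unless a failure mode plants one deliberately)
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
# the two-bead (Infinium I) partner
TWO_BEAD = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class SimConfig:
    """Study conditions for all simulators. ``seed`` is mandatory."""

    seed: int
    # genome
    n_chromosomes: int = 2          # per subgenome
    chromosome_length: int = 100_000
    divergence: float = 0.03        # per-bp homoeolog substitution rate
    planted_repeats: int = 0        # exact cross-subgenome repeat copies
    # variant panel
    n_genotypes: int = 12
    n_snps: int = 200
    failure_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "flanking": 0.10,
            "multiallelic": 0.05,
            "high_missing": 0.05,
            "high_het": 0.05,
            "freq_out": 0.05,
            "design_score": 0.05,
            "transversion": 0.05,
        }
    )
    # intensities
    n_samples: int = 200
    noise_sd: float = 0.03
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "GENOME_SPECIFIC": 0.60,
            "MULTI_CLUSTER_UNRESOLVABLE": 0.10,
            "SHIFTED": 0.15,
            "PRESENCE_ABSENCE": 0.05,
            "MONOMORPHIC": 0.05,
            "FAILED_LOW_INTENSITY": 0.05,
        }
    )
    # DH population
    n_lines: int = 124
    lg_maps: dict[str, list[float]] = field(
        default_factory=lambda: {
            "N1": [0.0, 5.0, 12.0, 20.0, 33.0, 47.5, 60.0, 72.0, 85.0, 100.0],
            "N2": [0.0, 8.0, 15.0, 27.0, 41.0, 55.0, 68.0, 80.0],
        }
    )
    dh_missing_rate: float = 0.0
    homoeologous_swap_fraction: float = 0.0
    translocated_blocks: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")
        if self.chromosome_length < 1000:
            raise ValueError("chromosome length must be >= 1 kb")
        if self.noise_sd <= 0:
            raise ValueError("intensity noise sd must be positive")
        for v in self.failure_fractions.values():
            if not 0 <= v <= 1:
                raise ValueError("failure fractions must lie in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth emitted alongside every simulated dataset."""

    # variant panel: snp_id -> first filter step failed (None = survivor)
    filter_truth: dict[str, str | None] = field(default_factory=dict)
    failure_mode: dict[str, str] = field(default_factory=dict)
    allele_freq: dict[str, float] = field(default_factory=dict)
    # genome
    homoeolog_of: dict[str, str] = field(default_factory=dict)
    # intensities: snp_id -> planted pattern; (snp, sample) genotypes
    pattern_truth: dict[str, str] = field(default_factory=dict)
    genotype_truth: dict[str, dict[str, str]] = field(default_factory=dict)
    target_subgenome: dict[str, str] = field(default_factory=dict)
    # DH map
    true_map: pd.DataFrame | None = None
    true_anchors: dict[str, PhysicalAnchor] = field(default_factory=dict)
    recombined_pairs: dict[str, list[bool]] = field(default_factory=dict)
    swapped_markers: list[str] = field(default_factory=list)
    translocated: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        def conv(o):
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="records")
            if isinstance(o, PhysicalAnchor):
                return o.__dict__
            return o

        payload = {k: conv(v) for k, v in self.__dict__.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# Reference genome
# ---------------------------------------------------------------------------

def simulate_allotetraploid(config: SimConfig) -> tuple[ReferenceGenome, SimTruth]:
    """Subgenome A at random; subgenome C by per-bp substitution at the
    configured divergence; homoeolog correspondence recorded in truth."""
    rng = np.random.default_rng(config.seed)
    truth = SimTruth()
    sequences: dict[str, str] = {}
    subgenome: dict[str, str] = {}
    for i in range(1, config.n_chromosomes + 1):
        a = rng.integers(0, 4, size=config.chromosome_length)
        c = a.copy()
        sub = rng.random(config.chromosome_length) < config.divergence
        # substitute to one of the three other bases
        c[sub] = (c[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
        a_name, c_name = f"A{i}", f"C{i}"
        sequences[a_name] = "".join(BASES[a])
        sequences[c_name] = "".join(BASES[c])
        subgenome[a_name], subgenome[c_name] = "A", "C"
        truth.homoeolog_of[a_name] = c_name
        truth.homoeolog_of[c_name] = a_name
    # planted exact repeats: copy a window from an A chromosome into C
    for j in range(config.planted_repeats):
        src = f"A{1 + j % config.n_chromosomes}"
        dst = f"C{1 + j % config.n_chromosomes}"
        start = int(rng.integers(0, config.chromosome_length - 200))
        dest = int(rng.integers(0, config.chromosome_length - 200))
        s = sequences[dst]
        sequences[dst] = s[:dest] + sequences[src][start:start + 200] + s[dest + 200:]
    return ReferenceGenome(sequences, subgenome), truth


def write_fasta(reference: ReferenceGenome, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in reference.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_subgenome_tsv(reference: ReferenceGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, tag in reference.subgenome.items():
            fh.write(f"{name}\t{tag}\n")


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------

_DEPTH = 20          # comfortably above both platform minima
_HOM_FRACTION = 0.95
_HET_FRACTION = 0.5


def _site_positions(rng: np.random.Generator, chrom_len: int, n: int,
                    spacing: int = 170, margin: int = 70) -> np.ndarray:
    """Primary-site positions >= 150 bp apart, so that flank-contamination
    partners planted at +/-40 bp of two adjacent victims can never stray
    inside one another's 60-bp windows by accident."""
    usable = chrom_len - 2 * margin
    if n * spacing > usable:
        raise ValueError("requested SNP count exceeds genome capacity")
    slots = np.sort(rng.choice(usable // spacing, size=n, replace=False))
    jitter = rng.integers(0, 21, size=n)
    return margin + slots * spacing + jitter


def simulate_variant_panel(
    reference: ReferenceGenome, config: SimConfig
) -> tuple[list[GenotypeVariantSet], SimTruth, dict[str, float]]:
    """Plant candidate sites with controlled panel statistics and failure modes.

    Per-genotype calls are constructed from exact count compositions (not iid
    draws) so each site's missing/het/frequency statistics land deterministically
    inside or outside the filter bands its truth label requires. Returns the
    variant sets, the truth record, and the per-site design-score column.

    Truth labels name the first cascade step (in the canonical order) each
    site fails, or None for survivors.
    """
    rng = np.random.default_rng(config.seed + 1)
    truth = SimTruth()
    n_g = config.n_genotypes
    if n_g < 8:
        raise ValueError("variant panel needs >= 8 genotypes for the failure bands")
    chrom = next(iter(reference.sequences))
    chrom_len = len(reference.sequences[chrom])

    modes = list(config.failure_fractions)
    counts = {m: int(round(config.failure_fractions[m] * config.n_snps)) for m in modes}
    n_fail = sum(counts.values())
    if n_fail > config.n_snps:
        raise ValueError("failure fractions sum above 1")
    n_clean = config.n_snps - n_fail

    # flanking victims need a contaminating partner planted on both sides;
    # partners are extra clean sites at +/-40 bp
    n_primary = config.n_snps
    positions = _site_positions(rng, chrom_len, n_primary)
    labels = [m for m in modes for _ in range(counts[m])] + ["clean"] * n_clean
    rng.shuffle(labels)

    design_scores: dict[str, float] = {}
    # per-genotype accumulators
    geno_calls: dict[str, list[tuple[str, int, str, str, str]]] = {
        f"g{j}": [] for j in range(n_g)
    }  # (chrom, pos, ref, alt, kind)

    def compose(label: str) -> tuple[int, int, int]:
        """(n_missing, n_het, n_hom_alt) realising the label's statistics."""
        if label == "high_missing":
            m = min(int(np.ceil(0.7 * n_g)) + 1, n_g - 1)
            return m, 0, n_g - m
        if label == "high_het":
            m = 1
            nm = n_g - m
            h = int(np.floor(0.4 * nm)) + 1
            hom = max(1, int(round(0.45 * nm - 0.5 * h)))
            return m, h, hom
        if label == "freq_out":
            m = 1
            nm = n_g - m
            if rng.random() < 0.5:
                return m, 0, nm  # freq 1.0 > 0.8
            return m, 0, 1      # freq 1/nm < 0.2 for panels of >= 8

        # clean-band composition for every other label
        m = int(rng.integers(0, 2))
        nm = n_g - m
        h = int(rng.integers(0, max(1, int(0.3 * nm))))
        lo = int(np.ceil(0.25 * nm - 0.5 * h))
        hi = int(np.floor(0.75 * nm - 0.5 * h))
        hom = int(rng.integers(max(lo, 1), max(hi, max(lo, 1)) + 1))
        return m, h, hom

    def plant_site(pos: int, label: str, snp_id: str) -> None:
        ref_base = reference.base(chrom, pos)
        if label == "transversion":
            alt = TWO_BEAD[ref_base]
        else:
            alt = TRANSITION[ref_base]
        m, h, hom = compose(label)
        kinds = (["MISSING"] * m + ["HET"] * h + ["HOM"] * hom
                 + ["REF"] * (n_g - m - h - hom))
        rng.shuffle(kinds)
        alt2 = None
        if label == "multiallelic":
            alt2 = TWO_BEAD[ref_base]  # any third allele
        hom_seen = 0
        for j, kind in enumerate(kinds):
            g = f"g{j}"
            this_alt = alt
            if alt2 is not None and kind == "HOM":
                hom_seen += 1
                if hom_seen % 2 == 0:
                    this_alt = alt2
            geno_calls[g].append((chrom, pos, ref_base, this_alt, kind))
        nm = n_g - m
        truth.allele_freq[snp_id] = (hom + 0.5 * h) / nm if nm else float("nan")
        design_scores[snp_id] = (
            float(rng.uniform(0.0, 0.55)) if label == "design_score"
            else float(rng.uniform(0.65, 1.0))
        )
        step = {
            "clean": None,
            "flanking": "flanking",
            "multiallelic": "multiallelic",
            "high_missing": "confidence",
            "high_het": "confidence",
            "freq_out": "confidence",
            "design_score": "design_score",
            "transversion": "transversion",
        }[label]
        truth.filter_truth[snp_id] = step
        truth.failure_mode[snp_id] = label

    for pos, label in zip(positions, labels):
        pos = int(pos)
        snp_id = f"{chrom}:{pos + 1}"
        plant_site(pos, label, snp_id)
        if label == "flanking":
            # contaminate both flanks with clean partner sites
            for off in (-40, 40):
                p2 = pos + off
                plant_site(p2, "clean", f"{chrom}:{p2 + 1}")

    platforms = [Platform.LONG_454, Platform.SHORT_ILLUMINA]
    variant_sets = []
    for j in range(n_g):
        g = f"g{j}"
        vs = GenotypeVariantSet(genotype_id=g, platform=platforms[j % 2])
        holes = []
        for c, pos, ref_base, alt, kind in geno_calls[g]:
            if kind == "MISSING":
                holes.append(pos)
            elif kind == "HET":
                vs.variants.append(VariantRecord(c, pos, ref_base, alt, _DEPTH, _HET_FRACTION))
            elif kind == "HOM":
                vs.variants.append(VariantRecord(c, pos, ref_base, alt, _DEPTH, _HOM_FRACTION))
        # coverage: whole chromosomes minus one-bp holes at missing sites
        intervals: dict[str, list[tuple[int, int]]] = {}
        holes = sorted(set(holes))
        prev = 0
        ivs = []
        for hpos in holes:
            if hpos > prev:
                ivs.append((prev, hpos))
            prev = hpos + 1
        ivs.append((prev, chrom_len))
        intervals[chrom] = ivs
        for other in reference.sequences:
            if other != chrom:
                intervals[other] = [(0, len(reference.sequences[other]))]
        vs.set_coverage(intervals)
        variant_sets.append(vs)
    return variant_sets, truth, design_scores


def write_vcf(vs: GenotypeVariantSet, reference: ReferenceGenome, path: str | Path) -> None:
    """Minimal single-sample VCF (uncompressed text) with INFO DP and AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, seq in reference.sequences.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(vs.variants, key=lambda v: (v.chrom, v.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"DP={v.depth};AF={v.alt_fraction:.4f}\n"
            )


def write_bed(vs: GenotypeVariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, (starts, ends) in vs.coverage.items():
            for s, e in zip(starts, ends):
                fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Intensity panels
# ---------------------------------------------------------------------------

_NO_SIGNAL_R = 0.05
_SIGNAL_R = 1.0


def simulate_intensities(
    config: SimConfig,
    species: Sequence[str] | None = None,
) -> tuple[IntensityMatrix, SimTruth]:
    """Theta/R clouds for each planted cluster-pattern class.

    ``species`` optionally tags each sample (NAPUS / OLERACEA / RAPA); a
    genome-specific assay targeting subgenome A yields no signal in the
    C-genome diploid (OLERACEA) and vice versa, emulating probe loss in the
    ancestral species.
    """
    mixture = config.class_mixture
    if abs(sum(mixture.values()) - 1.0) > 1e-9:
        raise ValueError("class mixture must sum to 1")
    rng = np.random.default_rng(config.seed + 2)
    truth = SimTruth()
    n_samples = config.n_samples
    sample_ids = [f"s{i}" for i in range(n_samples)]
    species = list(species) if species is not None else ["NAPUS"] * n_samples

    classes = list(mixture)
    n_per = {c: int(round(mixture[c] * config.n_snps)) for c in classes}
    # rounding remainder goes to the first class
    n_per[classes[0]] += config.n_snps - sum(n_per.values())
    labels = [c for c in classes for _ in range(n_per[c])]
    rng.shuffle(labels)

    sd = config.noise_sd
    rows = []
    for k, label in enumerate(labels):
        snp_id = f"snp{k:05d}"
        truth.pattern_truth[snp_id] = label
        target = "A" if rng.random() < 0.5 else "C"
        truth.target_subgenome[snp_id] = target
        theta = np.empty(n_samples)
        r = np.empty(n_samples)
        genos: dict[str, str] = {}

        if label in ("GENOME_SPECIFIC", "SHIFTED"):
            if label == "GENOME_SPECIFIC":
                means = {"AA": 0.03, "AB": 0.5, "BB": 0.97}
            else:
                base = rng.random() < 0.5  # compress into the lower or upper half
                means = (
                    {"AA": 0.04, "AB": 0.2, "BB": 0.38}
                    if base else {"AA": 0.62, "AB": 0.8, "BB": 0.96}
                )
            p = rng.uniform(0.3, 0.7)
            draws = rng.choice(
                ["AA", "AB", "BB"], size=n_samples,
                p=[(1 - p) ** 2, 2 * p * (1 - p), p**2],
            )
            for i, g in enumerate(draws):
                genos[sample_ids[i]] = g
                theta[i] = means[g] + rng.normal(0, sd)
                r[i] = rng.normal(_SIGNAL_R, 0.1)
        elif label == "MULTI_CLUSTER_UNRESOLVABLE":
            means = np.array([0.05, 0.27, 0.5, 0.73, 0.95])
            comp = rng.choice(5, size=n_samples, p=[0.08, 0.12, 0.6, 0.12, 0.08])
            theta = means[comp] + rng.normal(0, sd, n_samples)
            r = rng.normal(_SIGNAL_R, 0.1, n_samples)
        elif label == "PRESENCE_ABSENCE":
            present = rng.random(n_samples) < 0.7
            pos = 0.05 if rng.random() < 0.5 else 0.95
            theta = np.where(present, pos + rng.normal(0, sd, n_samples),
                             rng.uniform(0, 1, n_samples))
            r = np.where(present, rng.normal(_SIGNAL_R, 0.1, n_samples),
                         rng.uniform(0.0, _NO_SIGNAL_R, n_samples))
            for i in range(n_samples):
                genos[sample_ids[i]] = (
                    ("AA" if pos <= 0.5 else "BB") if present[i]
                    else ("BB" if pos <= 0.5 else "AA")
                )
        elif label == "MONOMORPHIC":
            pos = rng.choice([0.08, 0.92])
            theta = pos + rng.normal(0, sd, n_samples)
            r = rng.normal(_SIGNAL_R, 0.1, n_samples)
        elif label == "FAILED_LOW_INTENSITY":
            theta = rng.uniform(0, 1, n_samples)
            r = rng.uniform(0.0, _NO_SIGNAL_R, n_samples)
        else:
            raise ValueError(f"unknown pattern class {label!r}")

        # species-dependent loss for genome-specific probes
        if label == "GENOME_SPECIFIC":
            dead_species = "OLERACEA" if target == "A" else "RAPA"
            for i, sp in enumerate(species):
                if sp == dead_species:
                    r[i] = float(rng.uniform(0.0, _NO_SIGNAL_R))

        # fold boundary noise back into [0, 1]: the polar transform compresses
        # clouds against the theta rails rather than truncating them, and a
        # hard clip would plant artificial point masses at 0 and 1
        theta = np.abs(theta)
        theta = 1.0 - np.abs(1.0 - theta)
        r = np.maximum(r, 0.0)
        if genos:
            truth.genotype_truth[snp_id] = genos
        for i in range(n_samples):
            rows.append((snp_id, sample_ids[i], theta[i], r[i]))

    data = pd.DataFrame(rows, columns=["snp_id", "sample_id", "theta", "R"])
    return IntensityMatrix(data, dict(zip(sample_ids, species))), truth


# ---------------------------------------------------------------------------
# Doubled-haploid populations
# ---------------------------------------------------------------------------

def simulate_dh(
    config: SimConfig,
    lg_to_chrom: dict[str, str] | None = None,
    kb_per_cm: float = 400.0,
) -> tuple[DHGenotypeMatrix, GeneticMap, dict[str, PhysicalAnchor], SimTruth]:
    """DH population from true per-LG marker positions.

    Crossovers are placed per line without interference: the allele flips
    between adjacent markers with probability equal to the inverse Kosambi
    of the true interval length. Planted homoeologous swaps move a marker's
    physical anchor to the homoeologous chromosome; planted translocated
    blocks move a run of adjacent markers to an unrelated chromosome.
    """
    rng = np.random.default_rng(config.seed + 3)
    truth = SimTruth()
    lg_to_chrom = lg_to_chrom or {
        lg: f"A{i + 1}" for i, lg in enumerate(config.lg_maps)
    }
    n_lg = len(config.lg_maps)
    homoeo = HomoeologyTable.numbered(19)  # default A1..A19 <-> C1..C19 pairs

    marker_order: dict[str, list[str]] = {}
    map_rows = []
    columns: dict[str, np.ndarray] = {}
    anchors: dict[str, PhysicalAnchor] = {}
    for lg, cms in config.lg_maps.items():
        if len(cms) < 2:
            raise ValueError("each linkage group needs >= 2 markers")
        if any(b < a for a, b in zip(cms, cms[1:])) or cms[0] < 0:
            raise ValueError("map positions must be non-negative and sorted")
        markers = [f"{lg}_m{i}" for i in range(len(cms))]
        marker_order[lg] = markers
        chrom = lg_to_chrom[lg]
        rs = [kosambi_inverse(b - a) for a, b in zip(cms, cms[1:])]
        alleles = np.empty((config.n_lines, len(markers)), dtype="<U1")
        alleles[:, 0] = np.where(rng.random(config.n_lines) < 0.5, "A", "B")
        recombined = []
        for j, r in enumerate(rs):
            flip = rng.random(config.n_lines) < r
            prev = alleles[:, j]
            alleles[:, j + 1] = np.where(
                flip, np.where(prev == "A", "B", "A"), prev
            )
            recombined.append(bool(flip.any()))
        truth.recombined_pairs[lg] = recombined
        for i, m in enumerate(markers):
            columns[m] = alleles[:, i]
            map_rows.append({"marker": m, "lg": lg, "cm": float(cms[i])})
            anchors[m] = PhysicalAnchor(
                m, chrom, int(cms[i] * kb_per_cm * 1000), 99.0
            )

    # planted homoeologous swaps
    all_markers = [m for ms in marker_order.values() for m in ms]
    n_swap = int(round(config.homoeologous_swap_fraction * len(all_markers)))
    swap_ids = list(rng.choice(all_markers, size=n_swap, replace=False)) if n_swap else []
    for m in swap_ids:
        a = anchors[m]
        anchors[m] = PhysicalAnchor(m, homoeo.homoeolog(a.chrom), a.bp, a.identity)
    truth.swapped_markers = [str(m) for m in swap_ids]

    # planted translocated blocks: runs of 4 adjacent markers moved to an
    # unrelated chromosome (neither expected nor homoeologous)
    chroms = sorted({c for c in lg_to_chrom.values()}) + [
        homoeo.homoeolog(c) for c in lg_to_chrom.values()
    ]
    block_len = 4
    for b in range(config.translocated_blocks):
        lg = list(marker_order)[b % n_lg]
        ms = [m for m in marker_order[lg] if m not in swap_ids]
        if len(ms) < block_len + 2:
            continue
        start = int(rng.integers(1, len(ms) - block_len))
        block = ms[start:start + block_len]
        own = lg_to_chrom[lg]
        candidates = [c for c in chroms if c not in (own, homoeo.homoeolog(own))]
        dest = candidates[b % len(candidates)] if candidates else own
        for m in block:
            a = anchors[m]
            anchors[m] = PhysicalAnchor(m, dest, a.bp, a.identity)
        truth.translocated.append(
            {"lg": lg, "markers": block, "dest_chrom": dest}
        )

    data = pd.DataFrame(columns, index=[f"line{i}" for i in range(config.n_lines)])
    if config.dh_missing_rate > 0:
        mask = rng.random(data.shape) < config.dh_missing_rate
        arr = data.to_numpy()
        arr[mask] = "-"
        data = pd.DataFrame(arr, index=data.index, columns=data.columns)
    matrix = DHGenotypeMatrix(data, marker_order)
    true_map = GeneticMap(pd.DataFrame(map_rows))
    truth.true_map = true_map.table
    truth.true_anchors = anchors
    return matrix, true_map, anchors, truth


def write_dh_matrix(matrix: DHGenotypeMatrix, path: str | Path, order_path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t")
    rows = [
        {"marker": m, "lg": lg}
        for lg, ms in matrix.marker_order.items()
        for m in ms
    ]
    pd.DataFrame(rows).to_csv(order_path, sep="\t", index=False)
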