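"""Cross-panel aggregation of per-genotype variant calls.

Combines independent per-genotype variant calls and coverage intervals over a
shared (allotetraploid) reference into one summary matrix: one row per
candidate SNP site, one column per genotype, each cell a missing / reference /
heterozygous / homozygous-variant call, plus per-site panel statistics
(missing fraction, heterozygote fraction, alternate-allele frequency) that
drive downstream assay-design filters.

Coordinates are 0-based half-open internally; VCF positions are converted at
the I/O boundary.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


class Platform(Enum):
    """Sequencing platform of a genotype's read data (sets the depth minimum)."""

    LONG_454 = "LONG_454"
    SHORT_ILLUMINA = "SHORT_ILLUMINA"


class CallKind(Enum):
    MISSING = "MISSING"
    REFERENCE = "REFERENCE"
    HET = "HET"
    HOM_VARIANT = "HOM_VARIANT"


@dataclass(frozen=True)
class SiteCall:
    """A single genotype's call at one site.

    ``alleles`` is empty for MISSING, ``(ref,)`` for REFERENCE, ``(ref, alt)``
    for HET and ``(alt,)`` for HOM_VARIANT.
    """

    kind: CallKind
    alleles: tuple[str, ...] = ()
    depth: int = 0
    alt_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind is CallKind.MISSING and self.alleles:
            raise ValueError("MISSING call carries no alleles")
        if self.kind is CallKind.HET and len(set(self.alleles)) != 2:
            raise ValueError("HET call requires two distinct alleles")

    @property
    def is_variant(self) -> bool:
        return self.kind in (CallKind.HET, CallKind.HOM_VARIANT)


@dataclass(frozen=True)
class DepthThresholds:
    """Depth minima per platform and the within-genotype heterozygote band.

    A variant observation whose alternate-read fraction falls inside
    ``het_band`` (inclusive) is called heterozygous; above it, homozygous
    variant; below it, reference.
    """

    min_depth_long_454: int = 3
    min_depth_short_illumina: int = 8
    het_band: tuple[float, float] = (0.2, 0.8)

    def __post_init__(self) -> None:
        if self.min_depth_long_454 < 1 or self.min_depth_short_illumina < 1:
            raise ValueError("depth minima must be >= 1")
        lo, hi = self.het_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("het band must satisfy 0 <= lo < hi <= 1")

    def min_depth(self, platform: Platform) -> int:
        if platform is Platform.LONG_454:
            return self.min_depth_long_454
        if platform is Platform.SHORT_ILLUMINA:
            return self.min_depth_short_illumina
        raise ValueError(f"unknown platform {platform!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One raw variant observation in one genotype (0-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_fraction: float


@dataclass
class GenotypeVariantSet:
    """All variant observations and covered intervals for one genotype."""

    genotype_id: str
    platform: Platform
    variants: list[VariantRecord] = field(default_factory=list)
    # chrom -> sorted array pairs (starts, ends), half-open 0-based
    coverage: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def set_coverage(self, intervals: Mapping[str, Sequence[tuple[int, int]]]) -> None:
        """Normalise intervals per chromosome: sort and merge overlaps."""
        self.coverage = {}
        for chrom, ivs in intervals.items():
            merged: list[list[int]] = []
            for s, e in sorted(ivs):
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self.coverage[chrom] = (starts, ends)

    def is_covered(self, chrom: str, pos: int) -> bool:
        if chrom not in self.coverage:
            return False
        starts, ends = self.coverage[chrom]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus a subgenome tag per chromosome."""

    sequences: dict[str, str]
    subgenome: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"chromosome {name} has invalid bases {bad}")
        missing = set(self.sequences) - set(self.subgenome)
        if missing:
            raise ValueError(f"chromosomes without subgenome tag: {missing}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def base(self, chrom: str, pos: int) -> str:
        return self.sequences[chrom][pos]


def build_site_call(
    variant: VariantRecord | None,
    covered: bool,
    platform: Platform,
    thresholds: DepthThresholds,
    ref_allele: str | None = None,
) -> SiteCall:
    """Classify one genotype at one site as MISSING / REFERENCE / HET / HOM_VARIANT.

    MISSING if the site is uncovered, or a variant observation is below the
    platform depth minimum. With adequate coverage and no variant record the
    call is REFERENCE. A variant observation is classified by its
    alternate-read fraction against the het band.
    """
    min_depth = thresholds.min_depth(platform)
    if variant is None:
        if not covered:
            return SiteCall(CallKind.MISSING)
        ref = (ref_allele,) if ref_allele else ()
        return SiteCall(CallKind.REFERENCE, alleles=ref)
    if not covered or variant.depth < min_depth:
        return SiteCall(CallKind.MISSING)
    lo, hi = thresholds.het_band
    f = variant.alt_fraction
    if f < lo:
        return SiteCall(
            CallKind.REFERENCE, alleles=(variant.ref,), depth=variant.depth, alt_fraction=f
        )
    if f <= hi:
        return SiteCall(
            CallKind.HET, alleles=(variant.ref, variant.alt), depth=variant.depth, alt_fraction=f
        )
    return SiteCall(
        CallKind.HOM_VARIANT, alleles=(variant.alt,), depth=variant.depth, alt_fraction=f
    )


def panel_stats(
    calls: Iterable[SiteCall], het_alt_weight: float = 0.5
) -> tuple[float, float, float]:
    """Per-site panel statistics over the genotype columns.

    Returns (missing fraction, het fraction among non-missing, alternate-allele
    frequency among non-missing calls with HET contributing ``het_alt_weight``).
    When every call is missing the frequency is NaN (sentinel), never an
    exception.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("panel_stats needs at least one genotype column")
    n = len(calls)
    n_missing = sum(c.kind is CallKind.MISSING for c in calls)
    non_missing = n - n_missing
    missing_frac = n_missing / n
    if non_missing == 0:
        return missing_frac, 0.0, float("nan")
    n_het = sum(c.kind is CallKind.HET for c in calls)
    n_hom_alt = sum(c.kind is CallKind.HOM_VARIANT for c in calls)
    het_frac = n_het / non_missing
    alt_freq = (n_hom_alt + het_alt_weight * n_het) / non_missing
    return missing_frac, het_frac, alt_freq


@dataclass
class SNPSummaryMatrix:
    """Cross-genotype call matrix for candidate SNP sites.

    ``sites`` is a DataFrame indexed by row with columns chrom, pos (0-based),
    ref, alts (tuple), missing_frac, het_frac, alt_freq, ref_mismatch;
    ``calls[genotype_id]`` is the parallel list of SiteCall per row.
    """

    sites: pd.DataFrame
    calls: dict[str, list[SiteCall]]
    genotype_ids: list[str]

    def __len__(self) -> int:
        return len(self.sites)

    def row_calls(self, i: int) -> dict[str, SiteCall]:
        return {g: self.calls[g][i] for g in self.genotype_ids}

    def variant_positions(self) -> dict[str, np.ndarray]:
        """All candidate positions per chromosome (used by flank screening)."""
        out: dict[str, np.ndarray] = {}
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            out[str(chrom)] = np.sort(grp["pos"].to_numpy())
        return out


def aggregate_panel(
    variant_sets: Sequence[GenotypeVariantSet],
    reference: ReferenceGenome,
    thresholds: DepthThresholds | None = None,
    het_alt_weight: float = 0.5,
) -> SNPSummaryMatrix:
    """Combine per-genotype variant sets into a cross-panel summary matrix.

    Emits one row per site carrying at least one (post-threshold) variant call
    in at least one genotype, sorted by (chromosome, position). A variant
    record whose stated reference allele disagrees with the reference genome
    is retained with a warning flag on the row.
    """
    thresholds = thresholds or DepthThresholds()
    ids = [vs.genotype_id for vs in variant_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("genotype ids must be unique")

    # index variants per genotype by (chrom, pos)
    by_site: dict[tuple[str, int], dict[str, VariantRecord]] = {}
    for vs in variant_sets:
        for v in vs.variants:
            if v.chrom not in reference.sequences:
                raise ValueError(f"variant chromosome {v.chrom} not in reference")
            by_site.setdefault((v.chrom, v.pos), {})[vs.genotype_id] = v

    rows = []
    calls: dict[str, list[SiteCall]] = {g: [] for g in ids}
    for chrom, pos in sorted(by_site):
        site_variants = by_site[(chrom, pos)]
        ref_base = reference.base(chrom, pos)
        mismatch = any(v.ref != ref_base for v in site_variants.values())
        if mismatch:
            warnings.warn(
                f"reference allele disagreement at {chrom}:{pos + 1}; row retained",
                stacklevel=2,
            )
        site_calls: dict[str, SiteCall] = {}
        for vs in variant_sets:
            v = site_variants.get(vs.genotype_id)
            covered = vs.is_covered(chrom, pos)
            site_calls[vs.genotype_id] = build_site_call(
                v, covered, vs.platform, thresholds, ref_allele=ref_base
            )
        if not any(c.is_variant for c in site_calls.values()):
            continue
        alts = tuple(
            sorted(
                {
                    a
                    for c in site_calls.values()
                    if c.is_variant
                    for a in c.alleles
                    if a != ref_base
                }
            )
        )
        miss, het, freq = panel_stats(site_calls.values(), het_alt_weight)
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref_base,
                "alts": alts,
                "missing_frac": miss,
                "het_frac": het,
                "alt_freq": freq,
                "ref_mismatch": mismatch,
            }
        )
        for g in ids:
            calls[g].append(site_calls[g])

    sites = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "ref",
            "alts",
            "missing_frac",
            "het_frac",
            "alt_freq",
            "ref_mismatch",
        ],
    )
    return SNPSummaryMatrix(sites=sites, calls=calls, genotype_ids=ids)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CALL_CODES = {
    CallKind.MISSING: "./.",
    CallKind.REFERENCE: "0/0",
    CallKind.HET: "0/1",
    CallKind.HOM_VARIANT: "1/1",
}


def read_reference(fasta_path: str | Path, subgenome_tsv: str | Path) -> ReferenceGenome:
    """Load a reference FASTA plus its `chrom<TAB>subgenome` sidecar."""
    seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    tags = pd.read_csv(
        subgenome_tsv, sep="\t", header=None, names=["chrom", "subgenome"], dtype=str
    )
    return ReferenceGenome(seqs, dict(zip(tags["chrom"], tags["subgenome"])))


def read_bed_intervals(bed_path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(bed_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.setdefault(chrom, []).append((int(start), int(end)))
    return out


def read_genotype_vcf(
    vcf_path: str | Path,
    bed_path: str | Path,
    genotype_id: str,
    platform: Platform,
) -> GenotypeVariantSet:
    """Load one genotype's variant calls (VCF) and coverage (BED).

    Depth is taken from INFO/DP, the alternate fraction from INFO/AF or from
    AD-style allele depths when AF is absent. Only SNV records are kept.
    """
    from cyvcf2 import VCF

    vs = GenotypeVariantSet(genotype_id=genotype_id, platform=platform)
    for rec in VCF(str(vcf_path)):
        if not rec.ALT or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            continue
        depth = int(rec.INFO.get("DP", 0))
        af = rec.INFO.get("AF")
        if af is None:
            ad = rec.INFO.get("AD")
            if ad is not None:
                ad = ad if isinstance(ad, tuple) else (ad,)
                total = sum(ad)
                af = ad[1] / total if total > 0 and len(ad) > 1 else 0.0
            else:
                af = 0.0
        af = float(af[0]) if isinstance(af, tuple) else float(af)
        vs.variants.append(
            VariantRecord(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0], depth, af)
        )
    vs.set_coverage(read_bed_intervals(bed_path))
    return vs


def write_summary_matrix(matrix: SNPSummaryMatrix, path: str | Path) -> None:
    """Write the matrix as gzip TSV with the fixed header
    `chrom pos ref alts <genotype columns> missing_frac het_frac alt_freq`
    (positions written 1-based)."""
    df = matrix.sites.copy()
    df["pos"] = df["pos"] + 1
    df["alts"] = [",".join(a) for a in df["alts"]]
    for g in matrix.genotype_ids:
        df[g] = [_CALL_CODES[c.kind] for c in matrix.calls[g]]
    cols = ["chrom", "pos", "ref", "alts", *matrix.genotype_ids,
            "missing_frac", "het_frac", "alt_freq"]
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        df[cols].to_csv(fh, sep="\t", index=False)
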