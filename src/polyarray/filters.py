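"""Five-step candidate-SNP filter cascade with an attrition report.

The cascade mirrors the standard array-design funnel for a duplicated genome:
(1) require a clean 60-bp flank on at least one side of the SNP, (2) drop
multi-allelic sites, (3) drop low-confidence sites (too much missing data,
excess heterozygosity, or a panel allele frequency outside the retention
band), (4) drop sites with a low externally supplied design score, and
(5) drop transversion SNPs that require two-bead assays. Each step is an
independent predicate, so the survivor set is invariant under step
permutation; only the attribution of a failure to its first failing step
depends on the order.

All threshold inequalities are strict ("greater than 70 %", "less than 0.6"),
so exact-boundary candidates are retained.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .aggregate import ReferenceGenome, SNPSummaryMatrix


class TransversionMode(Enum):
    # exclude only the allele pairs that need Infinium I two-bead assays
    AT_CG_ONLY = "at_cg_only"
    # literal reading: exclude every purine<->pyrimidine pair
    ALL_TRANSVERSIONS = "all_transversions"


TRANSITIONS = ({"A", "G"}, {"C", "T"})
INFINIUM_I_PAIRS = ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class FilterThresholds:
    flank_length: int = 60
    max_alleles: int = 2
    max_missing: float = 0.70
    max_het: float = 0.40
    freq_band: tuple[float, float] = (0.2, 0.8)
    min_design_score: float = 0.6
    transversion_mode: TransversionMode = TransversionMode.AT_CG_ONLY
    missing_score_fails: bool = True

    def __post_init__(self) -> None:
        if self.flank_length < 1:
            raise ValueError("flank length must be >= 1")
        lo, hi = self.freq_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("frequency band must satisfy 0 <= lo < hi <= 1")
        for v in (self.max_missing, self.max_het, self.min_design_score):
            if not 0.0 <= v <= 1.0:
                raise ValueError("fractional thresholds must lie in [0, 1]")


@dataclass
class CandidateSNP:
    """One candidate assay site with its flank annotation and panel stats."""

    snp_id: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alts: tuple[str, ...]
    flank_up: str = ""
    flank_down: str = ""
    up_clean: bool = False
    down_clean: bool = False
    missing_frac: float = 0.0
    het_frac: float = 0.0
    alt_freq: float = float("nan")
    design_score: float | None = None

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alts)

    @property
    def allele_pair(self) -> set[str]:
        return {self.ref, self.alts[0]} if self.alts else {self.ref}


@dataclass
class FilterReport:
    """Ordered per-step attrition: (step name, excluded, remaining)."""

    initial_count: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, excluded: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.initial_count
        self.steps.append((name, excluded, prev - excluded))

    @property
    def final_count(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial_count

    def check_telescoping(self) -> bool:
        prev = self.initial_count
        for _, excl, remaining in self.steps:
            if remaining != prev - excl or remaining < 0:
                return False
            prev = remaining
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = [("none", 0, self.initial_count)] + self.steps
        return pd.DataFrame(rows, columns=["step", "excluded", "remaining"])


def annotate_flanks(
    matrix: SNPSummaryMatrix,
    reference: ReferenceGenome,
    flank_length: int = 60,
) -> list[CandidateSNP]:
    """Attach flank sequences and per-side clean flags to every matrix row.

    A side is clean iff its full-length window fits on the chromosome,
    contains no N, and contains no other candidate position from the complete
    pre-filter site set. Truncated flanks are simply unclean, never an error.
    """
    positions = matrix.variant_positions()
    out: list[CandidateSNP] = []
    for i, row in matrix.sites.iterrows():
        chrom, pos = row["chrom"], int(row["pos"])
        seq = reference.sequences[chrom]
        neighbours = positions[chrom]
        up_start = pos - flank_length
        down_end = pos + 1 + flank_length
        flank_up = seq[max(up_start, 0):pos]
        flank_down = seq[pos + 1:down_end]

        def window_clean(lo: int, hi: int, flank: str, full: int) -> bool:
            if len(flank) < full or "N" in flank:
                return False
            # any other panel variant inside [lo, hi)?
            j = int(np.searchsorted(neighbours, lo, side="left"))
            k = int(np.searchsorted(neighbours, hi, side="left"))
            inside = neighbours[j:k]
            return not any(p != pos for p in inside)

        up_clean = window_clean(up_start, pos, flank_up, flank_length)
        down_clean = window_clean(pos + 1, down_end, flank_down, flank_length)
        out.append(
            CandidateSNP(
                snp_id=f"{chrom}:{pos + 1}",
                chrom=chrom,
                pos=pos,
                ref=row["ref"],
                alts=tuple(row["alts"]),
                flank_up=flank_up,
                flank_down=flank_down,
                up_clean=up_clean,
                down_clean=down_clean,
                missing_frac=float(row["missing_frac"]),
                het_frac=float(row["het_frac"]),
                alt_freq=float(row["alt_freq"]),
            )
        )
    return out


# --- individual step predicates (True = candidate passes) -------------------

def passes_flanking(c: CandidateSNP, t: FilterThresholds) -> bool:
    return c.up_clean or c.down_clean


def passes_multiallelic(c: CandidateSNP, t: FilterThresholds) -> bool:
    return len(set(c.alleles)) <= t.max_alleles


def passes_confidence(c: CandidateSNP, t: FilterThresholds) -> bool:
    if math.isnan(c.alt_freq):
        return False
    lo, hi = t.freq_band
    return (
        c.missing_frac <= t.max_missing
        and c.het_frac <= t.max_het
        and lo <= c.alt_freq <= hi
    )


def passes_design_score(c: CandidateSNP, t: FilterThresholds) -> bool:
    if c.design_score is None:
        return not t.missing_score_fails
    return c.design_score >= t.min_design_score


def passes_transversion(c: CandidateSNP, t: FilterThresholds) -> bool:
    pair = c.allele_pair
    if len(pair) != 2:
        return True
    if t.transversion_mode is TransversionMode.AT_CG_ONLY:
        return pair not in INFINIUM_I_PAIRS
    return pair in TRANSITIONS


STEP_PREDICATES: dict[str, Callable[[CandidateSNP, FilterThresholds], bool]] = {
    "flanking": passes_flanking,
    "multiallelic": passes_multiallelic,
    "confidence": passes_confidence,
    "design_score": passes_design_score,
    "transversion": passes_transversion,
}

DEFAULT_STEP_ORDER = ("flanking", "multiallelic", "confidence", "design_score", "transversion")


def apply_filter(
    candidates: Sequence[CandidateSNP], step: str, thresholds: FilterThresholds
) -> tuple[list[CandidateSNP], list[CandidateSNP]]:
    """Split candidates into (pass, fail) under one named step."""
    pred = STEP_PREDICATES[step]
    passed, failed = [], []
    for c in candidates:
        (passed if pred(c, thresholds) else failed).append(c)
    return passed, failed


def filter_flanking(candidates, thresholds=FilterThresholds()):
    return apply_filter(candidates, "flanking", thresholds)


def filter_multiallelic(candidates, thresholds=FilterThresholds()):
    return apply_filter(candidates, "multiallelic", thresholds)


def filter_confidence(candidates, thresholds=FilterThresholds()):
    return apply_filter(candidates, "confidence", thresholds)


def filter_design_score(candidates, thresholds=FilterThresholds()):
    return apply_filter(candidates, "design_score", thresholds)


def filter_transversion(candidates, thresholds=FilterThresholds()):
    return apply_filter(candidates, "transversion", thresholds)


def run_cascade(
    candidates: Sequence[CandidateSNP],
    thresholds: FilterThresholds | None = None,
    step_order: Sequence[str] = DEFAULT_STEP_ORDER,
) -> tuple[FilterReport, list[CandidateSNP]]:
    """Run all five steps in order; attribute each failure to its first step."""
    thresholds = thresholds or FilterThresholds()
    if sorted(step_order) != sorted(DEFAULT_STEP_ORDER):
        raise ValueError("step order must be a permutation of the five steps")
    report = FilterReport(initial_count=len(candidates))
    current = list(candidates)
    for step in step_order:
        current, failed = apply_filter(current, step, thresholds)
        report.add(step, len(failed))
    return report, current


def first_failed_step(
    c: CandidateSNP,
    thresholds: FilterThresholds | None = None,
    step_order: Sequence[str] = DEFAULT_STEP_ORDER,
) -> str | None:
    """Name of the first step this candidate fails, or None if it survives."""
    thresholds = thresholds or FilterThresholds()
    for step in step_order:
        if not STEP_PREDICATES[step](c, thresholds):
            return step
    return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def attach_design_scores(
    candidates: Sequence[CandidateSNP], scores: pd.DataFrame | dict[str, float]
) -> None:
    """Attach an external `snp_id -> score` column (e.g. an assay-design score)."""
    if isinstance(scores, pd.DataFrame):
        scores = dict(zip(scores.iloc[:, 0].astype(str), scores.iloc[:, 1].astype(float)))
    for c in candidates:
        c.design_score = scores.get(c.snp_id, c.design_score)


def read_design_scores(path: str | Path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "score"])
    return dict(zip(df["snp_id"].astype(str), df["score"].astype(float)))


def write_survivors(candidates: Sequence[CandidateSNP], path: str | Path) -> None:
    rows = [
        {
            "snp_id": c.snp_id,
            "chrom": c.chrom,
            "pos": c.pos + 1,
            "ref": c.ref,
            "alts": ",".join(c.alts),
            "up_clean": c.up_clean,
            "down_clean": c.down_clean,
            "missing_frac": c.missing_frac,
            "het_frac": c.het_frac,
            "alt_freq": c.alt_freq,
            "design_score": "" if c.design_score is None else c.design_score,
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_report(report: FilterReport, path: str | Path) -> None:
    report.to_frame().to_csv(path, index=False)
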