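"""Probe extraction, genome-wide match counting, and SNP selection.

An Infinium assay hybridises a single 50-bp probe adjacent to the SNP; in a
duplicated genome a probe may hybridise at several near-identical loci. A
probe is counted as matching a genomic locus when the two share an exact
(gapless, mismatch-free) common substring of at least ``min_run`` consecutive
base pairs (default 35) on either strand; overlapping hits are merged into
one locus. SNPs are then ranked by their best probe's match count and those
with fewer matches preferentially selected.

The probe excludes the SNP base itself (single-base-extension chemistry
interrogates the base immediately 3' of the probe).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import pandas as pd

from .aggregate import ReferenceGenome
from .filters import INFINIUM_I_PAIRS, CandidateSNP

PROBE_LENGTH = 50

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class Side(Enum):
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"


class AssayClass(Enum):
    INFINIUM_II = "INFINIUM_II"  # one bead, two-colour extension
    INFINIUM_I = "INFINIUM_I"    # A/T and C/G SNPs: two allele-specific beads


@dataclass
class ProbeAssay:
    snp_id: str
    probe_seq: str
    side: Side
    strand: str  # strand of design relative to the reference ('+' or '-')
    assay_class: AssayClass
    match_count: int = 0
    design_score: float | None = None

    def __post_init__(self) -> None:
        if len(self.probe_seq) != PROBE_LENGTH:
            raise ValueError(f"probe must be {PROBE_LENGTH} bp, got {len(self.probe_seq)}")


def assay_class_for(allele_pair: set[str]) -> AssayClass:
    return AssayClass.INFINIUM_I if allele_pair in INFINIUM_I_PAIRS else AssayClass.INFINIUM_II


def extract_probes(candidate: CandidateSNP, reference: ReferenceGenome) -> list[ProbeAssay]:
    """One probe per clean flank side of sufficient length.

    The upstream probe is the 50 bp immediately 5' of the SNP on the
    reference strand. The downstream probe is the reverse complement of the
    50 bp immediately 3', so that in both cases the probe's 3' end abuts the
    SNP base.
    """
    seq = reference.sequences[candidate.chrom]
    pos = candidate.pos
    klass = assay_class_for(candidate.allele_pair)
    probes: list[ProbeAssay] = []
    if candidate.up_clean and pos >= PROBE_LENGTH:
        probes.append(
            ProbeAssay(
                snp_id=candidate.snp_id,
                probe_seq=seq[pos - PROBE_LENGTH:pos],
                side=Side.UPSTREAM,
                strand="+",
                assay_class=klass,
                design_score=candidate.design_score,
            )
        )
    if candidate.down_clean and pos + 1 + PROBE_LENGTH <= len(seq):
        probes.append(
            ProbeAssay(
                snp_id=candidate.snp_id,
                probe_seq=revcomp(seq[pos + 1:pos + 1 + PROBE_LENGTH]),
                side=Side.DOWNSTREAM,
                strand="-",
                assay_class=klass,
                design_score=candidate.design_score,
            )
        )
    return probes


def _hit_intervals(probe: str, chrom_seq: str, min_run: int) -> list[tuple[int, int]]:
    """Genomic intervals whose min_run-mer occurs in probe (one strand pair).

    Checks the probe and its reverse complement, so hits on both strands land
    in reference coordinates.
    """
    kmers = {probe[i:i + min_run] for i in range(len(probe) - min_run + 1)}
    rc = revcomp(probe)
    kmers |= {rc[i:i + min_run] for i in range(len(rc) - min_run + 1)}
    hits = []
    for s in range(len(chrom_seq) - min_run + 1):
        if chrom_seq[s:s + min_run] in kmers:
            hits.append((s, s + min_run))
    return hits


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def count_probe_matches(
    probe_seq: str, reference: ReferenceGenome, min_run: int = 35
) -> int:
    """Number of distinct genomic loci matching the probe under the min-run rule.

    A locus matches when it shares an exact common substring of length >=
    ``min_run`` with the probe, on either strand. Overlapping hit windows
    (and coincident hits on opposite strands) merge into a single locus.
    The source locus itself is included, so a designable probe returns >= 1.
    """
    if set(probe_seq) - set("ACGT"):
        raise ValueError("probe contains non-ACGT bases; undesignable")
    if min_run > len(probe_seq):
        raise ValueError("min_run exceeds probe length")
    count = 0
    for chrom_seq in reference.sequences.values():
        count += len(_merge(_hit_intervals(probe_seq, chrom_seq, min_run)))
    return count


def count_matches_for_candidates(
    assays: Sequence[ProbeAssay],
    reference: ReferenceGenome,
    min_run: int = 35,
    per_snp: str = "min",
) -> dict[str, int]:
    """Per-SNP match count over that SNP's candidate probes.

    ``per_snp='min'`` takes the best (fewest-match) side, matching the design
    practice of picking the most specific probe; ``'max'`` is the
    conservative alternative.
    """
    agg = min if per_snp == "min" else max
    counts: dict[str, int] = {}
    for a in assays:
        a.match_count = count_probe_matches(a.probe_seq, reference, min_run)
        if a.snp_id in counts:
            counts[a.snp_id] = agg(counts[a.snp_id], a.match_count)
        else:
            counts[a.snp_id] = a.match_count
    return counts


@dataclass(frozen=True)
class SelectionPolicy:
    """How many SNPs to admit per probe-match-count class.

    ``max_match_count`` caps admissible counts (the published design admitted
    only unique and twice-matching probes); ``quota`` limits how many SNPs of
    a given count class are taken (None = unlimited). Ties break on higher
    design score, then lexicographic SNP id.
    """

    max_match_count: int = 2
    quota: dict[int, int | None] | None = None

    def class_quota(self, count: int) -> int | None:
        if self.quota is None:
            return None
        return self.quota.get(count)


def rank_and_select(
    assays: Sequence[ProbeAssay], policy: SelectionPolicy | None = None
) -> list[ProbeAssay]:
    """Select SNPs preferring the fewest genome-wide probe matches.

    Each SNP contributes its best (lowest match count) probe; SNPs are sorted
    ascending by match count with deterministic tie-breaking, then the count
    cap and per-class quotas are applied.
    """
    policy = policy or SelectionPolicy()
    best: dict[str, ProbeAssay] = {}
    for a in assays:
        cur = best.get(a.snp_id)
        if cur is None or a.match_count < cur.match_count:
            best[a.snp_id] = a
    ranked = sorted(
        best.values(),
        key=lambda a: (
            a.match_count,
            -(a.design_score if a.design_score is not None else 0.0),
            a.snp_id,
        ),
    )
    selected: list[ProbeAssay] = []
    taken_per_class: dict[int, int] = {}
    for a in ranked:
        if a.match_count > policy.max_match_count:
            continue
        q = policy.class_quota(a.match_count)
        n = taken_per_class.get(a.match_count, 0)
        if q is not None and n >= q:
            continue
        taken_per_class[a.match_count] = n + 1
        selected.append(a)
    return selected


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_probe_table(assays: Sequence[ProbeAssay], path: str | Path) -> None:
    rows = [
        {
            "snp_id": a.snp_id,
            "side": a.side.value,
            "strand": a.strand,
            "probe_seq": a.probe_seq,
            "assay_class": a.assay_class.value,
            "match_count": a.match_count,
        }
        for a in assays
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_probe_table(path: str | Path) -> list[ProbeAssay]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProbeAssay(
            snp_id=str(r.snp_id),
            probe_seq=r.probe_seq,
            side=Side(r.side),
            strand=r.strand,
            assay_class=AssayClass(r.assay_class),
            match_count=int(r.match_count),
        )
        for r in df.itertuples()
    ]


def read_alignment_hits(path: str | Path, fmt: str = "paf") -> pd.DataFrame:
    """Read pre-computed probe alignments (PAF or PSL) as an alternative to
    internal counting. Returns columns query, chrom, start, end, identity."""
    rows = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if not f or not f[0] or f[0].startswith("#"):
                continue
            if fmt == "paf":
                matches, aln_len = int(f[9]), int(f[10])
                rows.append(
                    {
                        "query": f[0],
                        "chrom": f[5],
                        "start": int(f[7]),
                        "end": int(f[8]),
                        "identity": 100.0 * matches / aln_len if aln_len else 0.0,
                    }
                )
            elif fmt == "psl":
                matches, mismatches = int(f[0]), int(f[1])
                total = matches + mismatches
                rows.append(
                    {
                        "query": f[9],
                        "chrom": f[13],
                        "start": int(f[15]),
                        "end": int(f[16]),
                        "identity": 100.0 * matches / total if total else 0.0,
                    }
                )
            else:
                raise ValueError(f"unknown alignment format {fmt!r}")
    return pd.DataFrame(rows, columns=["query", "chrom", "start", "end", "identity"])
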