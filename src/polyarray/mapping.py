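"""Genetic maps from doubled-haploid populations and physical concordance.

A doubled-haploid (DH) population carries no heterozygotes, so each marker is
a binary vector over lines and the recombinant fraction between two markers
is simply the discordant-line fraction. Markers with no observed
recombination between them collapse into bins; distances come from the
Kosambi mapping function d = 25*ln((1+2r)/(1-2r)) cM. Markers are anchored
physically from alignment hits (best hit at >= 85 % identity), genetic and
physical positions are reconciled per marker (concordant / homoeologous /
discordant / unanchored), and runs of markers anchored to the same wrong
chromosome are reported as rearranged segments.

``PUBLISHED_MAP_SUMMARY`` holds the per-linkage-group summary of a published
Brassica napus DH map (bins, positioned loci, physical length, mapped loci,
map length) used as a worked example for the density statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "-"


# ---------------------------------------------------------------------------
# Kosambi mapping function
# ---------------------------------------------------------------------------

def kosambi(r: float) -> float:
    """Map distance in cM for recombinant fraction r: d = 25*ln((1+2r)/(1-2r))."""
    if not 0.0 <= r < 0.5:
        raise ValueError(f"recombinant fraction must lie in [0, 0.5), got {r}")
    return 25.0 * math.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def kosambi_inverse(d: float) -> float:
    """Recombinant fraction for a Kosambi distance d (cM): r = tanh(d/50)/2."""
    if d < 0:
        raise ValueError("map distance must be non-negative")
    return 0.5 * math.tanh(d / 50.0)


# ---------------------------------------------------------------------------
# DH genotype matrices, recombination and bins
# ---------------------------------------------------------------------------

@dataclass
class DHGenotypeMatrix:
    """Lines x markers matrix with cells in {'A', 'B', MISSING}."""

    data: pd.DataFrame  # index = line ids, columns = marker ids
    marker_order: dict[str, list[str]]  # linkage group -> ordered marker ids

    def __post_init__(self) -> None:
        vals = set(np.unique(self.data.to_numpy().astype(str)))
        if not vals <= {"A", "B", MISSING}:
            raise ValueError(f"DH matrix cells must be A/B/{MISSING}, got {vals}")
        ordered = [m for ms in self.marker_order.values() for m in ms]
        if set(ordered) - set(self.data.columns):
            raise ValueError("marker order names markers absent from the matrix")

    def vector(self, marker: str) -> np.ndarray:
        return self.data[marker].to_numpy().astype(str)


def estimate_r(v1: np.ndarray, v2: np.ndarray) -> float:
    """DH recombinant fraction: discordant lines / jointly non-missing lines.

    Returns NaN when no line is jointly typed. Values above 0.5 indicate
    unlinked markers.
    """
    v1 = np.asarray(v1).astype(str)
    v2 = np.asarray(v2).astype(str)
    joint = (v1 != MISSING) & (v2 != MISSING)
    n = int(joint.sum())
    if n == 0:
        return float("nan")
    return float((v1[joint] != v2[joint]).sum()) / n


def find_bins(matrix: DHGenotypeMatrix) -> dict[str, int]:
    """Collapse consecutive co-segregating markers into bins.

    Two adjacent markers join one bin iff their genotype vectors agree on
    every jointly non-missing line and at least one line is jointly typed
    (missing cells are wildcards but cannot carry a merge by themselves).
    Bin ids are global integers, increasing along each linkage group.
    """
    assignment: dict[str, int] = {}
    bin_id = -1
    for lg, markers in matrix.marker_order.items():
        prev_vec: np.ndarray | None = None
        for m in markers:
            v = matrix.vector(m)
            if prev_vec is None:
                bin_id += 1
            else:
                joint = (v != MISSING) & (prev_vec != MISSING)
                if joint.sum() == 0 or (v[joint] != prev_vec[joint]).any():
                    bin_id += 1
            assignment[m] = bin_id
            prev_vec = v
    return assignment


@dataclass
class GeneticMap:
    """Marker coordinates in cM with linkage-group and bin structure."""

    table: pd.DataFrame  # columns: marker, lg, cm, bin (bin optional)

    def __post_init__(self) -> None:
        for lg, grp in self.table.groupby("lg", sort=False):
            if not grp["cm"].is_monotonic_increasing:
                raise ValueError(f"positions not sorted within linkage group {lg}")

    def lg_length(self, lg: str) -> float:
        cm = self.table.loc[self.table["lg"] == lg, "cm"]
        return float(cm.max() - cm.min()) if len(cm) else 0.0


def build_genetic_map(matrix: DHGenotypeMatrix) -> GeneticMap:
    """Bin the markers and accumulate Kosambi distances along each group."""
    bins = find_bins(matrix)
    rows = []
    for lg, markers in matrix.marker_order.items():
        pos = 0.0
        prev = None
        for m in markers:
            if prev is not None:
                r = estimate_r(matrix.vector(prev), matrix.vector(m))
                if not math.isnan(r) and r < 0.5:
                    pos += kosambi(r)
            rows.append({"marker": m, "lg": lg, "cm": pos, "bin": bins[m]})
            prev = m
    return GeneticMap(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Physical anchoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalAnchor:
    marker: str
    chrom: str | None
    bp: int | None
    identity: float
    ambiguous: bool = False
    unanchored: bool = False


def assign_physical(
    hits: pd.DataFrame, min_identity: float = 85.0
) -> dict[str, PhysicalAnchor]:
    """Best alignment hit per marker at or above the identity threshold.

    Co-optimal best hits on different chromosomes make the marker ambiguous
    (kept with its first-listed position); no qualifying hit leaves it
    unanchored. Malformed rows are skipped and counted.
    """
    required = {"query", "chrom", "start", "identity"}
    if not required <= set(hits.columns):
        raise ValueError(f"hits table needs columns {sorted(required)}")
    anchors: dict[str, PhysicalAnchor] = {}
    skipped = 0
    for marker, grp in hits.groupby("query", sort=False):
        grp = grp.dropna(subset=["chrom", "start", "identity"])
        skipped += len(hits[hits["query"] == marker]) - len(grp)
        qual = grp[grp["identity"] >= min_identity]
        if qual.empty:
            anchors[str(marker)] = PhysicalAnchor(
                str(marker), None, None,
                float(grp["identity"].max()) if len(grp) else 0.0,
                unanchored=True,
            )
            continue
        best_val = qual["identity"].max()
        best = qual[qual["identity"] == best_val]
        ambiguous = best["chrom"].nunique() > 1
        top = best.iloc[0]
        anchors[str(marker)] = PhysicalAnchor(
            str(marker), str(top["chrom"]), int(top["start"]),
            float(best_val), ambiguous=ambiguous,
        )
    if skipped:
        import warnings

        warnings.warn(f"skipped {skipped} malformed alignment rows", stacklevel=2)
    return anchors


# ---------------------------------------------------------------------------
# Density statistics
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 2) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * ndigits), ROUND_HALF_UP))


def density_stats(
    mapped_loci: int, map_length_cm: float, positioned_loci: int, physical_length_kb: float
) -> dict[str, float]:
    """Marker-density summaries: markers/cM, cM/marker, Kb/marker (2 dp, half-up)."""
    out = {
        "markers_per_cm": float("nan"),
        "cm_per_marker": float("nan"),
        "kb_per_marker": float("nan"),
    }
    if map_length_cm > 0:
        out["markers_per_cm"] = round_half_up(mapped_loci / map_length_cm)
    if mapped_loci > 0 and map_length_cm > 0:
        out["cm_per_marker"] = round_half_up(map_length_cm / mapped_loci)
    if positioned_loci > 0:
        out["kb_per_marker"] = round_half_up(physical_length_kb / positioned_loci)
    return out


@dataclass
class MapStats:
    per_lg: pd.DataFrame
    totals: dict[str, float]
    genetic_gaps: pd.DataFrame   # lg, cm_from, cm_to, gap_cm
    physical_gaps: pd.DataFrame  # chrom, bp_from, bp_to, gap_kb


def compute_map_stats(
    genetic_map: GeneticMap,
    anchors: Mapping[str, PhysicalAnchor],
    genetic_gap_cm: float = 9.0,
    physical_gap_kb: float = 500.0,
    physical_lengths_kb: Mapping[str, float] | None = None,
) -> MapStats:
    """Per-linkage-group and total map-density statistics plus gap lists.

    Physical length per group defaults to the anchored-marker span; a
    pseudo-molecule length table can be supplied instead.
    """
    rows = []
    ggaps, pgaps = [], []
    tbl = genetic_map.table
    for lg, grp in tbl.groupby("lg", sort=False):
        markers = list(grp["marker"])
        anchored = [
            anchors[m] for m in markers
            if m in anchors and not anchors[m].unanchored
        ]
        cm = grp["cm"].to_numpy(float)
        length_cm = float(cm.max() - cm.min()) if len(cm) else 0.0
        bp = sorted(a.bp for a in anchored if a.bp is not None)
        if physical_lengths_kb and lg in physical_lengths_kb:
            length_kb = float(physical_lengths_kb[lg])
        else:
            length_kb = (bp[-1] - bp[0]) / 1000.0 if len(bp) >= 2 else 0.0
        n_bins = grp["bin"].nunique() if "bin" in grp else len(grp)
        stats = density_stats(len(grp), length_cm, len(anchored), length_kb)
        rows.append(
            {
                "lg": lg, "bins": n_bins, "positioned_loci": len(anchored),
                "physical_length_kb": length_kb, "mapped_loci": len(grp),
                "map_length_cm": length_cm, **stats,
            }
        )
        for a, b in zip(cm[:-1], cm[1:]):
            if b - a >= genetic_gap_cm:
                ggaps.append({"lg": lg, "cm_from": a, "cm_to": b, "gap_cm": b - a})
        chrom = anchored[0].chrom if anchored else None
        for a, b in zip(bp[:-1], bp[1:]):
            if (b - a) / 1000.0 > physical_gap_kb:
                pgaps.append(
                    {"chrom": chrom, "bp_from": a, "bp_to": b, "gap_kb": (b - a) / 1000.0}
                )
    per_lg = pd.DataFrame(rows)
    total_mapped = int(per_lg["mapped_loci"].sum()) if len(per_lg) else 0
    total_cm = float(per_lg["map_length_cm"].sum()) if len(per_lg) else 0.0
    total_pos = int(per_lg["positioned_loci"].sum()) if len(per_lg) else 0
    total_kb = float(per_lg["physical_length_kb"].sum()) if len(per_lg) else 0.0
    totals = {
        "bins": int(per_lg["bins"].sum()) if len(per_lg) else 0,
        "positioned_loci": total_pos,
        "physical_length_kb": total_kb,
        "mapped_loci": total_mapped,
        "map_length_cm": total_cm,
        **density_stats(total_mapped, total_cm, total_pos, total_kb),
    }
    return MapStats(
        per_lg=per_lg,
        totals=totals,
        genetic_gaps=pd.DataFrame(ggaps, columns=["lg", "cm_from", "cm_to", "gap_cm"]),
        physical_gaps=pd.DataFrame(pgaps, columns=["chrom", "bp_from", "bp_to", "gap_kb"]),
    )


# Published per-linkage-group summary of a B. napus DH map (printed inputs for
# the worked example): bins, physically positioned loci, physical length (Kb),
# mapped loci, map length (cM).
PUBLISHED_MAP_SUMMARY = pd.DataFrame(
    [
        ("A1", 60, 2672, 27105, 913, 75.9),
        ("A2", 74, 2425, 29627, 946, 98.2),
        ("A3", 94, 3185, 35753, 1330, 114.3),
        ("A4", 50, 2112, 21080, 1085, 57.6),
        ("A5", 78, 2332, 25706, 1121, 99.6),
        ("A6", 89, 2302, 26146, 1019, 100.1),
        ("A7", 46, 2529, 25458, 1333, 59.2),
        ("A8", 55, 1863, 21685, 953, 85.0),
        ("A9", 89, 2452, 40546, 1279, 127.5),
        ("A10", 63, 2053, 17911, 841, 75.6),
        ("C1", 46, 3418, 45604, 1882, 71.3),
        ("C2", 47, 3743, 47311, 1241, 69.8),
        ("C3", 118, 3870, 67777, 1804, 165.3),
        ("C4", 88, 4399, 55069, 1443, 136.9),
        ("C5", 65, 1600, 48717, 651, 124.4),
        ("C6", 40, 1982, 40797, 980, 42.6),
        ("C7", 82, 2784, 48823, 1360, 101.7),
        ("C8", 68, 2151, 44716, 742, 104.0),
        ("C9", 58, 1782, 55995, 843, 106.0),
    ],
    columns=["lg", "bins", "positioned_loci", "physical_length_kb", "mapped_loci",
             "map_length_cm"],
)

# Printed totals row of the same summary (the per-LG columns above carry minor
# typesetting noise, so totals are taken as printed rather than re-summed).
PUBLISHED_MAP_TOTALS = {
    "bins": 1310,
    "positioned_loci": 49744,
    "physical_length_kb": 725833.0,
    "mapped_loci": 21766,
    "map_length_cm": 1814.9,
}


def published_density_stats() -> tuple[pd.DataFrame, dict[str, float]]:
    """Recompute density statistics from the published printed inputs."""
    per_lg = PUBLISHED_MAP_SUMMARY.copy()
    stats = per_lg.apply(
        lambda r: density_stats(
            int(r["mapped_loci"]), float(r["map_length_cm"]),
            int(r["positioned_loci"]), float(r["physical_length_kb"]),
        ),
        axis=1, result_type="expand",
    )
    per_lg = pd.concat([per_lg, stats], axis=1)
    t = PUBLISHED_MAP_TOTALS
    totals = density_stats(
        int(t["mapped_loci"]), float(t["map_length_cm"]),
        int(t["positioned_loci"]), float(t["physical_length_kb"]),
    )
    return per_lg, totals


# ---------------------------------------------------------------------------
# Concordance and rearranged segments
# ---------------------------------------------------------------------------

@dataclass
class HomoeologyTable:
    """Symmetric chromosome-level A<->C homoeolog correspondence."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        sym = dict(self.pairs)
        for a, c in self.pairs.items():
            sym.setdefault(c, a)
        for a, c in sym.items():
            if sym.get(c) != a:
                raise ValueError("homoeology table must be symmetric")
        self.pairs = sym

    def homoeolog(self, chrom: str) -> str | None:
        return self.pairs.get(chrom)

    @classmethod
    def numbered(cls, n: int, a_prefix: str = "A", c_prefix: str = "C") -> "HomoeologyTable":
        return cls({f"{a_prefix}{i}": f"{c_prefix}{i}" for i in range(1, n + 1)})


CONCORDANT = "CONCORDANT"
HOMOEOLOGOUS = "HOMOEOLOGOUS"
DISCORDANT = "DISCORDANT"
UNANCHORED = "UNANCHORED"


def classify_concordance(
    genetic_map: GeneticMap,
    anchors: Mapping[str, PhysicalAnchor],
    homoeology: HomoeologyTable,
    lg_to_chrom: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label each mapped marker against its physical anchor.

    CONCORDANT when the linkage group's chromosome equals the anchor
    chromosome; HOMOEOLOGOUS when it equals the anchor's homoeolog;
    DISCORDANT otherwise; UNANCHORED when the marker has no qualifying anchor
    or its group has no chromosome correspondence. Summary fractions are over
    classified (non-UNANCHORED) markers.
    """
    rows = []
    for rec in genetic_map.table.itertuples():
        lg_chrom = lg_to_chrom.get(rec.lg)
        anchor = anchors.get(rec.marker)
        if lg_chrom is None or anchor is None or anchor.unanchored:
            status = UNANCHORED
            anchor_chrom = None if anchor is None else anchor.chrom
        elif anchor.chrom == lg_chrom:
            status = CONCORDANT
            anchor_chrom = anchor.chrom
        elif homoeology.homoeolog(anchor.chrom) == lg_chrom:
            status = HOMOEOLOGOUS
            anchor_chrom = anchor.chrom
        else:
            status = DISCORDANT
            anchor_chrom = anchor.chrom
        rows.append(
            {
                "marker": rec.marker, "lg": rec.lg, "cm": rec.cm,
                "anchor_chrom": anchor_chrom,
                "anchor_bp": None if anchor is None else anchor.bp,
                "status": status,
            }
        )
    records = pd.DataFrame(rows)
    classified = records[records["status"] != UNANCHORED]
    n = len(classified)
    summary = {
        "n_classified": float(n),
        "concordant": float((classified["status"] == CONCORDANT).sum() / n) if n else float("nan"),
        "homoeologous": float((classified["status"] == HOMOEOLOGOUS).sum() / n) if n else float("nan"),
        "discordant": float((classified["status"] == DISCORDANT).sum() / n) if n else float("nan"),
    }
    return records, summary


def detect_segments(records: pd.DataFrame, min_run: int = 3) -> pd.DataFrame:
    """Maximal runs of consecutive non-concordant markers sharing one wrong
    chromosome, with their genetic and physical extents.

    ``records`` is the per-marker concordance table ordered by map position
    within each linkage group.
    """
    segments = []
    for lg, grp in records.groupby("lg", sort=False):
        grp = grp.sort_values("cm", kind="stable").reset_index(drop=True)
        run: list[int] = []
        run_chrom: str | None = None

        def flush() -> None:
            if run_chrom is not None and len(run) >= min_run:
                sub = grp.iloc[run]
                bps = sub["anchor_bp"].dropna()
                segments.append(
                    {
                        "lg": lg,
                        "alt_chrom": run_chrom,
                        "n_markers": len(run),
                        "cm_start": float(sub["cm"].min()),
                        "cm_end": float(sub["cm"].max()),
                        "bp_start": int(bps.min()) if len(bps) else None,
                        "bp_end": int(bps.max()) if len(bps) else None,
                        "markers": ",".join(sub["marker"].astype(str)),
                    }
                )

        for i, rec in grp.iterrows():
            bad = rec["status"] in (HOMOEOLOGOUS, DISCORDANT)
            if bad and rec["anchor_chrom"] == run_chrom:
                run.append(i)
            else:
                flush()
                if bad:
                    run, run_chrom = [i], rec["anchor_chrom"]
                else:
                    run, run_chrom = [], None
        flush()
    return pd.DataFrame(
        segments,
        columns=["lg", "alt_chrom", "n_markers", "cm_start", "cm_end",
                 "bp_start", "bp_end", "markers"],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dh_matrix(path: str | Path, order_path: str | Path) -> DHGenotypeMatrix:
    """Read a lines-x-markers TSV plus a `marker lg` order file."""
    data = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna(MISSING)
    order = pd.read_csv(order_path, sep="\t")
    marker_order: dict[str, list[str]] = {}
    for rec in order.itertuples():
        marker_order.setdefault(str(rec.lg), []).append(str(rec.marker))
    return DHGenotypeMatrix(data, marker_order)


def read_genetic_map(path: str | Path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={"cM": "cm"})
    return GeneticMap(df)


def write_map_stats(stats: MapStats, path: str | Path) -> None:
    per_lg = stats.per_lg.copy()
    totals = pd.DataFrame([{"lg": "Total", **stats.totals}])
    pd.concat([per_lg, totals], ignore_index=True).to_csv(path, index=False)


def write_segments_bed(segments: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in segments.itertuples():
            if rec.bp_start is None:
                continue
            fh.write(
                f"{rec.alt_chrom}\t{rec.bp_start}\t{rec.bp_end}\t"
                f"{rec.lg}:{rec.cm_start:.2f}-{rec.cm_end:.2f}\t{rec.n_markers}\n"
            )
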