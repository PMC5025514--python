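"""Theta-space genotype clustering, pattern taxonomy, and cluster files.

Two-colour intensities (X = allele-A signal, Y = allele-B signal) are
normalised to polar coordinates theta = (2/pi)*arctan(Y/X) in [0, 1] and
R = X + Y. For each SNP a one-dimensional Gaussian mixture over theta is
fitted (components selected by BIC, K in 1..5) and the resulting component
layout is classified into the cluster-pattern taxonomy seen on allopolyploid
arrays:

* GENOME_SPECIFIC — the probe hybridises one subgenome only; AA and BB
  clusters sit near the theta extremes (mean separation > 0.6) with an
  optional AB cluster between them.
* MULTI_CLUSTER_UNRESOLVABLE — both homoeologous loci segregate; four-to-five
  clusters with an excess of apparent heterozygotes; not scorable.
* SHIFTED / SHIFTED_RESCUED — a monomorphic homoeolog co-hybridises and
  compresses the true genotype clusters (AAAA/AAAB/AABB) into one half of
  theta space; relabelling the compressed clusters rescues the assay.
* PRESENCE_ABSENCE — one allele yields no fluorescence; samples split by
  total intensity R rather than theta, heterozygotes undetectable.
* MONOMORPHIC — a single cluster with signal.
* FAILED_LOW_INTENSITY — little signal in most samples; removed.

Calls are made by maximum component responsibility; the confidence score is
the margin between the best and second-best responsibility, with calls below
the no-call threshold (default 0.05) suppressed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture


class Pattern(Enum):
    GENOME_SPECIFIC = "GENOME_SPECIFIC"
    SHIFTED = "SHIFTED"
    SHIFTED_RESCUED = "SHIFTED_RESCUED"
    MULTI_CLUSTER_UNRESOLVABLE = "MULTI_CLUSTER_UNRESOLVABLE"
    PRESENCE_ABSENCE = "PRESENCE_ABSENCE"
    MONOMORPHIC = "MONOMORPHIC"
    FAILED_LOW_INTENSITY = "FAILED_LOW_INTENSITY"


UNSCORABLE = {Pattern.MULTI_CLUSTER_UNRESOLVABLE, Pattern.FAILED_LOW_INTENSITY, Pattern.SHIFTED}


@dataclass(frozen=True)
class ClusterParams:
    """Tunables for fitting and classifying per-SNP cluster models."""

    k_min: int = 1
    k_max: int = 5
    theta_separation: float = 0.6     # AA-BB mean gap for genome specificity
    no_call_threshold: float = 0.05
    low_r_threshold: float = 0.2      # R below this = no effective signal
    low_r_sample_fraction: float = 0.5
    excess_het_weight: float = 0.6    # middle-component weight => unresolvable
    shifted_boundary: float = 0.5
    pa_min_fraction: float = 0.1      # min. fraction of no-signal samples for P/A
    merge_tol: float = 0.1            # fitted components closer than this act as one cluster
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta_separation < 1):
            raise ValueError("theta separation must lie in (0, 1)")
        for v in (self.no_call_threshold, self.excess_het_weight, self.shifted_boundary):
            if not 0 <= v <= 1:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class Component:
    mean_theta: float
    sd_theta: float
    mean_r: float
    sd_r: float
    weight: float
    label: str = "none"  # AA / AB / BB / none


@dataclass
class ClusterModel:
    snp_id: str
    components: list[Component] = field(default_factory=list)
    pattern: Pattern = Pattern.FAILED_LOW_INTENSITY
    scorable: bool = False
    polymorphic: bool = False
    # per-sample posterior over components, aligned with the fitted sample order
    responsibilities: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.components)

    def sorted_by_theta(self) -> list[int]:
        return sorted(range(self.k), key=lambda i: self.components[i].mean_theta)


@dataclass
class IntensityMatrix:
    """Long-format intensity data: one row per (SNP, sample)."""

    data: pd.DataFrame  # columns: snp_id, sample_id, theta, R
    species: dict[str, str] = field(default_factory=dict)  # sample -> species tag

    @classmethod
    def from_channels(
        cls, df: pd.DataFrame, species: dict[str, str] | None = None
    ) -> "IntensityMatrix":
        theta, r = normalize(df["X"].to_numpy(float), df["Y"].to_numpy(float))
        out = df[["snp_id", "sample_id"]].copy()
        out["theta"], out["R"] = theta, r
        return cls(out, species or {})

    def snp_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["snp_id"]))

    def per_snp(self, snp_id: str) -> pd.DataFrame:
        return self.data[self.data["snp_id"] == snp_id]


@dataclass(frozen=True)
class GenotypeCall:
    snp_id: str
    sample_id: str
    call: str  # AA / AB / BB / NO_CALL
    confidence: float


def normalize(x: np.ndarray | float, y: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
    """Polar intensity transform: theta = (2/pi) arctan(Y/X), R = X + Y.

    theta is 0 for pure allele-A signal and 1 for pure allele-B signal; cells
    with X = Y = 0 get theta = NaN (no-signal sentinel) and R = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("channel intensities must be non-negative")
    r = x + y
    with np.errstate(invalid="ignore"):
        theta = (2.0 / np.pi) * np.arctan2(y, x)
    theta = np.where(r > 0, theta, np.nan)
    return theta, r


def fit_cluster_model(
    thetas: np.ndarray,
    rs: np.ndarray,
    params: ClusterParams | None = None,
    snp_id: str = "",
    sample_ids: Sequence[str] | None = None,
) -> ClusterModel:
    """Fit a 1-D Gaussian mixture over theta, selecting K in range by BIC.

    Only samples with effective signal (R above the low-intensity threshold)
    enter the fit; R statistics per component are computed from the hard
    assignments. Deterministic for a given ``params.seed``.
    """
    params = params or ClusterParams()
    thetas = np.asarray(thetas, float)
    rs = np.asarray(rs, float)
    sample_ids = list(sample_ids) if sample_ids is not None else [
        f"s{i}" for i in range(len(thetas))
    ]
    signal = (rs >= params.low_r_threshold) & ~np.isnan(thetas)
    model = ClusterModel(snp_id=snp_id, sample_ids=sample_ids)
    n_signal = int(signal.sum())
    if n_signal == 0:
        model.pattern = Pattern.FAILED_LOW_INTENSITY
        return model
    x = thetas[signal].reshape(-1, 1)
    k_cap = min(params.k_max, n_signal)
    best: GaussianMixture | None = None
    best_bic = np.inf
    for k in range(params.k_min, k_cap + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            random_state=params.seed,
            n_init=3,
            reg_covar=1e-6,
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic, best = bic, gm
    assert best is not None
    resp_signal = best.predict_proba(x)
    hard = resp_signal.argmax(axis=1)
    comps = []
    r_signal = rs[signal]
    for j in range(best.n_components):
        members = r_signal[hard == j]
        comps.append(
            Component(
                mean_theta=float(best.means_[j, 0]),
                sd_theta=float(np.sqrt(best.covariances_[j])),
                mean_r=float(members.mean()) if members.size else 0.0,
                sd_r=float(members.std()) if members.size else 0.0,
                weight=float(best.weights_[j]),
            )
        )
    # expand responsibilities to all samples; no-signal rows get all-zero
    resp = np.zeros((len(thetas), best.n_components))
    resp[np.flatnonzero(signal)] = resp_signal
    model.components = comps
    model.responsibilities = resp
    model._signal_mask = signal  # type: ignore[attr-defined]
    return model


def component_groups(model: ClusterModel, merge_tol: float) -> list[list[int]]:
    """Group component indices whose theta means sit within ``merge_tol``.

    BIC occasionally shaves a boundary-compressed cloud into two
    near-coincident Gaussians; for the pattern taxonomy and genotype labels
    such slivers act as one cluster.
    """
    order = model.sorted_by_theta()
    groups: list[list[int]] = []
    for i in order:
        if groups and (
            model.components[i].mean_theta
            - model.components[groups[-1][-1]].mean_theta
            < merge_tol
        ):
            groups[-1].append(i)
        else:
            groups.append([i])
    return groups


def _group_stats(model: ClusterModel, groups: list[list[int]]) -> tuple[list[float], list[float]]:
    """Weight-averaged theta mean and total weight per merged group."""
    means, weights = [], []
    for g in groups:
        w = sum(model.components[i].weight for i in g)
        mu = sum(model.components[i].weight * model.components[i].mean_theta for i in g)
        means.append(mu / w if w > 0 else model.components[g[0]].mean_theta)
        weights.append(w)
    return means, weights


def classify_pattern(model: ClusterModel, params: ClusterParams | None = None) -> Pattern:
    """Assign the cluster-pattern label using a fixed precedence order:
    low-intensity -> presence/absence -> multi-cluster -> genome-specific ->
    shifted -> monomorphic."""
    params = params or ClusterParams()
    signal = getattr(model, "_signal_mask", None)
    n_total = len(model.sample_ids) or (len(signal) if signal is not None else 0)

    # 1. failed: majority of samples below the intensity floor
    if not model.components:
        return Pattern.FAILED_LOW_INTENSITY
    if signal is not None and n_total:
        no_signal_frac = 1.0 - signal.sum() / n_total
        if no_signal_frac > params.low_r_sample_fraction:
            return Pattern.FAILED_LOW_INTENSITY
    else:
        no_signal_frac = 0.0

    groups = component_groups(model, params.merge_tol)
    means, weights = _group_stats(model, groups)
    k_eff = len(groups)
    spread = means[-1] - means[0]

    # 2. presence/absence: a real minority with no signal while the signal
    #    cloud(s) sit at a single theta position
    if no_signal_frac >= params.pa_min_fraction and spread < params.theta_separation:
        return Pattern.PRESENCE_ABSENCE

    # 3. unresolvable: too many clusters, or a bloated heterozygote cloud
    if k_eff >= 4:
        return Pattern.MULTI_CLUSTER_UNRESOLVABLE
    if k_eff == 3 and weights[1] > params.excess_het_weight:
        return Pattern.MULTI_CLUSTER_UNRESOLVABLE

    # 4. genome-specific: extreme clusters span theta space
    if 2 <= k_eff <= 3 and spread > params.theta_separation:
        return Pattern.GENOME_SPECIFIC

    # 5. shifted: >= 2 clusters all compressed into one half of theta space
    if k_eff >= 2 and (
        all(m <= params.shifted_boundary for m in means)
        or all(m >= params.shifted_boundary for m in means)
    ):
        return Pattern.SHIFTED

    if k_eff == 1:
        return Pattern.MONOMORPHIC
    # 2-3 clusters, sub-threshold spread straddling the midline: compressed
    # homoeolog pattern that cannot be confidently relabelled
    return Pattern.MULTI_CLUSTER_UNRESOLVABLE


def label_components(model: ClusterModel, merge_tol: float = 0.1) -> None:
    """Attach AA/AB/BB labels in theta order for scorable patterns.

    Labels are assigned per merged cluster group, so a boundary cloud that
    BIC split into two slivers still gets one genotype label on all its
    components.
    """
    groups = component_groups(model, merge_tol)
    for c in model.components:
        c.label = "none"
    if model.pattern in (Pattern.GENOME_SPECIFIC, Pattern.SHIFTED_RESCUED):
        if len(groups) == 2:
            labels = ["AA", "BB"]
        elif len(groups) == 3:
            labels = ["AA", "AB", "BB"]
        else:
            return
        for g, lab in zip(groups, labels):
            for i in g:
                model.components[i].label = lab
    elif model.pattern in (Pattern.MONOMORPHIC, Pattern.PRESENCE_ABSENCE):
        # single signal cloud: homozygous for whichever allele it sits on
        means, _ = _group_stats(model, groups)
        lab = "AA" if means[0] <= 0.5 else "BB"
        for i in groups[0]:
            model.components[i].label = lab


def fit_and_classify(
    thetas: np.ndarray,
    rs: np.ndarray,
    params: ClusterParams | None = None,
    snp_id: str = "",
    sample_ids: Sequence[str] | None = None,
    rescue: bool = True,
) -> ClusterModel:
    """Full per-SNP pipeline: fit, classify, rescue shifted, label, flag."""
    params = params or ClusterParams()
    model = fit_cluster_model(thetas, rs, params, snp_id, sample_ids)
    model.pattern = classify_pattern(model, params)
    if model.pattern is Pattern.SHIFTED and rescue:
        model = rescue_shifted(model, params.merge_tol)
    else:
        label_components(model, params.merge_tol)
    model.scorable = model.pattern not in UNSCORABLE
    # presence/absence assays segregate by signal vs silence, so they are
    # informative even with a single labelled signal cloud
    model.polymorphic = model.scorable and (
        model.pattern is Pattern.PRESENCE_ABSENCE
        or sum(c.label in ("AA", "BB") for c in model.components) >= 2
    )
    return model


def rescue_shifted(model: ClusterModel, merge_tol: float = 0.1) -> ClusterModel:
    """Relabel a homoeolog-compressed cluster set to its true genotypes.

    The extreme-theta clusters become AA and BB (the middle one, if present,
    AB) without touching any sample-to-component assignment: the fitted
    responsibilities are reused bit-for-bit. With more than three effective
    clusters the pattern is genuinely unresolvable and the model is returned
    unchanged.
    """
    if model.pattern not in (Pattern.SHIFTED, Pattern.SHIFTED_RESCUED):
        raise ValueError("rescue applies to SHIFTED models only")
    k_eff = len(component_groups(model, merge_tol))
    if k_eff > 3 or k_eff < 2:
        return model
    model.pattern = Pattern.SHIFTED_RESCUED
    label_components(model, merge_tol)
    model.scorable = True
    model.polymorphic = True
    return model


def call_genotypes(
    model: ClusterModel,
    thetas: np.ndarray | None = None,
    rs: np.ndarray | None = None,
    params: ClusterParams | None = None,
    sample_ids: Sequence[str] | None = None,
) -> list[GenotypeCall]:
    """Call each sample from component responsibilities.

    With no new intensities the stored fit responsibilities are used.
    Confidence is best-minus-second responsibility over labelled components;
    calls below the no-call threshold, samples nearest an unlabelled
    component, and all samples of an unscorable SNP are NO_CALL. For
    presence/absence SNPs a no-signal sample is called as the silent
    homozygote.
    """
    params = params or ClusterParams()
    if thetas is not None:
        thetas = np.asarray(thetas, float)
        rs = np.asarray(rs, float)
        sample_ids = list(sample_ids) if sample_ids is not None else [
            f"s{i}" for i in range(len(thetas))
        ]
        signal = (rs >= params.low_r_threshold) & ~np.isnan(thetas)
        if model.components:
            means = np.array([c.mean_theta for c in model.components])
            sds = np.maximum([c.sd_theta for c in model.components], 1e-3)
            w = np.array([max(c.weight, 1e-12) for c in model.components])
            z = (thetas[:, None] - means[None, :]) / sds[None, :]
            log_like = -0.5 * z**2 - np.log(sds)[None, :] + np.log(w)[None, :]
            log_like -= log_like.max(axis=1, keepdims=True)
            resp = np.exp(log_like)
            resp /= resp.sum(axis=1, keepdims=True)
            resp[~signal] = 0.0
        else:
            resp = np.zeros((len(thetas), 0))
    else:
        resp = model.responsibilities
        sample_ids = model.sample_ids
        signal = getattr(model, "_signal_mask", None)
        if signal is None:
            signal = resp.sum(axis=1) > 0 if resp is not None else None

    calls: list[GenotypeCall] = []
    if not model.scorable or resp is None or resp.shape[1] == 0:
        return [GenotypeCall(model.snp_id, s, "NO_CALL", 0.0) for s in sample_ids]

    labels = [c.label for c in model.components]
    # responsibilities aggregate per genotype label, so two fitted slivers of
    # one cloud do not compete against each other in the confidence margin
    label_set = list(dict.fromkeys(labels))
    silent_label = None
    if model.pattern is Pattern.PRESENCE_ABSENCE:
        main = next((l for l in labels if l != "none"), "AA")
        silent_label = "BB" if main == "AA" else "AA"

    for i, sample in enumerate(sample_ids):
        if signal is not None and not signal[i]:
            if silent_label is not None:
                calls.append(GenotypeCall(model.snp_id, sample, silent_label, 1.0))
            else:
                calls.append(GenotypeCall(model.snp_id, sample, "NO_CALL", 0.0))
            continue
        p_label = {
            lab: float(sum(resp[i][j] for j, l in enumerate(labels) if l == lab))
            for lab in label_set
        }
        ranked = sorted(p_label.items(), key=lambda kv: kv[1], reverse=True)
        best_lab, best_p = ranked[0]
        conf = float(best_p - (ranked[1][1] if len(ranked) > 1 else 0.0))
        if best_lab == "none" or conf < params.no_call_threshold:
            calls.append(GenotypeCall(model.snp_id, sample, "NO_CALL", conf))
        else:
            calls.append(GenotypeCall(model.snp_id, sample, best_lab, conf))
    return calls


def fit_panel(
    intensities: IntensityMatrix, params: ClusterParams | None = None
) -> dict[str, ClusterModel]:
    """Fit and classify every SNP of an intensity panel."""
    params = params or ClusterParams()
    models: dict[str, ClusterModel] = {}
    for snp_id in intensities.snp_ids():
        sub = intensities.per_snp(snp_id)
        models[snp_id] = fit_and_classify(
            sub["theta"].to_numpy(float),
            sub["R"].to_numpy(float),
            params,
            snp_id=snp_id,
            sample_ids=list(sub["sample_id"]),
        )
    return models


# ---------------------------------------------------------------------------
# Cluster files
# ---------------------------------------------------------------------------

def build_cluster_file(models: dict[str, ClusterModel]) -> dict:
    """Serialisable per-SNP cluster definitions (components, labels, pattern)."""
    out = {}
    for snp_id, m in models.items():
        out[snp_id] = {
            "pattern": m.pattern.value,
            "scorable": m.scorable,
            "polymorphic": m.polymorphic,
            "components": [
                {
                    "mean_theta": c.mean_theta,
                    "sd_theta": c.sd_theta,
                    "mean_r": c.mean_r,
                    "sd_r": c.sd_r,
                    "weight": c.weight,
                    "label": c.label,
                }
                for c in m.components
            ],
        }
    return out


def write_cluster_file(models: dict[str, ClusterModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(build_cluster_file(models), fh, indent=1, sort_keys=True)


def read_cluster_file(path: str | Path) -> dict[str, ClusterModel]:
    with open(path) as fh:
        raw = json.load(fh)
    models = {}
    for snp_id, rec in raw.items():
        m = ClusterModel(
            snp_id=snp_id,
            pattern=Pattern(rec["pattern"]),
            scorable=rec["scorable"],
            polymorphic=rec["polymorphic"],
            components=[Component(**c) for c in rec["components"]],
        )
        models[snp_id] = m
    return models


def derive_diploid_cluster_file(
    tetraploid_models: dict[str, ClusterModel],
    diploid_intensities: IntensityMatrix,
    species: str,
    params: ClusterParams | None = None,
) -> tuple[dict[str, ClusterModel], dict[str, int]]:
    """Derive a per-species cluster file from a diploid intensity panel.

    Assays whose probe targets the other subgenome lose all signal in this
    species and are marked FAILED_LOW_INTENSITY; the rest are refitted on the
    diploid samples (cluster positions shift relative to the tetraploid when
    the formerly co-hybridising homoeolog is absent). Returns the per-SNP
    models and summary counts of scorable and polymorphic assays.
    """
    params = params or ClusterParams()
    if not diploid_intensities.species:
        raise ValueError("diploid intensity matrix must carry sample species tags")
    keep = [
        s for s, sp in diploid_intensities.species.items() if sp == species
    ]
    if not keep:
        raise ValueError(f"no samples tagged with species {species!r}")
    sub = diploid_intensities.data[diploid_intensities.data["sample_id"].isin(keep)]
    panel = IntensityMatrix(sub, diploid_intensities.species)
    models: dict[str, ClusterModel] = {}
    for snp_id in panel.snp_ids():
        if snp_id not in tetraploid_models:
            continue
        d = panel.per_snp(snp_id)
        models[snp_id] = fit_and_classify(
            d["theta"].to_numpy(float),
            d["R"].to_numpy(float),
            params,
            snp_id=snp_id,
            sample_ids=list(d["sample_id"]),
        )
    counts = {
        "scorable": sum(m.scorable for m in models.values()),
        "polymorphic": sum(m.polymorphic for m in models.values()),
        "failed": sum(
            m.pattern is Pattern.FAILED_LOW_INTENSITY for m in models.values()
        ),
    }
    return models, counts


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_intensities(path: str | Path, sample_sheet: str | Path | None = None) -> IntensityMatrix:
    """Read `snp_id sample_id X Y` or `snp_id sample_id theta R` TSV."""
    df = pd.read_csv(path, sep="\t")
    species = {}
    if sample_sheet is not None:
        sheet = pd.read_csv(sample_sheet, sep="\t")
        species = dict(zip(sheet["sample_id"].astype(str), sheet["species"].astype(str)))
    if {"X", "Y"} <= set(df.columns):
        return IntensityMatrix.from_channels(df, species)
    if {"theta", "R"} <= set(df.columns):
        return IntensityMatrix(df[["snp_id", "sample_id", "theta", "R"]].copy(), species)
    raise ValueError("intensity file must have X/Y or theta/R columns")


def write_calls(calls: Sequence[GenotypeCall], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"snp_id": c.snp_id, "sample_id": c.sample_id, "call": c.call,
             "confidence": c.confidence}
            for c in calls
        ]
    ).to_csv(path, sep="\t", index=False)
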