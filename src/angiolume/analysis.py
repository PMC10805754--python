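"""Region-conditioned, lumen-weighted vascular statistics.

Every vessel segment is assigned to the region (healthy tissue, normoxic
tumor, hypoxic tumor) containing both of its endpoint nodes — with a
majority-of-centerline tie-break when they disagree — and segments
touching the volume border are excluded. Feature distributions are not
plotted as relative frequencies (which would over-weight capillaries):
each segment is weighted by its lumen, the share of the total vascular
volume its assigned voxels represent, so a single large vessel counts as
much vasculature as the many small ones of equal volume.

Group comparisons follow the study design: per-animal scalar summaries
(tumor volume, hypoxia ratio, vascularization index) are compared with
Welch's unequal-variance t-test, and pooled lumen-weighted feature
distributions are compared pairwise between region classes with a
(weighted) two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import RegionLabel, RegionLabelVolume
from .vesselgraph import VesselGraph

_REGION_NAMES = {
    int(RegionLabel.HEALTHY): "healthy",
    int(RegionLabel.NORMOXIC_TUMOR): "normoxic",
    int(RegionLabel.HYPOXIC_TUMOR): "hypoxic",
}

FEATURES = [
    "length", "volume", "avg_cross_section", "avg_radius",
    "min_radius", "max_radius", "curveness",
]


# ---------------------------------------------------------------------------
# segment → region assignment
# ---------------------------------------------------------------------------

def assign_segments(
    graph: VesselGraph,
    regions: RegionLabelVolume,
    animal_id: str = "specimen",
    group: str = "",
    border_margin_um: float | None = None,
) -> pd.DataFrame:
    """Build the per-segment region feature table of one specimen.

    Segments with an endpoint on the volume border are excluded, as are
    segments whose centerline lies mostly in the excluded (severe-AF)
    mask. ``lumen_weight`` is each included segment's assigned voxel count
    divided by the total over included segments (sums to 1).
    """
    sp = np.asarray(regions.spacing, float)
    shape = np.asarray(regions.labels.shape)
    if graph.shape and tuple(graph.shape) != tuple(regions.labels.shape):
        raise ValueError(
            f"coordinate frames inconsistent: graph grid {graph.shape} vs "
            f"regions grid {regions.labels.shape}"
        )
    margin = border_margin_um if border_margin_um is not None else 1.5 * float(sp.max())
    extent = shape * sp

    nodes = {n.id: n for n in graph.nodes}
    rows = []
    for s in graph.segments:
        if s.degenerate or s.features is None:
            continue
        pa = nodes[s.node_a].position_um if s.node_a in nodes else s.centerline_um[0]
        pb = nodes[s.node_b].position_um if s.node_b in nodes else s.centerline_um[-1]
        # the skeleton retracts from the mask surface by ~one radius, so the
        # border test allows for the local radius at each endpoint
        on_border = any(
            bool(np.any(p < margin + r) or np.any(p > extent - margin - r))
            for p, r in ((pa, s.radii_um[0]), (pb, s.radii_um[-1]))
        )
        if on_border:
            continue
        vox = np.minimum((s.centerline_um / sp).astype(int), shape - 1)
        labels_on_path = regions.labels[tuple(vox.T)]
        if np.mean(labels_on_path == int(RegionLabel.EXCLUDED)) > 0.5:
            continue
        la = regions.labels[tuple(np.minimum((pa / sp).astype(int), shape - 1))]
        lb = regions.labels[tuple(np.minimum((pb / sp).astype(int), shape - 1))]
        if la == lb and int(la) in _REGION_NAMES:
            region = _REGION_NAMES[int(la)]
        else:
            # endpoints disagree: majority of centerline points decides
            counted = labels_on_path[np.isin(labels_on_path, list(_REGION_NAMES))]
            if counted.size == 0:
                continue
            region = _REGION_NAMES[int(np.bincount(counted).argmax())]
        row = {
            "animal_id": animal_id,
            "group": group,
            "segment_id": s.id,
            "region": region,
            "voxel_count": s.voxel_count,
        }
        row.update(s.features.as_dict())
        rows.append(row)
    columns = ["animal_id", "group", "segment_id", "region", "voxel_count",
               *FEATURES, "lumen_weight"]
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table["lumen_weight"] = table["voxel_count"] / table["voxel_count"].sum()
    return table[columns]


# ---------------------------------------------------------------------------
# lumen-weighted descriptive statistics
# ---------------------------------------------------------------------------

def lumen_weighted_histogram(
    table: pd.DataFrame, feature: str, bins
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of a feature in % of total lumen per bin.

    Each segment contributes its lumen weight to the bin holding its
    feature value; bar heights sum to 100 over the in-range segments.
    """
    if len(table) == 0:
        edges = np.asarray(bins, float) if np.ndim(bins) else np.linspace(0, 1, int(bins) + 1)
        return np.zeros(len(edges) - 1), edges
    if feature not in table.columns:
        raise KeyError(f"unknown feature {feature!r}")
    w = table["lumen_weight"].to_numpy(float)
    hist, edges = np.histogram(table[feature].to_numpy(float), bins=bins, weights=w)
    total = hist.sum()
    if total > 0:
        hist = 100.0 * hist / total
    return hist, edges


def freedman_diaconis_bins(values: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Fixed-width bin edges from the (weighted) Freedman–Diaconis rule."""
    values = np.asarray(values, float)
    if weights is None:
        q25, q75 = np.percentile(values, [25, 75])
        n_eff = len(values)
    else:
        order = np.argsort(values)
        cw = np.cumsum(np.asarray(weights, float)[order])
        cw /= cw[-1]
        q25, q75 = np.interp([0.25, 0.75], cw, values[order])
        n_eff = float(np.sum(weights)) ** 2 / float(np.sum(np.square(weights)))
    width = 2.0 * (q75 - q25) / max(n_eff, 1.0) ** (1.0 / 3.0)
    lo, hi = values.min(), values.max()
    if width <= 0 or hi <= lo:
        return np.linspace(lo, lo + 1.0, 11)
    n_bins = max(int(np.ceil((hi - lo) / width)), 1)
    return np.linspace(lo, hi, n_bins + 1)


def vascularization_index(table: pd.DataFrame, regions: RegionLabelVolume, region: str) -> float:
    """Vessel segments per mm³ of the given region."""
    label = {v: k for k, v in _REGION_NAMES.items()}[region]
    vol = regions.volume_mm3(RegionLabel(label))
    if vol <= 0:
        raise ValueError(f"region {region!r} has zero volume")
    n = int((table["region"] == region).sum()) if len(table) else 0
    return n / vol


def hypoxia_ratio(hypoxic_volume: float, normoxic_volume: float) -> float:
    """Hypoxic / normoxic tumor volume; NaN when the normoxic volume is 0."""
    if normoxic_volume <= 0:
        return float("nan")
    return hypoxic_volume / normoxic_volume


# ---------------------------------------------------------------------------
# statistical tests
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    stars: str


def welch_t_test(group_a, group_b) -> WelchResult:
    """Unpaired two-tailed t-test with Welch's unequal-variance correction.

    Uses the Satterthwaite degrees of freedom; identical groups give
    t = 0, p = 1.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    if se2 == 0:
        return WelchResult(0.0, float(na + nb - 2), 1.0, "ns")
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    # tiny variances can underflow the Satterthwaite denominator; fall back
    # to the pooled degrees of freedom rather than 0/0
    df = se2**2 / denom if denom > 0 and np.isfinite(se2**2 / denom) else float(na + nb - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p), significance_stars(p))


@dataclass
class KSResult:
    D: float
    p: float
    stars: str


def weighted_ks_test(values_a, values_b, weights_a=None, weights_b=None) -> KSResult:
    """Two-sample Kolmogorov–Smirnov test on weighted samples.

    ``D`` is the supremum distance between the weighted empirical CDFs in
    double precision; the p-value uses the asymptotic Kolmogorov
    distribution with effective sample sizes ``(Σw)²/Σw²`` per side. With
    unit weights this reduces exactly to the classical two-sample KS
    statistic.
    """
    xa = np.asarray(values_a, np.float64)
    xb = np.asarray(values_b, np.float64)
    if xa.size == 0 or xb.size == 0:
        raise ValueError("both samples must be non-empty")
    wa = np.ones_like(xa) if weights_a is None else np.asarray(weights_a, np.float64)
    wb = np.ones_like(xb) if weights_b is None else np.asarray(weights_b, np.float64)
    if np.any(wa < 0) or np.any(wb < 0) or wa.sum() == 0 or wb.sum() == 0:
        raise ValueError("weights must be non-negative with a positive sum")

    oa, ob = np.argsort(xa, kind="mergesort"), np.argsort(xb, kind="mergesort")
    xa, wa = xa[oa], wa[oa]
    xb, wb = xb[ob], wb[ob]
    ca = np.cumsum(wa) / wa.sum()
    cb = np.cumsum(wb) / wb.sum()
    grid = np.concatenate([xa, xb])
    # weighted ECDF evaluated from the right (≤ x)
    fa = np.concatenate([[0.0], ca])[np.searchsorted(xa, grid, side="right")]
    fb = np.concatenate([[0.0], cb])[np.searchsorted(xb, grid, side="right")]
    D = float(np.max(np.abs(fa - fb)))

    na = wa.sum() ** 2 / np.square(wa).sum()
    nb = wb.sum() ** 2 / np.square(wb).sum()
    n_eff = na * nb / (na + nb)
    p = float(np.clip(stats.kstwobign.sf(D * math.sqrt(n_eff)), 0.0, 1.0))
    return KSResult(D, p, significance_stars(p))


def plot_lumen_weighted_histograms(
    tables: dict[str, pd.DataFrame],
    feature: str,
    bins=None,
    ax=None,
):
    """Overlay lumen-weighted feature distributions (one per region or
    group), % of total lumen per bin."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    if bins is None:
        pooled = pd.concat(tables.values(), ignore_index=True)
        bins = freedman_diaconis_bins(
            pooled[feature].to_numpy(float), pooled["lumen_weight"].to_numpy(float)
        )
    for label, table in tables.items():
        hist, edges = lumen_weighted_histogram(table, feature, bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax.step(centers, hist, where="mid", label=label)
    ax.set_xlabel(feature)
    ax.set_ylabel("% of total lumen")
    ax.legend(frameon=False)
    return ax


# ---------------------------------------------------------------------------
# cohort-level report
# ---------------------------------------------------------------------------

@dataclass
class GroupComparisonReport:
    summaries: pd.DataFrame          # one row per animal
    welch_tests: pd.DataFrame        # group vs control, per metric
    ks_tests: pd.DataFrame           # region-pair KS per group and feature
    warnings: list[str]


def summarize_animal(
    animal_id: str,
    group: str,
    table: pd.DataFrame,
    regions: RegionLabelVolume,
) -> dict:
    """Per-animal scalar summary used by the group comparisons."""
    tumor_v = regions.volume_mm3(RegionLabel.NORMOXIC_TUMOR) + regions.volume_mm3(RegionLabel.HYPOXIC_TUMOR)
    hyp_v = regions.volume_mm3(RegionLabel.HYPOXIC_TUMOR)
    norm_v = regions.volume_mm3(RegionLabel.NORMOXIC_TUMOR)
    vox_vol_mm3 = float(np.prod(regions.spacing)) * 1e-9
    vessel_vol = float(table["voxel_count"].sum()) * vox_vol_mm3 if len(table) else 0.0
    out = {
        "animal_id": animal_id,
        "group": group,
        "tumor_volume_mm3": tumor_v,
        "hypoxic_volume_mm3": hyp_v,
        "normoxic_volume_mm3": norm_v,
        "hypoxia_ratio": hypoxia_ratio(hyp_v, norm_v),
        "vessel_volume_per_tumor_volume": vessel_vol / tumor_v if tumor_v > 0 else float("nan"),
    }
    for region in ("healthy", "normoxic", "hypoxic"):
        try:
            vi = vascularization_index(table, regions, region)
        except ValueError:
            vi = float("nan")
        out[f"vascularization_index_{region}"] = vi
    return out


def group_comparison_report(
    tables: dict[str, pd.DataFrame],
    summaries: pd.DataFrame,
    control: str,
    metrics: tuple[str, ...] = ("tumor_volume_mm3", "hypoxia_ratio", "vascularization_index_normoxic"),
    features: tuple[str, ...] = ("avg_cross_section",),
) -> GroupComparisonReport:
    """Welch tests of per-animal metrics against the control group, and
    pairwise weighted-KS tests of pooled feature distributions between the
    three region classes within each group (plus treated-vs-control KS per
    feature pooled over regions of the tumor)."""
    warnings: list[str] = []
    groups = list(summaries["group"].unique())
    if control not in groups:
        raise ValueError(f"control group {control!r} not present in {groups}")

    welch_rows = []
    for g in groups:
        if g == control:
            continue
        for metric in metrics:
            a = summaries.loc[summaries["group"] == g, metric].dropna().to_numpy()
            b = summaries.loc[summaries["group"] == control, metric].dropna().to_numpy()
            if len(a) < 2 or len(b) < 2:
                warnings.append(f"group {g!r} metric {metric!r}: <2 animals, t-test skipped")
                continue
            res = welch_t_test(a, b)
            welch_rows.append(
                {"group": g, "control": control, "metric": metric,
                 "t": res.t, "df": res.df, "p": res.p, "stars": res.stars}
            )

    ks_rows = []
    pooled = {g: t for g, t in tables.items()}
    region_pairs = [("healthy", "normoxic"), ("healthy", "hypoxic"), ("normoxic", "hypoxic")]
    for g, table in pooled.items():
        if len(table) == 0:
            continue
        for feature in features:
            for ra, rb in region_pairs:
                sa = table[table["region"] == ra]
                sb = table[table["region"] == rb]
                if len(sa) == 0 or len(sb) == 0:
                    continue
                res = weighted_ks_test(
                    sa[feature], sb[feature], sa["lumen_weight"], sb["lumen_weight"]
                )
                ks_rows.append(
                    {"group": g, "comparison": f"{ra} vs {rb}", "feature": feature,
                     "D": res.D, "p": res.p, "stars": res.stars}
                )
    # treated-vs-control shift of the tumor vasculature
    for g in groups:
        if g == control:
            continue
        if len(pooled.get(g, [])) == 0 or len(pooled.get(control, [])) == 0:
            continue
        for feature in features:
            sa = pooled[g][pooled[g]["region"].isin(["normoxic", "hypoxic"])]
            sb = pooled[control][pooled[control]["region"].isin(["normoxic", "hypoxic"])]
            if len(sa) == 0 or len(sb) == 0:
                continue
            res = weighted_ks_test(sa[feature], sb[feature], sa["lumen_weight"], sb["lumen_weight"])
            ks_rows.append(
                {"group": g, "comparison": f"tumor vs {control} tumor", "feature": feature,
                 "D": res.D, "p": res.p, "stars": res.stars}
            )

    return GroupComparisonReport(
        summaries=summaries,
        welch_tests=pd.DataFrame(welch_rows),
        ks_tests=pd.DataFrame(ks_rows),
        warnings=warnings,
    )
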