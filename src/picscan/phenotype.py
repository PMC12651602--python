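"""Imaging-mass-cytometry-style event phenotyping.

Events (CTCs, LEVs, WBCs; standalone or in contact) carry mean ion counts
per marker.  Counts are log(1+x)-transformed to stabilize variance,
hierarchically clustered into k=2 phenotype groups (Ward linkage on
z-scored log values), gated into immune subtypes with a fixed decision
tree over CD45/CD3/CD4/CD8a/CD20/CD56/CD14/CD68 positivity, matched to
immunofluorescence coordinates, and tested for enrichment of in-contact
events in the CD4-T-like cluster with Fisher's exact test.

A negative-binomial generator provides synthetic matrices with planted
class labels so the whole stage is testable without instrument data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .errors import ConfigurationError, ValidationError
from .stats import GroupComparison, fisher_exact_2x2, mann_whitney

GATE_MARKERS = ("CD45", "CD3", "CD4", "CD8a", "CD20", "CD56", "CD14", "CD68")


def log_transform(raw):
    """Elementwise log(1 + x); monotone and invertible on counts >= 0."""
    arr = np.asarray(raw, dtype=float) if not isinstance(raw, pd.DataFrame) else raw
    if np.any(np.asarray(arr) < 0):
        raise ValidationError("ion counts must be >= 0")
    return np.log1p(arr)


def hierarchical_cluster(log_matrix: pd.DataFrame, k: int = 2,
                         markers=None) -> np.ndarray:
    """Agglomerative (Ward, Euclidean) clustering of log-scale rows, cut at k.

    Columns are z-scored first so no single high-count marker dominates the
    metric.  Labels are 1..k; with k=2 the cluster with the higher mean
    CD3+CD4 signature is relabeled 1, so "cluster 1 = CD4-T-like" is stable
    across runs.
    """
    cols = list(markers) if markers is not None else list(log_matrix.columns)
    X = log_matrix[cols].to_numpy(dtype=float)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(X):
        raise ValidationError(f"k={k} exceeds {len(X)} rows")
    if k == 1:
        return np.ones(len(X), dtype=int)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    labels = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    if k == 2 and {"CD3", "CD4"} <= set(cols):
        sig = log_matrix["CD3"].to_numpy() + log_matrix["CD4"].to_numpy()
        mean1 = sig[labels == 1].mean() if (labels == 1).any() else -np.inf
        mean2 = sig[labels == 2].mean() if (labels == 2).any() else -np.inf
        if mean2 > mean1:
            labels = 3 - labels
    return labels.astype(int)


@dataclass
class GateConfig:
    """Per-marker positivity thresholds on the log(1+count) scale.

    Default: positive iff the raw ion count exceeds 10 (log1p(10) on the
    transformed scale) for every marker.  ``derive_gate_thresholds`` offers
    data-driven midpoint thresholds as an alternative.
    """

    thresholds: dict = field(
        default_factory=lambda: {m: math.log1p(10.0) for m in GATE_MARKERS})

    def positive(self, row, marker) -> bool:
        if marker not in row.index:
            raise ConfigurationError(f"marker {marker!r} missing from row")
        if marker not in self.thresholds:
            raise ConfigurationError(f"no gate threshold for {marker!r}")
        return float(row[marker]) > self.thresholds[marker]


def derive_gate_thresholds(log_matrix: pd.DataFrame,
                           cluster_labels) -> GateConfig:
    """Midpoint-between-cluster-means threshold per marker (data-driven
    alternative default; degenerates when neither cluster expresses a
    marker, so inspect before use)."""
    labels = np.asarray(cluster_labels)
    thr = {}
    for m in log_matrix.columns:
        v = log_matrix[m].to_numpy(dtype=float)
        means = [v[labels == g].mean() for g in np.unique(labels)]
        thr[m] = float((max(means) + min(means)) / 2.0)
    return GateConfig(thresholds=thr)


def gate_immune_subtype(row: pd.Series, gate: GateConfig | None = None) -> str:
    """Immune subtype of one event from marker positivity.

    Decision tree (evaluated in order; CD3+CD4+CD8a+ double positives fall
    into the cd8_t branch by construction):

    CD45- -> non_immune; CD45+CD3+CD8a+ -> cd8_t; CD45+CD3+CD4+ -> cd4_t;
    CD45+CD3-CD20+ -> b_cell; CD45+CD3-CD56+ -> nk;
    CD45+(CD14+ or CD68+) -> monocyte_macrophage; else unclassified.
    """
    gate = gate or GateConfig()
    missing = [m for m in GATE_MARKERS if m not in row.index]
    if missing:
        raise ConfigurationError(f"missing gate markers: {missing}")
    pos = {m: gate.positive(row, m) for m in GATE_MARKERS}
    if not pos["CD45"]:
        return "non_immune"
    if pos["CD3"]:
        if pos["CD8a"]:
            return "cd8_t"
        if pos["CD4"]:
            return "cd4_t"
    else:
        if pos["CD20"]:
            return "b_cell"
        if pos["CD56"]:
            return "nk"
    if pos["CD14"] or pos["CD68"]:
        return "monocyte_macrophage"
    return "unclassified"


def match_coordinates(if_events: pd.DataFrame, imc_rois: pd.DataFrame,
                      tolerance_um: float,
                      transform=None) -> pd.DataFrame:
    """Greedy nearest-neighbor matching of IF event coordinates to IMC ROIs.

    Both frames need ``id``, ``x_um``, ``y_um`` columns; ``transform`` (an
    optional callable mapping (x, y) arrays to the IMC frame) reconciles
    coordinate systems.  Candidate pairs within the tolerance are assigned
    greedily by increasing distance; ties break toward the lowest event id,
    then lowest ROI id.  Each event and each ROI is matched at most once.
    Returns event_id, roi_id, distance_um for the matched pairs.
    """
    if tolerance_um <= 0:
        raise ValidationError("tolerance must be positive")
    ex = if_events["x_um"].to_numpy(dtype=float)
    ey = if_events["y_um"].to_numpy(dtype=float)
    if transform is not None:
        ex, ey = transform(ex, ey)
    rx = imc_rois["x_um"].to_numpy(dtype=float)
    ry = imc_rois["y_um"].to_numpy(dtype=float)
    if len(ex) == 0 or len(rx) == 0:
        return pd.DataFrame(columns=["event_id", "roi_id", "distance_um"])
    d = np.hypot(ex[:, None] - rx[None, :], ey[:, None] - ry[None, :])
    cand = np.argwhere(d <= tolerance_um)
    eids = if_events["id"].to_numpy()
    rids = imc_rois["id"].to_numpy()
    order = sorted(
        ((d[i, j], eids[i], rids[j], i, j) for i, j in cand),
        key=lambda t: (t[0], t[1], t[2]))
    used_e, used_r, rows = set(), set(), []
    for dist, eid, rid, i, j in order:
        if i in used_e or j in used_r:
            continue
        used_e.add(i)
        used_r.add(j)
        rows.append({"event_id": eid, "roi_id": rid, "distance_um": float(dist)})
    return pd.DataFrame(rows, columns=["event_id", "roi_id", "distance_um"])


def contact_cluster_table(contact_flags, cluster_labels) -> np.ndarray:
    """2x2 table: rows in_contact/standalone, columns cluster 1 / cluster 2."""
    contact = np.asarray(contact_flags, dtype=bool)
    labels = np.asarray(cluster_labels)
    return np.array([
        [int(((labels == 1) & contact).sum()), int(((labels != 1) & contact).sum())],
        [int(((labels == 1) & ~contact).sum()), int(((labels != 1) & ~contact).sum())],
    ])


def fisher_enrichment(table) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher p for in-contact enrichment in
    cluster 1 (the CD4-T-like cluster)."""
    return fisher_exact_2x2(table)


def differential_marker(group_a: pd.DataFrame, group_b: pd.DataFrame,
                        marker: str) -> tuple[GroupComparison, float]:
    """Mann-Whitney comparison of a marker's log values between two event
    groups, plus the difference of group medians (A - B)."""
    for g in (group_a, group_b):
        if marker not in g.columns:
            raise ConfigurationError(f"marker {marker!r} missing")
    a = group_a[marker].to_numpy(dtype=float)
    b = group_b[marker].to_numpy(dtype=float)
    comp = mann_whitney(a, b)
    return comp, float(np.median(a) - np.median(b))


# ---------------------------------------------------------------------------
# synthetic ion-count generator

@dataclass
class PhenoSimConfig:
    """Synthetic IMC matrix: negative-binomial mean ion counts per class.

    Two planted components: a CD4-T-like profile (high CD45/CD3/CD4, low
    CD8a and CK) and an epithelial-like profile (high CK, immune markers at
    noise level).  ``n_contact`` / ``n_standalone`` default to the group
    sizes of the CTC contact analysis (42 vs 143); in-contact events draw
    from the CD4-T-like component with probability ``contact_cd4_prob``.
    ``dispersion`` is the NB size parameter (shared across markers).
    """

    n_contact: int = 42
    n_standalone: int = 143
    contact_cd4_prob: float = 0.85
    standalone_cd4_prob: float = 0.20
    dispersion: float = 5.0
    cd4_means: dict = field(default_factory=lambda: {
        "CD45": 60.0, "CD3": 45.0, "CD4": 35.0, "CD8a": 2.0, "CD20": 1.0,
        "CD56": 1.0, "CD14": 2.0, "CD68": 2.0, "HLA-DR": 6.0,
        "cCaspase3": 3.0, "CK": 3.0})
    epi_means: dict = field(default_factory=lambda: {
        "CD45": 2.0, "CD3": 1.0, "CD4": 1.0, "CD8a": 1.0, "CD20": 1.0,
        "CD56": 1.0, "CD14": 1.0, "CD68": 1.0, "HLA-DR": 6.0,
        "cCaspase3": 5.0, "CK": 70.0})


def _nb_draw(rng, mean, size_param, n):
    if mean <= 0:
        return np.zeros(n)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n).astype(float)


def generate_phenotype_matrix(config: PhenoSimConfig | None = None,
                              seed: int = 0) -> pd.DataFrame:
    """Synthetic events x markers raw ion-count table with planted truth.

    Columns: the markers, plus ``contact`` (bool), ``true_class``
    ('cd4_t_like' | 'epithelial_like') and ``role`` ('ctc').
    """
    config = config or PhenoSimConfig()
    rng = np.random.default_rng(seed)
    markers = list(config.cd4_means)
    rows = []
    for contact, n, p_cd4 in ((True, config.n_contact, config.contact_cd4_prob),
                              (False, config.n_standalone, config.standalone_cd4_prob)):
        classes = np.where(rng.random(n) < p_cd4, "cd4_t_like", "epithelial_like")
        for cls in classes:
            means = config.cd4_means if cls == "cd4_t_like" else config.epi_means
            row = {m: _nb_draw(rng, means[m], config.dispersion, 1)[0]
                   for m in markers}
            row["contact"] = contact
            row["true_class"] = cls
            row["role"] = "ctc"
            rows.append(row)
    return pd.DataFrame(rows, columns=markers + ["contact", "true_class", "role"])
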