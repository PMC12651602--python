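"""Planted-truth experiments: benchmark drivers used by the test suite,
the examples and the acceptance script.

Each function generates synthetic data with known ground truth, runs the
relevant pipeline stage, and reports recovery metrics (precision/recall,
fold-change recovery, group-test statistics, clustering agreement).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.metrics import adjusted_rand_score

from .contact import PicThresholds, score_pair
from .detect import DetectionConfig, detect_events
from .phenotype import (PhenoSimConfig, contact_cluster_table,
                        fisher_enrichment, generate_phenotype_matrix,
                        hierarchical_cluster, log_transform)
from .simulate import GroundTruth, SimConfig, SlideCanvas, SlideImage
from .stats import GroupComparison, mann_whitney


def pair_slide(relationship: str, f: float, seed: int, arc_deg: float = 60.0,
               partner: str = "epi_ctc", canvas_px: int = 160
               ) -> tuple[SlideImage, GroundTruth, int, int]:
    """One WBC-tumor pair on a small canvas; returns (image, gt, wbc_id, tumor_id)."""
    cfg = SimConfig(width=canvas_px, height=canvas_px, n_wbc=0, n_epi_ctc=0,
                    n_im_ctc=0, n_epi_lev=0, n_im_lev=0, n_small_ev=0,
                    n_pic=0, n_overlap=0, n_gap_pair=0, seed=seed,
                    contact_fold=f, contact_arc_deg=arc_deg)
    canvas = SlideCanvas(cfg)
    wid, tid = canvas.plant_pair("wbc", partner, relationship,
                                 f=f if relationship == "pic" else None)
    img, gt = canvas.finalize()
    return img, gt, wid, tid


def simulate_fold_samples(n_pairs: int, relationship: str, f: float,
                          seed: int, arc_deg: float = 60.0) -> np.ndarray:
    """Recovered fold changes for ``n_pairs`` independently planted pairs.

    Scoring runs on the planted ground-truth masks, isolating the perimeter
    statistic from segmentation error.
    """
    folds = np.empty(n_pairs)
    rng = np.random.default_rng(seed)
    for i in range(n_pairs):
        s = int(rng.integers(0, 2**31 - 1))
        img, gt, wid, tid = pair_slide(relationship, f, s, arc_deg)
        sc = score_pair(img.channel("cd45").astype(float),
                        gt.object_mask(wid), gt.object_mask(tid))
        folds[i] = sc.enrichment.fold_change
    return folds


def pic_group_test(n_pic: int = 93, n_overlap: int = 16, f_pic: float = 2.0,
                   seed: int = 0) -> tuple[np.ndarray, np.ndarray, GroupComparison]:
    """Scaled-down shadow of the PIC-vs-overlap membrane-enrichment test.

    Simulates ``n_pic`` interacting pairs at fold ``f_pic`` and
    ``n_overlap`` passive overlaps (fold 1), recovers each WBC's contact
    fold change from the image, and compares the two groups with the
    Mann-Whitney U test.
    """
    folds_pic = simulate_fold_samples(n_pic, "pic", f_pic, seed)
    folds_ovl = simulate_fold_samples(n_overlap, "overlap", 1.0, seed + 1)
    return folds_pic, folds_ovl, mann_whitney(folds_pic, folds_ovl)


def classification_rates(n_pairs: int, f: float, seed: int,
                         arc_deg: float = 60.0,
                         thresholds: PicThresholds | None = None) -> dict:
    """Fraction of planted pairs classified pic / passive_overlap / gap.

    ``f > 1`` plants interacting pairs (so the 'pic' rate is sensitivity);
    ``f == 1`` plants passive overlaps (so the 'pic' rate is the false
    positive rate).
    """
    relationship = "pic" if f > 1 else "overlap"
    rng = np.random.default_rng(seed)
    counts = {"pic": 0, "passive_overlap": 0, "gap": 0}
    for _ in range(n_pairs):
        s = int(rng.integers(0, 2**31 - 1))
        img, gt, wid, tid = pair_slide(relationship, f, s, arc_deg)
        sc = score_pair(img.channel("cd45").astype(float),
                        gt.object_mask(wid), gt.object_mask(tid),
                        thresholds=thresholds)
        counts[sc.classification] += 1
    return {k: v / n_pairs for k, v in counts.items()}


# ---------------------------------------------------------------------------
# detection benchmark

_GT_TO_DETECTED = {
    "wbc": ("cell", "wbc"),
    "epi_ctc": ("cell", "epi"),
    "im_ctc": ("cell", "im"),
    "epi_lev": ("lev", "epi"),
    "im_lev": ("lev", "im"),
}


def detection_benchmark(sim_config: SimConfig | None = None,
                        det_config: DetectionConfig | None = None,
                        seed: int | None = None,
                        match_radius_px: float = 5.0) -> pd.DataFrame:
    """Per-class precision and recall of the detection stage on one
    synthetic slide, by centroid matching against planted ground truth.

    A planted object counts as recovered iff some detected event of the
    matching kind+phenotype lies within ``match_radius_px`` of its center;
    a detected event is a true positive iff it matches a planted object of
    its class.  Vesicles below the size cutoff are expected to be rejected
    and are excluded from the lev classes' ground truth.
    """
    from .simulate import generate_slide

    cfg = sim_config or SimConfig()
    if seed is not None:
        cfg.seed = seed
    image, gt = generate_slide(cfg)
    res = detect_events(image, det_config)

    detected = {}
    cells = res.cells
    detected[("cell", "wbc")] = cells[cells["phenotype"] == "wbc"]
    cand = cells[cells["ctc_candidate"]]
    detected[("cell", "epi")] = cand[cand["phenotype"] == "epi"]
    detected[("cell", "im")] = cand[cand["phenotype"] == "im"]
    levs = res.levs[res.levs["lev_candidate"]] if len(res.levs) else res.levs
    for ph in ("epi", "im"):
        detected[("lev", ph)] = (levs[levs["phenotype"] == ph]
                                 if len(levs) else levs)

    rows = []
    for cls, key in _GT_TO_DETECTED.items():
        planted = gt.objects[(gt.objects["cls"] == cls) & gt.objects["detectable"]]
        det = detected[key]
        n_p, n_d = len(planted), len(det)
        if n_p and n_d:
            tree = cKDTree(det[["cy", "cx"]].to_numpy())
            d, _ = tree.query(planted[["cy", "cx"]].to_numpy())
            tp = int((d <= match_radius_px).sum())
            tree_p = cKDTree(planted[["cy", "cx"]].to_numpy())
            d2, _ = tree_p.query(det[["cy", "cx"]].to_numpy())
            tp_det = int((d2 <= match_radius_px).sum())
        else:
            tp = tp_det = 0
        rows.append({
            "cls": cls, "n_planted": n_p, "n_detected": n_d,
            "recall": tp / n_p if n_p else np.nan,
            "precision": tp_det / n_d if n_d else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phenotype benchmark

def phenotype_benchmark(config: PhenoSimConfig | None = None,
                        seed: int = 0) -> dict:
    """Clustering + enrichment recovery on a synthetic ion-count matrix.

    Returns the adjusted Rand index between the k=2 cluster cut and planted
    class labels, plus the Fisher enrichment of in-contact events in the
    CD4-T-like cluster (odds ratio and two-sided p).
    """
    df = generate_phenotype_matrix(config, seed=seed)
    markers = [c for c in df.columns if c not in ("contact", "true_class", "role")]
    logm = log_transform(df[markers])
    labels = hierarchical_cluster(logm, k=2)
    truth = (df["true_class"] == "cd4_t_like").map({True: 1, False: 2})
    ari = adjusted_rand_score(truth, labels)
    table = contact_cluster_table(df["contact"], labels)
    odds, p = fisher_enrichment(table)
    return {"ari": float(ari), "odds_ratio": float(odds), "fisher_p": float(p),
            "table": table, "cluster_labels": labels}
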