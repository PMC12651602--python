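"""CTC / LEV / WBC identification from multichannel slide rasters.

The identification logic follows the enrichment-free liquid-biopsy
convention: every nucleated cell on the slide is segmented (here with a
classical Gaussian + Otsu + distance-transform-watershed stand-in behind a
swappable interface), events with DAPI more than ``k_dapi_low`` standard
deviations below the nucleated-cell mean are excluded as acellular, and CTC
candidates are the cells whose cytokeratin (CK) mean exceeds the
all-segmented-cell mean by ``k_ck`` standard deviations.  LEV candidates are
CK-channel components at the same CK threshold that are at least
``min_lev_diameter_um`` in equivalent diameter, below the nucleated DAPI
cutoff, and show a membrane ring in brightfield.  Immune-like (im.) versus
epithelial-like (epi.) phenotype is anchored to the observed leukocyte CD45
distribution.

All exclusions are recorded as flags, never deletions, so per-stage counts
stay reportable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple
import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from .errors import (ConfigurationError, DegenerateDistributionError,
                     InsufficientDataError)
from .simulate import SlideImage


@dataclass
class DetectionConfig:
    """Thresholds and segmentation parameters.

    ``k_dapi_low`` (default 3) and ``k_ck`` (default 6) are the SD
    multipliers of the DAPI-low exclusion and the CK positivity rule;
    ``min_lev_diameter_um`` (default 2.5) is the minimum LEV equivalent
    diameter.  ``cd45_k``: an event is immune-like iff its CD45 mean exceeds
    the detected-WBC CD45 mean minus ``cd45_k`` WBC SDs.  ``ring_tau`` is the
    minimum brightfield ring contrast (in units of background SD).
    """

    k_dapi_low: float = 3.0
    k_ck: float = 6.0
    min_lev_diameter_um: float = 2.5
    cd45_k: float = 2.0
    ring_tau: float = 2.0
    smooth_sigma: float = 1.0
    min_nucleus_area_px: int = 20
    min_lev_area_px: int = 4
    lev_smooth_sigma: float = 0.0
    # peak window must stay narrower than the smallest nucleus radius, or a
    # small WBC touching a much larger CTC is shadowed by the big cell's
    # distance-transform ridge and the pair merges into one region
    watershed_min_distance: int = 4
    dapi_threshold: float | None = None  # overrides Otsu when set

    def validate(self) -> None:
        if self.k_dapi_low <= 0 or self.k_ck <= 0:
            raise ConfigurationError("SD multipliers must be positive")
        if self.min_lev_diameter_um <= 0:
            raise ConfigurationError("min_lev_diameter_um must be positive")


EVENT_COLUMNS = [
    "event_id", "kind", "label", "cy", "cx", "area_px",
    "equivalent_diameter_um", "mean_dapi", "mean_ck", "mean_cd45", "mean_bf",
]


def _region_table(labels: np.ndarray, image: SlideImage, kind: str) -> pd.DataFrame:
    rows = []
    chans = {ch: image.channels[ch].astype(float)
             for ch in ("dapi", "ck", "cd45", "bf") if ch in image.channels}
    for rp in regionprops(labels):
        sl = rp.slice
        m = labels[sl] == rp.label
        row = {
            "event_id": rp.label, "kind": kind, "label": rp.label,
            "cy": rp.centroid[0], "cx": rp.centroid[1], "area_px": rp.area,
            "equivalent_diameter_um":
                2.0 * np.sqrt(rp.area / np.pi) * image.pixel_scale,
        }
        for ch in ("dapi", "ck", "cd45", "bf"):
            row[f"mean_{ch}"] = float(chans[ch][sl][m].mean()) if ch in chans else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def segment_nucleated_cells(image: SlideImage,
                            config: DetectionConfig | None = None
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment nuclei from the DAPI channel.

    Gaussian smoothing, a global Otsu threshold (or a fixed override), and a
    distance-transform watershed to split touching nuclei.  Returns the
    positive-integer label mask (background 0) and one event row per region
    of at least ``min_nucleus_area_px``.
    """
    config = config or DetectionConfig()
    config.validate()
    if "dapi" not in image.channels:
        raise ConfigurationError("slide has no 'dapi' channel")
    dapi = image.channels["dapi"].astype(float)
    smoothed = gaussian(dapi, sigma=config.smooth_sigma, preserve_range=True)
    if config.dapi_threshold is not None:
        thr = config.dapi_threshold
    elif smoothed.max() == smoothed.min():
        thr = np.inf  # constant image: nothing to segment
    else:
        # Otsu splits pure background noise in half on a blank slide, so the
        # threshold is floored at background median + 5 robust SDs
        med = np.median(smoothed)
        noise_floor = med + 5.0 * _background_sd(smoothed)
        thr = max(threshold_otsu(smoothed), noise_floor)
    fg = smoothed > thr
    if not fg.any():
        return np.zeros_like(dapi, dtype=np.int32), pd.DataFrame(columns=EVENT_COLUMNS)
    lab, _ = ndi.label(fg)
    areas = np.bincount(lab.ravel())
    small = np.flatnonzero(areas < config.min_nucleus_area_px)
    fg[np.isin(lab, small[small > 0])] = False
    if not fg.any():
        return np.zeros_like(dapi, dtype=np.int32), pd.DataFrame(columns=EVENT_COLUMNS)
    dist = ndi.distance_transform_edt(fg)
    dist_s = gaussian(dist, sigma=1.0, preserve_range=True)
    peaks = peak_local_max(dist_s, min_distance=config.watershed_min_distance,
                           labels=fg, exclude_border=False)
    markers = np.zeros(fg.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:  # tiny foreground without a clear peak
        markers, _ = ndi.label(fg)
    labels = watershed(-dist_s, markers, mask=fg).astype(np.int32)
    events = _region_table(labels, image, kind="cell")
    events = events[events["area_px"] >= config.min_nucleus_area_px].reset_index(drop=True)
    return labels, events


def channel_stats(events: pd.DataFrame, channel: str) -> tuple[float, float]:
    """Mean and sample SD of per-event mean intensities in ``channel``."""
    col = f"mean_{channel}"
    if col not in events.columns:
        raise ConfigurationError(f"no column {col!r} in event table")
    vals = events[col].to_numpy(dtype=float)
    if vals.size < 2:
        raise InsufficientDataError(
            f"need >= 2 events for channel stats, got {vals.size}")
    return float(vals.mean()), float(vals.std(ddof=1))


def filter_dapi_low(events: pd.DataFrame, k_dapi_low: float = 3.0) -> pd.DataFrame:
    """Flag events whose DAPI mean falls more than k SDs below the mean.

    Adds a boolean ``dapi_low_excluded`` column (flag, not deletion).
    Retained iff DAPI mean >= mu - k*sigma.
    """
    mu, sd = channel_stats(events, "dapi")
    if sd == 0:
        raise DegenerateDistributionError(
            "DAPI SD is zero; the low-DAPI cutoff is undefined")
    cutoff = mu - k_dapi_low * sd
    out = events.copy()
    out["dapi_low_excluded"] = out["mean_dapi"] < cutoff
    out.attrs["dapi_cutoff"] = cutoff
    return out


def detect_ctc_candidates(events: pd.DataFrame, k_ck: float = 6.0) -> pd.DataFrame:
    """Flag CTC candidates: CK mean strictly above mu + k*sigma.

    The CK mean/SD are computed across all retained nucleated cells
    (DAPI-low-excluded events do not contribute and cannot be candidates).
    Raising ``k_ck`` can only shrink the candidate set.
    """
    if "dapi_low_excluded" not in events.columns:
        raise ConfigurationError("run filter_dapi_low before CTC detection")
    retained = events[~events["dapi_low_excluded"]]
    mu, sd = channel_stats(retained, "ck")
    if sd == 0:
        raise DegenerateDistributionError(
            "CK SD is zero; the CTC threshold is undefined")
    thr = mu + k_ck * sd
    out = events.copy()
    out["ctc_candidate"] = (~out["dapi_low_excluded"]) & (out["mean_ck"] > thr)
    out.attrs.update(events.attrs)
    out.attrs["ck_threshold"] = thr
    return out


def _background_sd(channel: np.ndarray) -> float:
    """Robust SD of a mostly-background channel via the MAD."""
    med = np.median(channel)
    mad = np.median(np.abs(channel.astype(float) - med))
    return float(1.4826 * mad) or 1.0


def brightfield_ring_score(bf: np.ndarray, mask: np.ndarray,
                           bg_sd: float | None = None) -> float:
    """Contrast between object interior and a 2-px boundary band, in units
    of the brightfield background SD.  A membranous vesicle shows a dark
    boundary ring, giving a positive score."""
    bg_sd = bg_sd if bg_sd is not None else _background_sd(bf)
    inner = ndi.binary_erosion(mask, iterations=2)
    band = mask & ~inner
    if not band.any() or not inner.any():
        return 0.0
    bf = bf.astype(float)
    return float((bf[inner].mean() - bf[band].mean()) / bg_sd)


def detect_lev_candidates(image: SlideImage, cell_events: pd.DataFrame,
                          config: DetectionConfig | None = None
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Detect large-extracellular-vesicle candidates on the CK channel.

    The CK channel is segmented at the same CK threshold used for CTC
    detection (stored by :func:`detect_ctc_candidates` on the cell table).
    Components are retained iff equivalent diameter >= the 2.5 µm class
    cutoff, DAPI below the nucleated-cell cutoff (same cutoff as the
    cell-stage DAPI filter, so nucleated CK+ cells are never double-counted
    as LEVs), and brightfield ring score >= ``ring_tau``.  Each rejection
    reason is an independent flag.  A missing brightfield channel skips the
    ring check with a ``ring_skipped`` flag and a warning.
    """
    config = config or DetectionConfig()
    config.validate()
    ck_thr = cell_events.attrs.get("ck_threshold")
    dapi_cutoff = cell_events.attrs.get("dapi_cutoff")
    if ck_thr is None or dapi_cutoff is None:
        raise ConfigurationError(
            "cell table lacks ck_threshold/dapi_cutoff attrs; run "
            "filter_dapi_low and detect_ctc_candidates first")
    ck = image.channels["ck"].astype(float)
    # no smoothing before thresholding: vesicles near the 2.5 µm cutoff are
    # only a few pixels across and smoothing erodes them below size
    if config.lev_smooth_sigma > 0:
        ck = gaussian(ck, sigma=config.lev_smooth_sigma, preserve_range=True)
    # same noise-floor guard as the nucleus segmenter: when a slide carries
    # no CK+ events the 6-SD threshold over (CK-negative) cells lands inside
    # the pixel noise band and would segment pure noise
    noise_floor = float(np.median(ck)) + 5.0 * _background_sd(ck)
    fg = ck > max(ck_thr, noise_floor)
    raw_labels, _ = ndi.label(fg)
    # drop sub-minimum components before any per-region work: on a slide
    # with no CK+ events the threshold sits close to the noise floor and
    # tiny noise specks can number in the thousands
    areas = np.bincount(raw_labels.ravel())
    keep = np.flatnonzero(areas >= config.min_lev_area_px)
    keep = keep[keep > 0]
    lut = np.zeros(raw_labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = lut[raw_labels]
    events = _region_table(labels, image, kind="lev")

    have_bf = "bf" in image.channels
    if not have_bf:
        warnings.warn("no brightfield channel: LEV membrane-ring check skipped",
                      stacklevel=2)
        bf = None
        bg_sd = None
    else:
        bf = image.channels["bf"].astype(float)
        bg_sd = _background_sd(bf)

    slices = ndi.find_objects(labels)
    size_ex, dapi_ex, ring_fail, scores = [], [], [], []
    for _, row in events.iterrows():
        size_ex.append(row["equivalent_diameter_um"] < config.min_lev_diameter_um)
        dapi_ex.append(row["mean_dapi"] >= dapi_cutoff)
        if have_bf:
            lab = int(row["label"])
            sl = tuple(slice(max(s.start - 3, 0), min(s.stop + 3, n))
                       for s, n in zip(slices[lab - 1], labels.shape))
            s = brightfield_ring_score(bf[sl], labels[sl] == lab, bg_sd)
            scores.append(s)
            ring_fail.append(s < config.ring_tau)
        else:
            scores.append(np.nan)
            ring_fail.append(False)
    events["size_excluded"] = pd.Series(size_ex, dtype=bool)
    events["dapi_excluded"] = pd.Series(dapi_ex, dtype=bool)
    events["ring_score"] = scores
    events["ring_failed"] = pd.Series(ring_fail, dtype=bool)
    events["ring_skipped"] = not have_bf
    events["lev_candidate"] = ~(events["size_excluded"] | events["dapi_excluded"]
                                | events["ring_failed"])
    events.attrs["ck_threshold"] = ck_thr
    events.attrs["dapi_cutoff"] = dapi_cutoff
    return labels, events


def wbc_cd45_stats(cell_events: pd.DataFrame) -> tuple[float, float]:
    """CD45 mean/SD over detected WBCs (retained, non-candidate cells)."""
    if "ctc_candidate" not in cell_events.columns:
        raise ConfigurationError("run detect_ctc_candidates first")
    wbc = cell_events[~cell_events["dapi_low_excluded"]
                      & ~cell_events["ctc_candidate"]]
    return channel_stats(wbc, "cd45")


def classify_phenotype(events: pd.DataFrame, wbc_cd45_mu: float,
                       wbc_cd45_sd: float, cd45_k: float = 2.0) -> pd.DataFrame:
    """Assign epi/im phenotype to candidate events.

    Immune-like iff the event CD45 mean is strictly above
    mu_WBC - cd45_k * sigma_WBC (events exactly at the boundary are epi).
    """
    cutoff = wbc_cd45_mu - cd45_k * wbc_cd45_sd
    out = events.copy()
    out.attrs.update(events.attrs)
    out["phenotype"] = np.where(out["mean_cd45"] > cutoff, "im", "epi")
    out.attrs["cd45_cutoff"] = cutoff
    return out


class DetectionResult(NamedTuple):
    cell_labels: np.ndarray
    cells: pd.DataFrame
    lev_labels: np.ndarray
    levs: pd.DataFrame


def detect_events(image: SlideImage,
                  config: DetectionConfig | None = None) -> DetectionResult:
    """Full detection pipeline on one slide.

    Segments nuclei, applies the DAPI-low exclusion and the CK rule, detects
    LEVs, and phenotypes CTC and LEV candidates against the leukocyte CD45
    distribution.  ``cells`` gains ``phenotype`` ('wbc' for retained
    non-candidates, epi/im for candidates, 'excluded' for DAPI-low rows);
    ``levs`` gains epi/im for retained candidates.
    """
    config = config or DetectionConfig()
    cell_labels, cells = segment_nucleated_cells(image, config)
    if len(cells) < 2:
        raise InsufficientDataError("fewer than 2 nucleated cells segmented")
    cells = filter_dapi_low(cells, config.k_dapi_low)
    cells = detect_ctc_candidates(cells, config.k_ck)
    mu_w, sd_w = wbc_cd45_stats(cells)
    cells = classify_phenotype(cells, mu_w, sd_w, config.cd45_k)
    cells.loc[~cells["ctc_candidate"], "phenotype"] = "wbc"
    cells.loc[cells["dapi_low_excluded"], "phenotype"] = "excluded"
    lev_labels, levs = detect_lev_candidates(image, cells, config)
    if len(levs):
        levs = classify_phenotype(levs, mu_w, sd_w, config.cd45_k)
        levs.loc[~levs["lev_candidate"], "phenotype"] = "excluded"
    return DetectionResult(cell_labels, cells, lev_labels, levs)
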