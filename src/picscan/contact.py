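"""Contact-interface membrane enrichment scoring (the PIC statistic).

For each WBC touching a tumor event, the WBC perimeter is traced from its
segmented mask and split into a contact region (perimeter positions
adjacent to the partner mask) and a non-contact region (positions adjacent
to background).  The membrane-marker fold change
``mean(contact) / mean(non-contact)`` quantifies interface enrichment;
together with a circumferential asymmetry score (resultant-vector length of
the intensity-weighted perimeter directions) and the contact arc fraction,
it separates physiologically interacting clusters (PICs) from passive
overlaps.  Groups of fold changes are compared with the Mann-Whitney U test
(see :mod:`picscan.stats`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import DegenerateContactError, GeometryError, UndefinedRatioError
from .stats import GroupComparison, mann_whitney  # noqa: F401  (re-exported)

_CROSS = ndi.generate_binary_structure(2, 1)


@dataclass
class PerimeterProfile:
    """Ordered perimeter of one mask with per-position intensity and
    contact labels.

    ``coords`` is an (N, 2) array of (row, col) boundary pixels in closed
    circumferential order; ``intensity`` and ``contact`` align with it
    (``contact`` is None until :func:`label_contact_regions` runs).
    """

    coords: np.ndarray
    centroid: tuple[float, float]
    intensity: np.ndarray | None = None
    contact: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def perimeter_length(self) -> float:
        """Euclidean polyline length of the closed trace (diagonal steps
        count sqrt(2)); tracks the geometric circumference of disk-like
        masks far better than the raw boundary-pixel count."""
        if len(self.coords) < 2:
            return 0.0
        closed = np.vstack([self.coords, self.coords[:1]])
        steps = np.diff(closed, axis=0)
        return float(np.hypot(steps[:, 0], steps[:, 1]).sum())

    @property
    def contact_fraction(self) -> float:
        if self.contact is None:
            raise DegenerateContactError("contact regions not labeled yet")
        return float(self.contact.mean())

    def to_frame(self) -> pd.DataFrame:
        """Per-position trace (for Fig-style intensity-vs-position plots)."""
        df = pd.DataFrame({
            "position": np.arange(len(self.coords)),
            "y": self.coords[:, 0], "x": self.coords[:, 1],
        })
        if self.intensity is not None:
            df["intensity"] = self.intensity
        if self.contact is not None:
            df["region"] = np.where(self.contact, "contact", "non_contact")
        return df


def boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Unordered boundary set: mask pixels with a 4-neighbor outside."""
    eroded = ndi.binary_erosion(mask, structure=_CROSS, border_value=0)
    return np.argwhere(mask & ~eroded)


def extract_perimeter(mask: np.ndarray) -> PerimeterProfile:
    """Closed, ordered boundary trace of a single connected region.

    Boundary pixels (those with a 4-connected background neighbor) are
    ordered by polar angle about the region centroid — exact for
    star-convex masks, which disk-like cell masks are.  Every boundary
    pixel appears exactly once and the trace closes on itself.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise GeometryError("empty mask")
    n_comp = ndi.label(mask, structure=np.ones((3, 3)))[1]
    if n_comp != 1:
        raise GeometryError(f"mask has {n_comp} connected components, need 1")
    if ndi.binary_fill_holes(mask).sum() != mask.sum():
        raise GeometryError("mask is multiply-connected (has holes)")
    pts = boundary_pixels(mask)
    cy, cx = np.argwhere(mask).mean(axis=0)
    if len(pts) == 1:
        return PerimeterProfile(coords=pts, centroid=(cy, cx))
    ang = np.arctan2(pts[:, 0] - cy, pts[:, 1] - cx)
    # tie-break equal angles by radius so the order is deterministic
    rad = np.hypot(pts[:, 0] - cy, pts[:, 1] - cx)
    order = np.lexsort((rad, ang))
    return PerimeterProfile(coords=pts[order], centroid=(cy, cx))


def sample_perimeter_intensity(channel: np.ndarray, mask: np.ndarray,
                               profile: PerimeterProfile,
                               band_px: int = 1) -> PerimeterProfile:
    """Attach membrane-channel intensity to each perimeter position.

    ``band_px=1`` (default) samples the boundary pixel itself, which for an
    annular membrane always lies on the ring; ``band_px=2`` averages the
    8-neighborhood restricted to the mask, damping single-pixel noise at the
    cost of pulling in sub-membrane interior signal.
    """
    channel = np.asarray(channel, dtype=float)
    coords = profile.coords
    if band_px <= 1:
        vals = channel[coords[:, 0], coords[:, 1]]
    else:
        h, w = channel.shape
        sums = np.zeros(len(coords))
        cnts = np.zeros(len(coords))
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy = coords[:, 0] + dy
                xx = coords[:, 1] + dx
                ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)
                ok[ok] &= mask[yy[ok], xx[ok]]
                sums[ok] += channel[yy[ok], xx[ok]]
                cnts[ok] += 1
        vals = sums / np.maximum(cnts, 1)
    profile.intensity = vals
    return profile


def label_contact_regions(profile: PerimeterProfile, partner_mask: np.ndarray,
                          radius: int = 1) -> PerimeterProfile:
    """Label each perimeter position contact / non-contact.

    A position is contact iff it lies within ``radius`` (Chebyshev) of any
    partner-mask pixel.  Raises if the perimeter is entirely contact (the
    partner engulfs the WBC) or entirely non-contact (no adjacency): the
    fold change is undefined in both cases.
    """
    partner = np.asarray(partner_mask, dtype=bool)
    near = ndi.binary_dilation(partner, structure=np.ones((2 * radius + 1,) * 2))
    contact = near[profile.coords[:, 0], profile.coords[:, 1]]
    if contact.all():
        raise DegenerateContactError("perimeter entirely in contact "
                                     "(partner engulfs the cell)")
    if not contact.any():
        raise DegenerateContactError("no contact positions (gap pair)")
    profile.contact = contact
    return profile


@dataclass(frozen=True)
class EnrichmentResult:
    """Fold change of membrane intensity at the contact interface."""

    fold_change: float
    contact_fraction: float
    asymmetry: float


def enrichment_fold_change(profile: PerimeterProfile,
                           eps: float = 1e-12) -> EnrichmentResult:
    """mean(contact) / mean(non-contact) intensity plus asymmetry.

    The asymmetry score is the resultant-vector length of intensity-weighted
    unit directions from the centroid to each perimeter position: 0 for a
    circumferentially uniform ring, approaching 1 when all intensity sits on
    one narrow arc.  Invariant under multiplicative intensity gain.
    """
    if profile.intensity is None:
        raise GeometryError("profile has no sampled intensity")
    if profile.contact is None:
        raise DegenerateContactError("contact regions not labeled")
    inten = profile.intensity
    contact = profile.contact
    non_mean = float(inten[~contact].mean())
    if abs(non_mean) < eps:
        raise UndefinedRatioError("non-contact mean intensity is zero")
    fold = float(inten[contact].mean()) / non_mean
    vec = profile.coords - np.asarray(profile.centroid)
    norm = np.hypot(vec[:, 0], vec[:, 1])
    norm[norm == 0] = 1.0
    unit = vec / norm[:, None]
    w = np.clip(inten, 0, None)
    total = float(w.sum())
    asym = 0.0 if total <= eps else float(
        np.hypot(*(unit * w[:, None]).sum(axis=0)) / total)
    return EnrichmentResult(fold_change=fold,
                            contact_fraction=float(contact.mean()),
                            asymmetry=asym)


@dataclass(frozen=True)
class PicThresholds:
    """Classification gates for PIC vs passive overlap.

    These are analysis knobs, not published constants (the original
    annotation was by human review): a pair is a PIC iff fold change >=
    ``f_min``, asymmetry >= ``a_min``, and contact arc fraction within
    [``c_lo``, ``c_hi``].  Defaults recover planted folds >= 1.5 at >= 95%
    sensitivity while keeping uniform-ring false positives <= 5%
    (calibrated on the synthetic pair generator at its default geometry).
    """

    f_min: float = 1.3
    a_min: float = 0.04
    c_lo: float = 0.05
    c_hi: float = 0.9


def classify_pic(adjacent: bool, enrichment: EnrichmentResult | None,
                 thresholds: PicThresholds | None = None) -> str:
    """'gap' if no mask adjacency; else 'pic' iff all enrichment gates pass,
    else 'passive_overlap'."""
    if not adjacent:
        return "gap"
    if enrichment is None:
        raise DegenerateContactError(
            "adjacent pair requires a computed EnrichmentResult")
    t = thresholds or PicThresholds()
    is_pic = (enrichment.fold_change >= t.f_min
              and enrichment.asymmetry >= t.a_min
              and t.c_lo <= enrichment.contact_fraction <= t.c_hi)
    return "pic" if is_pic else "passive_overlap"


@dataclass
class PairScore:
    classification: str
    enrichment: EnrichmentResult | None
    profile: PerimeterProfile | None


def score_pair(channel: np.ndarray, wbc_mask: np.ndarray,
               partner_mask: np.ndarray, band_px: int = 1,
               contact_radius: int = 1,
               thresholds: PicThresholds | None = None) -> PairScore:
    """End-to-end scoring of one WBC-tumor pair on a membrane channel.

    Checks adjacency, traces the WBC perimeter, samples intensity, labels
    contact regions, computes the fold change and classifies the pair.
    """
    wbc = np.asarray(wbc_mask, dtype=bool)
    partner = np.asarray(partner_mask, dtype=bool)
    near = ndi.binary_dilation(partner,
                               structure=np.ones((2 * contact_radius + 1,) * 2))
    # the WBC mask may include pixels shared with the partner; adjacency is
    # contact of the WBC footprint with the (dilated) partner footprint
    if not (near & wbc).any():
        return PairScore(classification="gap", enrichment=None, profile=None)
    profile = extract_perimeter(wbc)
    profile = sample_perimeter_intensity(channel, wbc, profile, band_px=band_px)
    profile = label_contact_regions(profile, partner, radius=contact_radius)
    enr = enrichment_fold_change(profile)
    return PairScore(classification=classify_pic(True, enr, thresholds),
                     enrichment=enr, profile=profile)
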