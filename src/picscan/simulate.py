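"""Synthetic multichannel slide generator with exact planted ground truth.

Emulates the imaging substrate of an enrichment-free liquid biopsy: a dense
lawn of nucleated white blood cells (WBCs) with rare cytokeratin-positive
(CK+) circulating tumor cells (CTCs) and large extracellular vesicles (LEVs)
scattered among them, plus planted tumor-immune pairs in three relationship
classes:

``pic``
    touching pair whose WBC membrane (CD45) ring is multiplied by a fold
    ``f > 1`` on the arc facing the tumor partner — the signature of a
    physiologically interacting cluster;
``overlap``
    overlapping pair with a circumferentially uniform ring (``f = 1``);
``gap``
    pair separated by a configurable background gap (no mask contact).

Cells are disks with annular membrane rings; this is the simplest shape
whose perimeter partition has a closed-form oracle, which is exactly what
the downstream contact-scoring stage needs for verification.  Channels are
composed as background + max-of-signals (brightfield: background − dark
membrane ring) with additive Gaussian noise clipped to the 16-bit range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import PlacementError, ValidationError

CHANNELS = ("dapi", "ck", "cd45", "bf")

#: ground-truth object classes
CLASSES = ("wbc", "epi_ctc", "im_ctc", "epi_lev", "im_lev")


@dataclass
class SimConfig:
    """Parameters of one synthetic slide.

    Intensity levels are above-background amplitudes on the 16-bit scale;
    radii and the gap width are in micrometres, converted through
    ``pixel_scale`` (µm/px).  ``contact_arc_deg`` is the full wedge angle of
    the enriched membrane arc; for ``pic`` pairs the partner is placed so
    that the geometric contact arc matches it.
    """

    width: int = 2048
    height: int = 2048
    pixel_scale: float = 0.5  # µm per pixel

    # object counts; CK+ events are kept rare relative to WBCs because the
    # 6-SD cytokeratin rule assumes the CK distribution is dominated by
    # CK-negative nucleated cells (SD inflates like contrast * sqrt(p)
    # with CK+ fraction p, so p must stay below ~2%)
    n_wbc: int = 1500
    n_epi_ctc: int = 6
    n_im_ctc: int = 4
    n_epi_lev: int = 6
    n_im_lev: int = 4
    n_small_ev: int = 5  # vesicles below the 2.5 µm cutoff
    n_pic: int = 4
    n_overlap: int = 3
    n_gap_pair: int = 3

    wbc_radius_um: tuple[float, float] = (3.5, 5.0)
    ctc_radius_um: tuple[float, float] = (5.0, 8.0)
    lev_radius_um: tuple[float, float] = (1.5, 3.5)
    small_ev_radius_um: tuple[float, float] = (0.5, 1.1)

    background: dict = field(
        default_factory=lambda: {"dapi": 300.0, "ck": 300.0, "cd45": 300.0, "bf": 10000.0}
    )
    noise_sd: dict = field(
        default_factory=lambda: {"dapi": 50.0, "ck": 50.0, "cd45": 50.0, "bf": 100.0}
    )

    dapi_intensity: float = 12000.0
    ck_intensity: float = 8000.0
    cd45_im_intensity: float = 5000.0  # diffuse CD45 of immune-like tumor events
    membrane_intensity: float = 6000.0  # WBC CD45 ring amplitude (I_mem)
    bf_ring_depth: float = 3000.0  # brightfield dip of the vesicle membrane
    ring_width_px: int = 2
    intensity_cv: float = 0.1  # per-object lognormal brightness jitter (mean-preserving)

    contact_fold: float = 2.0  # f
    contact_arc_deg: float = 60.0  # θ, full wedge angle
    gap_um: float = 1.0  # g
    max_place_tries: int = 100
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_wbc, self.n_epi_ctc, self.n_im_ctc, self.n_epi_lev,
            self.n_im_lev, self.n_small_ev, self.n_pic, self.n_overlap,
            self.n_gap_pair,
        )
        if any(c < 0 for c in counts):
            raise ValidationError("object counts must be >= 0")
        if self.contact_fold < 1.0:
            raise ValidationError("contact_fold must be >= 1")
        if not 0.0 < self.contact_arc_deg <= 180.0:
            raise ValidationError("contact_arc_deg must be in (0, 180]")
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be positive")
        if self.gap_um <= 0:
            raise ValidationError("gap width must be positive")
        for rng_um in (self.wbc_radius_um, self.ctc_radius_um,
                       self.lev_radius_um, self.small_ev_radius_um):
            if not (0 < rng_um[0] <= rng_um[1]):
                raise ValidationError(f"bad radius range {rng_um}")
        if self.ring_width_px < 1:
            raise ValidationError("ring_width_px must be >= 1")
        if self.intensity_cv < 0:
            raise ValidationError("intensity_cv must be >= 0")


@dataclass
class SlideImage:
    """A multichannel 16-bit slide raster.

    ``channels`` holds the noisy uint16 images keyed by channel name;
    ``clean`` holds the pre-noise float intensity fields (kept so planted
    expectations can be verified without noise).
    """

    channels: dict
    pixel_scale: float
    clean: dict | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        return self.channels[name]


class GroundTruth:
    """Table of planted objects plus geometry helpers.

    Columns of ``objects``: id, cls, cx, cy, radius_px, fold, pair_id,
    relationship, detectable.  ``detectable`` marks vesicles whose planted
    diameter reaches the 2.5 µm class definition (cells are always True).
    """

    def __init__(self, objects: pd.DataFrame, shape: tuple[int, int], pixel_scale: float):
        self.objects = objects.reset_index(drop=True)
        self.shape = shape
        self.pixel_scale = pixel_scale

    def __len__(self) -> int:
        return len(self.objects)

    def row(self, obj_id: int) -> pd.Series:
        match = self.objects[self.objects["id"] == obj_id]
        if match.empty:
            raise KeyError(f"no planted object with id {obj_id}")
        return match.iloc[0]

    def object_mask(self, obj_id: int) -> np.ndarray:
        """Full-disk boolean footprint of one planted object."""
        r = self.row(obj_id)
        return disk_mask(self.shape, r["cx"], r["cy"], r["radius_px"])

    def label_mask(self, classes=None) -> np.ndarray:
        """Integer label image; overlap pixels go to the object whose
        boundary is farthest away (signed-distance assignment)."""
        labels = np.zeros(self.shape, dtype=np.int32)
        depth = np.full(self.shape, np.inf)
        sel = self.objects
        if classes is not None:
            sel = sel[sel["cls"].isin(classes)]
        for _, r in sel.iterrows():
            sl, dist = _disk_distance(self.shape, r["cx"], r["cy"], r["radius_px"])
            if sl is None:
                continue
            signed = dist - r["radius_px"]
            inside = signed <= 0
            better = inside & (signed < depth[sl])
            labels[sl][better] = int(r["id"])
            depth[sl][better] = signed[better]
        return labels

    def pairs(self) -> pd.DataFrame:
        """One row per planted pair: pair_id, relationship, wbc_id, tumor_id, fold."""
        paired = self.objects.dropna(subset=["pair_id"])
        rows = []
        for pid, grp in paired.groupby("pair_id"):
            wbc = grp[grp["cls"] == "wbc"]
            tumor = grp[grp["cls"] != "wbc"]
            rows.append({
                "pair_id": int(pid),
                "relationship": grp["relationship"].iloc[0],
                "wbc_id": int(wbc["id"].iloc[0]),
                "tumor_id": int(tumor["id"].iloc[0]),
                "fold": float(wbc["fold"].iloc[0]),
            })
        return pd.DataFrame(rows, columns=["pair_id", "relationship", "wbc_id", "tumor_id", "fold"])


# ---------------------------------------------------------------------------
# rasterization primitives

def _bbox(shape, cx, cy, r):
    y0 = max(int(math.floor(cy - r)) - 1, 0)
    y1 = min(int(math.ceil(cy + r)) + 2, shape[0])
    x0 = max(int(math.floor(cx - r)) - 1, 0)
    x1 = min(int(math.ceil(cx + r)) + 2, shape[1])
    if y0 >= y1 or x0 >= x1:
        return None
    return (slice(y0, y1), slice(x0, x1))


def _disk_distance(shape, cx, cy, r):
    sl = _bbox(shape, cx, cy, r)
    if sl is None:
        return None, None
    yy, xx = np.mgrid[sl]
    dist = np.hypot(yy - cy, xx - cx)
    return sl, dist


def disk_mask(shape, cx, cy, r) -> np.ndarray:
    """Rasterize a disk (pixel centers within Euclidean distance r)."""
    mask = np.zeros(shape, dtype=bool)
    sl, dist = _disk_distance(shape, cx, cy, r)
    if sl is not None:
        mask[sl] = dist <= r
    return mask


def _wrap_angle(a):
    return (a + np.pi) % (2 * np.pi) - np.pi


class SlideCanvas:
    """Mutable slide under construction: signal fields + placement state."""

    def __init__(self, config: SimConfig, rng: np.random.Generator | None = None):
        config.validate()
        self.config = config
        self.shape = (config.height, config.width)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.fields = {ch: np.zeros(self.shape) for ch in ("dapi", "ck", "cd45")}
        self.bf_dark = np.zeros(self.shape)
        self._placed: list[tuple[float, float, float]] = []
        self._rows: list[dict] = []
        self._next_id = 1
        self._next_pair = 1

    # -- placement ---------------------------------------------------------

    def _clear_of_others(self, cx, cy, r, clearance=2.0) -> bool:
        if not self._placed:
            return True
        px, py, pr = (np.asarray(v) for v in zip(*self._placed))
        return bool(np.all(np.hypot(cx - px, cy - py) >= r + pr + clearance))

    def _sample_center(self, r):
        h, w = self.shape
        margin = r + 2
        if 2 * margin >= w or 2 * margin >= h:
            raise PlacementError(
                f"object of effective radius {r:.1f} px does not fit on a "
                f"{h}x{w} canvas")
        cx = self.rng.uniform(margin, w - margin)
        cy = self.rng.uniform(margin, h - margin)
        return cx, cy

    def _radius_px(self, range_um):
        lo, hi = range_um
        return self.rng.uniform(lo, hi) / self.config.pixel_scale

    def _jitter(self) -> float:
        cv = self.config.intensity_cv
        if cv <= 0:
            return 1.0
        s = math.sqrt(math.log(1 + cv * cv))
        return float(self.rng.lognormal(-0.5 * s * s, s))  # mean-preserving

    # -- painting ----------------------------------------------------------

    def _paint_disk(self, chan, cx, cy, r, amp):
        tgt = self.bf_dark if chan == "bf_dark" else self.fields[chan]
        sl, dist = _disk_distance(self.shape, cx, cy, r)
        if sl is None:
            return
        patch = tgt[sl]
        inside = dist <= r
        np.maximum(patch, np.where(inside, amp, 0.0), out=patch)

    def _paint_ring(self, chan, cx, cy, r, amp, *, fold=1.0, arc_deg=None,
                    toward=None, width=None):
        """Paint an annular ring [r-width, r]; optionally multiply the amplitude
        by ``fold`` on the wedge of full angle ``arc_deg`` centered on the
        direction ``toward`` (radians)."""
        width = self.config.ring_width_px if width is None else width
        tgt = self.bf_dark if chan == "bf_dark" else self.fields[chan]
        sl, dist = _disk_distance(self.shape, cx, cy, r)
        if sl is None:
            return
        ring = (dist <= r) & (dist >= r - width)
        amps = np.where(ring, amp, 0.0)
        if fold != 1.0 and arc_deg is not None and toward is not None:
            yy, xx = np.mgrid[sl]
            ang = np.arctan2(yy - cy, xx - cx)
            wedge = np.abs(_wrap_angle(ang - toward)) <= math.radians(arc_deg) / 2.0
            amps = np.where(ring & wedge, amp * fold, amps)
        patch = tgt[sl]
        np.maximum(patch, amps, out=patch)

    def _record(self, cls, cx, cy, r, *, fold=1.0, pair_id=None,
                relationship=None, detectable=True) -> int:
        oid = self._next_id
        self._next_id += 1
        self._placed.append((cx, cy, r))
        self._rows.append({
            "id": oid, "cls": cls, "cx": cx, "cy": cy, "radius_px": r,
            "fold": fold, "pair_id": pair_id, "relationship": relationship,
            "detectable": bool(detectable),
        })
        return oid

    def _paint_object(self, cls, cx, cy, r, *, fold=1.0, toward=None):
        c = self.config
        if cls == "wbc":
            self._paint_disk("dapi", cx, cy, r, c.dapi_intensity * self._jitter())
            self._paint_ring("cd45", cx, cy, r, c.membrane_intensity * self._jitter(),
                             fold=fold, arc_deg=c.contact_arc_deg, toward=toward)
        elif cls in ("epi_ctc", "im_ctc"):
            self._paint_disk("dapi", cx, cy, r, c.dapi_intensity * self._jitter())
            self._paint_disk("ck", cx, cy, r, c.ck_intensity * self._jitter())
            if cls == "im_ctc":
                self._paint_disk("cd45", cx, cy, r, c.cd45_im_intensity * self._jitter())
        elif cls in ("epi_lev", "im_lev"):
            self._paint_disk("ck", cx, cy, r, c.ck_intensity * self._jitter())
            self._paint_ring("bf_dark", cx, cy, r, c.bf_ring_depth)
            if cls == "im_lev":
                self._paint_disk("cd45", cx, cy, r, c.cd45_im_intensity * self._jitter())
        else:
            raise ValidationError(f"unknown object class {cls!r}")

    # -- public building blocks -------------------------------------------

    def add_object(self, cls, radius_range_um=None) -> int:
        """Place and paint one standalone object of the given class."""
        c = self.config
        defaults = {
            "wbc": c.wbc_radius_um, "epi_ctc": c.ctc_radius_um,
            "im_ctc": c.ctc_radius_um, "epi_lev": c.lev_radius_um,
            "im_lev": c.lev_radius_um,
        }
        rng_um = radius_range_um if radius_range_um is not None else defaults[cls]
        r = self._radius_px(rng_um)
        for _ in range(c.max_place_tries):
            cx, cy = self._sample_center(r)
            if self._clear_of_others(cx, cy, r):
                break
        else:
            raise PlacementError(f"could not place standalone {cls} after "
                                 f"{c.max_place_tries} tries")
        self._paint_object(cls, cx, cy, r)
        detectable = (cls in ("wbc", "epi_ctc", "im_ctc")
                      or 2 * r * c.pixel_scale >= 2.5)
        return self._record(cls, cx, cy, r, detectable=detectable)

    def plant_pair(self, class_a="wbc", class_b="epi_ctc", relationship="pic",
                   f=None, arc_deg=None, gap_um=None) -> tuple[int, int]:
        """Place a WBC (class_a) and a tumor partner in the requested
        relationship; returns (wbc_id, partner_id).

        ``pic``: partner placed so the geometric contact arc equals the
        wedge angle, and the WBC ring amplitude is multiplied by ``f`` on
        that arc.  ``overlap``: overlapping, uniform ring (f forced to 1).
        ``gap``: center distance = r_a + r_b + gap (no contact).
        """
        c = self.config
        if class_a != "wbc":
            raise ValidationError("class_a of a pair must be 'wbc'")
        if relationship not in ("pic", "overlap", "gap"):
            raise ValidationError(f"unknown relationship {relationship!r}")
        f = c.contact_fold if f is None else float(f)
        arc_deg = c.contact_arc_deg if arc_deg is None else float(arc_deg)
        gap_um = c.gap_um if gap_um is None else float(gap_um)
        if relationship == "pic" and f <= 1.0:
            raise ValidationError("pic pairs require fold f > 1")
        if relationship == "gap" and gap_um <= 0:
            raise ValidationError("gap width must be positive")
        if not 0.0 < arc_deg <= 180.0:
            raise ValidationError("arc angle must be in (0, 180]")

        r_w = self._radius_px(c.wbc_radius_um)
        ranges = {"epi_ctc": c.ctc_radius_um, "im_ctc": c.ctc_radius_um,
                  "epi_lev": c.lev_radius_um, "im_lev": c.lev_radius_um}
        r_t = self._radius_px(ranges[class_b])

        if relationship == "gap":
            d = r_w + r_t + gap_um / c.pixel_scale
        elif relationship == "overlap":
            d = r_w + r_t - max(2.0, 0.15 * (r_w + r_t))
        else:  # pic: solve center distance so contact arc (adjacency radius
            # 1 px) spans arc_deg on the WBC perimeter
            beta = math.radians(arc_deg) / 2.0
            rt1 = r_t + 1.0
            disc = r_w * r_w * math.cos(beta) ** 2 - r_w * r_w + rt1 * rt1
            d = r_w * math.cos(beta) + math.sqrt(max(disc, 0.0))
            d = min(d, r_w + r_t - 0.5)  # pairs must genuinely overlap/touch

        pair_margin = gap_um / c.pixel_scale if relationship == "gap" else 0.0
        h, w = self.shape
        if 2 * (r_w + d + 4) >= min(h, w):
            raise PlacementError(
                f"{relationship} pair ({class_a}/{class_b}) does not fit on a "
                f"{h}x{w} canvas (span {2 * (r_w + d):.0f} px)")
        for _ in range(c.max_place_tries):
            cx, cy = self._sample_center(r_w + d + 2)
            if not self._clear_of_others(cx, cy, r_w, clearance=2.0 + pair_margin):
                continue
            psi = self.rng.uniform(0, 2 * np.pi)
            tx = cx + d * math.cos(psi)
            ty = cy + d * math.sin(psi)
            h, w = self.shape
            if not (r_t + 2 <= tx <= w - r_t - 2 and r_t + 2 <= ty <= h - r_t - 2):
                continue
            if self._clear_of_others(tx, ty, r_t, clearance=2.0 + pair_margin):
                break
        else:
            raise PlacementError(
                f"could not place {relationship} pair ({class_a}/{class_b}) "
                f"after {c.max_place_tries} tries")

        fold = f if relationship == "pic" else 1.0
        toward = psi if relationship == "pic" else None
        self._paint_object("wbc", cx, cy, r_w, fold=fold, toward=toward)
        self._paint_object(class_b, tx, ty, r_t)
        pid = self._next_pair
        self._next_pair += 1
        wid = self._record("wbc", cx, cy, r_w, fold=fold, pair_id=pid,
                           relationship=relationship)
        det = class_b in ("epi_ctc", "im_ctc") or 2 * r_t * c.pixel_scale >= 2.5
        tid = self._record(class_b, tx, ty, r_t, pair_id=pid,
                           relationship=relationship, detectable=det)
        return wid, tid

    # -- output ------------------------------------------------------------

    def finalize(self, with_noise: bool = True) -> tuple[SlideImage, GroundTruth]:
        c = self.config
        clean = {ch: c.background[ch] + self.fields[ch] for ch in ("dapi", "ck", "cd45")}
        clean["bf"] = c.background["bf"] - self.bf_dark
        channels = {}
        for ch in CHANNELS:
            img = clean[ch]
            if with_noise and c.noise_sd[ch] > 0:
                img = img + self.rng.normal(0.0, c.noise_sd[ch], self.shape)
            channels[ch] = np.clip(img, 0, 65535).astype(np.uint16)
        cols = ["id", "cls", "cx", "cy", "radius_px", "fold", "pair_id",
                "relationship", "detectable"]
        objects = pd.DataFrame(self._rows, columns=cols)
        objects["pair_id"] = objects["pair_id"].astype("Int64")
        gt = GroundTruth(objects, self.shape, c.pixel_scale)
        return SlideImage(channels=channels, pixel_scale=c.pixel_scale, clean=clean), gt


def generate_slide(config: SimConfig,
                   with_noise: bool = True) -> tuple[SlideImage, GroundTruth]:
    """Generate one synthetic slide and its exact ground truth.

    Identical config + seed produce bit-identical output.  Pairs are placed
    first (their geometry is the most constrained), then standalone events,
    then the WBC lawn.
    """
    canvas = SlideCanvas(config)
    c = config
    for _ in range(c.n_pic):
        canvas.plant_pair("wbc", "epi_ctc", "pic")
    for _ in range(c.n_overlap):
        canvas.plant_pair("wbc", "epi_ctc", "overlap")
    for _ in range(c.n_gap_pair):
        canvas.plant_pair("wbc", "epi_ctc", "gap")
    for cls, n in (("epi_ctc", c.n_epi_ctc), ("im_ctc", c.n_im_ctc),
                   ("epi_lev", c.n_epi_lev), ("im_lev", c.n_im_lev)):
        for _ in range(n):
            canvas.add_object(cls)
    for _ in range(c.n_small_ev):
        canvas.add_object("epi_lev", radius_range_um=c.small_ev_radius_um)
    for _ in range(c.n_wbc):
        canvas.add_object("wbc")
    return canvas.finalize(with_noise=with_noise)


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)


def config_from_dict(d: dict) -> SimConfig:
    cfg = SimConfig(**d)
    for key in ("wbc_radius_um", "ctc_radius_um", "lev_radius_um", "small_ev_radius_um"):
        setattr(cfg, key, tuple(getattr(cfg, key)))
    cfg.validate()
    return cfg
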