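"""Per-patient enumeration and cohort summaries.

Slide-level event counts are extrapolated to events per mL of blood via the
plated fraction (count x total cells / plated cells / blood volume — the
standard convention for enrichment-free platforms, where only part of the
nucleated-cell pellet is plated and analyzed), then aggregated into
per-patient totals and phenotype fractions and cohort positivity
percentages.

A small per-mL enumeration table for an eight-patient example cohort ships
with the package (``load_example_cohort``) so the summary arithmetic has a
worked reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import ValidationError

PHENO_COLS = ["im_ctc_per_ml", "epi_ctc_per_ml", "pic_ctc_per_ml",
              "im_lev_per_ml", "epi_lev_per_ml", "pic_lev_per_ml"]


@dataclass
class SlideMeta:
    """Sample bookkeeping needed to scale slide counts to counts per mL."""

    patient: str
    blood_ml: float = 8.0
    total_cells: float = 3e6
    plated_cells: float = 3e6
    slides_analyzed: int = 1
    slides_total: int = 1

    def validate(self) -> None:
        if self.blood_ml <= 0 or self.total_cells <= 0 or self.plated_cells <= 0:
            raise ValidationError("volumes and cell counts must be positive")
        if self.plated_cells > self.total_cells:
            raise ValidationError("plated cells cannot exceed total cells")
        if not 1 <= self.slides_analyzed <= self.slides_total:
            raise ValidationError("slides analyzed must be in [1, slides_total]")


def per_ml(count: float, meta: SlideMeta) -> float:
    """Events per mL: count x (total cells / plated-and-analyzed cells) / mL."""
    meta.validate()
    if count < 0:
        raise ValidationError("count must be >= 0")
    return count * (meta.total_cells / meta.plated_cells) / meta.blood_ml


def summarize_patient(row) -> dict:
    """Totals and fractions for one per-mL enumeration row.

    ``total_ctc_per_ml`` includes PIC CTCs (the inclusive denominator, also
    used for ``pic_ctc_fraction``); ``total_ctc_excl_pic_per_ml`` is emitted
    alongside since published usage is ambiguous on whether in-cluster CTCs
    count toward the total.  Fractions with zero denominators are NaN
    (undefined), never 0.
    """
    row = pd.Series(row) if not isinstance(row, pd.Series) else row
    im_c, epi_c, pic_c = (float(row[c]) for c in PHENO_COLS[:3])
    im_l, epi_l, pic_l = (float(row[c]) for c in PHENO_COLS[3:])
    total_c = im_c + epi_c + pic_c
    total_l = im_l + epi_l + pic_l

    def frac(num, den):
        return num / den if den > 0 else math.nan

    return {
        "total_ctc_per_ml": total_c,
        "total_ctc_excl_pic_per_ml": im_c + epi_c,
        "total_lev_per_ml": total_l,
        "total_lev_excl_pic_per_ml": im_l + epi_l,
        "pic_ctc_fraction": frac(pic_c, total_c),
        "pic_lev_fraction": frac(pic_l, total_l),
        "im_ctc_fraction": frac(im_c, im_c + epi_c),
        "im_lev_fraction": frac(im_l, im_l + epi_l),
    }


def round_percent(num: int, den: int) -> int:
    """Percentage rounded half-up to the nearest integer."""
    if den <= 0:
        raise ValidationError("denominator must be positive")
    return int(math.floor(num / den * 100.0 + 0.5))


def summarize_cohort(cohort: pd.DataFrame, n_patients_total: int | None = None) -> dict:
    """Cohort positivity counts and integer percentages.

    ``cohort`` holds one per-mL enumeration row per patient (columns of
    ``PHENO_COLS``).  ``n_patients_total`` is the full screened cohort size
    when the table only lists positive patients (denominator for the
    CTC-positivity percentage); defaults to the table length.
    """
    if cohort.empty:
        raise ValidationError("need at least one patient")
    n_total = n_patients_total if n_patients_total is not None else len(cohort)
    ctc_pos = int(((cohort["im_ctc_per_ml"] + cohort["epi_ctc_per_ml"]
                    + cohort["pic_ctc_per_ml"]) > 0).sum())
    im_ctc_pos = int((cohort["im_ctc_per_ml"] > 0).sum())
    lev_pos = int(((cohort["im_lev_per_ml"] + cohort["epi_lev_per_ml"]
                    + cohort["pic_lev_per_ml"]) > 0).sum())
    im_lev_pos = int((cohort["im_lev_per_ml"] > 0).sum())
    pic_pos = int(((cohort["pic_ctc_per_ml"] + cohort["pic_lev_per_ml"]) > 0).sum())
    return {
        "n_patients_total": n_total,
        "n_ctc_positive": ctc_pos,
        "pct_ctc_positive": round_percent(ctc_pos, n_total),
        "n_im_ctc_positive": im_ctc_pos,
        "pct_im_ctc_among_ctc_positive":
            round_percent(im_ctc_pos, ctc_pos) if ctc_pos else 0,
        "n_lev_positive": lev_pos,
        "n_im_lev_positive": im_lev_pos,
        "n_pic_positive": pic_pos,
    }


def load_example_cohort() -> pd.DataFrame:
    """Bundled eight-patient per-mL enumeration table (example data)."""
    with resources.files("picscan.data").joinpath("cohort_enumeration.csv").open() as fh:
        return pd.read_csv(fh)
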