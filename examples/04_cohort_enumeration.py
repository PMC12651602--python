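"""Per-patient enumeration arithmetic and cohort summaries.

Slide counts scale to events/mL through the plated fraction and blood
volume; per-patient rows aggregate into totals, phenotype fractions, and
cohort positivity percentages.
"""

from picscan.cohort import (SlideMeta, load_example_cohort, per_ml,
                            round_percent, summarize_cohort, summarize_patient)

# 100 events counted on slides holding a quarter of an 8 mL draw's cells
meta = SlideMeta("demo", blood_ml=8.0, total_cells=4e6, plated_cells=1e6)
print(f"100 events at 25% plated, 8 mL -> {per_ml(100, meta):.1f} events/mL")

cohort = load_example_cohort().set_index("patient")
for pid in ("P1", "P2", "P3"):
    s = summarize_patient(cohort.loc[pid])
    frac = s["pic_ctc_fraction"]
    print(f"{pid}: total CTC {s['total_ctc_per_ml']:.0f}/mL, "
          f"total LEV {s['total_lev_per_ml']:.0f}/mL, "
          f"PIC CTC fraction {100 * frac:.2f}%")

summary = summarize_cohort(load_example_cohort(), n_patients_total=148)
print(f"patients with any in-cluster (PIC) events: {summary['n_pic_positive']}")
print(f"immune-like CTC positives: {summary['n_im_ctc_positive']}")
# screening-level percentages from printed counts
print(f"40 of 148 CTC-positive -> {round_percent(40, 148)}%")
print(f"4 of 40 with immune-like CTCs -> {round_percent(4, 40)}%")
# only the two high-burden patients with both immune-like CTCs and LEVs
# carry PICs, and PICs stay a 3-4% minority of their total CTC burden
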