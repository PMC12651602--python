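"""Score tumor-immune contact interfaces and separate true interactions
from passive overlaps.

Each WBC touching a tumor event gets its perimeter traced and split into
contact / non-contact arcs; the CD45 fold change between the two arcs plus
a circumferential asymmetry score classifies the pair as a physiologically
interacting cluster (PIC), a passive overlap, or a gap.  A scaled group
comparison (93 interacting vs 16 overlapping WBCs) shows how the
Mann-Whitney U test separates the two populations.
"""

from picscan import score_pair
from picscan.experiments import pair_slide, pic_group_test

for relationship, fold in (("pic", 2.0), ("overlap", 1.0), ("gap", 1.0)):
    image, truth, wbc_id, tumor_id = pair_slide(relationship, fold, seed=8)
    score = score_pair(image.channel("cd45").astype(float),
                       truth.object_mask(wbc_id), truth.object_mask(tumor_id))
    if score.enrichment is None:
        print(f"planted {relationship:8s} -> classified {score.classification}")
    else:
        e = score.enrichment
        print(f"planted {relationship:8s} (f={fold}) -> "
              f"classified {score.classification}; fold {e.fold_change:.2f}, "
              f"contact arc {e.contact_fraction:.2f}, "
              f"asymmetry {e.asymmetry:.3f}")

# group test: recovered fold changes of 93 planted interactions (f = 2)
# versus 16 planted uniform-ring overlaps
folds_pic, folds_ovl, comp = pic_group_test(seed=8)
print(f"\ngroup medians: interacting {sorted(folds_pic)[len(folds_pic)//2]:.2f}"
      f" vs overlap {sorted(folds_ovl)[len(folds_ovl)//2]:.2f}")
print(f"Mann-Whitney U={comp.u:.0f}, two-sided p={comp.p:.3g}, "
      f"effect size r={comp.r:.2f}")
# a large r (close to the ~0.61 ceiling these group sizes allow) and a tiny
# p mean interface enrichment, not chance overlap, separates the groups
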