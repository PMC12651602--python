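"""Generate a synthetic slide and run rare-event detection on it.

A liquid-biopsy slide carries a lawn of white blood cells (WBCs) with a
handful of cytokeratin-positive (CK+) circulating tumor cells (CTCs) and
large extracellular vesicles (LEVs).  Detection segments every nucleus,
drops DAPI-low debris (mean - 3 SD), calls CTC candidates above the CK
mean + 6 SD threshold, and finds LEVs as CK+ DAPI- components >= 2.5 µm
with a brightfield membrane ring.
"""

from picscan import SimConfig, detect_events, generate_slide

# a slide at 1/4 the default lawn density keeps this example fast; the CK+
# fraction must stay rare (~1%) or the 6-SD rule loses its meaning
config = SimConfig(width=1024, height=1024, n_wbc=600, n_epi_ctc=3,
                   n_im_ctc=2, n_epi_lev=3, n_im_lev=2, n_small_ev=2,
                   n_pic=2, n_overlap=1, n_gap_pair=1, seed=20)
image, truth = generate_slide(config)
print(f"planted: {truth.objects['cls'].value_counts().to_dict()}")

result = detect_events(image)
cells, levs = result.cells, result.levs

print(f"segmented nucleated cells: {len(cells)}")
print(f"CK threshold (mean + 6 SD over all cells): "
      f"{cells.attrs['ck_threshold']:.0f}")
print(f"CTC candidates by phenotype: "
      f"{cells[cells['ctc_candidate']]['phenotype'].value_counts().to_dict()}")
kept = levs[levs["lev_candidate"]]
print(f"LEV candidates by phenotype: "
      f"{kept['phenotype'].value_counts().to_dict()}")
print(f"LEV rejections - too small: {int(levs['size_excluded'].sum())}, "
      f"nucleated: {int(levs['dapi_excluded'].sum())}, "
      f"no membrane ring: {int(levs['ring_failed'].sum())}")
# epi = epithelial-like (CD45 at background), im = immune-like (CD45 near
# the leukocyte level); counts should match the planted composition above
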