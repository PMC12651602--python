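# picscan

Rare-event detection and tumor–immune contact scoring for enrichment-free
liquid-biopsy slide images.

## The problem

Enrichment-free liquid biopsy plates every nucleated cell from a blood draw
onto slides and finds rare events by multiplexed immunofluorescence:
circulating tumor cells (CTCs, nucleated and cytokeratin-positive), large
extracellular vesicles (LEVs, CK+ but non-nucleated, ≥ 2.5 µm), and — the
interesting minority — tumor events in direct physical contact with white
blood cells. Because cells are randomly deposited at high density, apparent
contacts can be pure coincidence. The question this package operationalizes
is: *when a WBC touches a tumor event, does its membrane marker (CD45)
concentrate at the contact interface?* Interface enrichment with
circumferential asymmetry is the signature of a physiologically interacting
cluster (PIC) — consistent with immune-synapse-like engagement and
trogocytosis — and distinguishes it from a passive overlap.

`picscan` implements the full analysis as a tested Python library:

| stage | module | what it does |
|---|---|---|
| simulation | `picscan.simulate` | synthetic 4-channel slides (DAPI/CK/CD45/brightfield) with planted ground truth |
| detection | `picscan.detect` | nucleus segmentation, DAPI-low exclusion (µ − 3σ), CK threshold (µ + 6σ), LEV size/DAPI/ring filters, epi/im phenotyping |
| neighbors | `picscan.neighbors` | mask-adjacency pairs, per-10⁶-cell normalization, chance-overlap null |
| contact scoring | `picscan.contact` | perimeter tracing, contact/non-contact partition, fold change, asymmetry, PIC classification |
| phenotyping | `picscan.phenotype` | log-transform, Ward clustering, immune gating, coordinate matching, Fisher enrichment |
| cohort | `picscan.cohort` | events/mL extrapolation, per-patient totals and fractions, positivity percentages |

## The statistics at the core

For a WBC with perimeter positions split into contact arc *C* (adjacent to
the tumor mask) and non-contact arc *N* (adjacent to background), the
**interface fold change** is

    FC = mean(I_CD45 over C) / mean(I_CD45 over N),

with an **asymmetry score** A = |Σᵢ Iᵢ·ûᵢ| / Σᵢ Iᵢ (resultant length of
intensity-weighted perimeter directions, 0 = uniform ring, →1 = one arc).
Groups of fold changes (interacting vs overlapping WBCs) are compared with
a two-sided **Mann–Whitney U test**; the effect size is r = |z|/√(n₁+n₂).
Phenotype enrichment of in-contact events in the CD4-T-like cluster uses
**Fisher's exact test** on the 2×2 contact × cluster table. Detection
thresholds are distributional: nucleated events more than 3 SD below the
mean DAPI level are excluded, and CTC candidates exceed the all-cell CK
mean by 6 SD.

## Worked example

```sh
python examples/02_contact_scoring.py
```

```
planted pic      (f=2.0) -> classified pic; fold 1.95, contact arc 0.16, asymmetry 0.126
planted overlap  (f=1.0) -> classified passive_overlap; fold 1.00, contact arc 0.32, asymmetry 0.015
planted gap      -> classified gap

group medians: interacting 1.95 vs overlap 1.00
Mann-Whitney U=1488, two-sided p=1.94e-10, effect size r=0.61
```

A pair planted with a 2× CD45 enrichment on a 60° contact wedge is
recovered with fold 1.95 and classified as a PIC; a uniform-ring overlap
scores fold 1.00 and stays a passive overlap; a gapped pair is classified
from geometry alone. At the group level, 93 planted interactions against 16
overlaps give complete rank separation (U = n₁n₂ = 1488) — r = 0.61 is the
ceiling these group sizes allow under the normal approximation.

The other examples cover slide simulation + detection
(`01_simulate_and_detect.py`), ion-count phenotyping with Fisher enrichment
(`03_phenotype_profiling.py`), and cohort enumeration arithmetic
(`04_cohort_enumeration.py`).

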