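patient,im_ctc_per_ml,epi_ctc_per_ml,pic_ctc_per_ml,im_lev_per_ml,epi_lev_per_ml,pic_lev_per_ml
P1,7582,216,278,9991,2521,501
P2,2872,3863,271,1097,4317,136
P3,0,250,0,2,2330,0
P4,50,39,0,61,128,0
P5,0,75,0,0,232,0
P8,0,65,0,0,725,0
P9,9,54,0,0,82,0
P12,0,48,0,0,58,0
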