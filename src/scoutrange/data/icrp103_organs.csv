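# ICRP publication 103 tissue weighting factors with a reference organ
# z-table. z is measured in mm from the superior lung boundary (z = 0),
# positive caudally, on a reference phantom with a 240 mm lung.
# The z extents are a synthetic stand-in for a computational-phantom organ
# model: plausible adult anatomy, configuration rather than clinical claims.
# The 13 remainder tissues share w = 0.12/13 each.
organ,weight,z_start_mm,z_end_mm
red_bone_marrow,0.12,-300,800
colon,0.12,330,540
lung,0.12,0,240
stomach,0.12,220,320
breast,0.12,60,160
gonads,0.08,600,660
bladder,0.04,560,640
oesophagus,0.04,-30,250
liver,0.04,200,330
thyroid,0.04,-60,-25
bone_surface,0.01,-300,800
brain,0.01,-260,-140
salivary_glands,0.01,-150,-110
skin,0.01,-300,800
adrenals,0.009230769230769231,270,310
extrathoracic_region,0.009230769230769231,-180,-60
gall_bladder,0.009230769230769231,280,340
heart,0.009230769230769231,90,210
kidneys,0.009230769230769231,270,390
lymph_nodes,0.009230769230769231,-250,700
muscle,0.009230769230769231,-300,800
oral_mucosa,0.009230769230769231,-160,-120
pancreas,0.009230769230769231,260,330
prostate_uterus,0.009230769230769231,580,640
small_intestine,0.009230769230769231,330,520
spleen,0.009230769230769231,210,300
thymus,0.009230769230769231,20,80
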