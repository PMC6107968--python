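source_ref,species,quantity,value_lo,value_hi,units,substrate,remarks
CR40,various hylids,friction,5.5,585.7,mN,PMMA,whole animal
CR71,Litoria caerulea,friction,285.4,285.4,mN,Glass,sd 94.5; whole animal
CR6,Osteopilus septentrionalis,friction,24.9,55.4,mN,,single limb; endpoint sds 6.6 and 6.3
CR6,Osteopilus septentrionalis,friction,3.0,130.3,mN,,single limb; normal load 2.5 mN; v 10-2500 um/s
CR10,Rhacophorus pardalis,shear_stress,1.5,1.5,mN_per_mm2,Glass,single pad
CR25,Litoria caerulea,shear_stress,1.08,2.01,mN_per_mm2,Glass,single pad; normal load 0.1 mN; v 500 um/s
CR39,Rhacophorus dennysi,friction,25.1,51.2,mN,,varying detachment kinematics; normal load 2 mN; v 600 um/s
CR39,Rhacophorus dennysi,shear_stress,9.6,9.6,mN_per_mm2,,varying detachment kinematics
CR46,Hyla versicolor,friction,357.1,357.1,mN,,pulling experiment; frontlimbs
CR53,Polypedates megacephalus,friction,17.52,17.52,mN,Glass,single pad; normal load 3 mN; v 300 um/s
CR80,Trachycephalus resinifictrix,friction,110,1270,mN,Wood,jumping kinematics; single limb
CR97,Litoria caerulea,shear_stress,7.8,7.8,mN_per_mm2,Resin,sd 12.9; normal load 2 mN; v 1000 um/s
CR97,Litoria caerulea,shear_stress,5.9,5.9,mN_per_mm2,PDMS,sd 2.6
CR113,Litoria caerulea,friction,1.6,10.4,mN,,single limb
CR112,Polypedates megacephalus,friction,14.5,122.7,mN,,repeated sliding
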