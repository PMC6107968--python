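source_ref,species,quantity,value_lo,value_hi,units,substrate,remarks
CR6,Osteopilus septentrionalis,adhesion,75.5,75.5,mN,PMMA,whole animal
CR6,Osteopilus septentrionalis,tenacity,1.2,1.2,mN_per_mm2,PMMA,whole animal
CR24,Hyla cinerea,adhesion,39.24,39.24,mN,Teflon,whole animal
CR24,Hyla cinerea,tenacity,1.4,1.4,mN_per_mm2,Teflon,whole animal
CR40,various hylids,adhesion,2.0,372.0,mN,PMMA,whole animal
CR40,various hylids,tenacity,0.4,1.3,mN_per_mm2,PMMA,whole animal
CR41,various hylids,adhesion,4.3,180.2,mN,PMMA,whole animal
CR41,various hylids,tenacity,0.4,0.7,mN_per_mm2,PMMA,whole animal
CR42,various hylids,adhesion,0.5,200.0,mN,PMMA,whole animal
CR42,various hylids,tenacity,0.30,1.08,mN_per_mm2,PMMA,whole animal
CR71,Litoria caerulea,adhesion,255.3,255.3,mN,Glass,sd 73.7; whole animal
CR6,Osteopilus septentrionalis,adhesion,5.9,14.9,mN,,single limb; endpoint sds 2.1 and 3.6
CR10,Rhacophorus pardalis,tenacity,1.5,1.5,mN_per_mm2,PE,single pad
CR39,Rhacophorus dennysi,adhesion,1.7,11.3,mN,,varying detachment kinematics
CR39,Rhacophorus dennysi,tenacity,1.1,2.3,mN_per_mm2,,varying detachment kinematics
CR65,Hyla arborea,adhesion,127.53,127.53,mN,Metal,single limb; frontlimb
CR71,Litoria caerulea,tenacity,1.08,1.08,mN_per_mm2,Glass,sd 0.24; single pad
CR97,Litoria caerulea,tenacity,1.74,1.74,mN_per_mm2,Resin,sd 1.90; single pad
CR97,Litoria caerulea,tenacity,1.43,1.43,mN_per_mm2,PDMS,sd 0.60; single pad
CR101,Litoria caerulea,tenacity,0.04,1.12,mN_per_mm2,,varying load angle
CR113,Litoria caerulea,adhesion,13.9,34.0,mN,,single limb
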