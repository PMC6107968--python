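source_ref,species,quantity,value_lo,value_hi,units,substrate,remarks
CR21,Litoria caerulea,E_star,33.5,33.5,kPa,,sd 4.1; ex vivo; AFM; Hertz theory; d_i 0.2 um
CR21,Ranoidea prominanus,E_star,28.7,28.7,kPa,,sd 10.5; ex vivo; AFM; Hertz theory; d_i 0.2 um
CR22,Litoria caerulea,E_star,14000,14000,kPa,,pyramidal AFM tip; d_i 1.6 um
CR47,Litoria caerulea,E_star,4,25,kPa,,spherical microtribometer; JKR model; d_i 200 um
CR69,Litoria caerulea,E_star,54,54,kPa,,sd 7; ex vivo; spherical AFM; Hertz theory; d_i 0.5 um; r_i 0.4 um
CR69,Litoria caerulea,E_star,40.7,40.7,kPa,,sd 3.2; ex vivo; spherical AFM; Hertz theory; r_i 13.3 um
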