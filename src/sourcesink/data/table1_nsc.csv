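species,organ,treatment,hexose_mg_g,sucrose_mg_g,starch_mg_g
rice,mature_leaf,onset,9.5,36.7,5.0
rice,young_leaves,onset,12.8,10.5,2.0
oil_palm,mature_leaf,onset,17.7,42.3,5.5
oil_palm,trunk,onset,5.8,37.2,302.1
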