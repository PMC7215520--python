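# N-terminal group of the published SiteMap/CPORT consensus binding site
# of carbonic anhydrase VIII (residues identified by both predictors).
Gly26
Val27
Glu28
Trp29
Gly30
Tyr31
Glu32
Glu33
Gly34
Val35
Glu36
Leu39
Val40
Ala44
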