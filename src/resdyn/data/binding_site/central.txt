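# Central group of the published SiteMap/CPORT consensus binding site.
Leu93
Lys94
Glu111
Tyr113
Arg116
Ser147
Gly151
Ile153
Asp214
Ile224
Arg237
Tyr238
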