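# C-terminal group of the published SiteMap/CPORT consensus binding site.
Thr255
His256
Leu262
Val263
Glu264
Gly265
Ile269
Phe274
Pro276
Gln278
Phe289
Gln290
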