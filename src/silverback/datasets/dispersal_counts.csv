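sex,orphan_class,dispersed,n
F,non_orphan,12,32
F,infant,6,11
F,juv_subadult,6,8
M,non_orphan,15,40
M,juv_subadult,11,13
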