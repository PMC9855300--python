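characteristic,total,center_a,center_b,center_c,center_d
patients,665,282,84,205,94
hgsc,436,213,26,136,61
non_hgsc,229,69,58,69,33
ccc,98,27,25,31,15
mc,51,20,12,14,5
lgsc,22,13,1,5,3
ec,58,9,20,19,10
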