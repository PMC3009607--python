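cross	born_total	weaned_balancer	weaned_non_balancer	died_pre_wean
Tapt1KO_x_L5Jcs1	31	21	0	10
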