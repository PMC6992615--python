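case,gas_volume_pct_prone,gas_volume_pct_supine,angle_deg_prone,angle_deg_supine
1,58.4,58.8,23.6,-16.1
2,59.7,59.0,20.7,13.2
3,58.2,58.3,29.9,6.2
4,70.8,70.2,12.7,-6.3
5,67.6,67.3,14.5,9.7
6,34.9,34.5,9.5,9.5
7,62.4,62.6,11.7,-2.2
8,68.7,69.0,6.3,0
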