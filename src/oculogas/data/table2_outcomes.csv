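case,tamponade_agent,mri_day_after_surgery,bcva_preop_logmar,bcva_postop_logmar,initial_reattachment,iol_optic_capture,pvr
1,SF6 (20%),4,0.10,-0.08,Yes,No,No
2,SF6 (20%),4,1.22,0.52,Yes,No,No
3,SF6 (20%),4,0.40,0.00,Yes,No,No
4,SF6 (20%),4,0.40,0.05,Yes,No,No
5,SF6 (20%),4,0.82,0.22,Yes,No,No
6,SF6 (20%),4,2.00,0.05,Yes,No,No
7,SF6 (20%),4,-0.08,0.10,Yes,No,No
8,SF6 (20%),4,1.70,0.00,Yes,No,No
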