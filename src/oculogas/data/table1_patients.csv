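case,age_years,sex,eye,lens_status,axial_length_mm,quadrants,n_breaks,break_position_vs_equator,break_clock_hours,macula
1,63,M,R,Phakic,23.8,1,3,Anterior,5;5:30;6,On
2,54,F,L,Phakic,26.4,2,1,Anterior,11,Off
3,61,F,R,Phakic,25.7,2,2,Anterior,9;12,On
4,66,M,L,Phakic,25.9,4,8,Anterior,2;2:30;5;5:30;6;7;11;12,On
5,57,F,L,Phakic,24.5,2,3,Anterior,2;11:30;12,Off
6,65,M,R,Phakic,25.8,1,1,Anterior,11,On
7,60,F,R,Phakic,24.1,1,1,Anterior,2:30,On
8,52,M,R,Phakic,26.7,2,3,Anterior,5:30;6;10,On
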