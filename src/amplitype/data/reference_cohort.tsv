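sample	ancestry	allele1	allele2	sbt_allele1	sbt_allele2
NA16688	Ch	B*15:07:01G	B*35:01:01G
NA17019	Ch	B*15:02:01G	B*15:11:01G	B*15:02:01G	B*15:11:01G
NA17240	C	B*07:02:01G	B*57:01:01G	B*07:02:01G	B*57:01:01G
NA19834	A	B*35:01:01G	B*39:10:01
UDRUGS01	C	B*40:02:01G	B*44:02:01G	B*40:02:01G	B*44:02:01G
UDRUGS02	C	B*15:01:01G	B*44:02:01G	B*15:01:01G	B*44:02:01G
UDRUGS29	C	B*18:01:01G	B*27:09	B*18:01:01G	B*27:09
UDRUGS41	C	B*15:01:01G	B*51:01:01G	B*15:01:01G	B*51:01:01G
UDRUGS44	C	B*15:01:01G	B*44:03:01G	B*15:01:01G	B*44:03:01G
PI_A1	0.25 NM 0.75 C	B*37:01:01G	B*39:01:01G	B*37:01:01G	B*39:01:01G
PI_A2	0.5 NM 0.5 C	B*27:05:02G	B*57:01:01G	B*27:05:02G	B*57:01:01G
PI_A3	0.5 CM 0.5 P	B*39:05:01	B*52:01:01G	B*39:05:01	B*52:01:01G
PI_A5	0.125 NM 0.25 P 0.625 C	B*08:01:01G	B*35:01:01G
PI_B1	1.0 S	B*46:01:01G	B*55:02:01G
PI_B2	0.5 NM 0.5 C	B*07:02:01G	B*57:01:01G
PI_B3	U	B*27:07:01G	B*35:03:01G
PI_B4	0.333 NM 0.667 P	B*40:01:01G	B*44:02:01G	B*40:01:01G	B*44:02:01G
PI_B5	0.5 NM 0.5 C	B*07:02:01G	B*55:02:01G
PI_B6	1.0 S	B*40:01:01G	B*56:02:01
PI_C1	0.5 NM	B*44:02:01G	B*55:02:01G
PI_C2	U	B*52:02:01	B*52:02:01
PI_C3	0.25 NM 0.25 C	B*44:04	B*56:02:01
PI_C4	0.25 NM 0.75 C	B*08:156	B*42:01:01
PI_C5	0.25 NM 0.75 N	B*55:01:01G	B*55:02:01G
PI_C6	0.25 NM 0.75 C	B*44:02:01G	B*55:01:01G
PI_D1	0.5 NM 0.5 C	B*15:01:01G	B*49:01:01G
PI_D2	0.125 NM 0.875 C	B*08:01:01G	B*44:03:01G
PI_D3	0.25 NM 0.75 C	B*40:01:01G	B*51:01:01G
PI_D4	0.5 NM 0.5 C	B*13:02:01G	B*39:01:01G
PI_D5	0.25 NM 0.5 N 0.25 C	B*40:01:01G	B*40:01:01G
PI_D6	0.375 NM 0.125 C	B*35:60	B*56:09
PI_E1	0.5 NM 0.5 C	B*35:03:01G	B*40:01:01G
PI_E2	0.5 S 0.5 N	B*56:02:01	B*56:02:01
PI_E4	0.5 NM 0.5 C	B*14:02:01G	B*56:01:01G
PI_E5	0.5 NM 0.5 S	B*39:01:01G	B*55:01:01G
PI_F1	0.5 NM 0.5 C	B*44:02:01G	B*50:01:01G
PI_F2	0.75 NM 0.25 C	B*07:02:01G	B*40:01:01G
PI_F3	0.125 CM 0.875 C	B*18:01:01G	B*44:02:01G
PI_F4	0.5 NM 0.5 C	B*44:02:01G	B*43:03:01G
PI_F5	0.125 NM 0.875 C	B*08:01:01G	B*40:01:01G
PI_F6	0.25 NM 0.75 C	B*35:01:01G	B*48:01:01G
PI_G1	0.5 NM 0.5 C	B*15:17:01G	B*37:01:01G
PI_G2	1.0 U	B*07:02:01G	B*53:17:02
PI_G4	0.125 NM 0.875 C	B*07:02:01G	B*07:02:01G
PI_G5	0.25 NM 0.25 C	B*35:01:01G	B*40:01:01G
PI_G6	0.333 NM 0.583 N 0.083 C	B*40:01:01G	B*44:03:01G
PI_H1	0.5 NM 0.5 C	B*27:10	B*55:01:01G
PI_H2	0.5 NM 0.5 C	B*07:02:01G	B*40:10:01G
PI_H3	1.0 NM	B*40:01:01G	B*48:01:01G
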