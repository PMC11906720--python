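gene	label	chrom	position	in_previous_models
miR29B2C	C1	chr1	207823681	true
miR29B2C	C2	chr1	207823705	false
FHL2	C1	chr2	105399282	true
FHL2	C2	chr2	105399288	true
FHL2	C3	chr2	105399297	false
FHL2	C4	chr2	105399300	false
FHL2	C5	chr2	105399327	false
FHL2	C6	chr2	105399360	false
FHL2	C7	chr2	105399363	false
FHL2	C8	chr2	105399388	false
TRIM59	C1	chr3	160450179	false
TRIM59	C2	chr3	160450184	false
TRIM59	C3	chr3	160450189	true
TRIM59	C4	chr3	160450192	false
TRIM59	C5	chr3	160450199	true
ELOVL2	C1	chr6	11044628	true
ELOVL2	C2	chr6	11044634	false
ELOVL2	C3	chr6	11044640	false
ELOVL2	C4	chr6	11044644	false
ELOVL2	C5	chr6	11044647	false
ELOVL2	C6	chr6	11044655	false
ELOVL2	C7	chr6	11044661	true
ELOVL2	C8	chr6	11044683	false
ELOVL2	C9	chr6	11044702	false
KLF14	C1	chr7	130734398	false
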