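repName	role	group	family	superfamily	partners
LTR12	ltr	LTR12	ERV9	ERV1	HERV9-int
LTR12C	ltr	LTR12C	ERV9	ERV1	HERV9-int
HERV9-int	internal	HERV9	ERV9	ERV1	LTR12,LTR12C
LTR7	ltr	LTR7	HERVH	ERV1	HERVH-int
HERVH-int	internal	HERVH	HERVH	ERV1	LTR7
LTR2	ltr	LTR2	HERVW	ERV1	HERV17-int
LTR2B	ltr	LTR2B	HERVW	ERV1	HERV17-int
LTR2C	ltr	LTR2C	HERVW	ERV1	HERV17-int
HERV17-int	internal	HERV17	HERVW	ERV1	LTR2,LTR2B,LTR2C
LTR8	ltr	LTR8	HUERSP1	ERV1	HUERS-P1-int
HUERS-P1-int	internal	HUERS-P1	HUERSP1	ERV1	LTR8
LOR1a	ltr	LOR1a	LOR1	ERV1	LOR1-int
LOR1-int	internal	LOR1	LOR1	ERV1	LOR1a
MER39	ltr	MER39	MER39	ERV1	MER39-int
MER39-int	internal	MER39	MER39	ERV1	MER39
MER4C	ltr	MER4C	MER4	ERV1	MER4-int
MER4-int	internal	MER4	MER4	ERV1	MER4C
MER52A	ltr	MER52A	MER52	ERV1	MER52-int
MER52-int	internal	MER52	MER52	ERV1	MER52A
MER57B1	ltr	MER57B1	MER57	ERV1	MER57-int
MER57-int	internal	MER57	MER57	ERV1	MER57B1
LTR5_Hs	ltr	LTR5_Hs	HERVK10	ERVK	HERVK-int
HERVK-int	internal	HERVK	HERVK10	ERVK	LTR5_Hs
MER11C	ltr	MER11C	HERVK11	ERVK	HERVK11-int
HERVK11-int	internal	HERVK11	HERVK11	ERVK	MER11C
LTR16A1	ltr	LTR16A1	HERV16	ERVL	HERV16-int
HERV16-int	internal	HERV16	HERV16	ERVL	LTR16A1
LTR33	ltr	LTR33	HERVL33	ERVL	HERVL33-int
HERVL33-int	internal	HERVL33	HERVL33	ERVL	LTR33
LTR52	ltr	LTR52	HERVL52	ERVL	HERVL52-int
HERVL52-int	internal	HERVL52	HERVL52	ERVL	LTR52
LTR66	ltr	LTR66	HERVL66	ERVL	HERVL66-int
HERVL66-int	internal	HERVL66	HERVL66	ERVL	LTR66
MLT1D	ltr	MLT1D	MLT	ERVL-MaLR	MLT-int
MLT2B3	ltr	MLT2B3	MLT	ERVL-MaLR	MLT-int
MLT-int	internal	MLT	MLT	ERVL-MaLR	MLT1D,MLT2B3
MSTD	ltr	MSTD	MST	ERVL-MaLR	MST-int
MST-int	internal	MST	MST	ERVL-MaLR	MSTD
THE1A	ltr	THE1A	THE1	ERVL-MaLR	THE1-int
THE1B	ltr	THE1B	THE1	ERVL-MaLR	THE1-int
THE1C	ltr	THE1C	THE1	ERVL-MaLR	THE1-int
THE1D	ltr	THE1D	THE1	ERVL-MaLR	THE1-int
THE1-int	internal	THE1	THE1	ERVL-MaLR	THE1A,THE1B,THE1C,THE1D
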