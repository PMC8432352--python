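subtype	phage
TSP1-1	GG32
TSP1-1	Kage
TSP1-1	S117
TSP1-1	SFP10
TSP1-1	STP07
TSP1-1	Aagejoakim
TSP1-1	S8
TSP1-1	4HA11
TSP1-1	CBA120
TSP4-7	FEC14
TSP4-7	SS3
TSP4-7	SS9
TSP4-7	Se-E
TSP2-1	Rabagast
TSP2-1	Moki
TSP2-1	Heyday
TSP2-1	SeHz-1
TSP2-1	S118
TSP2-1	S115
TSP2-1	Se-U
TSP2-1	Pa-sanjiao
TSP2-1	S8
TSP2-1	Se-D
TSP2-1	Se-B
TSP2-1	BSP101
TSP2-1	Kage
TSP2-1	SFP10
TSP2-1	STP07
TSP2-1	Se_EM1
TSP2-1	GG32
TSP2-1	4HA11
TSP2-1	Se-E
TSP2-1	FEC14
TSP2-1	S117
TSP2-1	EP75
TSP2-1	SJ3
TSP2-1	PhaxI
TSP2-1	FSL_SP-063
TSP2-1	FSL_SP-029
TSP2-1	STML-13-1
TSP2-1	ECML-4
TSP2-1	Aagejoakim
TSP2-1	CBA120
TSP3-1	PS5
TSP3-1	Marshall
TSP3-1	Mooltan
TSP3-1	STML-13-1
TSP3-1	Matapan
TSP3-1	Maynard
TSP3-1	FSL-SP-029
TSP3-1	FSL-SP-063
TSP3-1	SJ2
TSP3-1	Sal157lw
TSP3-1	Bering
TSP3-1	ISTP3
TSP3-1	Se-H
TSP3-1	BSP101
TSP3-1	Se-I
TSP3-1	Se-J
TSP3-1	Se-N
TSP3-1	Se-S
TSP3-1	SP1
TSP3-1	Dinky
TSP3-1	SenASZ3
TSP3-1	Sh19
TSP3-1	Moki
TSP3-1	S117
TSP3-1	Pa-sanjiao
TSP3-1	S115
TSP3-1	S118
TSP3-1	Se-U
TSP3-1	SFP10
TSP3-1	Aagejoakim
TSP3-1	Kage
TSP3-1	Rabagast
TSP3-1	4HA11
TSP3-1	SeHz-1
TSP3-1	Se-E
TSP3-1	Heyday
TSP3-1	S8
TSP3-1	GG32
TSP3-1	STP07
TSP3-1	Se-F
TSP3-1	Se-G
TSP3-1	SenALZ1
TSP3-1	SeTs-2
TSP3-1	Se-B
TSP3-1	Se-D
TSP3-1	Pertopsoe
TSP3-1	SS3
TSP3-1	SeSz-1
TSP3-1	Se_AO1
TSP3-1	Se_EM3
TSP3-1	Se_EM1
TSP3-1	Se_EM4
TSP4-8	SE14
TSP4-8	mane
TSP3-4	CBA120
TSP4-2	BSP101
TSP4-2	S8
TSP4-2	PhaxI
TSP4-2	CBA120
TSP3-3	FEC14
TSP3-2	SJ3
TSP3-2	EP75
TSP3-2	LPSTP4
TSP3-2	Mutine
TSP3-2	PM10
TSP3-2	Chennai
TSP3-2	SenM-2
TSP3-2	barely
TSP3-2	Det7
TSP2-10	SenM-2
TSP2-10	barely
TSP2-10	Det7
TSP1-3	SeTs-2
TSP1-3	Se-F
TSP1-3	Se-G
TSP1-3	SenALZ1
TSP1-3	EP75
TSP1-26	PhiDP23.1
TSP1-26	Coodle
TSP1-26	XF4
TSP1-26	PhiD3
TSP1-26	Kamild
TSP1-26	Limestone1
TSP1-26	JA15
TSP1-26	PhiDP10.3
TSP1-26	RC-2014
TSP1-26	Ds16CZ
TSP1-26	Ds9CZ
TSP1-26	Ds5CZ
TSP1-26	Ds3CZ
TSP1-26	Ds23CZ
TSP1-26	Ds20CZ
TSP1-26	Ds25CZ
TSP1-26	PP35
TSP2-18	0507-KN2-1
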