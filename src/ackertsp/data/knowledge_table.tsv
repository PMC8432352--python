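subtype	receptor	host_taxa	evidence	evidence_phage	printed_total	source
TSP1-1	O:21	Salmonella Ruiru;Salmonella Minnesota	experimental	CBA120	9	Plattner2019
TSP4-7	O:21	Salmonella enterica	inferred		4	shared module with TSP1-1
TSP2-1	O:157	Escherichia coli	experimental	CBA120	32	Plattner2019
TSP3-1	O:4;O:9	Salmonella Typhimurium;Salmonella Derby;Salmonella 4.12:i:-;Salmonella 4.5.12:i:-;Salmonella Enteritidis;Salmonella Goettingen	experimental	S117	52	this-work
TSP4-8	O:4;O:9	Salmonella enterica	inferred		2	shared module with TSP3-1
TSP3-4	O:77	Escherichia coli	experimental	CBA120	1	Plattner2019
TSP4-2	O:78	Escherichia coli	experimental	CBA120	4	Plattner2019
TSP3-3	O:78	Escherichia coli	inferred		1	shared module with TSP4-2
TSP3-2	O:4	Salmonella Typhimurium	experimental	Det7	9	Walter2008
TSP2-10	O:3	Salmonella Anatum	experimental	Det7	3	Gebhart2017
TSP1-3	O:18A	Escherichia coli	experimental	EP75	5	Gambino2020
TSP1-26	(2)-beta-D-6-deoxy-D-altrose-(1) O-antigen	Dickeya solani;Lelliottia F154	experimental	PP35	17	Kabanova2019
TSP2-18	KN2 capsular polysaccharide	Klebsiella	experimental	0507-KN2-1	1	Hsieh2017
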