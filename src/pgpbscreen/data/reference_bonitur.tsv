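strain_id	source	soil	genus	iaa	fepo4	alpo4	siderophore_index	tomato_rdw	tomato_sdw	lulo_rdw	lulo_sdw	printed_total	printed_rank
019S	BS	ORG	Enterobacter	3	3	2	0	2	1	1	2	14	1
021T	TR	ORG	Rhizobium	1	2	2	2	1	2	1	1	12	2
027S	BS	ORG	Enterobacter	3	3	0	0	0	2	2	2	12	2
028S	BS	ORG	Enterobacter	3	3	1	0	1	0	2	2	12	2
04T	TR	CH	Rhizobium	3	1	0	2	0	2	2	2	12	2
014L	LR	ORG	Rhizobium	2	0	1	2	1	1	2	2	11	3
017T	TR	CH	Pseudomonas	1	3	1	2	1	0	1	2	11	3
022S	BS	ORG	Enterobacter	3	3	1	0	0	0	2	2	11	3
023S	BS	ORG	Pseudomonas	0	1	2	2	0	2	2	2	11	3
026S	BS	ORG	Cupriavidus	0	1	3	0	2	1	2	2	11	3
027L	LR	SF	Rhizobium	2	1	0	2	1	1	2	2	11	3
029T	TR	CH	Rhizobium	1	1	1	2	0	2	2	2	11	3
035T	TR	SF	Rhizobium	3	1	1	0	2	0	2	2	11	3
036T	TR	SF	Rhizobium	0	3	0	2	2	0	2	2	11	3
041T	TR	CH	Rhizobium	3	1	1	2	0	0	2	2	11	3
09S	BS	SF	Pseudomonas	1	2	3	0	2	0	1	2	11	3
015S	BS	CH	Enterobacter	3	3	3	0	0	1	0	0	10	4
016S	BS	ORG	Pseudomonas	0	2	3	2	2	1	0	0	10	4
024S	BS	ORG	Burkholderia	0	2	3	2	1	2	0	0	10	4
025S	BS	ORG	Pseudomonas	0	2	1	2	1	1	1	2	10	4
025T	TR	ORG	Rhizobium	1	2	0	2	0	2	1	2	10	4
02T	TR	ORG	Rhizobium	1	2	0	2	0	1	2	2	10	4
050T	TR	CH	Rhizobium	1	2	1	0	1	1	2	2	10	4
08T	TR	ORG	Rhizobium	2	0	0	2	0	2	2	2	10	4
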