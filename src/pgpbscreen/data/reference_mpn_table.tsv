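source	soil	medium	n	mpn
BS	SF	JMV	5	7.67
BS	SF	NFb	0	0
BS	SF	JNFb	3	3.33
BS	SF	LGI	0	0
BS	SF	LGI-P	0	0
BS	CH	JMV	0	0
BS	CH	NFb	0	0
BS	CH	JNFb	5	7.67
BS	CH	LGI	0	0
BS	CH	LGI-P	0	0
BS	ORG	JMV	10	16.00
BS	ORG	NFb	0	0
BS	ORG	JNFb	2	1.33
BS	ORG	LGI	1	1.33
BS	ORG	LGI-P	0	0
TR	SF	JMV	7	18.00
TR	SF	NFb	2	3.00
TR	SF	JNFb	2	3.33
TR	SF	LGI	2	2.00
TR	SF	LGI-P	1	1.00
TR	CH	JMV	9	9.00
TR	CH	NFb	2	2.67
TR	CH	JNFb	4	4.00
TR	CH	LGI	3	4.00
TR	CH	LGI-P	0	0
TR	ORG	JMV	5	8.00
TR	ORG	NFb	0	0
TR	ORG	JNFb	5	6.33
TR	ORG	LGI	0	1.00
TR	ORG	LGI-P	0	0
LR	SF	JMV	5	10.0
LR	SF	NFb	1	1.00
LR	SF	JNFb	4	8.33
LR	SF	LGI	1	3.33
LR	SF	LGI-P	1	2.67
LR	CH	JMV	2	3.67
LR	CH	NFb	0	1.00
LR	CH	JNFb	1	2.33
LR	CH	LGI	1	2.33
LR	CH	LGI-P	0	0
LR	ORG	JMV	6	5.67
LR	ORG	NFb	1	1.00
LR	ORG	JNFb	5	7.67
LR	ORG	LGI	5	9.00
LR	ORG	LGI-P	0	1.33
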