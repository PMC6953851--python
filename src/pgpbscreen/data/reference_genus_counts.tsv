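genus	class	count
Rhizobium	Alphaproteobacteria	59
Pseudomonas	Gammaproteobacteria	12
Burkholderia	Betaproteobacteria	11
Enterobacter	Gammaproteobacteria	5
Variovorax	Betaproteobacteria	4
Cupriavidus	Betaproteobacteria	3
Stenotrophomonas	Gammaproteobacteria	2
Caulobacter	Alphaproteobacteria	1
Novosphingobium	Alphaproteobacteria	1
Xanthomonas	Gammaproteobacteria	1
Pelomonas	Betaproteobacteria	1
unclassified	unclassified	1
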