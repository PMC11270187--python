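>IGHV4-59|heavy|synthetic stand-in, consensus-derived, not an IMGT allele
QVQLQQSGPEVKQPGASVKVSCKASGYTFTSSYWSWVRQPPGKGLEWVGWISGNTNYAQK
LQGRVRVTITVDKSTSTFYMELRSEDTAVYYCARARGYSDDY
>IGHV2-26|heavy|synthetic stand-in, consensus-derived, not an IMGT allele
EVTLKQSGATVRKPGASTKVSCKASGYTFTSNARMWVRQAPGKGLEWIGWISGNTNYAQK
LQGRVRLTITKDKSTSTVYMELRSEDTAVYYCARARIHDDDY
>IGHV4-4|heavy|synthetic stand-in, consensus-derived, not an IMGT allele
QVQLQQSGPEVKQPGATVKVSCKGSGYTFTSNYYSWVRQAPGRGLEWVGWISGNTNYAQK
LQGRVRVTISVDKSTSTFYMELRSEDTAVYYCARARGSTDDY
>IGHV2-9|heavy|synthetic stand-in, consensus-derived, not an IMGT allele
EVKLKQSGASVKKPSASVKVSCKASGYTFTDYYMNWVRQAPGKGLRWVGWISGNTNYAQK
LQGRVRFTITKDKSTSTVYMNLRSNDSAVYYCVRGGYGSDDY
>IGKV1-16|kappa|synthetic stand-in, consensus-derived, not an IMGT allele
DIQMTQSPSSLSASVGDRVTITCRASQGNSNYLAWYQQKPGKAPKLLIYWASTRESGVPS
RFSGSGSGTDFTLFISSLQPEDFATYYCQQYNSYSLT
>IGKV1-39|kappa|synthetic stand-in, consensus-derived, not an IMGT allele
DIQMTQSPSSLSASVGERVTITCRASQSNSNYLAWYQQKPGKAPKLLIYWASTRESGVPS
RFSGSGSGTDFTLTISSLQPEDFATYYCQQSYSYSLT
>IGKV1-6|kappa|synthetic stand-in, consensus-derived, not an IMGT allele
DIQMTQSPSSLSASVGDRVTLTCRASQGNINYLAWYQQKPGKAPKLLIYWASTRESGVPS
RFSGSGSGTEFTLTISSLQAEDFATYYCLQDYNYSLT
>IGKV9-124|kappa|synthetic stand-in, consensus-derived, not an IMGT allele
DIVMTQTPASMSASLGDRVSITCKASQNNVNYLAWYQQKSGSAPKLLIYWASTRESGIPK
RFTGSRSGTDFTLTINSLQSEDLATYYCQQYDEYSLT
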