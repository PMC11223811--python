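# synthetic kissing-loop pair table (wireweaver fixture)
# 180-degree kissing-loop candidates: seq_b is the reverse complement of seq_a;
# entries are mutually distinct 7-mers with moderate-to-high GC content.
# Replace with an experimentally validated table for wet-lab designs.
# id	seq_a	seq_b
KL01	GCUAAAG	CUUUAGC
KL02	UACACGU	ACGUGUA
KL03	CAGCACG	CGUGCUG
KL04	UUGGCCC	GGGCCAA
KL05	AGUGUGA	UCACACU
KL06	AUCGCUU	AAGCGAU
KL07	AAGGGUU	AACCCUU
KL08	UGUGAUG	CAUCACA
KL09	CAUACGC	GCGUAUG
KL10	UGCUGUG	CACAGCA
KL11	UCCACCC	GGGUGGA
KL12	CAUCGGA	UCCGAUG
KL13	CUGGCAU	AUGCCAG
KL14	ACACUCA	UGAGUGU
KL15	GAAACAG	CUGUUUC
KL16	AACUCGG	CCGAGUU
KL17	UGACAGG	CCUGUCA
KL18	UCACGCA	UGCGUGA
KL19	UGAAGUG	CACUUCA
KL20	CGUGGAC	GUCCACG
KL21	ACUCGCU	AGCGAGU
KL22	UACCCAC	GUGGGUA
KL23	UCUGCCA	UGGCAGA
KL24	AACUCCA	UGGAGUU
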