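>DUF4198|HG|Pseudomonas_putida GH5 signal peptide (OAS21937.1)
MRHWIFASLLVLSTPPATA
>DUF6702|HE|Hydrogenophaga_sp. DUF4198 signal peptide (WP_086125165.1)
MKKWIFSSLLVLVSTAQA
>Ang-1|H|Roseiconus_lacunae SOD_Ni signal peptide (WP_230780104.1)
MTRLLTATLALMFTASIASA
>Ang-2|H|Streptomyces_sp. GH16 signal peptide (A0A399HGR6)
MSGAPRIRRRHPAHRARPRNLRIAVAVATVTGLAAVTLTATAQA
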