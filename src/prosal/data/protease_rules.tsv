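protease_id	rule_kind	rule	evidence
CTSD	positional_sets	P1=FWYL	illustrative: aspartic cathepsin, bulky hydrophobic P1
CTSE	positional_sets	P1=FL	illustrative: aspartic cathepsin E
CTSK	positional_sets	P2=P; P1=GA	illustrative: collagenolytic cathepsin K, Pro at P2
CTSL	positional_sets	P2=FWY	illustrative: cathepsin L aromatic P2
CTSS	positional_sets	P2=LV	illustrative: cathepsin S aliphatic P2
CTSB	positional_sets	P2=RK	illustrative: cathepsin B basic P2
CAPN1	positional_sets	P2=LV; P1=KR	illustrative: calpain-1 Leu/Val P2
CAPN2	positional_sets	P2=LV; P1=TR	illustrative: calpain-2
CASP6	positional_sets	P1=D	illustrative: caspase Asp P1
FURIN	positional_sets	P2=KR; P1=R	illustrative: proprotein convertase basic motif
MMP2	positional_sets	P1'=LI	illustrative: gelatinase A, hydrophobic P1'
MMP11	positional_sets	P1=A; P1'=L	illustrative: stromelysin-3
MMP25	positional_sets	P1'=L	illustrative: MT6-MMP
MEP1A	positional_sets	P1'=DE	illustrative: meprin alpha acidic P1'
TMPRSS6	positional_sets	P1=KR	illustrative: type II transmembrane serine protease
KLK5	positional_sets	P1=KR; P1'=ST	illustrative: kallikrein 5 tryptic
ELANE	positional_sets	P1=AV	illustrative: neutrophil elastase small aliphatic P1
NPEPPS	positional_sets	P1=AL; P1'=AS	illustrative: puromycin-sensitive aminopeptidase products
QGEP	site_octamer	XXXQ|GXXX	illustrative: glutamine endopeptidase Q|G site
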