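# Synonyms for mitochondrial gene names as they appear in GenBank
# /gene and /product qualifiers, mapped to HGNC-style symbols.
# Keys are matched after uppercasing and collapsing spaces/hyphens.
# alias	symbol
ND1	MT-ND1
NAD1	MT-ND1
NADH1	MT-ND1
NADH DEHYDROGENASE SUBUNIT 1	MT-ND1
MT-ND1	MT-ND1
ND2	MT-ND2
NAD2	MT-ND2
NADH2	MT-ND2
NADH DEHYDROGENASE SUBUNIT 2	MT-ND2
MT-ND2	MT-ND2
ND3	MT-ND3
NAD3	MT-ND3
NADH3	MT-ND3
NADH DEHYDROGENASE SUBUNIT 3	MT-ND3
MT-ND3	MT-ND3
ND4	MT-ND4
NAD4	MT-ND4
NADH4	MT-ND4
NADH DEHYDROGENASE SUBUNIT 4	MT-ND4
MT-ND4	MT-ND4
ND4L	MT-ND4L
NAD4L	MT-ND4L
NADH4L	MT-ND4L
NADH DEHYDROGENASE SUBUNIT 4L	MT-ND4L
MT-ND4L	MT-ND4L
ND5	MT-ND5
NAD5	MT-ND5
NADH5	MT-ND5
NADH DEHYDROGENASE SUBUNIT 5	MT-ND5
MT-ND5	MT-ND5
ND6	MT-ND6
NAD6	MT-ND6
NADH6	MT-ND6
NADH DEHYDROGENASE SUBUNIT 6	MT-ND6
MT-ND6	MT-ND6
CO1	MT-CO1
COI	MT-CO1
COX1	MT-CO1
COXI	MT-CO1
CYTOCHROME C OXIDASE SUBUNIT 1	MT-CO1
CYTOCHROME C OXIDASE SUBUNIT I	MT-CO1
MT-CO1	MT-CO1
CO2	MT-CO2
COII	MT-CO2
COX2	MT-CO2
COXII	MT-CO2
CYTOCHROME C OXIDASE SUBUNIT 2	MT-CO2
CYTOCHROME C OXIDASE SUBUNIT II	MT-CO2
MT-CO2	MT-CO2
CO3	MT-CO3
COIII	MT-CO3
COX3	MT-CO3
COXIII	MT-CO3
CYTOCHROME C OXIDASE SUBUNIT 3	MT-CO3
CYTOCHROME C OXIDASE SUBUNIT III	MT-CO3
MT-CO3	MT-CO3
ATP6	MT-ATP6
ATPASE6	MT-ATP6
ATPASE 6	MT-ATP6
ATP SYNTHASE F0 SUBUNIT 6	MT-ATP6
MT-ATP6	MT-ATP6
ATP8	MT-ATP8
ATPASE8	MT-ATP8
ATPASE 8	MT-ATP8
ATP SYNTHASE F0 SUBUNIT 8	MT-ATP8
MT-ATP8	MT-ATP8
CYTB	MT-CYB
COB	MT-CYB
CYB	MT-CYB
CYTOCHROME B	MT-CYB
MT-CYB	MT-CYB
RRNS	MT-RNR1
12S	MT-RNR1
12S RRNA	MT-RNR1
12S RIBOSOMAL RNA	MT-RNR1
S RRNA	MT-RNR1
SMALL SUBUNIT RIBOSOMAL RNA	MT-RNR1
MT-RNR1	MT-RNR1
RRNL	MT-RNR2
16S	MT-RNR2
16S RRNA	MT-RNR2
16S RIBOSOMAL RNA	MT-RNR2
L RRNA	MT-RNR2
LARGE SUBUNIT RIBOSOMAL RNA	MT-RNR2
MT-RNR2	MT-RNR2
D LOOP	CR
DLOOP	CR
CONTROL REGION	CR
CR	CR
TRNF	MT-TF
TRNA PHE	MT-TF
MT-TF	MT-TF
TRNV	MT-TV
TRNA VAL	MT-TV
MT-TV	MT-TV
TRNL1	MT-TL1
TRNL(UUR)	MT-TL1
TRNA LEU(UUR)	MT-TL1
TRNA LEU (UUR)	MT-TL1
MT-TL1	MT-TL1
TRNI	MT-TI
TRNA ILE	MT-TI
MT-TI	MT-TI
TRNQ	MT-TQ
TRNA GLN	MT-TQ
MT-TQ	MT-TQ
TRNM	MT-TM
TRNA MET	MT-TM
MT-TM	MT-TM
TRNW	MT-TW
TRNA TRP	MT-TW
MT-TW	MT-TW
TRNA ALA	MT-TA
MT-TA	MT-TA
TRNN	MT-TN
TRNA ASN	MT-TN
MT-TN	MT-TN
TRNC	MT-TC
TRNA CYS	MT-TC
MT-TC	MT-TC
TRNY	MT-TY
TRNA TYR	MT-TY
MT-TY	MT-TY
TRNS1	MT-TS1
TRNS(UCN)	MT-TS1
TRNA SER(UCN)	MT-TS1
TRNA SER (UCN)	MT-TS1
MT-TS1	MT-TS1
TRND	MT-TD
TRNA ASP	MT-TD
MT-TD	MT-TD
TRNK	MT-TK
TRNA LYS	MT-TK
MT-TK	MT-TK
TRNG	MT-TG
TRNA GLY	MT-TG
MT-TG	MT-TG
TRNR	MT-TR
TRNA ARG	MT-TR
MT-TR	MT-TR
TRNH	MT-TH
TRNA HIS	MT-TH
MT-TH	MT-TH
TRNS2	MT-TS2
TRNS(AGY)	MT-TS2
TRNA SER(AGY)	MT-TS2
TRNA SER (AGY)	MT-TS2
MT-TS2	MT-TS2
TRNL2	MT-TL2
TRNL(CUN)	MT-TL2
TRNA LEU(CUN)	MT-TL2
TRNA LEU (CUN)	MT-TL2
MT-TL2	MT-TL2
TRNT	MT-TT
TRNA THR	MT-TT
MT-TT	MT-TT
TRNP	MT-TP
TRNA PRO	MT-TP
MT-TP	MT-TP
TRNE	MT-TE
TRNA GLU	MT-TE
MT-TE	MT-TE
TRNA	MT-TA
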