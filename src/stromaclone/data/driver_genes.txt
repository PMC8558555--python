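# Curated pancreatic ductal adenocarcinoma driver genes.
# One symbol per line; an optional second whitespace-separated field
# records provenance: "cohort" = recurrently hit in the motivating
# paired stroma/neoplasm cohort, "consensus" = pan-PDAC consensus
# driver catalogs from large sequencing studies.
KRAS	cohort
TP53	cohort
CDKN2A	cohort
SMAD4	cohort
ARID1A	cohort
GNAS	cohort
KDM6A	cohort
RNF43	cohort
TGFBR2	cohort
ARID2	consensus
ACVR1B	consensus
ACVR2A	consensus
ATM	consensus
BCORL1	consensus
BRAF	consensus
BRCA1	consensus
BRCA2	consensus
CTNNB1	consensus
KMT2C	consensus
KMT2D	consensus
MAP2K4	consensus
MARK2	consensus
NF1	consensus
PBRM1	consensus
PIK3CA	consensus
RB1	consensus
RREB1	consensus
SETD2	consensus
SF3B1	consensus
SMARCA4	consensus
STK11	consensus
TGFBR1	consensus
U2AF1	consensus
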