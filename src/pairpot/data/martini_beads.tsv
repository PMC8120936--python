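# pairpot side-chain bead mapping, version 1
# Follows the MARTINI 2.x amino-acid topology: one group of heavy atoms per
# side-chain bead; bead position is the unweighted centroid of the group.
# GLY and ALA carry no side-chain bead (backbone bead only).
# columns: residue <TAB> bead <TAB> comma-separated atom names
CYS	SC1	CB,SG
VAL	SC1	CB,CG1,CG2
LEU	SC1	CB,CG,CD1,CD2
ILE	SC1	CB,CG1,CG2,CD1
MET	SC1	CB,CG,SD,CE
PRO	SC1	CB,CG,CD
ASN	SC1	CB,CG,OD1,ND2
GLN	SC1	CB,CG,CD,OE1,NE2
ASP	SC1	CB,CG,OD1,OD2
GLU	SC1	CB,CG,CD,OE1,OE2
THR	SC1	CB,OG1,CG2
SER	SC1	CB,OG
LYS	SC1	CB,CG,CD
LYS	SC2	CE,NZ
ARG	SC1	CB,CG,CD
ARG	SC2	NE,CZ,NH1,NH2
HIS	SC1	CB,CG
HIS	SC2	CD2,NE2
HIS	SC3	ND1,CE1
PHE	SC1	CB,CG
PHE	SC2	CD1,CE1
PHE	SC3	CD2,CE2,CZ
TYR	SC1	CB,CG
TYR	SC2	CD1,CE1
TYR	SC3	CD2,CE2,CZ,OH
TRP	SC1	CB,CG
TRP	SC2	CD1,NE1,CE2
TRP	SC3	CD2,CE3
TRP	SC4	CZ2,CZ3,CH2
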