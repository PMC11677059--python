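# Side-chain dihedral definitions (IUPAC atom quadruples) for the 20
# standard residues. Columns: res_name  angle  a1  a2  a3  a4
# ALA and GLY have no side-chain dihedrals and are absent.
ARG	chi1	N	CA	CB	CG
ARG	chi2	CA	CB	CG	CD
ARG	chi3	CB	CG	CD	NE
ARG	chi4	CG	CD	NE	CZ
ASN	chi1	N	CA	CB	CG
ASN	chi2	CA	CB	CG	OD1
ASP	chi1	N	CA	CB	CG
ASP	chi2	CA	CB	CG	OD1
CYS	chi1	N	CA	CB	SG
GLN	chi1	N	CA	CB	CG
GLN	chi2	CA	CB	CG	CD
GLN	chi3	CB	CG	CD	OE1
GLU	chi1	N	CA	CB	CG
GLU	chi2	CA	CB	CG	CD
GLU	chi3	CB	CG	CD	OE1
HIS	chi1	N	CA	CB	CG
HIS	chi2	CA	CB	CG	ND1
ILE	chi1	N	CA	CB	CG1
ILE	chi2	CA	CB	CG1	CD1
LEU	chi1	N	CA	CB	CG
LEU	chi2	CA	CB	CG	CD1
LYS	chi1	N	CA	CB	CG
LYS	chi2	CA	CB	CG	CD
LYS	chi3	CB	CG	CD	CE
LYS	chi4	CG	CD	CE	NZ
MET	chi1	N	CA	CB	CG
MET	chi2	CA	CB	CG	SD
MET	chi3	CB	CG	SD	CE
PHE	chi1	N	CA	CB	CG
PHE	chi2	CA	CB	CG	CD1
PRO	chi1	N	CA	CB	CG
PRO	chi2	CA	CB	CG	CD
SER	chi1	N	CA	CB	OG
THR	chi1	N	CA	CB	OG1
TRP	chi1	N	CA	CB	CG
TRP	chi2	CA	CB	CG	CD1
TYR	chi1	N	CA	CB	CG
TYR	chi2	CA	CB	CG	CD1
VAL	chi1	N	CA	CB	CG1
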