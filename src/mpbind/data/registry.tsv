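comp_id	category
ALA	amino_acid
ARG	amino_acid
ASN	amino_acid
ASP	amino_acid
CYS	amino_acid
GLN	amino_acid
GLU	amino_acid
GLY	amino_acid
HIS	amino_acid
ILE	amino_acid
LEU	amino_acid
LYS	amino_acid
MET	amino_acid
PHE	amino_acid
PRO	amino_acid
SER	amino_acid
THR	amino_acid
TRP	amino_acid
TYR	amino_acid
VAL	amino_acid
DA	nucleotide
DC	nucleotide
DG	nucleotide
DT	nucleotide
A	nucleotide
C	nucleotide
G	nucleotide
U	nucleotide
ZN	ion
MG	ion
CA	ion
NA	ion
K	ion
FE	ion
FE2	ion
MN	ion
CU	ion
CO	ion
NI	ion
CD	ion
CL	ion
IOD	ion
BR	ion
HG	ion
FAD	ligand
FMN	ligand
NAD	ligand
NAP	ligand
NDP	ligand
ATP	ligand
ADP	ligand
AMP	ligand
ANP	ligand
GTP	ligand
GDP	ligand
GNP	ligand
UDP	ligand
HEM	ligand
HEC	ligand
HEA	ligand
SAM	ligand
SAH	ligand
PLP	ligand
COA	ligand
ACO	ligand
GLC	ligand
GAL	ligand
MAN	ligand
BMA	ligand
NAG	ligand
BGC	ligand
FUC	ligand
SIA	ligand
RET	ligand
CIT	ligand
CLR	lipid
PLM	lipid
OLA	lipid
CDL	lipid
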