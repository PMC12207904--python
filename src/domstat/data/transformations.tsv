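# Default biochemical transformation database (version 1).
# Mass differences are computed at load time from monoisotopic atomic
# masses of the listed composition, so they are exact by construction.
# Sources: common condensation/elimination moieties used in FT-ICR MS
# transformation analyses, proteinogenic amino-acid residues, and
# glycan residues.
name	composition
H2	H2
O	O
S	S
H2O	H2O
NH	HN
NH3	H3N
CH2	CH2
CH4	CH4
CO	CO
CO2	CO2
H2S	H2S
C2H2	C2H2
C2H4	C2H4
CH2O	CH2O
CH2O2	CH2O2
CH4O	CH4O
C2H2O	C2H2O
C2H4O	C2H4O
C2H4O2	C2H4O2
C2H6O	C2H6O
C3H4O2	C3H4O2
C3H6O2	C3H6O2
C4H6O2	C4H6O2
C2H2O2	C2H2O2
C2H5N	C2H5N
CH3N	CH3N
CH2S	CH2S
SO2	SO2
SO3	SO3
HPO3	HPO3
H3PO4	H3PO4
C2H3NO	C2H3NO
CHNO	CHNO
C6H6	C6H6
C3H2O	C3H2O
C4H4O	C4H4O
C2O2	C2O2
H2O2	H2O2
CH2O3	CH2O3
C3H2O3	C3H2O3
C4H2O4	C4H2O4
C6H4O	C6H4O
glycine_residue	C2H3NO
alanine_residue	C3H5NO
serine_residue	C3H5NO2
proline_residue	C5H7NO
valine_residue	C5H9NO
threonine_residue	C4H7NO2
cysteine_residue	C3H5NOS
leucine_residue	C6H11NO
asparagine_residue	C4H6N2O2
aspartate_residue	C4H5NO3
glutamine_residue	C5H8N2O2
lysine_residue	C6H12N2O
glutamate_residue	C5H7NO3
methionine_residue	C5H9NOS
histidine_residue	C6H7N3O
phenylalanine_residue	C9H9NO
arginine_residue	C6H12N4O
tyrosine_residue	C9H9NO2
tryptophan_residue	C11H10N2O
pentose_residue	C5H8O4
hexose_residue	C6H10O5
deoxyhexose_residue	C6H10O4
hexuronic_residue	C6H8O6
aminohexose_residue	C6H11NO4
glucose	C6H12O6
glycerol	C3H8O3
acetyl	C2H2O
malonyl	C3H2O3
succinyl	C4H4O3
glutathione	C10H17N3O6S
palmitoyl	C16H30O
biotinyl	C10H14N2O2S
pyridoxal	C8H9NO3
co2_h2o	CH2O3
urea	CH4N2O
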