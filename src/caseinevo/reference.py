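"""Reference constants: the mature bovine kappa-casein sequence and landmarks.

The mature bovine chain (UniProt P02668, signal peptide removed, 169
residues) is the coordinate reference of the analysis: the chymosin/pepsin
cleavage site between Phe105 and Met106 splits it into para-kappa-casein
(residues 1-105) and the glycomacropeptide (106-169). Landmarks used in
tests: cysteines at positions 11 and 88; the conserved Fam20C phosphoserine
S149 flanked by glutamates at 147 and 151.
"""

BOVINE_MATURE_KAPPA_CASEIN = (
    "QEQNQEQPIRCEKDERFFSDKIAKYIPIQYVLSRYPSYGLNYYQQKPVAL"
    "INNQFLPYPYYAKPAAVRSPAQILQWQVLSNTVPAKSCQAQPTTMARHPH"
    "PHLSFMAIPPKKNQDKTEIPTINTIASGEPTSTPTTEAVESTVATLEDSP"
    "EVIESPPEINTVQVTSTAV"
)

# Cleavage after residue 105 (Phe105 | Met106) of the mature chain.
BOVINE_CLEAVAGE_POS = 105

BOVINE_PKC = BOVINE_MATURE_KAPPA_CASEIN[:BOVINE_CLEAVAGE_POS]
BOVINE_GMP = BOVINE_MATURE_KAPPA_CASEIN[BOVINE_CLEAVAGE_POS:]
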