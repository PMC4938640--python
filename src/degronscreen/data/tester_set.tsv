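id	peptide
CL1	ACKNWFSSLSHFVIHL
10-1	KSVTLESRSPKFLNWFSVFSLFKVITTG
10-6	DFFFLFVLPSEQKVKSPECDKDILRLTITQVLSHKTPYI
10-13	CSEIIPMSRSTPISTMG
10-15	SYWLTVY
10-21	ENQEGLLKFQSIFVYCYRLLLKTLPL
10-31	SIFYHIGTDLWTLSEHYYEGVLSLVASVIISGR
10-34	VVLVVVF
10-40	YMSILRCASGKISIAAPPYIF
10-43	QSHMTIESKTRIERKMLVCTPG
12-32	LWLEDLQRTVVLIMVKPG
12-33	AGESFNFMVKLLYKHPILPCLKTLLSIRSSCSPR
12-86	VSFAFNLNSLIVGILRFHW
12-98	SQAFIATLLFDSSMSALPIIPKQNSVSVGLFTH
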