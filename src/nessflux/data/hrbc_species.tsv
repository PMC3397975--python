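# Reduced human red blood cell network: metabolites.
# Reconstructed from textbook stoichiometry of erythrocyte glycolysis, the
# 2,3-DPG (Rapoport-Leubering) shunt and the pentose phosphate pathway;
# concentrations are typical literature values for the human erythrocyte and
# blood plasma (mol/L).  Species with id suffix 'X' are extracellular
# (boundary) pools; their balance is not enforced at steady state.
id	cbar	u	is_boundary
GLC	5e-03	0.0	false
G6P	3.8e-05	0.0	false
F6P	1.4e-05	0.0	false
FDP	7.6e-06	0.0	false
GAP	6.7e-06	0.0	false
DPG13	4e-07	0.0	false
DPG23	5e-03	0.0	false
PG3	6.9e-05	0.0	false
PG2	1e-05	0.0	false
PEP	1.7e-05	0.0	false
PYR	8.4e-05	0.0	false
LAC	1.4e-03	0.0	false
RU5P	5e-06	0.0	false
R5P	1.4e-05	0.0	false
X5P	1.4e-05	0.0	false
S7P	2.4e-05	0.0	false
E4P	5e-06	0.0	false
CO2	1.2e-03	0.0	false
ATP	1.8e-03	0.0	false
ADP	2.2e-04	0.0	false
Pi	1e-03	0.0	false
NAD	6e-05	0.0	false
NADH	2e-07	0.0	false
NADP	1e-06	0.0	false
NADPH	6.5e-05	0.0	false
GLCX	5e-03	0.0	true
LACX	1e-03	0.0	true
CO2X	1.2e-03	0.0	true
KX	4e-03	0.0	true
NAX	1.4e-01	0.0	true
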