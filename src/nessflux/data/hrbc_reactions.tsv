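# Reduced human red blood cell network: reactions (21 pathway reactions plus
# the ATPase and NADPHase pumps).  Reconstructed from textbook stoichiometry:
# aldolase and triosephosphate isomerase are lumped (FDP -> 2 GAP), and the
# oxidative pentose phosphate branch (G6PDH + lactonase + 6PGDH) is lumped
# into a single G6PDH step.  The ATPase row carries the K+/Na+ exchange with
# opposite signs (2 K+ pumped in, 3 Na+ pumped out, per ATP); the buffered
# intracellular ion pools are not tracked.
id	formula	qmax
GLCtr	GLCX -> GLC	0.1
HK	GLC + ATP -> G6P + ADP	0.1
PGI	G6P -> F6P	0.1
PFK	F6P + ATP -> FDP + ADP	0.1
ALD	FDP -> 2 GAP	0.1
GAPDH	GAP + NAD + Pi -> DPG13 + NADH	0.1
PGK	DPG13 + ADP -> PG3 + ATP	0.1
DPGM	DPG13 -> DPG23	0.1
DPGase	DPG23 -> PG3 + Pi	0.1
PGM	PG3 -> PG2	0.1
EN	PG2 -> PEP	0.1
PK	PEP + ADP -> PYR + ATP	0.1
LDH	PYR + NADH -> LAC + NAD	0.1
LACtr	LAC -> LACX	0.1
G6PDH	G6P + 2 NADP -> RU5P + CO2 + 2 NADPH	0.1
RPI	RU5P -> R5P	0.1
RPE	RU5P -> X5P	0.1
TKI	R5P + X5P -> S7P + GAP	0.1
TA	S7P + GAP -> F6P + E4P	0.1
TKII	X5P + E4P -> F6P + GAP	0.1
CO2tr	CO2 -> CO2X	0.1
ATPase	ATP + 2 KX -> ADP + Pi + 3 NAX	0.1
NADPHase	NADPH -> NADP	0.1
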