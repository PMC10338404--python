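# amadori_shifts v1 -- fructoselysine (Amadori product) 1H/13C cross-peak library
# All shifts DSS-referenced, beta-pyranose values from glycated-BSA assignments.
# Minor-form (alpha-pyranose, furanose) positions are SYNTHETIC placeholders:
# published main-text assignments exist only for the beta-pyranose form, so the
# minor forms carry configurable stand-in positions kept >= 1 ppm (13C) away
# from the beta-pyranose diagnostic markers. Populations are the equilibrium
# abundances of N-eps-fructoselysine (~70/13/13/4, open forms < 1% omitted).
form,label,c13_ppm,h1_ppm,multiplicity,protons_in_signal,diagnostic,exchange_affected,hsqc_visible,population
beta-pyranose,C1-H1,55.6,3.29,CH2,2,False,True,True,0.70
beta-pyranose,C2,98.2,,Cq,1,False,False,False,0.70
beta-pyranose,C3-H3,72.4,3.75,CH,1,False,False,True,0.70
beta-pyranose,C4-H4,72.1,3.89,CH,1,False,False,True,0.70
beta-pyranose,C5-H5,71.8,4.00,CH,1,True,False,True,0.70
beta-pyranose,C6-H6,66.7,3.99,CH2,1,True,False,True,0.70
beta-pyranose,C6-H6',66.7,3.76,CH2,1,True,False,True,0.70
beta-pyranose,Lys Ce-He,50.9,3.06,CH2,2,False,False,True,0.70
alpha-pyranose,C3-H3,70.0,3.62,CH,1,False,False,True,0.04
alpha-pyranose,C4-H4,70.6,3.95,CH,1,False,False,True,0.04
alpha-pyranose,C5-H5,69.0,4.08,CH,1,False,False,True,0.04
beta-furanose,C3-H3,76.4,4.12,CH,1,False,False,True,0.13
beta-furanose,C4-H4,75.4,4.02,CH,1,False,False,True,0.13
beta-furanose,C5-H5,81.6,3.92,CH,1,False,False,True,0.13
alpha-furanose,C3-H3,82.6,4.06,CH,1,False,False,True,0.13
alpha-furanose,C4-H4,77.6,3.96,CH,1,False,False,True,0.13
alpha-furanose,C5-H5,80.2,4.16,CH,1,False,False,True,0.13
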