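# diffuse reflectance vs source-detector separation, layered slab (15 mm extracerebral preset), generated by speckleflow.montecarlo.run_layered_mc
# n_photons=4000000 seed=20240850 wavelength_nm=850
sds_mm,reflectance_per_cm2
5,5.67973107e-02
10,6.34171433e-03
15,1.09202496e-03
20,2.37212782e-04
25,6.47192144e-05
30,1.86357462e-05
35,6.84889343e-06
40,2.89259998e-06
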