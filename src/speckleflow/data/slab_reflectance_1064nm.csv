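# diffuse reflectance vs source-detector separation, layered slab (15 mm extracerebral preset), generated by speckleflow.montecarlo.run_layered_mc
# n_photons=4000000 seed=20241064 wavelength_nm=1064
sds_mm,reflectance_per_cm2
5,6.49394977e-02
10,1.03019155e-02
15,2.28861148e-03
20,6.31838468e-04
25,1.99875283e-04
30,6.69018686e-05
35,2.61161913e-05
40,1.03731433e-05
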