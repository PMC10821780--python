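# Optical and flow properties of the four head-tissue categories used by
# all preset simulations (per wavelength; mu in 1/cm, BFi in cm^2/s).
optical_properties:
  850:
    scalp: {mu_a: 0.164, mu_s_prime: 7.4, refractive_index: 1.4}
    skull: {mu_a: 0.155, mu_s_prime: 8.1, refractive_index: 1.4}
    csf:   {mu_a: 0.017, mu_s_prime: 0.1, refractive_index: 1.4}
    brain: {mu_a: 0.170, mu_s_prime: 11.6, refractive_index: 1.4}
  1064:
    scalp: {mu_a: 0.11,  mu_s_prime: 5.3, refractive_index: 1.4}
    skull: {mu_a: 0.13,  mu_s_prime: 5.8, refractive_index: 1.4}
    csf:   {mu_a: 0.122, mu_s_prime: 0.07, refractive_index: 1.4}
    brain: {mu_a: 0.17,  mu_s_prime: 8.3, refractive_index: 1.4}
flow:
  baseline:  {scalp: 1.0e-8, skull: 1.0e-10, csf: 1.0e-10, brain: 6.0e-8}
  perturbed: {scalp: 1.0e-8, skull: 1.0e-10, csf: 1.0e-10, brain: 7.2e-8}
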