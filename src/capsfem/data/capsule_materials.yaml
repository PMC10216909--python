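# Regional constants for the glenohumeral capsule.
# Yeoh coefficients c1..c3 in MPa, thicknesses in mm; labrum is linear
# elastic (tensile modulus in MPa) with a 4 mm band thickness.
regions:
  antero_superior: {c1: 20.5, c2: -26.5, c3: 185.3, thickness: 2.8}
  posterior:       {c1: 13.2, c2: -19.6, c3: 125.9, thickness: 1.5}
  ab_ighl:         {c1: 11.9, c2: -11.1, c3: 95.8,  thickness: 2.8}
  pb_ighl:         {c1: 29.1, c2: -18.4, c3: 206.5, thickness: 1.3}
  axillary_pouch:  {c1: 0.22, c2: -17.4, c3: 111.9, thickness: 4.3}
labrum:
  tensile_modulus: 45.6
  poisson_ratio: 0.449
  thickness: 4.0
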