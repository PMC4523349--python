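# Halodule wrightii (shoal grass) HSI model.
#
# SYNTHETIC APPROXIMATION: breakpoints are read off published look-up graphs
# for the Caloosahatchee estuary system, which exist only in figure form; the
# numbers below reproduce the curve shapes (a salt-tolerant species favouring
# marine salinities, warm water and well-lit bottoms) but are not an official
# parameterisation.  Salinity in PSU, temperature in degC, ADBL in
# umol m^-2 s^-1; each pair is [variable value, suitability index].
species:
  name: Halodule wrightii
  surface_transmission: 0.9
  curves:
    salinity:
      - [0.0, 0.0]
      - [5.0, 0.05]
      - [15.0, 0.5]
      - [24.0, 1.0]
      - [38.0, 1.0]
      - [45.0, 0.5]
      - [55.0, 0.0]
    temperature:
      - [10.0, 0.0]
      - [17.0, 0.3]
      - [22.0, 1.0]
      - [30.0, 1.0]
      - [35.0, 0.3]
      - [40.0, 0.0]
    adbl:
      - [0.0, 0.0]
      - [100.0, 0.15]
      - [300.0, 0.7]
      - [500.0, 1.0]
      - [1000.0, 1.0]
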