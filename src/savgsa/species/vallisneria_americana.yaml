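# Vallisneria americana (tape grass) HSI model.
#
# SYNTHETIC APPROXIMATION: breakpoints are read off published look-up graphs
# for the Caloosahatchee estuary system, which exist only in figure form; the
# numbers below reproduce the curve shapes (a salt-intolerant species of
# shallow fresh reaches) but are not an official parameterisation.
#
# Tape grass uses two ADBL curves because its light-use efficiency degrades
# under salt stress: the low-salinity curve applies below the salinity
# threshold, the less efficient high-salinity curve at or above it.
species:
  name: Vallisneria americana
  surface_transmission: 0.9
  adbl_salinity_threshold: 8.0
  curves:
    salinity:
      - [0.0, 1.0]
      - [3.0, 1.0]
      - [8.0, 0.5]
      - [12.0, 0.1]
      - [15.0, 0.0]
    temperature:
      - [10.0, 0.0]
      - [16.0, 0.5]
      - [20.0, 1.0]
      - [30.0, 1.0]
      - [33.0, 0.5]
      - [36.0, 0.0]
    adbl_low_salinity:
      - [0.0, 0.0]
      - [50.0, 0.2]
      - [200.0, 0.8]
      - [350.0, 1.0]
      - [1000.0, 1.0]
    adbl_high_salinity:
      - [0.0, 0.0]
      - [100.0, 0.1]
      - [300.0, 0.5]
      - [600.0, 1.0]
      - [1000.0, 1.0]
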