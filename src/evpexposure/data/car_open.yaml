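# Car with windows opened a 3-inch gap, 2 users among 4 occupants, 1-h
# exposure.  ach reconstructed by calibration (see car_closed.yaml).
name: car_open
volume_m3: 3.17
ach_per_h: 52.4802
duration_h: 1.0
n_users: 2
n_occupants: 4
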