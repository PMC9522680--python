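# Restaurant, 15 users among 100 occupants, 2-h exposure.
# ach reconstructed by calibration (see car_closed.yaml).
name: restaurant
volume_m3: 270.0
ach_per_h: 4.8807
duration_h: 2.0
n_users: 15
n_occupants: 100
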