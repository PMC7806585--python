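name,semi_axis_a_cm,semi_axis_b_cm,length_cm
oral_cavity,1.37736230588,0.688681152939,7
pharynx,0.777681672504,0.388840836252,6
larynx,0.638307648642,0.319153824321,3
trachea_end,0.95,0.95,0
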