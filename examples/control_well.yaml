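# Baseline swirling-well configuration: one well of a 12-well plate,
# 767 µl (2 mm mean depth), 150 rpm on a 10 mm-diameter orbit.
name: control
well_radius_mm: 11.05
mean_depth_mm: 2
orbital_radius_mm: 5
rpm: 150
fluid:
  density_liquid_kg_m3: 1003
  density_air_kg_m3: 1.1115
  dynamic_viscosity_pa_s: 0.78e-3
  surface_tension_n_m: 0.072
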