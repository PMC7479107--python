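# Worked-example farm: ten identical turbines in a single 2000 m row.
farm:
  turbines:
    - blade_length_m: 40
      tower_height_m: 80
      rotor_speed_rpm: 10
      count: 10
  rows: 1
  frontal_area_m2: 240000  # 2000 m row width x 120 m (L + r)
location:
  low_visibility_days: 36
  observation_days: 360
  sensitive_area_distance_km: 30
  on_migratory_pass: true
  neighbour_farm_distances_km: [7.0]
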