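# Needle-electrode catalog. Dimensions are editable nominal values
# (manufacturer data sheets are not reproduced here); edit freely.
electrodes:
  - id: hex-7
    style: hexagonal
    needle_diameter_mm: 0.7
    active_lengths_mm: [10.0, 20.0, 30.0]
    default_active_length_mm: 20.0
    hex_radius_mm: 7.3
    max_voltage_v: 1000.0
  - id: linear-2
    style: linear
    needle_diameter_mm: 0.7
    active_lengths_mm: [10.0, 20.0, 30.0]
    default_active_length_mm: 20.0
    offsets_mm: [[-4.0, 0.0], [4.0, 0.0]]
    max_voltage_v: 1000.0
  - id: finger-axial
    style: finger-axial
    needle_diameter_mm: 0.7
    active_lengths_mm: [5.0, 10.0]
    default_active_length_mm: 10.0
    offsets_mm: [[-2.5, 0.0], [2.5, 0.0]]
    max_voltage_v: 1000.0
  - id: finger-perpendicular
    style: finger-perpendicular
    needle_diameter_mm: 0.7
    active_lengths_mm: [5.0, 10.0]
    default_active_length_mm: 10.0
    offsets_mm: [[-2.0, -2.0], [2.0, 2.0]]
    max_voltage_v: 1000.0
  - id: variable-single
    style: variable
    needle_diameter_mm: 1.2
    active_lengths_mm: [10.0, 15.0, 20.0, 25.0, 30.0, 40.0]
    default_active_length_mm: 20.0
    max_voltage_v: 3000.0
  - id: variable-single-fine
    style: variable
    needle_diameter_mm: 1.0
    active_lengths_mm: [10.0, 15.0, 20.0, 25.0, 30.0]
    default_active_length_mm: 20.0
    max_voltage_v: 3000.0
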