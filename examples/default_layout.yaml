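tank:
  length_cm: 150.0
  width_cm: 70.0
  depth_cm: 30.0
  burrows:
  - entrance_x_cm: 32.14285714285714
    entrance_y_cm: 17.5
    interior_x_cm: 8.650541623209428
    interior_y_cm: 17.500000000000004
    tunnel_length_cm: 25.0
    tunnel_inclination_deg: 20.0
    entrance_diameter_cm: 10.0
    tunnel_diameter_cm: 7.0
  - entrance_x_cm: 32.14285714285714
    entrance_y_cm: 52.5
    interior_x_cm: 8.650541623209428
    interior_y_cm: 52.5
    tunnel_length_cm: 25.0
    tunnel_inclination_deg: 20.0
    entrance_diameter_cm: 10.0
    tunnel_diameter_cm: 7.0
  - entrance_x_cm: 117.85714285714285
    entrance_y_cm: 5.833333333333333
    interior_x_cm: 141.34945837679055
    interior_y_cm: 5.833333333333333
    tunnel_length_cm: 25.0
    tunnel_inclination_deg: 20.0
    entrance_diameter_cm: 10.0
    tunnel_diameter_cm: 7.0
  - entrance_x_cm: 117.85714285714285
    entrance_y_cm: 64.16666666666666
    interior_x_cm: 141.34945837679055
    interior_y_cm: 64.16666666666666
    tunnel_length_cm: 25.0
    tunnel_inclination_deg: 20.0
    entrance_diameter_cm: 10.0
    tunnel_diameter_cm: 7.0
antennas:
- id: 1
  x_cm: 10.714285714285714
  y_cm: 5.833333333333333
  controller: 1
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 2
  x_cm: 32.14285714285714
  y_cm: 5.833333333333333
  controller: 1
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 3
  x_cm: 53.57142857142857
  y_cm: 5.833333333333333
  controller: 1
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 4
  x_cm: 75.0
  y_cm: 5.833333333333333
  controller: 1
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 5
  x_cm: 96.42857142857142
  y_cm: 5.833333333333333
  controller: 1
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 6
  x_cm: 117.85714285714285
  y_cm: 5.833333333333333
  controller: 1
  role: burrow_entrance
  active: true
  field_radius_cm: 3.0
- id: 7
  x_cm: 139.28571428571428
  y_cm: 5.833333333333333
  controller: 1
  role: burrow_interior
  active: true
  field_radius_cm: 3.0
- id: 8
  x_cm: 10.714285714285714
  y_cm: 17.5
  controller: 2
  role: burrow_interior
  active: true
  field_radius_cm: 3.0
- id: 9
  x_cm: 32.14285714285714
  y_cm: 17.5
  controller: 2
  role: burrow_entrance
  active: true
  field_radius_cm: 3.0
- id: 10
  x_cm: 53.57142857142857
  y_cm: 17.5
  controller: 2
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 11
  x_cm: 75.0
  y_cm: 17.5
  controller: 2
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 12
  x_cm: 96.42857142857142
  y_cm: 17.5
  controller: 2
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 13
  x_cm: 117.85714285714285
  y_cm: 17.5
  controller: 2
  role: grid
  active: false
  field_radius_cm: 3.0
- id: 14
  x_cm: 139.28571428571428
  y_cm: 17.5
  controller: 2
  role: grid
  active: false
  field_radius_cm: 3.0
- id: 15
  x_cm: 10.714285714285714
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 16
  x_cm: 32.14285714285714
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 17
  x_cm: 53.57142857142857
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 18
  x_cm: 75.0
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 19
  x_cm: 96.42857142857142
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: false
  field_radius_cm: 3.0
- id: 20
  x_cm: 117.85714285714285
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: false
  field_radius_cm: 3.0
- id: 21
  x_cm: 139.28571428571428
  y_cm: 29.166666666666664
  controller: 3
  role: grid
  active: false
  field_radius_cm: 3.0
- id: 22
  x_cm: 10.714285714285714
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 23
  x_cm: 32.14285714285714
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 24
  x_cm: 53.57142857142857
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 25
  x_cm: 75.0
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 26
  x_cm: 96.42857142857142
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 27
  x_cm: 117.85714285714285
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 28
  x_cm: 139.28571428571428
  y_cm: 40.83333333333333
  controller: 4
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 29
  x_cm: 10.714285714285714
  y_cm: 52.5
  controller: 5
  role: burrow_interior
  active: true
  field_radius_cm: 3.0
- id: 30
  x_cm: 32.14285714285714
  y_cm: 52.5
  controller: 5
  role: burrow_entrance
  active: true
  field_radius_cm: 3.0
- id: 31
  x_cm: 53.57142857142857
  y_cm: 52.5
  controller: 5
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 32
  x_cm: 75.0
  y_cm: 52.5
  controller: 5
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 33
  x_cm: 96.42857142857142
  y_cm: 52.5
  controller: 5
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 34
  x_cm: 117.85714285714285
  y_cm: 52.5
  controller: 5
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 35
  x_cm: 139.28571428571428
  y_cm: 52.5
  controller: 5
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 36
  x_cm: 10.714285714285714
  y_cm: 64.16666666666666
  controller: 6
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 37
  x_cm: 32.14285714285714
  y_cm: 64.16666666666666
  controller: 6
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 38
  x_cm: 53.57142857142857
  y_cm: 64.16666666666666
  controller: 6
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 39
  x_cm: 75.0
  y_cm: 64.16666666666666
  controller: 6
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 40
  x_cm: 96.42857142857142
  y_cm: 64.16666666666666
  controller: 6
  role: grid
  active: true
  field_radius_cm: 3.0
- id: 41
  x_cm: 117.85714285714285
  y_cm: 64.16666666666666
  controller: 6
  role: burrow_entrance
  active: true
  field_radius_cm: 3.0
- id: 42
  x_cm: 139.28571428571428
  y_cm: 64.16666666666666
  controller: 6
  role: burrow_interior
  active: true
  field_radius_cm: 3.0
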