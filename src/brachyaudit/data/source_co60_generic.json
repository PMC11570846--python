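{
 "label": "generic Co-60 HDR line source",
 "radionuclide": "Co-60",
 "lambda_cGy_per_h_per_U": 1.087,
 "active_length_mm": 3.5,
 "geometry_model": "line",
 "radial_dose": [
  [
   0.25,
   1.002
  ],
  [
   0.5,
   1.001
  ],
  [
   1.0,
   1.0
  ],
  [
   1.5,
   0.999
  ],
  [
   2.0,
   0.998
  ],
  [
   2.5,
   0.997
  ],
  [
   3.0,
   0.996
  ],
  [
   3.5,
   0.995
  ],
  [
   4.0,
   0.993
  ],
  [
   5.0,
   0.99
  ],
  [
   6.0,
   0.986
  ],
  [
   8.0,
   0.977
  ],
  [
   10.0,
   0.966
  ]
 ],
 "anisotropy": {
  "r_cm": [
   0.5,
   1.0,
   2.0,
   3.0,
   5.0
  ],
  "theta_deg": [
   0,
   10,
   20,
   30,
   40,
   50,
   60,
   70,
   80,
   90,
   100,
   110,
   120,
   130,
   140,
   150,
   160,
   170,
   180
  ],
  "F": [
   [
    0.8,
    0.85,
    0.893,
    0.929,
    0.957,
    0.977,
    0.99,
    0.997,
    1.0,
    1.0,
    1.0,
    0.997,
    0.99,
    0.977,
    0.957,
    0.929,
    0.893,
    0.85,
    0.8
   ],
   [
    0.81,
    0.857,
    0.899,
    0.933,
    0.959,
    0.978,
    0.991,
    0.997,
    1.0,
    1.0,
    1.0,
    0.997,
    0.991,
    0.978,
    0.959,
    0.933,
    0.899,
    0.857,
    0.81
   ],
   [
    0.82,
    0.865,
    0.904,
    0.936,
    0.962,
    0.98,
    0.991,
    0.997,
    1.0,
    1.0,
    1.0,
    0.997,
    0.991,
    0.98,
    0.962,
    0.936,
    0.904,
    0.865,
    0.82
   ],
   [
    0.83,
    0.872,
    0.909,
    0.94,
    0.964,
    0.981,
    0.992,
    0.997,
    1.0,
    1.0,
    1.0,
    0.997,
    0.992,
    0.981,
    0.964,
    0.94,
    0.909,
    0.872,
    0.83
   ],
   [
    0.84,
    0.88,
    0.915,
    0.943,
    0.966,
    0.982,
    0.992,
    0.998,
    1.0,
    1.0,
    1.0,
    0.998,
    0.992,
    0.982,
    0.966,
    0.943,
    0.915,
    0.88,
    0.84
   ]
  ]
 },
 "metadata": {
  "provenance": "synthetic generic dataset; values representative of published consensus-style Co-60 HDR data, not a vendor characterization",
  "generator": "scripts/make_source_fixtures.py"
 }
}
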