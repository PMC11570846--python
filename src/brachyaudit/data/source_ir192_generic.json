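{
 "label": "generic Ir-192 HDR line source",
 "radionuclide": "Ir-192",
 "lambda_cGy_per_h_per_U": 1.109,
 "active_length_mm": 3.5,
 "geometry_model": "line",
 "radial_dose": [
  [
   0.25,
   0.99
  ],
  [
   0.5,
   0.994
  ],
  [
   1.0,
   1.0
  ],
  [
   1.5,
   1.003
  ],
  [
   2.0,
   1.005
  ],
  [
   2.5,
   1.006
  ],
  [
   3.0,
   1.006
  ],
  [
   3.5,
   1.005
  ],
  [
   4.0,
   1.004
  ],
  [
   5.0,
   0.999
  ],
  [
   6.0,
   0.991
  ],
  [
   8.0,
   0.965
  ],
  [
   10.0,
   0.93
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
    0.62,
    0.715,
    0.797,
    0.866,
    0.919,
    0.957,
    0.981,
    0.994,
    0.999,
    1.0,
    0.999,
    0.994,
    0.981,
    0.957,
    0.919,
    0.866,
    0.797,
    0.715,
    0.62
   ],
   [
    0.64,
    0.73,
    0.808,
    0.873,
    0.923,
    0.959,
    0.982,
    0.995,
    0.999,
    1.0,
    0.999,
    0.995,
    0.982,
    0.959,
    0.923,
    0.873,
    0.808,
    0.73,
    0.64
   ],
   [
    0.67,
    0.752,
    0.824,
    0.883,
    0.93,
    0.963,
    0.984,
    0.995,
    0.999,
    1.0,
    0.999,
    0.995,
    0.984,
    0.963,
    0.93,
    0.883,
    0.824,
    0.752,
    0.67
   ],
   [
    0.69,
    0.767,
    0.835,
    0.89,
    0.934,
    0.965,
    0.985,
    0.995,
    0.999,
    1.0,
    0.999,
    0.995,
    0.985,
    0.965,
    0.934,
    0.89,
    0.835,
    0.767,
    0.69
   ],
   [
    0.71,
    0.782,
    0.845,
    0.897,
    0.938,
    0.967,
    0.986,
    0.996,
    0.999,
    1.0,
    0.999,
    0.996,
    0.986,
    0.967,
    0.938,
    0.897,
    0.845,
    0.782,
    0.71
   ]
  ]
 },
 "metadata": {
  "provenance": "synthetic generic dataset; values representative of published consensus-style Ir-192 HDR data, not a vendor characterization",
  "generator": "scripts/make_source_fixtures.py"
 }
}
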