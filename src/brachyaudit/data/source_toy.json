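{
 "label": "toy unit point source",
 "radionuclide": "toy",
 "lambda_cGy_per_h_per_U": 1.0,
 "active_length_mm": 0.0,
 "geometry_model": "point",
 "radial_dose": [
  [
   0.01,
   1.0
  ],
  [
   1.0,
   1.0
  ],
  [
   1000.0,
   1.0
  ]
 ],
 "anisotropy": {
  "r_cm": [
   0.01,
   1.0,
   1000.0
  ],
  "theta_deg": [
   0.0,
   90.0,
   180.0
  ],
  "F": [
   [
    1.0,
    1.0,
    1.0
   ],
   [
    1.0,
    1.0,
    1.0
   ],
   [
    1.0,
    1.0,
    1.0
   ]
  ]
 },
 "metadata": {
  "provenance": "synthetic idealized dataset for analytic cross-checks",
  "notes": "inverse-square only; not a physical source model"
 }
}
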