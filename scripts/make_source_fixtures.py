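"""One-off generator for the bundled synthetic source-dataset fixtures."""
import json
import numpy as np
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "brachyaudit" / "data"
OUT.mkdir(parents=True, exist_ok=True)

THETA = list(range(0, 181, 10))


def anisotropy(a_by_r, exponent=1.5):
    r = sorted(a_by_r)
    F = []
    for rr in r:
        a = a_by_r[rr]
        row = [round(1.0 - a * (1.0 - np.sin(np.deg2rad(t))) ** exponent, 3)
               for t in THETA]
        row[THETA.index(90)] = 1.0
        F.append(row)
    return {"r_cm": r, "theta_deg": THETA, "F": F}


def write(name, payload):
    (OUT / name).write_text(json.dumps(payload, indent=1) + "\n")
    print("wrote", name)


# idealized unit point source: Lambda*S_K = 1 cGy/h at 1 cm, g == F == 1
write("source_toy.json", {
    "label": "toy unit point source",
    "radionuclide": "toy",
    "lambda_cGy_per_h_per_U": 1.0,
    "active_length_mm": 0.0,
    "geometry_model": "point",
    "radial_dose": [[0.01, 1.0], [1.0, 1.0], [1000.0, 1.0]],
    "anisotropy": {"r_cm": [0.01, 1.0, 1000.0], "theta_deg": [0.0, 90.0, 180.0],
                   "F": [[1.0, 1.0, 1.0]] * 3},
    "metadata": {
        "provenance": "synthetic idealized dataset for analytic cross-checks",
        "notes": "inverse-square only; not a physical source model"},
})

r_grid = [0.25, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 10.0]

write("source_ir192_generic.json", {
    "label": "generic Ir-192 HDR line source",
    "radionuclide": "Ir-192",
    "lambda_cGy_per_h_per_U": 1.109,
    "active_length_mm": 3.5,
    "geometry_model": "line",
    "radial_dose": [list(p) for p in zip(r_grid,
        [0.990, 0.994, 1.000, 1.003, 1.005, 1.006, 1.006,
         1.005, 1.004, 0.999, 0.991, 0.965, 0.930])],
    "anisotropy": anisotropy({0.5: 0.38, 1.0: 0.36, 2.0: 0.33,
                              3.0: 0.31, 5.0: 0.29}),
    "metadata": {
        "provenance": "synthetic generic dataset; values representative of "
                      "published consensus-style Ir-192 HDR data, not a "
                      "vendor characterization",
        "generator": "scripts/make_source_fixtures.py"},
})

write("source_co60_generic.json", {
    "label": "generic Co-60 HDR line source",
    "radionuclide": "Co-60",
    "lambda_cGy_per_h_per_U": 1.087,
    "active_length_mm": 3.5,
    "geometry_model": "line",
    "radial_dose": [list(p) for p in zip(r_grid,
        [1.002, 1.001, 1.000, 0.999, 0.998, 0.997, 0.996,
         0.995, 0.993, 0.990, 0.986, 0.977, 0.966])],
    "anisotropy": anisotropy({0.5: 0.20, 1.0: 0.19, 2.0: 0.18,
                              3.0: 0.17, 5.0: 0.16}),
    "metadata": {
        "provenance": "synthetic generic dataset; values representative of "
                      "published consensus-style Co-60 HDR data, not a "
                      "vendor characterization",
        "generator": "scripts/make_source_fixtures.py"},
})
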