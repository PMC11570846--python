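name,percent,gum_type
Calibration coefficient,0.69,A
Calibration coefficient (Type B),0.54,B
Reading of a dosimeter,0.15,A
Individual dosimeter sensitivity correction factor,0.42,A
Dosimeter positioning during readout,0.18,A
Dose response non-linearity correction factor,0.83,A
Fading correction factor,0.01,A
RAKR (Type B),1.35,B
Dose calculation in the RPLD volume (MC derived),0.90,A
Total correction factor k_tot,0.83,A
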