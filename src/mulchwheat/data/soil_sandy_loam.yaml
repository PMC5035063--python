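# Sandy loam profile (Punjab Agricultural University, Ludhiana field sites).
# Layer bounds in cm; LL/DUL/SAT volumetric (cm3 cm-3); BD g cm-3;
# SWCON = fraction of water above DUL draining per day; KL = daily root
# extraction efficiency. U/cona are the stage-1/stage-2 soil evaporation
# parameters (mm, mm d^-1/2); bund height limits surface runoff.
name: sandy_loam
u_mm: 10.0
cona: 2.0
bund_mm: 100.0
layers:
  - {top_cm: 0,   bottom_cm: 15,  ll: 0.07, dul: 0.26, sat: 0.36, bd: 1.61, swcon: 0.50, kl: 0.07}
  - {top_cm: 15,  bottom_cm: 30,  ll: 0.07, dul: 0.27, sat: 0.31, bd: 1.76, swcon: 0.50, kl: 0.06}
  - {top_cm: 30,  bottom_cm: 60,  ll: 0.06, dul: 0.23, sat: 0.36, bd: 1.61, swcon: 0.50, kl: 0.06}
  - {top_cm: 60,  bottom_cm: 90,  ll: 0.06, dul: 0.21, sat: 0.39, bd: 1.53, swcon: 0.50, kl: 0.03}
  - {top_cm: 90,  bottom_cm: 120, ll: 0.07, dul: 0.21, sat: 0.39, bd: 1.53, swcon: 0.50, kl: 0.02}
  - {top_cm: 120, bottom_cm: 150, ll: 0.05, dul: 0.21, sat: 0.39, bd: 1.52, swcon: 0.50, kl: 0.01}
  - {top_cm: 150, bottom_cm: 180, ll: 0.05, dul: 0.20, sat: 0.39, bd: 1.52, swcon: 0.50, kl: 0.01}
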