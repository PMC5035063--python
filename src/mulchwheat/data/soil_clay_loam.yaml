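# Clay loam profile (Punjab Agricultural University, Ludhiana field sites).
# Same conventions as soil_sandy_loam.yaml. The higher U (12 mm) and cona
# (4 mm) reflect the finer texture's larger stage-1 evaporation capacity.
name: clay_loam
u_mm: 12.0
cona: 4.0
bund_mm: 100.0
layers:
  - {top_cm: 0,   bottom_cm: 15,  ll: 0.10, dul: 0.31, sat: 0.35, bd: 1.50, swcon: 0.50, kl: 0.08}
  - {top_cm: 15,  bottom_cm: 30,  ll: 0.12, dul: 0.32, sat: 0.39, bd: 1.71, swcon: 0.30, kl: 0.06}
  - {top_cm: 30,  bottom_cm: 60,  ll: 0.11, dul: 0.33, sat: 0.38, bd: 1.46, swcon: 0.40, kl: 0.04}
  - {top_cm: 60,  bottom_cm: 90,  ll: 0.09, dul: 0.31, sat: 0.41, bd: 1.48, swcon: 0.50, kl: 0.02}
  - {top_cm: 90,  bottom_cm: 120, ll: 0.07, dul: 0.24, sat: 0.40, bd: 1.33, swcon: 0.50, kl: 0.01}
  - {top_cm: 120, bottom_cm: 150, ll: 0.05, dul: 0.20, sat: 0.38, bd: 1.39, swcon: 0.50, kl: 0.01}
  - {top_cm: 150, bottom_cm: 180, ll: 0.05, dul: 0.20, sat: 0.38, bd: 1.42, swcon: 0.50, kl: 0.00}
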