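# Monthly climate normals for Ludhiana, Punjab (30.9 N), wheat season
# 1970-2010: mean daily Tmax/Tmin (degC), mean daily solar radiation
# (MJ m-2 d-1), mean monthly rainfall total with observed range (mm).
# November-April are station normals; October and May are gradient
# extrapolations from the adjacent months, and June-September (monsoon,
# outside the wheat season and never used by the simulations) are
# climatological placeholders so whole calendar years can be generated.
# `observed: false` flags the assumed months.
latitude: 30.9
months:
  1:  {tmax: 17.6, tmin: 10.8, radn: 5.4,  rain_mean: 28.4,  rain_min: 0.0, rain_max: 83.0,  observed: true}
  2:  {tmax: 18.8, tmin: 12.5, radn: 6.8,  rain_mean: 32.4,  rain_min: 0.0, rain_max: 108.0, observed: true}
  3:  {tmax: 27.3, tmin: 18.1, radn: 12.0, rain_mean: 22.6,  rain_min: 0.0, rain_max: 80.0,  observed: true}
  4:  {tmax: 32.3, tmin: 21.4, radn: 16.4, rain_mean: 16.5,  rain_min: 0.0, rain_max: 122.0, observed: true}
  5:  {tmax: 37.3, tmin: 24.7, radn: 20.8, rain_mean: 15.0,  rain_min: 0.0, rain_max: 120.0, observed: false}
  6:  {tmax: 39.0, tmin: 26.5, radn: 20.0, rain_mean: 60.0,  rain_min: 0.0, rain_max: 300.0, observed: false}
  7:  {tmax: 34.5, tmin: 26.5, radn: 17.0, rain_mean: 200.0, rain_min: 5.0, rain_max: 500.0, observed: false}
  8:  {tmax: 33.5, tmin: 25.8, radn: 16.5, rain_mean: 190.0, rain_min: 5.0, rain_max: 500.0, observed: false}
  9:  {tmax: 33.5, tmin: 23.5, radn: 16.5, rain_mean: 120.0, rain_min: 0.0, rain_max: 450.0, observed: false}
  10: {tmax: 33.2, tmin: 16.4, radn: 14.8, rain_mean: 10.0,  rain_min: 0.0, rain_max: 100.0, observed: false}
  11: {tmax: 26.6, tmin: 13.4, radn: 10.5, rain_mean: 7.3,   rain_min: 0.0, rain_max: 85.0,  observed: true}
  12: {tmax: 20.0, tmin: 10.4, radn: 6.2,  rain_mean: 16.5,  rain_min: 0.0, rain_max: 112.0, observed: true}
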