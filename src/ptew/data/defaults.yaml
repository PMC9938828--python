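# Default configuration: regulatory standards, toxicological constants,
# receptor exposure profiles, and the study design (seasonal concentration
# moments of the 2021 Shiraz tap-water survey) used by the synthetic
# generator and the mean-based index/risk reports.
version: 1

metals:
  Pb:
    standards: {EPA: 15.0, WHO: 10.0}   # permissible S_i, ug/L
    ideal: 0.0                          # I_i, ug/L
    tdi: 0.0035                         # mg/kg/day (Pb uses TDI, not RfD)
    sf: 0.0085                          # carcinogenic slope factor, (mg/kg/day)^-1
  Hg:
    standards: {EPA: 2.0, WHO: 6.0}
    ideal: 0.0
    rfd: 0.0003
  Mn:
    standards: {EPA: 50.0, WHO: 400.0}
    ideal: 100.0
    rfd: 0.14
  Fe:
    standards: {EPA: 300.0, WHO: 300.0}
    ideal: 0.0
    rfd: 0.7

profiles:
  children:
    ir: 1.25            # water intake, L/day
    ef: {min: 180, mode: 345, max: 365}   # exposure frequency, days/year
    ed: 6.0             # exposure duration, years
    bw: 10.64           # body weight, kg
    f: 1000.0           # ug -> mg conversion
    lifetime_years: 70.0
  adults:
    ir: 1.95
    ef: {min: 180, mode: 345, max: 365}
    ed: 50.0
    bw: 61.68
    f: 1000.0
    lifetime_years: 70.0

study:
  n_per_season: 45
  # seasonal arithmetic mean/sd and observed range, ug/L
  concentrations:
    Pb:
      winter: {mean: 0.36, sd: 0.08, low: 0.22, high: 0.60}
      summer: {mean: 0.50, sd: 0.62, low: 0.11, high: 3.80}
    Hg:
      winter: {mean: 0.32, sd: 0.12, low: 0.17, high: 0.60}
      summer: {mean: 0.20, sd: 0.11, low: 0.10, high: 0.60}
    Mn:
      winter: {mean: 2.28, sd: 3.91, low: 0.28, high: 16.23}
      summer: {mean: 0.55, sd: 0.57, low: 0.19, high: 3.68}
    Fe:
      winter: {mean: 8.72, sd: 6.35, low: 3.69, high: 32.53}
      summer: {mean: 10.36, sd: 3.04, low: 6.86, high: 26.64}

mcs:
  # Coefficients of variation assumed for intake rate (normal, truncated at 0)
  # and body weight (lognormal); the source survey states only the
  # distribution families, not spreads. Override to match other populations.
  ir_cv: 0.20
  bw_cv: 0.20
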