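# Climatic suitability thresholds for greenhouse tomato, by phenological
# stage and time of day, together with the phenology calendar.
#
# Each (stage, period, variable) cell gives the optimal interval (closed)
# and the two critical cuts: values strictly below `critical_below` or
# strictly above `critical_above` are critical; everything between the
# critical cuts that is not optimal is suboptimal.  Units: T in degC,
# RH in %, VPD in kPa (classified on absolute value).

phenology:
  transplant_date: 2024-03-14
  stages:
    - {name: vegetative,   start_dat: 0,   end_dat: 50,  duration_days: 50}
    - {name: reproductive, start_dat: 51,  end_dat: 109, duration_days: 59}
    - {name: harvest,      start_dat: 110, end_dat: 190, duration_days: 81}

thresholds:
  vegetative:
    day:
      T:   {optimal: [20.0, 28.0], critical_below: 18.0, critical_above: 34.0}
      RH:  {optimal: [55.0, 75.0], critical_below: 50.0, critical_above: 85.0}
      VPD: {optimal: [0.5, 1.1],   critical_below: 0.4,  critical_above: 2.0}
    night:
      T:   {optimal: [15.0, 19.0], critical_below: 12.0, critical_above: 20.0}
      RH:  {optimal: [50.0, 75.0], critical_below: 45.0, critical_above: 80.0}
      VPD: {optimal: [0.5, 0.9],   critical_below: 0.3,  critical_above: 1.5}
  reproductive:
    day:
      T:   {optimal: [19.0, 26.0], critical_below: 17.0, critical_above: 34.0}
      RH:  {optimal: [50.0, 80.0], critical_below: 45.0, critical_above: 89.0}
      VPD: {optimal: [0.5, 1.2],   critical_below: 0.4,  critical_above: 2.0}
    night:
      T:   {optimal: [15.0, 19.0], critical_below: 13.0, critical_above: 20.0}
      RH:  {optimal: [50.0, 75.0], critical_below: 45.0, critical_above: 85.0}
      VPD: {optimal: [0.5, 0.9],   critical_below: 0.3,  critical_above: 1.5}
  harvest:
    day:
      T:   {optimal: [19.0, 24.0], critical_below: 17.0, critical_above: 34.0}
      RH:  {optimal: [50.0, 80.0], critical_below: 45.0, critical_above: 89.0}
      VPD: {optimal: [0.5, 1.2],   critical_below: 0.4,  critical_above: 2.0}
    night:
      T:   {optimal: [15.0, 19.0], critical_below: 13.0, critical_above: 20.0}
      RH:  {optimal: [50.0, 75.0], critical_below: 45.0, critical_above: 85.0}
      VPD: {optimal: [0.5, 0.9],   critical_below: 0.3,  critical_above: 1.5}
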