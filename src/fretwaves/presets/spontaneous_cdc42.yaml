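# Spontaneous scenario: interior activity waves with a 110 s period, plus
# 24 edge sections (10 stalling, 7 protruding at the 1.061 hotspot level,
# 7 retracting at the 0.938 non-protruding level) moving for the first 240 s.
scenario:
  height: 176
  width: 176
  pixel_size: 0.5
  frame_interval: 1.0
  n_frames: 1250
  seed: 13
  cell:
    center: [44.0, 44.0]
    radius: 36.0
    n_sections: 24
  schedule:
    - {section: 10, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 11, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 12, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 13, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 14, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 15, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 16, velocity: 0.015, start: 0.0, stop: 240.0}
    - {section: 17, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 18, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 19, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 20, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 21, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 22, velocity: -0.015, start: 0.0, stop: 240.0}
    - {section: 23, velocity: -0.015, start: 0.0, stop: 240.0}
  activity:
    baseline: 1.0
    edge_bands:
      depth: 24.0
      levels:
        10: 1.061
        11: 1.061
        12: 1.061
        13: 1.061
        14: 1.061
        15: 1.061
        16: 1.061
        17: 0.938
        18: 0.938
        19: 0.938
        20: 0.938
        21: 0.938
        22: 0.938
        23: 0.938
    wave:
      period: 110.0
      wavelength: 5.0
      amplitude: 0.2
      direction: [-1.0, 0.0]
      start_time: 0.0
      region_radius: 12.0
  nuisance:
    shading_strength: 0.1
    background_donor: 100.0
    background_acceptor: 100.0
    alpha: 0.35
    beta: 0.0
    bleach_donor: 0.0002
    bleach_acceptor: 0.0002
    gain: 0.5
    read_noise: 2.0
    donor_brightness: 2000.0
    calibration: 1.0
correction:
  background: auto
  photobleach: auto
  epsilon: 0.05
  flatfield: true
  bleedthrough: controls
analysis:
  wave_roi: {center: [48.0, 44.0], area: 4.0}
  period_intervals: 10
  smoothing_s: 5.0
  prominence_sd: 0.5
  m: 1
  v0: 0.005
  section_window_s: 240.0
tolerances:
  period_tol_s: 10.0
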