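# Spontaneous scenario: 24 edge sections (10 stalling, 7 protruding at the
# 0.831 low-activity level, 7 retracting at the 1.109 elevated level).
scenario:
  height: 176
  width: 176
  pixel_size: 0.5
  frame_interval: 1.0
  n_frames: 240
  seed: 17
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
        10: 0.831
        11: 0.831
        12: 0.831
        13: 0.831
        14: 0.831
        15: 0.831
        16: 0.831
        17: 1.109
        18: 1.109
        19: 1.109
        20: 1.109
        21: 1.109
        22: 1.109
        23: 1.109
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
  m: 1
  v0: 0.005
tolerances: {}
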