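# Bead-stimulation scenario: retrograde activity waves with a 70 s period
# plus a slow retraction of the edge section facing the bead.
scenario:
  height: 72
  width: 72
  pixel_size: 0.4
  frame_interval: 1.0
  n_frames: 800
  seed: 11
  cell:
    center: [14.4, 14.4]
    radius: 11.0
    n_sections: 8
  schedule:
    - {section: 4, velocity: -0.008, start: 120.0, stop: 700.0}
  activity:
    baseline: 1.0
    wave:
      period: 70.0
      wavelength: 5.0
      amplitude: 0.2
      direction: [-1.0, 0.0]
      start_time: 0.0
  nuisance: &nuisance
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
  wave_roi: {center: [17.4, 14.4], area: 4.0}
  period_intervals: 10
  smoothing_s: 5.0
  prominence_sd: 0.5
  m: 1
  v0: 0.005
tolerances:
  period_tol_s: 5.0
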