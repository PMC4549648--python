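# Local-stimulation scenario: a central activity ramp starting 8 s after
# vesicle delivery at t = 60 s, followed by edge retraction from t = 170 s.
scenario:
  height: 72
  width: 72
  pixel_size: 0.4
  frame_interval: 1.0
  n_frames: 300
  seed: 19
  cell:
    center: [14.4, 14.4]
    radius: 11.0
    n_sections: 8
  schedule:
    - {section: 4, velocity: -0.03, start: 170.0, stop: 290.0}
  activity:
    baseline: 1.0
  stimulus:
    time: 60.0
    position: [14.4, 14.4]
    region_radius: 5.0
    delay: 8.0
    rate: 0.004
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
  onset_roi: {center: [14.4, 14.4], area: 4.0}
  stimulus_time: 60.0
  onset_k: 3.0
  onset_sustain_s: 5.0
  m: 1
  v0: 0.005
tolerances:
  onset_max_s: 30.0
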