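geometry:
  # 9-view, 25-degree limited-angle scan in 3.125-degree increments
  angles: [-12.5, -9.375, -6.25, -3.125, 0.0, 3.125, 6.25, 9.375, 12.5]
  source_to_isocenter: 617.0   # mm
  isocenter_to_support: 20.0   # mm
  support_to_detector: 23.0    # mm
  detector_shape: [64, 64]     # pixels; enlarge to cover the imaged volume
  detector_pitch: 0.1          # mm/pixel
noise:
  sigma_q: 0.05                # post-log quantum noise std at unit exposure
  sigma_r: 0.01                # readout noise std
  exposure_factor: 1.0
  blur_taps:                   # 2-pixel-FWHM Gaussian taps (renormalized
    [[0.00086505, 0.00692042, 0.01384083, 0.00692042, 0.00086505],
     [0.00692042, 0.05536332, 0.11072664, 0.05536332, 0.00692042],  # on
     [0.01384083, 0.11072664, 0.22145329, 0.11072664, 0.01384083],  # load)
     [0.00692042, 0.05536332, 0.11072664, 0.05536332, 0.00692042],
     [0.00086505, 0.00692042, 0.01384083, 0.00692042, 0.00086505]]
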