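# Electrical tissue properties and calibrated pulse protocols.
#
# All numbers here are editable literature-derived defaults (baseline and
# post-permeabilization conductivities, sigmoid transition interval of the
# field-dependent conductivity, and per-protocol reversible/irreversible
# field thresholds in V/cm). They are configuration, not results.
tissues:
  background: {sigma0: 0.20, sigma_max: 0.40, e_low: 400.0, e_high: 800.0}
  liver:      {sigma0: 0.10, sigma_max: 0.35, e_low: 400.0, e_high: 800.0}
  vessel:     {sigma0: 0.70, sigma_max: 0.70, e_low: 400.0, e_high: 800.0}
  tumor:      {sigma0: 0.20, sigma_max: 0.70, e_low: 400.0, e_high: 800.0}
  bone:       {sigma0: 0.02, sigma_max: 0.02, e_low: 400.0, e_high: 800.0}
  brain:      {sigma0: 0.10, sigma_max: 0.30, e_low: 400.0, e_high: 800.0}

protocols:
  - mode: ECT
    pulse_count: 8
    pulse_duration_us: 100.0
    frequency_hz: 1.0
    thresholds:   # tissue: [reversible, irreversible] V/cm
      default: [400.0, 800.0]
      tumor:   [400.0, 800.0]
      liver:   [400.0, 800.0]
  - mode: IRE
    pulse_count: 90
    pulse_duration_us: 100.0
    frequency_hz: 1.0
    thresholds:
      default: [300.0, 600.0]
      tumor:   [300.0, 600.0]
      liver:   [300.0, 600.0]
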