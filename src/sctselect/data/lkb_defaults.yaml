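# Default Lyman-Kutcher-Burman parameters per toxicity endpoint.
#
# These are the classical Emami/Burman probit fits (TD50 in Gy for uniform
# whole-organ irradiation, m the probit slope, n the volume-effect exponent).
# They are defaults: override with an institution-specific file via
# `load_lkb_params(path)` or the --params CLI option.
heart_pericarditis:
  TD50_gy: 48.0
  m: 0.10
  n: 0.35
  source: "Burman et al. 1991 probit fit to Emami tolerance data (heart, pericarditis)"
lung_pneumonitis:
  TD50_gy: 24.5
  m: 0.18
  n: 0.87
  source: "Burman et al. 1991 probit fit to Emami tolerance data (lung, pneumonitis)"
esophagus_perforation:
  TD50_gy: 68.0
  m: 0.11
  n: 0.06
  source: "Burman et al. 1991 probit fit to Emami tolerance data (esophagus, perforation)"
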