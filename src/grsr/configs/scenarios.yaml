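# Thermal-guild scenario presets: OGT of both cell populations and the
# environmental temperature each guild is simulated at.
thermophile:
  T_plus: 45.0
  T_minus: 45.0
  T_env: 37.0
mesophile:
  T_plus: 30.0
  T_minus: 30.0
  T_env: 30.0
psychrophile:
  T_plus: 20.0
  T_minus: 20.0
  T_env: 4.0
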