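# CTAS guideline targets for time to physician assessment, in minutes.
# Level I ("immediate") is operationalised as < 3 minutes.
targets:
  ctas_1: 3
  ctas_2: 15
  ctas_3: 30
  ctas_4: 60
  ctas_5: 120
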