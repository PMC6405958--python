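{
  "model1b": {
    "remove": ["attachment", "omad2_decay"],
    "note": "short-timescale (pro-metaphase) variant: no kinetochore attachment, no O-Mad2 decay"
  },
  "model2b": {
    "remove": ["attachment"],
    "note": "short-timescale (pro-metaphase) variant: no kinetochore attachment"
  },
  "model3b": {
    "remove": ["attachment"],
    "note": "short-timescale (pro-metaphase) variant: no kinetochore attachment"
  }
}
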