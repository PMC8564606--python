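# Canonical capture-table schema. Version this file together with the
# simulator and readers so that the two can never drift apart.
version: 1
columns:
  tag:          {type: str,   required: true}
  plot:         {type: str,   required: true}
  year:         {type: int,   required: true, min: 1900, max: 2100}
  week:         {type: int,   required: true, min: 1, max: 52}
  day:          {type: int,   required: true, min: 1, max: 3}
  x:            {type: float, required: true, min: 0.0}
  y:            {type: float, required: true, min: 0.0}
  sex:          {type: str,   required: false, domain: [F, M, U]}
  age:          {type: str,   required: false, domain: [juvenile, subadult, adult, U]}
  mass_g:       {type: float, required: false, min: 0.0}
  ticks:        {type: int,   required: false, min: 0}
  botflies:     {type: int,   required: false, min: 0}
  impair_codes: {type: str,   required: false}   # semicolon-joined vocabulary codes
  tail_snip:    {type: bool,  required: false}
impairment_vocabulary:
  tail: [tail_missing, tail_partial, tail_broken]
  limb: [limb_missing, limb_partial, limb_broken]
  eye:  [eye_missing, cataract]
default_dialect:
  # identity header mapping; user dialects map arbitrary headers onto these
  tag: tag
  plot: plot
  year: year
  week: week
  day: day
  x: x
  y: y
  sex: sex
  age: age
  mass_g: mass_g
  ticks: ticks
  botflies: botflies
  impair_codes: impair_codes
  tail_snip: tail_snip
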