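# Context-tissue color synonym table.
# Ridgway-style color names mapped to the three broad context-color classes:
# white; pinkish-buff to cinnamon-buff (light brown); cinnamon brown (dark
# brown).  Matching is case-insensitive with hyphens treated as spaces.
# Unmapped terms raise UnknownColorTerm — extend this file rather than
# guessing in code.
white:
  - white
  - white to light buff
  - pure white
buff:
  - buff
  - light buff
  - cream
  - cream to light buff
  - pink buff
  - pinkish buff
  - cinnamon buff
  - pink buff to cinnamon buff
  - pinkish buff to cinnamon buff
  - light brown
dark_brown:
  - cinnamon brown
  - dark cinnamon brown
  - dark brown
  - cinnamon brown to black
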