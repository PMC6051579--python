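# Reference character profiles for the 13 laccate Ganodermataceae taxa of the
# United States: modal states of the characters consulted by the
# identification key (context color class, contextual features,
# chlamydospores, stipe habit, pores/mm, host group, geography, in-vitro
# growth-rate class, and basidiospore means in µm).
"G. curtisii":
  context_color: buff
  melanoid_deposits: present
  concentric_zones: absent
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: stipitate
  pores_per_mm: [5, 8]
  host_group: hardwood
  region: eastern_US
  growth_rate_class: fast
  spore_length_mean: 10.6
  spore_width_mean: 6.4
"G. curtisii f.sp. meredithiae":
  context_color: buff
  melanoid_deposits: present
  concentric_zones: absent
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: stipitate
  pores_per_mm: [5, 8]
  host_group: conifer
  region: eastern_US
  growth_rate_class: slow
  spore_length_mean: 10.8
  spore_width_mean: 6.8
"G. lucidum":
  context_color: buff
  melanoid_deposits: absent
  concentric_zones: present
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: stipitate
  pores_per_mm: [4, 5]
  host_group: hardwood
  region: restricted_UT_CA
  spore_length_mean: 10.7
  spore_width_mean: 7.1
"G. martinicense":
  context_color: dark_brown
  melanoid_deposits: present
  concentric_zones: present
  contextual_chlamydospores: absent
  culture_chlamydospores: present
  stipe_class: pseudostipitate
  pores_per_mm: [5, 6]
  host_group: hardwood
  region: eastern_US
  spore_length_mean: 11.1
  spore_width_mean: 6.9
"G. oregonense":
  context_color: white
  melanoid_deposits: absent
  concentric_zones: absent
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: sessile
  pores_per_mm: [3, 4]
  host_group: conifer
  region: pacific_northwest
  spore_length_mean: 12.9
  spore_width_mean: 8.0
"G. polychromum":
  context_color: buff
  melanoid_deposits: absent
  concentric_zones: present
  contextual_chlamydospores: present
  culture_chlamydospores: present
  stipe_class: sessile
  pores_per_mm: [4, 5]
  host_group: hardwood
  region: western_US
  spore_length_mean: 12.2
  spore_width_mean: 6.8
"G. ravenelii":
  context_color: buff
  melanoid_deposits: absent
  concentric_zones: absent
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: stipitate
  pores_per_mm: [6, 7]
  host_group: hardwood
  region: eastern_US
  spore_length_mean: 11.2
  spore_width_mean: 5.2
"G. sessile":
  context_color: buff
  melanoid_deposits: absent
  concentric_zones: present
  contextual_chlamydospores: absent
  culture_chlamydospores: present
  stipe_class: sessile
  pores_per_mm: [5, 7]
  host_group: hardwood
  region: eastern_US
  spore_length_mean: 11.4
  spore_width_mean: 6.6
"G. tsugae":
  context_color: white
  melanoid_deposits: absent
  concentric_zones: absent
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: sessile
  pores_per_mm: [5, 7]
  host_group: conifer
  region: eastern_US
  spore_length_mean: 9.9
  spore_width_mean: 6.5
"G. tuberculosum":
  context_color: dark_brown
  melanoid_deposits: present
  concentric_zones: present
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: sessile
  pores_per_mm: [4, 7]
  host_group: hardwood
  region: subtropical
  spore_length_mean: 10.5
  spore_width_mean: 7.3
"G. cf. weberianum":
  context_color: buff
  melanoid_deposits: absent
  concentric_zones: present
  contextual_chlamydospores: present
  culture_chlamydospores: present
  stipe_class: sessile
  pores_per_mm: [5, 7]
  host_group: hardwood
  region: subtropical
  spore_length_mean: 8.4
  spore_width_mean: 5.6
"G. zonatum":
  context_color: dark_brown
  melanoid_deposits: absent
  concentric_zones: present
  contextual_chlamydospores: absent
  culture_chlamydospores: absent
  stipe_class: sessile
  pores_per_mm: [4, 6]
  host_group: monocot
  region: eastern_US
  spore_length_mean: 11.8
  spore_width_mean: 5.9
"T. colossus":
  context_color: white
  melanoid_deposits: absent
  concentric_zones: absent
  contextual_chlamydospores: present
  culture_chlamydospores: present
  stipe_class: sessile
  pores_per_mm: [3, 4]
  host_group: cycad
  region: subtropical
  spore_length_mean: 16.1
  spore_width_mean: 10.4
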