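# Dichotomous key to the laccate Ganoderma species (and Tomophagus colossus)
# of the United States, encoded as data: 12 numbered couplets, two leads each.
# A lead either forwards to another couplet (goto) or terminates at a species.
# Predicates are conjunctions of atomic tests over CharacterProfile fields;
# ops: eq, neq, in, not_in, lt, range (closed endpoints).  Spore-size atoms
# use the printed per-taxon (min–max) ranges in µm.
couplets:
  1:
    a:
      text: Context tissue white when fresh
      predicates:
        - {character: context_color, op: eq, value: white}
      goto: 2
    b:
      text: Context tissue not as above
      predicates:
        - {character: context_color, op: in, value: [buff, dark_brown]}
      goto: 4
  2:
    a:
      text: Large basidiospores, ~16.1 (14.6–17.3) x 10.4 (9.5–11.3) µm; fruiting body spongy, light, shiny yellow
      predicates:
        - {character: spore_length_mean, op: range, value: [14.6, 17.3]}
        - {character: spore_width_mean, op: range, value: [9.5, 11.3]}
      species: T. colossus
    b:
      text: Basidiospores smaller than above
      predicates:
        - {character: spore_length_mean, op: lt, value: 14.6}
      goto: 3
  3:
    a:
      text: On conifers in the Pacific Northwest; basidiospores ~12.9 (11.6–14.9) x 8.0 (6.7–9.3) µm
      predicates:
        - {character: host_group, op: eq, value: conifer}
        - {character: region, op: eq, value: pacific_northwest}
        - {character: spore_length_mean, op: range, value: [11.6, 14.9]}
        - {character: spore_width_mean, op: range, value: [6.7, 9.3]}
      species: G. oregonense
    b:
      text: On conifers (predominately Tsuga canadensis) in the eastern U.S.; basidiospores ~9.9 (8.9–11.5) x 6.5 (5.2–7.7) µm
      predicates:
        - {character: host_group, op: eq, value: conifer}
        - {character: region, op: eq, value: eastern_US}
        - {character: spore_length_mean, op: range, value: [8.9, 11.5]}
        - {character: spore_width_mean, op: range, value: [5.2, 7.7]}
      species: G. tsugae
  4:
    a:
      text: Context tissue cream to buff
      predicates:
        - {character: context_color, op: eq, value: buff}
      goto: 5
    b:
      text: Context tissue dark brown (cinnamon brown)
      predicates:
        - {character: context_color, op: eq, value: dark_brown}
      goto: 11
  5:
    a:
      text: Shiny melanoid deposits present in the context tissue
      predicates:
        - {character: melanoid_deposits, op: eq, value: present}
      goto: 6
    b:
      text: Melanoid bands absent; concentric growth zones sometimes present
      predicates:
        - {character: melanoid_deposits, op: eq, value: absent}
      goto: 7
  6:
    a:
      text: Growing somewhat rapidly (~6 mm/day) on malt extract agar; laterally stipitate, on hardwoods in the eastern U.S.
      predicates:
        - {character: growth_rate_class, op: eq, value: fast}
      species: G. curtisii
    b:
      text: Growing slowly (<3 mm/day) as a dikaryotic isolate; laterally stipitate, on pines in the southeastern U.S.
      predicates:
        - {character: growth_rate_class, op: eq, value: slow}
      species: G. curtisii f.sp. meredithiae
  7:
    a:
      text: Typically sessile, or stipe shorter than the pileus width (pseudostipitate)
      predicates:
        - {character: stipe_class, op: in, value: [sessile, pseudostipitate]}
      goto: 8
    b:
      text: Typically laterally stipitate; no melanoid bands; concentric zones sometimes present
      predicates:
        - {character: stipe_class, op: eq, value: stipitate}
      goto: 10
  8:
    a:
      text: In association with hardwoods in the western United States, often with conspicuous concentric growth zones
      predicates:
        - {character: region, op: eq, value: western_US}
      species: G. polychromum
    b:
      text: Found in the eastern United States
      predicates:
        - {character: region, op: in, value: [eastern_US, subtropical]}
      goto: 9
  9:
    a:
      text: Pigmented double-walled globose-to-ovoid chlamydospores in the context tissue; restricted to tropical locations
      predicates:
        - {character: contextual_chlamydospores, op: eq, value: present}
        - {character: region, op: eq, value: subtropical}
      species: G. cf. weberianum
    b:
      text: Widely distributed east of the Rocky Mountains, predominately on hardwoods; basidiospores ~11.4 (9.7–14.0) x 6.6 (5.2–8.4) µm
      predicates:
        - {character: contextual_chlamydospores, op: eq, value: absent}
      species: G. sessile
  10:
    a:
      text: Concentric growth zones absent; southeastern U.S.; basidiospores ~11.2 (9.1–13.6) x 5.2 (4.2–6.8) µm
      predicates:
        - {character: concentric_zones, op: eq, value: absent}
      species: G. ravenelii
    b:
      text: Concentric growth zones present; restricted to isolated populations in northern Utah and northern California
      predicates:
        - {character: concentric_zones, op: eq, value: present}
        - {character: region, op: in, value: [restricted_UT_CA, western_US]}
      species: G. lucidum
  11:
    a:
      text: Basidiospores elongated, ~11.8 (10.3–13.7) x 5.9 (5.0–6.6) µm; on monocots, typically palms
      predicates:
        - {character: host_group, op: eq, value: monocot}
        - {character: spore_length_mean, op: range, value: [10.3, 13.7]}
      species: G. zonatum
    b:
      text: Not as above
      predicates:
        - {character: host_group, op: not_in, value: [monocot]}
      goto: 12
  12:
    a:
      text: Central dark red-to-black pseudostipe; on hardwoods; concentric zones and melanoid deposits in the context; 5–6 pores/mm
      predicates:
        - {character: stipe_class, op: eq, value: pseudostipitate}
      species: G. martinicense
    b:
      text: Sessile; concentric zones and shiny resinous deposits in the context; 4–7 pores/mm; restricted to tropical locations; basidiospores ~10.5 (9.2–12.0) x 7.3 (6.2–8.6) µm
      predicates:
        - {character: stipe_class, op: eq, value: sessile}
      species: G. tuberculosum
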