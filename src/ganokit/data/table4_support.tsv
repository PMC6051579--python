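taxon	ITS	tef1a	rpb1	rpb2	concatenated
G. curtisii	89	100	100	100	85
G. curtisii f.sp. meredithiae	NR	NR	NR	NR	NR
G. lucidum	NR	98	91	86	89
G. martinicense	93	R*	100	100	99
G. oregonense	NR	98	78	NR	83
G. polychromum	97	90	R*	NT	99
G. ravenelii	85	100	100	NR*	100
G. sessile	48	100	57	100	87
G. tsugae	NR	93	100	81	99
G. tuberculosum	100	R*	87	NR*	100
G. cf. weberianum	97	100	100	NT	100
G. zonatum	100	91	99	97	100
T. colossus	100	100	100	NT	100
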