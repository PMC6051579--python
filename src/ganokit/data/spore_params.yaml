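# Per-taxon basidiospore dimensions in µm: published mean and (min–max)
# range for length and width.  The synthetic generator draws truncated
# normals on [min, max] with sd defaulting to (max−min)/4, which keeps ~95%
# of the untruncated mass inside the range.
"G. curtisii":                  {length: [10.6, 8.3, 12.1], width: [6.4, 5.4, 7.5]}
"G. curtisii f.sp. meredithiae": {length: [10.8, 9.5, 11.5], width: [6.8, 6.4, 7.3]}
"G. lucidum":                   {length: [10.7, 8.2, 12.1], width: [7.1, 4.8, 8.9]}
"G. martinicense":              {length: [11.1, 9.0, 13.6], width: [6.9, 5.3, 8.3]}
"G. oregonense":                {length: [12.9, 11.6, 14.9], width: [8.0, 6.7, 9.3]}
"G. polychromum":               {length: [12.2, 10.8, 13.2], width: [6.8, 6.0, 7.4]}
"G. ravenelii":                 {length: [11.2, 9.1, 13.6], width: [5.2, 4.2, 6.8]}
"G. sessile":                   {length: [11.4, 9.7, 14.0], width: [6.6, 5.2, 8.4]}
"G. tsugae":                    {length: [9.9, 8.9, 11.5], width: [6.5, 5.2, 7.7]}
"G. tuberculosum":              {length: [10.5, 9.2, 12.0], width: [7.3, 6.2, 8.6]}
"G. cf. weberianum":            {length: [8.4, 7.7, 9.5], width: [5.6, 4.7, 7.3]}
"G. zonatum":                   {length: [11.8, 10.3, 13.7], width: [5.9, 5.0, 6.6]}
"T. colossus":                  {length: [16.1, 14.6, 17.3], width: [10.4, 9.5, 11.3]}
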