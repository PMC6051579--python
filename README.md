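# ganokit

Tools for identifying the laccate (varnished-cap) *Ganoderma* species of the
United States and for evaluating candidate DNA-barcode loci by how well they
resolve those species as supported clades.

For most of the last century nearly every shiny *Ganoderma* on a North
American hardwood was filed under the European name *G. lucidum*. Multilocus
molecular surveys instead recognize thirteen laccate taxa in the U.S.
Ganodermataceae — *G. curtisii*, *G. curtisii* f.sp. *meredithiae*,
*G. lucidum* sensu stricto, *G. martinicense*, *G. oregonense*,
*G. polychromum*, *G. ravenelii*, *G. sessile*, *G. tsugae*,
*G. tuberculosum*, *G. cf. weberianum*, *G. zonatum* and *Tomophagus
colossus* — distinguishable by context-tissue color, melanoid deposits,
chlamydospores, stipe habit, basidiospore morphometrics, host group and
geography. `ganokit` packages that identification workflow and the
companion molecular analysis for mycologists, plant pathologists and
arborists who need reproducible species calls.

## What it computes

* **Dichotomous key engine** (`ganokit.key`) — the 12-couplet key to the 13
  taxa, shipped as data and executed with three-valued logic: a missing
  character sends the traversal down both leads, so an identification is a
  *set* of candidates that can only grow as information is lost.
* **Spore morphometrics** (`ganokit.spores`) — per spore, the shape index
  SSI = 100·(width/length) and elongation Q = length/width (so SSI·Q = 100
  exactly), summarized per taxon as "mean (min–max)" in µm.
* **Desk-scale phylogenetics** (`ganokit.phylo`) — alignment I/O,
  '?'-padded supermatrix concatenation with a partition table, p/JC69/K2P
  distances under pairwise deletion, Saitou–Nei neighbor joining with
  deterministic tie-breaking, nonparametric bootstrap support, outgroup
  rooting and a bipartition-level congruence check.
* **Barcode-locus scoring** (`ganokit.scoring`) — for each species and each
  single-locus tree, terminal-clade status (supported / below threshold /
  resolved-unscored / not resolved / not tested at a bootstrap floor of
  75%); per locus, the **number of terminal clades** and the **total
  score** (summed bootstrap of well-supported clades); loci ranked on that
  pair.
* **Synthetic data** (`ganokit.synthetic`) — species trees with planted
  clades and a two-tip outgroup, Jukes–Cantor sequence evolution on the
  survey's locus dimensions (ITS 521, tef1α 764, rpb1 615, rpb2 570
  columns; 2470 concatenated), truncated-normal spore tables and noisy
  character profiles — so every pipeline stage can be validated by
  parameter recovery.

## Worked example

Score the published per-taxon support columns (shipped with the package)
under the 75% floor:

```python
>>> from ganokit.scoring import load_printed_support_table, score_locus
>>> table = load_printed_support_table()
>>> for locus, records in table.items():
...     s = score_locus(records, locus)
...     print(locus, s.n_terminal_clades, s.total_score)
ITS 8 761.0
tef1a 12 970.0
rpb1 11 955.0
rpb2 8 564.0
concatenated 12 1141.0
```

ITS, the default fungal barcode, resolves only 8 of 13 taxa (total 761);
tef1α resolves 12 (970) and rpb1 11 (955), so the protein-coding loci are
the better barcodes for this group, and the four-locus concatenation is
best of all (12 clades, 1141). Note the 48% ITS clade for *G. sessile*
counts toward neither number: it is monophyletic but below the floor.

Identify a specimen from a character profile (dark context tissue, on a
palm, elongated spores):

```console
$ ganokit identify profile.yaml
candidates: G. zonatum
trace: 1b -> 4b -> 11a
```

The trace reads: context not white (couplet 1, lead b) → dark brown
(4b) → monocot host with spores in the 10.3–13.7 µm window (11a), which is
diagnostic for *G. zonatum*. A full synthetic pipeline —
simulate → concatenate → bootstrap trees → score table — runs with
`ganokit run --seed 11 --outdir run1/`.

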