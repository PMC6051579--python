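"""Synthetic data with planted species structure.

Generates everything the analysis pipeline consumes, with known truth:

* a species tree with each species expanded into a shallow clade of tips
  (deep between-species divergence, shallow within-species divergence) and a
  designated two-tip outgroup species, mirroring a survey design where two
  outgroup isolates root the tree;
* per-locus alignments evolved along that tree under Jukes–Cantor
  substitution, with the default locus set (ITS 521, tef1a 764, rpb1 615,
  rpb2 570 columns) matching the survey's alignment dimensions;
* per-taxon spore measurement tables (truncated normals on the published
  ranges);
* character profiles derived from the reference profiles with characters
  masked to missing at a configurable noise rate.

All randomness flows from one integer seed through named substreams (tree,
sequences, spores, profiles), so each component regenerates independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import yaml
from scipy.stats import truncnorm

from .morpho import SPECIES, CharacterProfile, load_reference_profiles
from .phylo import Alignment, SupportTree, write_alignment
from .scoring import TaxonMap, write_taxon_map_tsv
from .spores import SporeMeasurement, write_spores_tsv

__all__ = [
    "DEFAULT_LOCI",
    "SimulationConfig",
    "PlantedTruth",
    "load_spore_params",
    "simulate_species_tree",
    "evolve_alignment",
    "simulate_alignments",
    "simulate_spores",
    "generate_profiles",
    "simulate_all",
]

DEFAULT_LOCI: tuple[tuple[str, int], ...] = (
    ("ITS", 521), ("tef1a", 764), ("rpb1", 615), ("rpb2", 570),
)

_STREAMS = {"tree": 0, "sequences": 1, "spores": 2, "profiles": 3}


def _rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream], index)))


def load_spore_params() -> dict[str, dict[str, tuple[float, float, float]]]:
    """Published per-taxon spore dimension parameters (mean, min, max) in µm."""
    text = resources.files("ganokit.data").joinpath("spore_params.yaml").read_text("utf-8")
    raw = yaml.safe_load(text)
    return {sp: {axis: tuple(v) for axis, v in axes.items()} for sp, axes in raw.items()}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 13 species, 1–8 representatives each, four loci
    totalling 2470 columns, deep between-species and shallow within-species
    divergence in expected substitutions/site."""

    seed: int
    n_species: int = 13
    tips_per_species: tuple[int, int] = (1, 8)
    loci: tuple[tuple[str, int], ...] = DEFAULT_LOCI
    between_species_depth: float = 0.15
    within_species_depth: float = 0.005

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("need at least 3 species")
        lo, hi = self.tips_per_species
        if not (1 <= lo <= hi):
            raise ValueError("tips_per_species range must be ordered and >= 1")
        if not (0 < self.within_species_depth < self.between_species_depth):
            raise ValueError("require 0 < within_species_depth < between_species_depth")
        for name, length in self.loci:
            if length <= 0:
                raise ValueError(f"locus {name!r} has non-positive length")


@dataclass
class PlantedTruth:
    """The generating tree and tip→species assignment of one simulation."""

    tree: SupportTree  # rooted, with branch lengths in substitutions/site
    taxon_map: TaxonMap
    outgroup_species: str
    config: SimulationConfig

    @property
    def outgroup_tips(self) -> set[str]:
        return self.taxon_map.tips_of(self.outgroup_species)


def _species_names(n: int) -> tuple[list[str], str]:
    if n == len(SPECIES):
        names = list(SPECIES)
    else:
        names = [f"sp{i + 1:02d}" for i in range(n)]
    return names, names[-1]  # last species is the designated outgroup


def _short_code(species: str) -> str:
    return species.split()[-1].replace(".", "")


def simulate_species_tree(config: SimulationConfig) -> PlantedTruth:
    """Random species topology by sequential random joins, each species
    expanded into a shallow tip clade; the outgroup species gets exactly
    two tips."""
    rng = _rng(config.seed, "tree")
    names, outgroup = _species_names(config.n_species)
    lo, hi = config.tips_per_species
    tns = dendropy.TaxonNamespace()
    tip_to_species: dict[str, str] = {}

    def edge_len(depth: float) -> float:
        return depth * rng.uniform(0.5, 1.5)

    clades: list[dendropy.Node] = []
    for species in names:
        k = 2 if species == outgroup else int(rng.integers(lo, hi + 1))
        leaves = []
        for i in range(k):
            label = f"{_short_code(species)}_{i + 1}"
            tip_to_species[label] = species
            leaf = dendropy.Node(taxon=dendropy.Taxon(label=label))
            leaves.append(leaf)
        if k == 1:
            node = leaves[0]
        else:
            node = dendropy.Node()
            for leaf in leaves:
                node.add_child(leaf)
                leaf.edge.length = edge_len(config.within_species_depth)
        clades.append(node)

    while len(clades) > 1:
        i, j = sorted(rng.choice(len(clades), size=2, replace=False))
        parent = dendropy.Node()
        for child in (clades[i], clades[j]):
            parent.add_child(child)
            child.edge.length = edge_len(config.between_species_depth / 2.0)
        clades = [c for k, c in enumerate(clades) if k not in (i, j)] + [parent]

    tree = dendropy.Tree(seed_node=clades[0], taxon_namespace=tns)
    for leaf in tree.leaf_node_iter():
        tns.add_taxon(leaf.taxon)
    tree.is_rooted = True
    return PlantedTruth(
        tree=SupportTree(tree),
        taxon_map=TaxonMap(tip_to_species, species=tuple(names)),
        outgroup_species=outgroup,
        config=config,
    )


_BASES = np.array(list("ACGT"))


def evolve_alignment(tree: SupportTree, length: int, seed: int,
                     locus_name: str = "locus") -> Alignment:
    """Evolve an alignment along a tree under Jukes–Cantor substitution.

    The root sequence is i.i.d. uniform over {A,C,G,T}; along a branch of
    length t each site substitutes with probability p(t) = (3/4)(1 −
    e^(−4t/3)), choosing uniformly among the three other bases.
    """
    if length <= 0:
        raise ValueError("alignment length must be positive")
    rng = np.random.default_rng(seed)
    root = tree.tree.seed_node
    states: dict[int, np.ndarray] = {id(root): rng.integers(0, 4, size=length)}
    sequences: dict[str, str] = {}
    for node in tree.tree.preorder_node_iter():
        if node is root:
            parent_state = states[id(root)]
        else:
            t = node.edge.length or 0.0
            p = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
            state = states[id(node.parent_node)].copy()
            hit = rng.random(length) < p
            n_hit = int(hit.sum())
            if n_hit:
                state[hit] = (state[hit] + rng.integers(1, 4, size=n_hit)) % 4
            states[id(node)] = state
            parent_state = state
        if node.is_leaf():
            sequences[node.taxon.label] = "".join(_BASES[parent_state])
    return Alignment(locus_name=locus_name, sequences=sequences)


def simulate_alignments(truth: PlantedTruth) -> dict[str, Alignment]:
    """One alignment per configured locus, each from its own substream."""
    out: dict[str, Alignment] = {}
    for idx, (name, length) in enumerate(truth.config.loci):
        child_seed = int(_rng(truth.config.seed, "sequences", idx).integers(0, 2**31 - 1))
        out[name] = evolve_alignment(truth.tree, length, child_seed, locus_name=name)
    return out


def simulate_spores(species: str, n: int, seed: int,
                    params: Optional[dict] = None) -> list[SporeMeasurement]:
    """Draw n spore length×width pairs for a taxon from truncated normals
    on the published [min, max] range (sd = (max−min)/4)."""
    if n < 1:
        raise ValueError("need n >= 1 spores")
    table = params if params is not None else load_spore_params()
    if species not in table:
        raise KeyError(f"no spore parameters for species {species!r}")
    rng = np.random.default_rng(seed)

    def draw(axis: str) -> np.ndarray:
        mean, lo, hi = table[species][axis]
        sd = (hi - lo) / 4.0
        a, b = (lo - mean) / sd, (hi - mean) / sd
        return truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)

    lengths, widths = draw("length"), draw("width")
    code = _short_code(species)
    return [
        SporeMeasurement(specimen_id=f"sim_{code}", spore_id=f"{code}_s{i + 1}",
                         length=float(l), width=float(min(w, l)))
        for i, (l, w) in enumerate(zip(lengths, widths))
    ]


def generate_profiles(noise_rate: float, seed: int) -> list[tuple[str, CharacterProfile]]:
    """Reference profile per species with each character independently
    masked to missing at ``noise_rate``; returns (true species, profile)."""
    if not 0 <= noise_rate < 1:
        raise ValueError("noise_rate must be in [0, 1)")
    rng = _rng(seed, "profiles")
    maskable = [
        "context_color", "melanoid_deposits", "concentric_zones",
        "contextual_chlamydospores", "culture_chlamydospores", "stipe_class",
        "pores_per_mm", "host_group", "region", "growth_rate_class",
        "spore_length_mean", "spore_width_mean",
    ]
    out = []
    for species, profile in load_reference_profiles().items():
        masked = [c for c in maskable if rng.random() < noise_rate]
        out.append((species, profile.without(*masked)))
    return out


def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Write a full synthetic dataset and return its manifest.

    Outputs: per-locus FASTA, the true tree (Newick), tip→species map TSV,
    a spores TSV (25 spores per taxon), a profiles TSV, and a JSON manifest
    with the config and a checksum per file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = simulate_species_tree(config)
    files: dict[str, Path] = {}

    alignments = simulate_alignments(truth)
    for name, aln in alignments.items():
        path = outdir / f"{name}.fasta"
        write_alignment(aln, path)
        files[f"alignment:{name}"] = path

    tree_path = outdir / "true_tree.nwk"
    tree_path.write_text(truth.tree.to_newick(), encoding="utf-8")
    files["true_tree"] = tree_path

    map_path = outdir / "taxon_map.tsv"
    write_taxon_map_tsv(truth.taxon_map, map_path)
    files["taxon_map"] = map_path

    spore_rng = _rng(config.seed, "spores")
    measurements = []
    if config.n_species == len(SPECIES):
        for species in SPECIES:
            child = int(spore_rng.integers(0, 2**31 - 1))
            measurements.extend(simulate_spores(species, 25, child))
    spores_path = outdir / "spores.tsv"
    write_spores_tsv(measurements, spores_path)
    files["spores"] = spores_path

    profiles_path = outdir / "profiles.tsv"
    if config.n_species == len(SPECIES):
        rows = generate_profiles(0.0, config.seed)
    else:
        rows = []
    import pandas as pd
    pd.DataFrame(
        [{"species": sp, **{k: v for k, v in asdict(p).items()}} for sp, p in rows]
    ).to_csv(profiles_path, sep="\t", index=False)
    files["profiles"] = profiles_path

    manifest = {
        "config": {**asdict(config), "loci": [list(l) for l in config.loci],
                   "tips_per_species": list(config.tips_per_species)},
        "outgroup_species": truth.outgroup_species,
        "files": {
            key: {"path": str(path),
                  "sha256": hashlib.sha256(path.read_bytes()).hexdigest()}
            for key, path in files.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
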