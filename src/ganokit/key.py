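"""Dichotomous-key engine.

The 12-couplet key to the U.S. laccate *Ganoderma* species is shipped as a
structured data file and executed here.  Each couplet offers two leads; a
lead is a conjunction of atomic predicates over a
:class:`~ganokit.morpho.CharacterProfile` and either forwards to another
couplet or terminates at a species.

Evaluation uses three-valued logic: an atom over a missing character is
*unknown*.  At each couplet the traversal follows a single lead only when
exactly one lead is definitely true and the other definitely false; in every
other situation (a consulted character missing, a measurement outside all
sibling ranges, or — in a malformed key — both leads true) it follows both
leads and the candidate set is the union of everything reached.  An
identification therefore always returns at least one candidate, and removing
information can only grow the candidate set, never shrink it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence, Union

import yaml

from .morpho import MISSING, SPECIES, CharacterProfile

__all__ = [
    "Key",
    "KeyCouplet",
    "KeyLead",
    "IdentificationResult",
    "KeyStructureError",
    "load_key",
    "identify",
    "distinguishing_characters",
]

_NUMERIC_CHARACTERS = {"spore_length_mean", "spore_width_mean"}


class KeyStructureError(ValueError):
    """Structural defect in a key file (cycle, dangling reference, ...)."""


@dataclass(frozen=True)
class Atom:
    """One atomic predicate: ``character <op> value``."""

    character: str
    op: str  # eq | neq | in | not_in | lt | range
    value: object

    def evaluate(self, profile: CharacterProfile) -> Optional[bool]:
        """True/False, or None when the character is unobserved."""
        observed = getattr(profile, self.character)
        if observed is None or observed == MISSING:
            return None
        if self.op == "eq":
            return observed == self.value
        if self.op == "neq":
            return observed != self.value
        if self.op == "in":
            return observed in self.value
        if self.op == "not_in":
            return observed not in self.value
        if self.op == "lt":
            return observed < self.value
        if self.op == "range":
            lo, hi = self.value
            return lo <= observed <= hi
        raise ValueError(f"unknown predicate op {self.op!r}")


@dataclass(frozen=True)
class KeyLead:
    text: str
    atoms: tuple[Atom, ...]
    target: Union[int, str]  # couplet id or species name

    @property
    def is_terminal(self) -> bool:
        return isinstance(self.target, str)

    def evaluate(self, profile: CharacterProfile) -> Optional[bool]:
        """Conjunction under three-valued logic: any False wins, then unknown."""
        saw_unknown = False
        for atom in self.atoms:
            v = atom.evaluate(profile)
            if v is False:
                return False
            if v is None:
                saw_unknown = True
        return None if saw_unknown else True

    def characters(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.character not in seen:
                seen.append(a.character)
        return seen


@dataclass(frozen=True)
class KeyCouplet:
    couplet_id: int
    lead_a: KeyLead
    lead_b: KeyLead

    @property
    def leads(self) -> tuple[KeyLead, KeyLead]:
        return (self.lead_a, self.lead_b)


@dataclass(frozen=True)
class IdentificationResult:
    candidates: frozenset[str]
    trace: tuple[tuple[int, str], ...]  # (couplet_id, "a" | "b" | "both")
    unresolved_characters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.candidates:
            raise ValueError("identification must return at least one candidate")


class Key:
    """A validated dichotomous key (DAG of couplets rooted at couplet 1)."""

    def __init__(self, couplets: dict[int, KeyCouplet]):
        self.couplets = couplets
        self._validate()

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        if 1 not in self.couplets:
            raise KeyStructureError("key has no couplet 1 to start from")
        for cid, couplet in self.couplets.items():
            for lead in couplet.leads:
                if lead.is_terminal:
                    if lead.target not in SPECIES:
                        raise KeyStructureError(
                            f"couplet {cid}: lead terminates at unknown species {lead.target!r}"
                        )
                elif lead.target not in self.couplets:
                    raise KeyStructureError(
                        f"couplet {cid}: dangling reference to couplet {lead.target}"
                    )
        self._check_acyclic()
        reachable = self.reachable_species()
        unreachable = set(SPECIES) - reachable
        if unreachable:
            raise KeyStructureError(f"species unreachable from couplet 1: {sorted(unreachable)}")

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        state = {cid: WHITE for cid in self.couplets}

        def visit(cid: int) -> None:
            state[cid] = GRAY
            for lead in self.couplets[cid].leads:
                if lead.is_terminal:
                    continue
                nxt = lead.target
                if state[nxt] == GRAY:
                    raise KeyStructureError(f"cycle through couplet {nxt}")
                if state[nxt] == WHITE:
                    visit(nxt)
            state[cid] = BLACK

        visit(1)

    def reachable_species(self, start: int = 1) -> set[str]:
        out: set[str] = set()
        stack = [start]
        seen: set[int] = set()
        while stack:
            cid = stack.pop()
            if cid in seen:
                continue
            seen.add(cid)
            for lead in self.couplets[cid].leads:
                if lead.is_terminal:
                    out.add(lead.target)
                else:
                    stack.append(lead.target)
        return out

    # -- traversal ----------------------------------------------------------

    def identify(self, profile: CharacterProfile) -> IdentificationResult:
        candidates: set[str] = set()
        trace: list[tuple[int, str]] = []
        unresolved: list[str] = []
        visited: set[int] = set()

        def walk(cid: int) -> None:
            if cid in visited:
                return
            visited.add(cid)
            couplet = self.couplets[cid]
            va = couplet.lead_a.evaluate(profile)
            vb = couplet.lead_b.evaluate(profile)
            if va is True and vb is False:
                chosen: Sequence[tuple[str, KeyLead]] = [("a", couplet.lead_a)]
            elif vb is True and va is False:
                chosen = [("b", couplet.lead_b)]
            else:
                chosen = [("both", couplet.lead_a), ("both", couplet.lead_b)]
                for lead in couplet.leads:
                    for atom in lead.atoms:
                        if atom.evaluate(profile) is None and atom.character not in unresolved:
                            unresolved.append(atom.character)
            trace.append((cid, chosen[0][0]))
            for _, lead in chosen:
                if lead.is_terminal:
                    candidates.add(lead.target)
                else:
                    walk(lead.target)

        walk(1)
        return IdentificationResult(
            candidates=frozenset(candidates),
            trace=tuple(trace),
            unresolved_characters=tuple(unresolved),
        )

    # -- species paths ------------------------------------------------------

    def path_to(self, species: str) -> list[tuple[int, str]]:
        """The (couplet, lead) walk from couplet 1 to a species terminal."""
        if species not in SPECIES:
            raise ValueError(f"unknown species {species!r}")

        def search(cid: int) -> Optional[list[tuple[int, str]]]:
            couplet = self.couplets[cid]
            for label, lead in (("a", couplet.lead_a), ("b", couplet.lead_b)):
                if lead.is_terminal:
                    if lead.target == species:
                        return [(cid, label)]
                else:
                    tail = search(lead.target)
                    if tail is not None:
                        return [(cid, label)] + tail
            return None

        path = search(1)
        if path is None:
            raise KeyStructureError(f"{species!r} not reachable in this key")
        return path


def load_key(key_file=None) -> Key:
    """Load and validate a key definition; defaults to the shipped U.S. key."""
    if key_file is None:
        text = resources.files("ganokit.data").joinpath("key_us_laccate.yaml").read_text("utf-8")
        raw = yaml.safe_load(text)
    else:
        with open(key_file, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    couplets: dict[int, KeyCouplet] = {}
    for cid, leads in raw["couplets"].items():
        cid = int(cid)
        if set(leads) != {"a", "b"}:
            raise KeyStructureError(f"couplet {cid}: needs exactly leads 'a' and 'b'")
        parsed = {}
        for label in ("a", "b"):
            spec = leads[label]
            if ("goto" in spec) == ("species" in spec):
                raise KeyStructureError(
                    f"couplet {cid}{label}: exactly one of goto/species required"
                )
            atoms = tuple(
                Atom(p["character"], p["op"],
                     tuple(p["value"]) if isinstance(p["value"], list) else p["value"])
                for p in spec.get("predicates", [])
            )
            for atom in atoms:
                if not hasattr(CharacterProfile(), atom.character):
                    raise KeyStructureError(
                        f"couplet {cid}{label}: unknown character {atom.character!r}"
                    )
            target = spec.get("species", spec.get("goto"))
            parsed[label] = KeyLead(text=spec.get("text", ""), atoms=atoms, target=target)
        couplets[cid] = KeyCouplet(cid, parsed["a"], parsed["b"])
    return Key(couplets)


def identify(profile: CharacterProfile, key: Key) -> IdentificationResult:
    """Identify a specimen; convenience wrapper around :meth:`Key.identify`."""
    return key.identify(profile)


def distinguishing_characters(species_a: str, species_b: str, key: Key) -> list[str]:
    """Characters separating two species at the first couplet where their
    key paths diverge (atoms identical in both leads are not separating)."""
    if species_a == species_b:
        return []
    path_a = key.path_to(species_a)
    path_b = key.path_to(species_b)
    for (cid_a, lead_a), (cid_b, lead_b) in zip(path_a, path_b):
        if cid_a != cid_b:
            break  # paths diverged at the previous couplet's leads
        if lead_a != lead_b:
            couplet = key.couplets[cid_a]
            la = couplet.lead_a if lead_a == "a" else couplet.lead_b
            lb = couplet.lead_a if lead_b == "a" else couplet.lead_b
            shared = set(la.atoms) & set(lb.atoms)
            chars: list[str] = []
            for lead in (la, lb):
                for atom in lead.atoms:
                    if atom not in shared and atom.character not in chars:
                        chars.append(atom.character)
            return chars
    raise KeyStructureError(
        f"paths of {species_a!r} and {species_b!r} never diverge — malformed key"
    )
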