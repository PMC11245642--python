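"""Dichotomous identification keys as executable data structures.

A dichotomous key is a sequence of numbered *couplets*, each offering two
contrasting *leads*; a lead either names a terminal taxon or points to
another couplet.  This module represents such keys as validated data
(loaded from JSON), evaluates leads against specimen evidence under
three-valued (Kleene) logic — so incomplete specimens key out to a
candidate *set* rather than failing — and ships a key to the species of
the predatory nematode genus *Mononchus* as a bundled resource.

Evidence semantics
------------------
A character value may be a point (one specimen's measurement), a closed
interval (a population range), or a qualitative state.  A quantitative
condition evaluated against an interval is true if the interval wholly
satisfies it, false if it wholly violates it, and unknown when it partially
overlaps.  Missing characters evaluate to unknown.  A lead is the Kleene
conjunction of its conditions; at each couplet every non-false lead is
followed, so unknowns widen the candidate set but never mis-direct it.

Printed range boundaries are treated as closed: a value lying exactly on a
threshold shared by both leads satisfies both (the traversal branches),
while a value falling into a gap between the two leads' ranges satisfies
neither and is reported as a dead end naming the failed conditions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Truth",
    "CharacterDefinition",
    "CharacterValue",
    "Condition",
    "Lead",
    "Couplet",
    "TaxonomicKey",
    "IdentificationResult",
    "ValidationReport",
    "RangeZone",
    "KeyError_",
    "load_key",
    "load_bundled_key",
    "validate_key",
    "evaluate_condition",
    "identify",
    "discriminating_characters",
    "path_evidence",
]


class KeyError_(ValueError):
    """Raised for structurally invalid key documents."""


class Truth(Enum):
    """Three-valued (Kleene) truth."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"


def kleene_and(values: Iterable[Truth]) -> Truth:
    out = Truth.TRUE
    for v in values:
        if v is Truth.FALSE:
            return Truth.FALSE
        if v is Truth.UNKNOWN:
            out = Truth.UNKNOWN
    return out


@dataclass(frozen=True)
class CharacterDefinition:
    char_id: str
    name: str
    kind: str  # "quantitative" | "qualitative"
    unit: str | None = None  # µm | mm | ratio | percent | count
    states: tuple[str, ...] = ()
    sex: str = "both"  # female | male | both

    def __post_init__(self) -> None:
        if self.kind not in ("quantitative", "qualitative"):
            raise KeyError_(f"character {self.char_id}: bad kind {self.kind!r}")
        if self.kind == "qualitative" and len(self.states) < 2:
            raise KeyError_(f"character {self.char_id}: qualitative characters need ≥2 states")
        if self.sex not in ("female", "male", "both"):
            raise KeyError_(f"character {self.char_id}: bad sex_applicability {self.sex!r}")


@dataclass(frozen=True)
class CharacterValue:
    """One piece of evidence: a point, a closed interval, or a state.

    ``value`` is a float (point), a (lo, hi) tuple (interval), or a string
    (qualitative state).  ``provenance`` distinguishes a single observation
    from a population range; it does not affect evaluation.
    """

    char_id: str
    value: float | tuple[float, float] | str
    provenance: str = "observed"  # observed | population-range
    unit: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.value, tuple):
            lo, hi = self.value
            if lo > hi:
                raise KeyError_(f"{self.char_id}: interval lo {lo} > hi {hi}")

    @property
    def interval(self) -> tuple[float, float] | None:
        if isinstance(self.value, tuple):
            return self.value
        if isinstance(self.value, (int, float)):
            return (float(self.value), float(self.value))
        return None


@dataclass(frozen=True)
class Condition:
    """One clause of a lead: a threshold on a character.

    Comparators: ``in`` (closed range, needs lo and hi), ``ge``, ``le``
    (one-sided, need threshold), ``is`` (a single qualitative state),
    ``state-in`` (any of a set of states; used where a lead contrasts one
    state against several, e.g. "distinctly sclerotised" = rhomb or drop).
    """

    char_id: str
    cmp: str
    lo: float | None = None
    hi: float | None = None
    threshold: float | None = None
    state: str | None = None
    states: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cmp not in ("in", "ge", "le", "is", "state-in"):
            raise KeyError_(f"condition on {self.char_id}: bad comparator {self.cmp!r}")
        if self.cmp == "in" and (self.lo is None or self.hi is None or self.lo > self.hi):
            raise KeyError_(f"condition on {self.char_id}: bad range [{self.lo}, {self.hi}]")
        if self.cmp in ("ge", "le") and self.threshold is None:
            raise KeyError_(f"condition on {self.char_id}: {self.cmp} needs a threshold")
        if self.cmp == "is" and self.state is None:
            raise KeyError_(f"condition on {self.char_id}: 'is' needs a state")
        if self.cmp == "state-in" and not self.states:
            raise KeyError_(f"condition on {self.char_id}: 'state-in' needs states")

    def numeric_interval(self) -> tuple[float, float] | None:
        """The satisfying set as a closed interval (inf-bounded for ge/le)."""
        if self.cmp == "in":
            return (float(self.lo), float(self.hi))
        if self.cmp == "ge":
            return (float(self.threshold), float("inf"))
        if self.cmp == "le":
            return (float("-inf"), float(self.threshold))
        return None

    def allowed_states(self) -> tuple[str, ...]:
        if self.cmp == "is":
            return (self.state,)
        if self.cmp == "state-in":
            return self.states
        return ()

    def describe(self) -> str:
        if self.cmp == "in":
            return f"{self.char_id} in [{self.lo}, {self.hi}]"
        if self.cmp == "ge":
            return f"{self.char_id} ≥ {self.threshold}"
        if self.cmp == "le":
            return f"{self.char_id} ≤ {self.threshold}"
        if self.cmp == "is":
            return f"{self.char_id} = {self.state}"
        return f"{self.char_id} in {{{', '.join(self.states)}}}"


@dataclass(frozen=True)
class Lead:
    """One of a couplet's two alternatives: conditions (a conjunction) plus
    a target, which is either another couplet id or ≥1 terminal taxa."""

    conditions: tuple[Condition, ...]
    goto: str | None = None
    taxa: tuple[str, ...] = ()
    text: str = ""

    def __post_init__(self) -> None:
        if (self.goto is None) == (not self.taxa):
            raise KeyError_("a lead must target exactly one of: a couplet, terminal taxa")


@dataclass(frozen=True)
class Couplet:
    couplet_id: str
    leads: tuple[Lead, Lead]


@dataclass(frozen=True)
class TaxonomicKey:
    name: str
    characters: Mapping[str, CharacterDefinition]
    couplets: Mapping[str, Couplet]
    start_id: str
    notes: str = ""

    @property
    def taxa(self) -> tuple[str, ...]:
        """All terminal taxon names, in couplet order."""
        seen: dict[str, None] = {}
        for c in self.couplets.values():
            for lead in c.leads:
                for t in lead.taxa:
                    seen.setdefault(t, None)
        return tuple(seen)


@dataclass
class IdentificationResult:
    candidates: frozenset[str]
    paths: tuple[tuple[str, ...], ...]  # couplet-id sequences reaching a terminal
    status: str  # unique | ambiguous | dead_end
    unresolved_couplets: tuple[str, ...] = ()
    conflicts: tuple[tuple[str, tuple[str, ...]], ...] = ()  # (couplet, failed conds)


@dataclass(frozen=True)
class RangeZone:
    """Relationship of the two leads' numeric conditions on one character."""

    couplet_id: str
    char_id: str
    kind: str  # "gap" | "overlap" | "boundary"
    lo: float
    hi: float


@dataclass
class ValidationReport:
    unreachable_taxa: tuple[str, ...]
    unreachable_couplets: tuple[str, ...]
    unused_characters: tuple[str, ...]
    zones: tuple[RangeZone, ...]

    def gaps(self) -> tuple[RangeZone, ...]:
        return tuple(z for z in self.zones if z.kind == "gap")


# ---------------------------------------------------------------------------
# loading / validation


def _parse_condition(doc: Mapping, characters: Mapping[str, CharacterDefinition]) -> Condition:
    char_id = doc["char"]
    if char_id not in characters:
        raise KeyError_(f"condition references unknown character {char_id!r}")
    cond = Condition(
        char_id=char_id,
        cmp=doc["cmp"],
        lo=doc.get("lo"),
        hi=doc.get("hi"),
        threshold=doc.get("threshold"),
        state=doc.get("state"),
        states=tuple(doc.get("states", ())),
    )
    cdef = characters[char_id]
    if cond.cmp in ("is", "state-in"):
        if cdef.kind != "qualitative":
            raise KeyError_(f"state condition on quantitative character {char_id}")
        for s in cond.allowed_states():
            if s not in cdef.states:
                raise KeyError_(f"{char_id}: state {s!r} not in {cdef.states}")
    elif cdef.kind != "quantitative":
        raise KeyError_(f"numeric condition on qualitative character {char_id}")
    return cond


def load_key(document: str | Mapping) -> TaxonomicKey:
    """Load and fully validate a key from a JSON string or parsed mapping.

    Raises :class:`KeyError_` naming the defect: schema violations,
    duplicate characters, dangling lead targets, cycles in the couplet
    graph, or terminal taxa unreachable from the start couplet.
    """
    doc = json.loads(document) if isinstance(document, str) else document
    for required in ("name", "start", "characters", "couplets"):
        if required not in doc:
            raise KeyError_(f"key document missing field {required!r}")

    characters: dict[str, CharacterDefinition] = {}
    for cdoc in doc["characters"]:
        cdef = CharacterDefinition(
            char_id=cdoc["id"],
            name=cdoc.get("name", cdoc["id"]),
            kind=cdoc["kind"],
            unit=cdoc.get("unit"),
            states=tuple(cdoc.get("states", ())),
            sex=cdoc.get("sex", "both"),
        )
        if cdef.char_id in characters:
            raise KeyError_(f"duplicate character id {cdef.char_id!r}")
        characters[cdef.char_id] = cdef

    couplets: dict[str, Couplet] = {}
    for cid, cdoc in doc["couplets"].items():
        leads_doc = cdoc["leads"]
        if len(leads_doc) != 2:
            raise KeyError_(f"couplet {cid}: needs exactly two leads, got {len(leads_doc)}")
        leads = []
        for ldoc in leads_doc:
            taxa = ldoc.get("taxon", ())
            if isinstance(taxa, str):
                taxa = (taxa,)
            leads.append(
                Lead(
                    conditions=tuple(
                        _parse_condition(c, characters) for c in ldoc.get("conditions", ())
                    ),
                    goto=ldoc.get("goto"),
                    taxa=tuple(taxa),
                    text=ldoc.get("text", ""),
                )
            )
        couplets[str(cid)] = Couplet(couplet_id=str(cid), leads=(leads[0], leads[1]))

    key = TaxonomicKey(
        name=doc["name"],
        characters=characters,
        couplets=couplets,
        start_id=str(doc["start"]),
        notes=doc.get("notes", ""),
    )
    _check_structure(key)
    return key


def _check_structure(key: TaxonomicKey) -> None:
    if key.start_id not in key.couplets:
        raise KeyError_(f"start couplet {key.start_id!r} does not exist")
    for cid, couplet in key.couplets.items():
        for lead in couplet.leads:
            if lead.goto is not None and lead.goto not in key.couplets:
                raise KeyError_(f"couplet {cid}: dangling target {lead.goto!r}")
    # cycle check: DFS with colouring over the couplet graph
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {cid: WHITE for cid in key.couplets}

    def visit(cid: str, trail: tuple[str, ...]) -> None:
        if colour[cid] == GREY:
            raise KeyError_(f"cycle in couplet graph: {' → '.join(trail + (cid,))}")
        if colour[cid] == BLACK:
            return
        colour[cid] = GREY
        for lead in key.couplets[cid].leads:
            if lead.goto is not None:
                visit(lead.goto, trail + (cid,))
        colour[cid] = BLACK

    visit(key.start_id, ())
    unreachable = [t for t in key.taxa if t not in _reachable_taxa(key)]
    if unreachable:
        raise KeyError_(f"terminal taxa unreachable from start: {unreachable}")


def _reachable_taxa(key: TaxonomicKey) -> frozenset[str]:
    seen: set[str] = set()
    stack = [key.start_id]
    visited: set[str] = set()
    while stack:
        cid = stack.pop()
        if cid in visited or cid not in key.couplets:
            continue
        visited.add(cid)
        for lead in key.couplets[cid].leads:
            seen.update(lead.taxa)
            if lead.goto is not None:
                stack.append(lead.goto)
    return frozenset(seen)


_BUNDLED = {"mononchus": "mononchus_key.json"}


def load_bundled_key(name: str = "mononchus") -> TaxonomicKey:
    """Load a key shipped with the package (currently ``"mononchus"``)."""
    try:
        fname = _BUNDLED[name]
    except KeyError:
        raise KeyError_(f"no bundled key named {name!r}; have {sorted(_BUNDLED)}")
    text = resources.files("monotax.data").joinpath(fname).read_text(encoding="utf-8")
    return load_key(text)


def _lead_numeric_intervals(lead: Lead) -> dict[str, tuple[float, float]]:
    """Per-character satisfying interval for a lead (conditions intersected)."""
    out: dict[str, tuple[float, float]] = {}
    for cond in lead.conditions:
        iv = cond.numeric_interval()
        if iv is None:
            continue
        if cond.char_id in out:
            lo, hi = out[cond.char_id]
            iv = (max(lo, iv[0]), min(hi, iv[1]))
        out[cond.char_id] = iv
    return out


def validate_key(key: TaxonomicKey) -> ValidationReport:
    """Report-only diagnostics on a structurally valid key.

    Flags unreachable taxa/couplets, characters never used by a condition,
    and — for every character constrained numerically by both leads of a
    couplet — the relationship of the two ranges: an ``overlap`` (inherent
    ambiguity zone), a shared ``boundary`` point, or a ``gap`` into which a
    measured value satisfies neither lead (e.g. a body length falling
    between a "large species" and a "smaller species" range).
    """
    reachable_cpl: set[str] = set()
    stack = [key.start_id]
    while stack:
        cid = stack.pop()
        if cid in reachable_cpl:
            continue
        reachable_cpl.add(cid)
        for lead in key.couplets[cid].leads:
            if lead.goto is not None:
                stack.append(lead.goto)
    unreachable_couplets = tuple(c for c in key.couplets if c not in reachable_cpl)
    unreachable_taxa = tuple(t for t in key.taxa if t not in _reachable_taxa(key))

    used: set[str] = set()
    for couplet in key.couplets.values():
        for lead in couplet.leads:
            used.update(c.char_id for c in lead.conditions)
    unused = tuple(c for c in key.characters if c not in used)

    zones: list[RangeZone] = []
    for cid, couplet in key.couplets.items():
        iv_a = _lead_numeric_intervals(couplet.leads[0])
        iv_b = _lead_numeric_intervals(couplet.leads[1])
        for char_id in sorted(set(iv_a) & set(iv_b)):
            (alo, ahi), (blo, bhi) = iv_a[char_id], iv_b[char_id]
            lo, hi = max(alo, blo), min(ahi, bhi)
            if lo < hi:
                zones.append(RangeZone(cid, char_id, "overlap", lo, hi))
            elif lo == hi:
                zones.append(RangeZone(cid, char_id, "boundary", lo, hi))
            else:
                zones.append(RangeZone(cid, char_id, "gap", hi, lo))
    return ValidationReport(
        unreachable_taxa=unreachable_taxa,
        unreachable_couplets=unreachable_couplets,
        unused_characters=unused,
        zones=tuple(zones),
    )


# ---------------------------------------------------------------------------
# evaluation


def evaluate_condition(
    cond: Condition,
    value: CharacterValue | None,
    definition: CharacterDefinition | None = None,
) -> Truth:
    """Evaluate one condition against one piece of evidence (or None).

    Point values use standard comparison; interval values are true if the
    whole interval satisfies the condition, false if none of it does, and
    unknown otherwise; missing evidence is unknown.
    """
    if value is None:
        return Truth.UNKNOWN
    if definition is not None and value.unit is not None and definition.unit is not None:
        if value.unit != definition.unit:
            raise KeyError_(
                f"{cond.char_id}: evidence unit {value.unit!r} does not match "
                f"character unit {definition.unit!r}"
            )
    if cond.cmp in ("is", "state-in"):
        if not isinstance(value.value, str):
            raise KeyError_(f"{cond.char_id}: expected a qualitative state, got {value.value!r}")
        return Truth.TRUE if value.value in cond.allowed_states() else Truth.FALSE
    iv = value.interval
    if iv is None:
        raise KeyError_(f"{cond.char_id}: expected a numeric value, got {value.value!r}")
    vlo, vhi = iv
    clo, chi = cond.numeric_interval()
    if vhi < clo or vlo > chi:
        return Truth.FALSE
    if clo <= vlo and vhi <= chi:
        return Truth.TRUE
    return Truth.UNKNOWN


def _evidence_map(
    key: TaxonomicKey, evidence: Iterable[CharacterValue], sex: str | None
) -> dict[str, CharacterValue]:
    ev: dict[str, CharacterValue] = {}
    for cv in evidence:
        if cv.char_id not in key.characters:
            warnings.warn(f"ignoring evidence for unknown character {cv.char_id!r}", stacklevel=3)
            continue
        cdef = key.characters[cv.char_id]
        if sex is not None and cdef.sex not in ("both", sex):
            # e.g. spicule measurements are inapplicable to female evidence
            continue
        ev[cv.char_id] = cv
    return ev


def _eval_lead(key: TaxonomicKey, lead: Lead, ev: Mapping[str, CharacterValue]) -> Truth:
    return kleene_and(
        evaluate_condition(c, ev.get(c.char_id), key.characters.get(c.char_id))
        for c in lead.conditions
    )


def identify(
    key: TaxonomicKey,
    evidence: Iterable[CharacterValue],
    sex: str | None = None,
) -> IdentificationResult:
    """Run a specimen's evidence through the key.

    Depth-first traversal from the start couplet: a lead whose conjunction
    is true or unknown is followed; when both leads are non-false the
    traversal branches (status ``ambiguous``), and when both are false the
    branch is a dead end whose failed conditions are recorded.  The result
    enumerates every couplet path that reached a terminal taxon.

    ``sex`` (``"female"``/``"male"``) masks evidence for characters
    inapplicable to that sex, so e.g. spicule conditions evaluate to
    unknown for female specimens.
    """
    ev = _evidence_map(key, evidence, sex)
    candidates: dict[str, None] = {}
    paths: list[tuple[str, ...]] = []
    unresolved: dict[str, None] = {}
    conflicts: list[tuple[str, tuple[str, ...]]] = []

    def walk(cid: str, trail: tuple[str, ...]) -> None:
        couplet = key.couplets[cid]
        trail = trail + (cid,)
        truths = [_eval_lead(key, lead, ev) for lead in couplet.leads]
        live = [i for i, t in enumerate(truths) if t is not Truth.FALSE]
        if not live:
            failed = tuple(
                cond.describe()
                for lead in couplet.leads
                for cond in lead.conditions
                if evaluate_condition(cond, ev.get(cond.char_id)) is Truth.FALSE
            )
            conflicts.append((cid, failed))
            return
        if len(live) > 1 or any(truths[i] is Truth.UNKNOWN for i in live):
            unresolved[cid] = None
        for i in live:
            lead = couplet.leads[i]
            if lead.goto is not None:
                walk(lead.goto, trail)
            else:
                for t in lead.taxa:
                    candidates.setdefault(t, None)
                paths.append(trail)

    walk(key.start_id, ())
    cand = frozenset(candidates)
    if not cand:
        status = "dead_end"
    elif len(cand) == 1 and len(paths) == 1:
        status = "unique"
    else:
        status = "ambiguous"
    return IdentificationResult(
        candidates=cand,
        paths=tuple(paths),
        status=status,
        unresolved_couplets=tuple(unresolved),
        conflicts=tuple(conflicts),
    )


# ---------------------------------------------------------------------------
# analysis helpers


def _all_paths(key: TaxonomicKey) -> dict[str, list[tuple[tuple[str, int], ...]]]:
    """taxon → list of paths, each a sequence of (couplet_id, lead_index)."""
    out: dict[str, list[tuple[tuple[str, int], ...]]] = {}

    def walk(cid: str, trail: tuple[tuple[str, int], ...]) -> None:
        for i, lead in enumerate(key.couplets[cid].leads):
            step = trail + ((cid, i),)
            if lead.goto is not None:
                walk(lead.goto, step)
            else:
                for t in lead.taxa:
                    out.setdefault(t, []).append(step)

    walk(key.start_id, ())
    return out


def discriminating_characters(
    key: TaxonomicKey, candidates: Iterable[str]
) -> list[tuple[str, int]]:
    """Rank characters by how many candidate pairs they separate.

    For each pair of remaining candidates, the couplet where their key
    paths first diverge separates them; every character conditioned on in
    that couplet's two leads gets credit for the pair.  Returns
    ``(char_id, n_pairs_separated)`` sorted by decreasing count — a
    "measure this next" suggestion.
    """
    cands = sorted(set(candidates))
    if len(cands) < 2:
        raise ValueError("discriminating_characters needs ≥2 candidates")
    paths = _all_paths(key)
    for c in cands:
        if c not in paths:
            raise KeyError_(f"candidate {c!r} is not a terminal of this key")
    separated: dict[str, set[tuple[str, str]]] = {}
    for i, a in enumerate(cands):
        for b in cands[i + 1 :]:
            for pa in paths[a]:
                for pb in paths[b]:
                    k = 0
                    while k < min(len(pa), len(pb)) and pa[k] == pb[k]:
                        k += 1
                    if k == min(len(pa), len(pb)) or pa[k][0] != pb[k][0]:
                        continue  # no single-couplet divergence on this path pair
                    couplet = key.couplets[pa[k][0]]
                    for lead in couplet.leads:
                        for cond in lead.conditions:
                            separated.setdefault(cond.char_id, set()).add((a, b))
    ranked = sorted(separated.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return [(char, len(pairs)) for char, pairs in ranked]


def path_evidence(key: TaxonomicKey, taxon: str) -> list[CharacterValue]:
    """Construct evidence satisfying the conjunction of all conditions along
    a taxon's key path (the first path, if several).

    Numeric constraints along the path are intersected per character and a
    witness is taken from the interior of the intersection; state
    constraints are intersected and the first state in the character's
    declared order is used.  Useful for soundness checks and for seeding
    synthetic specimens.
    """
    paths = _all_paths(key)
    if taxon not in paths:
        raise KeyError_(f"{taxon!r} is not a terminal of this key")
    path = paths[taxon][0]
    intervals: dict[str, tuple[float, float]] = {}
    states: dict[str, set[str]] = {}
    for cid, lead_idx in path:
        lead = key.couplets[cid].leads[lead_idx]
        for cond in lead.conditions:
            iv = cond.numeric_interval()
            if iv is not None:
                lo, hi = intervals.get(cond.char_id, (float("-inf"), float("inf")))
                intervals[cond.char_id] = (max(lo, iv[0]), min(hi, iv[1]))
            else:
                allowed = set(cond.allowed_states())
                states[cond.char_id] = states.get(cond.char_id, allowed) & allowed
    evidence: list[CharacterValue] = []
    for char_id, (lo, hi) in intervals.items():
        if lo > hi:
            raise KeyError_(f"contradictory numeric constraints on {char_id} along path")
        if lo == float("-inf"):
            witness = hi - 1.0
        elif hi == float("inf"):
            witness = lo + 1.0
        else:
            witness = (lo + hi) / 2.0
        evidence.append(CharacterValue(char_id, witness))
    for char_id, allowed in states.items():
        if not allowed:
            raise KeyError_(f"contradictory state constraints on {char_id} along path")
        ordered = [s for s in key.characters[char_id].states if s in allowed]
        evidence.append(CharacterValue(char_id, ordered[0]))
    return evidence
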