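"""Synthetic specimens and sequence families for pipeline testing.

Morphometric populations are emulated by drawing each published character
from a truncated normal distribution — mean and SD from a printed
``mean ± sd``, truncation at the printed range; where only a range is
printed the mean is its midpoint and the SD a quarter of its width (a
stated convention, not a claim about the data).  Characters are sampled
independently: the printed ratio characters (a, b, c, c', V, buccal
capsule length/width, tooth position) are drawn directly and the dependent
raw measurement is back-derived, which keeps every specimen internally
consistent and every derived index within its species range.  No
covariance between characters (e.g. body and tail length) is modelled —
only marginal ranges are published.

Sequence families use a two-rate star design: a random ancestor is mutated
per species at the interspecific rate, and each isolate mutates its
species root at the intraspecific rate, with uniform (Jukes–Cantor-style)
substitutions.  All randomness flows from an integer seed through
:func:`numpy.random.default_rng`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from monotax.key import CharacterValue
from monotax.morphometrics import SpecimenMeasurements, compute_indices
from monotax.seqdist import SeqRecord

__all__ = [
    "QuantSpec",
    "SpeciesProfile",
    "SeqFamilySpec",
    "sample_specimens",
    "sample_sequences",
    "pseudoaquaticus_profile",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class QuantSpec:
    """Truncated-normal parameters for one quantitative character."""

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.mean <= self.hi):
            raise ValueError(f"mean {self.mean} outside [{self.lo}, {self.hi}]")
        if self.sd < 0:
            raise ValueError("sd must be ≥ 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.sd == 0 or self.lo == self.hi:
            return np.full(n, self.mean)
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


#: characters a profile may specify, with their role in back-derivation
_PROFILE_CHARS = (
    "body_length",  # mm
    "a", "b", "c", "c_prime", "V", "G1", "G2",
    "buccal_capsule_length", "bc_ratio", "tooth_position",
    "lip_region_width", "rectum_length",
)


@dataclass(frozen=True)
class SpeciesProfile:
    """Per-character sampling distributions for one species.

    ``quantitative`` maps character ids (``body_length`` in mm; ratios and
    percents dimensionless; the rest µm) to :class:`QuantSpec`;
    ``states`` maps qualitative character ids to their fixed state."""

    name: str
    quantitative: Mapping[str, QuantSpec]
    states: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.quantitative) - set(_PROFILE_CHARS)
        if unknown:
            raise ValueError(f"unknown quantitative characters: {sorted(unknown)}")
        if "body_length" not in self.quantitative:
            raise ValueError("a profile requires body_length")

    @classmethod
    def from_ranges(
        cls,
        name: str,
        ranges: Mapping[str, tuple[float, float]],
        states: Mapping[str, str] | None = None,
    ) -> "SpeciesProfile":
        """Build a profile from printed (lo, hi) ranges: mean = midpoint,
        sd = width/4, truncation at the range."""
        quant = {
            char: QuantSpec(mean=(lo + hi) / 2, sd=(hi - lo) / 4, lo=lo, hi=hi)
            for char, (lo, hi) in ranges.items()
        }
        return cls(name=name, quantitative=quant, states=dict(states or {}))


def pseudoaquaticus_profile() -> SpeciesProfile:
    """Profile for *Mononchus pseudoaquaticus* built from the published
    female morphometrics (pooled over the five known populations)."""
    return SpeciesProfile.from_ranges(
        "M. pseudoaquaticus sp. nov.",
        ranges={
            "body_length": (1.23, 1.88),
            "a": (20.2, 33.6),
            "b": (4.0, 4.7),
            "c": (7.2, 10.2),
            "c_prime": (4.7, 5.8),
            "V": (48.3, 53.9),
            "G1": (8.0, 12.9),
            "G2": (7.5, 13.3),
            "buccal_capsule_length": (29, 33),
            "bc_ratio": (1.8, 2.0),
            "tooth_position": (18, 21),
            "lip_region_width": (23, 26),
            "rectum_length": (26, 31),
        },
        states={
            "gonads": "didelphic",
            "spinneret": "terminal",
            "pars_refringens": "rhomb",
            "subventral_ribs": "at_level_or_posterior",
            "amphid_position": "anterior",
            "vagina": "not_spotted",
            "tail_shape": "not_digitate",
            "prevulval_papilla": "absent",
            "caudal_glands": "grouped",
        },
    )


_MAX_REJECTS = 100


def sample_specimens(
    profile: SpeciesProfile,
    n: int,
    seed: int | None = None,
) -> tuple[list[SpecimenMeasurements], list[list[CharacterValue]]]:
    """Draw ``n`` synthetic specimens from a species profile.

    Returns the raw measurement records and, per specimen, the character
    evidence (measured values, derived indices and qualitative states) in
    the form the key engine consumes.  Internal consistency (tail shorter
    than body, tooth apex inside the capsule, ...) is enforced by
    back-derivation plus bounded rejection sampling; deterministic under a
    fixed seed.
    """
    if n < 0:
        raise ValueError("n must be ≥ 0")
    rng = np.random.default_rng(seed)
    specimens: list[SpecimenMeasurements] = []
    evidence: list[list[CharacterValue]] = []
    for k in range(n):
        for attempt in range(_MAX_REJECTS):
            draw = {c: float(spec.draw(rng, 1)[0]) for c, spec in profile.quantitative.items()}
            try:
                m = _derive_measurements(profile.name, k, draw)
            except ValueError:
                continue
            break
        else:
            raise ValueError(
                f"could not draw a consistent specimen for {profile.name} "
                f"after {_MAX_REJECTS} attempts"
            )
        specimens.append(m)
        evidence.append(_specimen_evidence(m, profile.states))
    return specimens, evidence


def _derive_measurements(name: str, k: int, draw: Mapping[str, float]) -> SpecimenMeasurements:
    body = draw["body_length"] * 1000.0  # mm → µm

    def over(char: str, num: float) -> float | None:
        return num / draw[char] if char in draw else None

    tail = over("c", body)
    bcl = draw.get("buccal_capsule_length")
    return SpecimenMeasurements(
        specimen_id=f"{name}-{k + 1}",
        taxon_label=name,
        body_length=body,
        max_body_diameter=over("a", body),
        pharynx_length=over("b", body),
        tail_length=tail,
        body_diameter_at_anus=None if tail is None else over("c_prime", tail),
        vulva_distance=draw["V"] * body / 100.0 if "V" in draw else None,
        anterior_gonad_length=draw["G1"] * body / 100.0 if "G1" in draw else None,
        posterior_gonad_length=draw["G2"] * body / 100.0 if "G2" in draw else None,
        buccal_capsule_length=bcl,
        buccal_capsule_width=None if bcl is None else over("bc_ratio", bcl),
        tooth_apex_distance=None
        if bcl is None or "tooth_position" not in draw
        else draw["tooth_position"] * bcl / 100.0,
        lip_region_width=draw.get("lip_region_width"),
        rectum_length=draw.get("rectum_length"),
    )


def _specimen_evidence(
    m: SpecimenMeasurements, states: Mapping[str, str]
) -> list[CharacterValue]:
    idx = compute_indices(m)
    ev: list[CharacterValue] = [CharacterValue("body_length", idx.L)]
    numeric: dict[str, float | None] = {
        "c": idx.c,
        "c_prime": idx.c_prime,
        "bc_ratio": idx.bc_ratio,
        "tooth_position": idx.tooth_position,
        "tail_length": m.tail_length,
        "buccal_capsule_length": m.buccal_capsule_length,
        "buccal_capsule_width": m.buccal_capsule_width,
        "lip_region_width": m.lip_region_width,
        "rectum_length": m.rectum_length,
    }
    if m.buccal_capsule_length is not None and m.lip_region_width is not None:
        numeric["buccal_vs_labial"] = m.buccal_capsule_length / m.lip_region_width
    for char, value in numeric.items():
        if value is not None:
            ev.append(CharacterValue(char, float(value)))
    for char, state in states.items():
        ev.append(CharacterValue(char, state))
    return ev


@dataclass(frozen=True)
class SeqFamilySpec:
    """Parameters of a two-rate star family of rDNA-like sequences.

    ``intra_rate`` and ``inter_rate`` are per-site substitution
    probabilities applied on the isolate→species-root and
    species-root→ancestor edges respectively; realistic rDNA barcoding
    structure has intra ≈ 0–0.003 against inter ≈ 0.05–0.12."""

    n_species: int = 3
    isolates_per_species: int = 3
    seq_length: int = 1000
    intra_rate: float = 0.0015
    inter_rate: float = 0.08
    seed: int | None = None
    genus: str = "Simulomonchus"

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.isolates_per_species < 1 or self.seq_length < 1:
            raise ValueError("counts must be ≥ 1")
        if not (0 <= self.intra_rate < self.inter_rate <= 0.75):
            raise ValueError("rates must satisfy 0 ≤ intra < inter ≤ 0.75")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``, uniformly choosing
    one of the three other bases (Jukes–Cantor-style)."""
    out = seq.copy()
    hits = np.nonzero(rng.random(seq.size) < rate)[0]
    if hits.size:
        shift = rng.integers(1, 4, size=hits.size)
        base_idx = np.searchsorted(BASES, out[hits])
        out[hits] = BASES[(base_idx + shift) % 4]
    return out


def sample_sequences(spec: SeqFamilySpec) -> tuple[list[SeqRecord], dict[str, tuple[str, str]]]:
    """Generate a sequence family and its ``seq_id → (species, genus)``
    label map."""
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(BASES, size=spec.seq_length)
    records: list[SeqRecord] = []
    labels: dict[str, tuple[str, str]] = {}
    for s in range(spec.n_species):
        species = f"species_{s + 1}"
        root = _mutate(ancestor, spec.inter_rate, rng)
        for k in range(spec.isolates_per_species):
            iso = _mutate(root, spec.intra_rate, rng)
            seq_id = f"{species}_iso{k + 1}"
            records.append(
                SeqRecord(seq_id=seq_id, residues="".join(iso), taxon=species, genus=spec.genus)
            )
            labels[seq_id] = (species, spec.genus)
    return records, labels
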