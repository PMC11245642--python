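"""Sequence divergence: p-distances, divergence tiers, neighbour joining.

The species-delimitation logic implemented here follows the standard rDNA
barcoding workflow for nematodes: align, trim to the common covered span,
count raw nucleotide differences and uncorrected p-distances (no
multiple-hit correction) under pairwise or complete deletion of missing
data, partition the pairwise comparisons into intraspecific /
interspecific / intergeneric tiers, and flag taxa whose divergences fall
outside the reference interspecific band — a nominally distinct species
pair diverging *below* the band is a conspecificity candidate, and a
nominally congeneric taxon diverging *above* it is a candidate for generic
misplacement.  Exploratory trees are built by neighbour joining with
column-resampling bootstrap support.

Ambiguity codes (R, Y, N, ...) are by default treated as missing for
distance purposes, i.e. excluded like gaps under pairwise deletion;
IUPAC-intersection matching is available behind ``iupac=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SeqRecord",
    "PairwiseAlignment",
    "DistanceMatrix",
    "DivergenceSummary",
    "DivergenceFlag",
    "TreeNode",
    "PhyloTree",
    "global_align",
    "trim_alignment",
    "count_differences",
    "distance_matrix",
    "group_divergence",
    "species_pair_divergence",
    "conspecificity_flags",
    "nj_tree",
    "bootstrap_support",
]

IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"), "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"), "N": frozenset("ACGT"),
}
UNAMBIGUOUS = frozenset("ACGT")
ALPHABET = frozenset(IUPAC) | {"-"}


@dataclass(frozen=True)
class SeqRecord:
    """A nucleotide sequence with optional species/genus labels.

    Residues are upper-cased and U is normalised to T on construction;
    gaps are allowed (pre-aligned input)."""

    seq_id: str
    residues: str
    taxon: str | None = None
    genus: str | None = None

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("U", "T")
        object.__setattr__(self, "residues", norm)
        if not norm:
            raise ValueError(f"{self.seq_id}: empty sequence")
        bad = set(norm) - ALPHABET
        if bad:
            raise ValueError(f"{self.seq_id}: illegal characters {sorted(bad)}")

    def degapped(self) -> "SeqRecord":
        return replace(self, residues=self.residues.replace("-", ""))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global pairwise alignment: two gapped sequences of equal length."""

    aligned1: str
    aligned2: str
    score: float
    match: float
    mismatch: float
    gap: float

    def __post_init__(self) -> None:
        if len(self.aligned1) != len(self.aligned2):
            raise ValueError("aligned sequences differ in length")


def global_align(
    s1: SeqRecord | str,
    s2: SeqRecord | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with a linear gap penalty.

    Intended for near-identical pairs (e.g. conspecific isolates), not as a
    multiple aligner.  Traceback ties are broken deterministically:
    diagonal (substitution) is preferred, then up (gap in the second
    sequence), then left.
    """
    a = s1.residues if isinstance(s1, SeqRecord) else s1.upper().replace("U", "T")
    b = s2.residues if isinstance(s2, SeqRecord) else s2.upper().replace("U", "T")
    if not a or not b:
        raise ValueError("global_align requires non-empty sequences")
    if "-" in a or "-" in b:
        raise ValueError("global_align expects ungapped input")
    n, m = len(a), len(b)
    score = np.empty((n + 1, m + 1), dtype=float)
    score[0, :] = np.arange(m + 1) * gap
    score[:, 0] = np.arange(n + 1) * gap
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(b.encode(), dtype="S1") == a[i - 1].encode(), match, mismatch)
        row, prev = score[i], score[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + sub[j - 1], prev[j] + gap, row[j - 1] + gap)
    # traceback, preferring diagonal, then up
    out1, out2 = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            if score[i, j] == score[i - 1, j - 1] + s:
                out1.append(a[i - 1]); out2.append(b[j - 1])
                i -= 1; j -= 1
                continue
        if i > 0 and score[i, j] == score[i - 1, j] + gap:
            out1.append(a[i - 1]); out2.append("-")
            i -= 1
            continue
        out1.append("-"); out2.append(b[j - 1])
        j -= 1
    return PairwiseAlignment(
        aligned1="".join(reversed(out1)),
        aligned2="".join(reversed(out2)),
        score=float(score[n, m]),
        match=match,
        mismatch=mismatch,
        gap=gap,
    )


def trim_alignment(aln: Sequence[SeqRecord]) -> list[SeqRecord]:
    """Trim an alignment to the span covered by every sequence.

    Columns falling in any sequence's terminal missing-data run (leading or
    trailing gaps/N) are removed for all sequences — trimming to the length
    of the shortest sequence; interior columns are untouched.
    """
    if not aln:
        return []
    lengths = {len(r) for r in aln}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    length = lengths.pop()
    lead = trail = 0
    for rec in aln:
        s = rec.residues
        i = 0
        while i < length and s[i] in "-N":
            i += 1
        j = 0
        while j < length and s[length - 1 - j] in "-N":
            j += 1
        lead, trail = max(lead, i), max(trail, j)
    if lead + trail >= length:
        raise ValueError("no alignment column is covered by every sequence")
    return [replace(r, residues=r.residues[lead : length - trail]) for r in aln]


def _site_arrays(seqs: Sequence[str]) -> np.ndarray:
    return np.array([list(s) for s in seqs], dtype="U1")


# 4-bit base encoding: A=1, C=2, G=4, T=8; ambiguity codes are unions;
# gaps and anything else map to 0
_CODE_TABLE = bytes(
    sum(1 << "ACGT".index(b) for b in IUPAC.get(chr(i), ())) if chr(i) in IUPAC else 0
    for i in range(256)
)
_STRICT_CODES = frozenset((1, 2, 4, 8))


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(_CODE_TABLE), dtype=np.uint8)


def _usable(codes: np.ndarray, iupac: bool) -> np.ndarray:
    if iupac:
        return codes > 0
    return np.isin(codes, (1, 2, 4, 8))


def _pair_counts(
    ca: np.ndarray, cb: np.ndarray, keep: np.ndarray, iupac: bool
) -> tuple[int, int]:
    if iupac:
        diffs = int(np.sum(((ca & cb) == 0) & keep))
    else:
        diffs = int(np.sum((ca != cb) & keep))
    return diffs, int(np.sum(keep))


def count_differences(
    s1: SeqRecord | str,
    s2: SeqRecord | str,
    deletion: str = "pairwise",
    context: Sequence[SeqRecord] | None = None,
    iupac: bool = False,
) -> tuple[int, int]:
    """Count nucleotide differences and compared sites between two aligned
    sequences.

    Under ``pairwise`` deletion a site is excluded when either sequence has
    a gap or (by default) an ambiguity code there; under ``complete``
    deletion sites are excluded once for the whole alignment (``context``,
    which must contain both sequences' columns).  With ``iupac=True``
    ambiguity codes participate and two sites differ only when their IUPAC
    sets are disjoint.
    """
    a = s1.residues if isinstance(s1, SeqRecord) else s1.upper().replace("U", "T")
    b = s2.residues if isinstance(s2, SeqRecord) else s2.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion mode {deletion!r}")
    ca, cb = _encode(a), _encode(b)
    if deletion == "complete":
        rows = {r.residues for r in (context if context is not None else [])} | {a, b}
        keep = np.logical_and.reduce([_usable(_encode(r), iupac) for r in rows])
    else:
        keep = _usable(ca, iupac) & _usable(cb, iupac)
    return _pair_counts(ca, cb, keep, iupac)


@dataclass(frozen=True)
class DistanceMatrix:
    """Pairwise nucleotide differences, compared sites, and p-distances."""

    ids: tuple[str, ...]
    nt_diffs: np.ndarray  # int, n×n
    compared_sites: np.ndarray  # int, n×n
    p_dist: np.ndarray  # float in [0, 1], n×n

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def pair(self, id1: str, id2: str) -> tuple[int, int, float]:
        i, j = self.index(id1), self.index(id2)
        return int(self.nt_diffs[i, j]), int(self.compared_sites[i, j]), float(self.p_dist[i, j])

    def submatrix(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index(s) for s in keep_ids]
        return DistanceMatrix(
            ids=tuple(keep_ids),
            nt_diffs=self.nt_diffs[np.ix_(idx, idx)],
            compared_sites=self.compared_sites[np.ix_(idx, idx)],
            p_dist=self.p_dist[np.ix_(idx, idx)],
        )


def distance_matrix(
    seqs: Sequence[SeqRecord],
    deletion: str = "pairwise",
    iupac: bool = False,
) -> DistanceMatrix:
    """All pairwise :func:`count_differences` assembled into a matrix."""
    if len(seqs) < 2:
        raise ValueError("distance_matrix requires ≥2 sequences")
    ids = tuple(r.seq_id for r in seqs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    lengths = {len(r) for r in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    n = len(seqs)
    codes = np.stack([_encode(r.residues) for r in seqs])
    usable = _usable(codes, iupac)
    complete_keep = usable.all(axis=0) if deletion == "complete" else None
    diffs = np.zeros((n, n), dtype=int)
    sites = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            keep = complete_keep if complete_keep is not None else usable[i] & usable[j]
            d, s = _pair_counts(codes[i], codes[j], keep, iupac)
            diffs[i, j] = diffs[j, i] = d
            sites[i, j] = sites[j, i] = s
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(sites > 0, diffs / np.maximum(sites, 1), 0.0)
    np.fill_diagonal(p, 0.0)
    return DistanceMatrix(ids=ids, nt_diffs=diffs, compared_sites=sites, p_dist=p)


@dataclass(frozen=True)
class DivergenceSummary:
    """Min–max divergence for one group of pairwise comparisons.

    ``tier`` is intraspecific, interspecific or intergeneric; ``label``
    names the group (a species, a genus, or a genus pair); percentages are
    100·p."""

    tier: str
    label: str
    n_pairs: int
    nt_min: int
    nt_max: int
    pct_min: float
    pct_max: float


def group_divergence(
    dm: DistanceMatrix,
    labels: Mapping[str, tuple[str, str]],
    exclude: Iterable[str] = (),
) -> list[DivergenceSummary]:
    """Partition all pairwise comparisons into divergence tiers.

    ``labels`` maps every sequence id to ``(species, genus)``.  Summaries
    are produced per species (intraspecific), per genus (interspecific:
    same genus, different species) and per genus pair (intergeneric), each
    as the min–max of nucleotide differences and of percent p-distance.
    ``exclude`` removes outlier isolates from all ranges (they still exist
    in the matrix; ranges are simply recomputed without them).
    """
    excluded = set(exclude)
    for sid in dm.ids:
        if sid not in labels:
            raise ValueError(f"sequence {sid!r} has no (species, genus) label")
    buckets: dict[tuple[str, str], list[tuple[int, float]]] = {}
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dm.ids[i], dm.ids[j]
            if a in excluded or b in excluded:
                continue
            sp_a, g_a = labels[a]
            sp_b, g_b = labels[b]
            if g_a == g_b and sp_a == sp_b:
                key = ("intraspecific", sp_a)
            elif g_a == g_b:
                key = ("interspecific", f"{g_a} spp.")
            else:
                key = ("intergeneric", " vs ".join(sorted((g_a, g_b))))
            buckets.setdefault(key, []).append(
                (int(dm.nt_diffs[i, j]), float(dm.p_dist[i, j]))
            )
    tier_order = {"intraspecific": 0, "interspecific": 1, "intergeneric": 2}
    out = []
    for (tier, label), pairs in sorted(buckets.items(), key=lambda kv: (tier_order[kv[0][0]], kv[0][1])):
        nts = [p[0] for p in pairs]
        pcts = [100.0 * p[1] for p in pairs]
        out.append(
            DivergenceSummary(
                tier=tier,
                label=label,
                n_pairs=len(pairs),
                nt_min=min(nts),
                nt_max=max(nts),
                pct_min=min(pcts),
                pct_max=max(pcts),
            )
        )
    return out


def species_pair_divergence(
    dm: DistanceMatrix,
    labels: Mapping[str, tuple[str, str]],
    exclude: Iterable[str] = (),
) -> list[DivergenceSummary]:
    """Per-comparison divergence summaries: one row per species (its
    intraspecific range) and one per species pair (interspecific when
    congeneric, intergeneric otherwise) — the granularity at which
    conspecificity reasoning operates."""
    excluded = set(exclude)
    for sid in dm.ids:
        if sid not in labels:
            raise ValueError(f"sequence {sid!r} has no (species, genus) label")
    buckets: dict[tuple[str, str], list[tuple[int, float]]] = {}
    n = len(dm.ids)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = dm.ids[i], dm.ids[j]
            if a in excluded or b in excluded:
                continue
            (sp_a, g_a), (sp_b, g_b) = labels[a], labels[b]
            if sp_a == sp_b:
                key = ("intraspecific", sp_a)
            else:
                tier = "interspecific" if g_a == g_b else "intergeneric"
                key = (tier, " vs ".join(sorted((sp_a, sp_b))))
            buckets.setdefault(key, []).append((int(dm.nt_diffs[i, j]), float(dm.p_dist[i, j])))
    tier_order = {"intraspecific": 0, "interspecific": 1, "intergeneric": 2}
    return [
        DivergenceSummary(
            tier=tier, label=label, n_pairs=len(pairs),
            nt_min=min(p[0] for p in pairs), nt_max=max(p[0] for p in pairs),
            pct_min=min(100 * p[1] for p in pairs), pct_max=max(100 * p[1] for p in pairs),
        )
        for (tier, label), pairs in sorted(
            buckets.items(), key=lambda kv: (tier_order[kv[0][0]], kv[0][1])
        )
    ]


@dataclass(frozen=True)
class DivergenceFlag:
    """A species-delimitation flag raised by :func:`conspecificity_flags`."""

    kind: str  # "conspecificity_candidate" | "generic_misplacement_candidate"
    label: str
    pct_min: float
    pct_max: float
    reference_min: float
    reference_max: float | None


def conspecificity_flags(
    summaries: Iterable[DivergenceSummary],
    reference_interspecific_min: float,
    reference_interspecific_max: float | None = None,
) -> list[DivergenceFlag]:
    """Flag divergence summaries falling outside the reference
    interspecific band (percent p-distance).

    A nominally interspecific (or intergeneric) comparison whose *maximum*
    divergence lies below the minimum reference interspecific divergence is
    a conspecificity candidate — the two names likely denote one species.
    Conversely, when a reference maximum is given, a comparison whose
    *minimum* divergence exceeds it is a generic-misplacement candidate —
    the taxon diverges from its nominal congeners more than genera normally
    allow.
    """
    if reference_interspecific_min is None:
        raise ValueError("a reference interspecific minimum is required")
    flags = []
    for s in summaries:
        if s.tier == "intraspecific":
            continue
        if s.pct_max < reference_interspecific_min:
            flags.append(
                DivergenceFlag(
                    "conspecificity_candidate", s.label, s.pct_min, s.pct_max,
                    reference_interspecific_min, reference_interspecific_max,
                )
            )
        if reference_interspecific_max is not None and s.pct_min > reference_interspecific_max:
            flags.append(
                DivergenceFlag(
                    "generic_misplacement_candidate", s.label, s.pct_min, s.pct_max,
                    reference_interspecific_min, reference_interspecific_max,
                )
            )
    return flags


# ---------------------------------------------------------------------------
# trees


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap %, internal edges only
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        return [lf for ch in self.children for lf in ch.leaves()]


@dataclass
class PhyloTree:
    """An unrooted tree stored with an arbitrary (trifurcating) root."""

    root: TreeNode

    @property
    def leaf_names(self) -> frozenset[str]:
        return frozenset(lf.name for lf in self.root.leaves())

    def splits(self) -> frozenset[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-lexicographic
        side's leaf set (rooting-invariant)."""
        all_leaves = self.leaf_names
        out: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf():
                return frozenset((node.name,))
            below = frozenset().union(*(walk(ch) for ch in node.children))
            if 2 <= len(below) <= len(all_leaves) - 2:
                other = all_leaves - below
                out.add(min(below, other, key=lambda s: (len(s), sorted(s))))
            return below

        walk(self.root)
        return frozenset(out)

    def to_newick(self, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.{decimals}g}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = "" if node.support is None else str(int(round(node.support)))
            return f"({inner}){label}:{node.length:.{decimals}g}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        label = "" if self.root.support is None else str(int(round(self.root.support)))
        return f"({inner}){label};"


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Neighbour joining (Saitou–Nei) on a distance matrix.

    Agglomerates the pair minimising the Q-criterion; ties are broken by
    the smallest index pair, so the result is deterministic.  Negative
    branch lengths are clamped to zero with a warning.  On additive
    distances the generating topology is recovered.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("nj_tree requires ≥3 taxa")
    d = dm.p_dist.astype(float).copy()
    if not np.all(np.isfinite(d)):
        raise ValueError("distances must be finite")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    active = list(range(n))
    dist = {(i, j): d[i, j] for i in range(n) for j in range(n) if i < j}

    def get(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    clamped = False
    next_id = n
    while len(active) > 3:
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        m = len(active)
        best, best_q = None, None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                if best_q is None or q < best_q:  # strict: first minimal pair wins
                    best_q, best = q, (i, j)
        i, j = best
        dij = get(i, j)
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0 or lj < 0:
            clamped = True
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dist[(k, next_id) if k < next_id else (next_id, k)] = 0.5 * (
                get(i, k) + get(j, k) - dij
            )
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    i, j, k = active
    dij, dik, djk = get(i, j), get(i, k), get(j, k)
    lens = [0.5 * (dij + dik - djk), 0.5 * (dij + djk - dik), 0.5 * (dik + djk - dij)]
    if any(l < 0 for l in lens):
        clamped = True
    for node_idx, l in zip((i, j, k), lens):
        nodes[node_idx].length = max(l, 0.0)
    if clamped:
        warnings.warn("negative branch lengths clamped to 0", stacklevel=2)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root=root)


def bootstrap_support(
    seqs: Sequence[SeqRecord],
    n_reps: int = 1000,
    seed: int | None = None,
    deletion: str = "pairwise",
) -> PhyloTree:
    """Neighbour-joining tree with column-resampling bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of each internal edge of the point-estimate tree is the
    percentage of replicate trees containing the same bipartition.
    """
    if len(seqs) < 4:
        raise ValueError("bootstrap_support requires ≥4 sequences")
    if n_reps < 1:
        raise ValueError("n_reps must be ≥1")
    lengths = {len(r) for r in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal lengths)")
    length = lengths.pop()
    point = nj_tree(distance_matrix(seqs, deletion=deletion))
    counts: dict[frozenset[str], int] = {split: 0 for split in point.splits()}
    rng = np.random.default_rng(seed)
    cols = _site_arrays([r.residues for r in seqs])
    for _ in range(n_reps):
        pick = rng.integers(0, length, size=length)
        resampled = ["".join(row) for row in cols[:, pick]]
        rep_seqs = [replace(r, residues=s) for r, s in zip(seqs, resampled)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep_tree = nj_tree(distance_matrix(rep_seqs, deletion=deletion))
        for split in rep_tree.splits():
            if split in counts:
                counts[split] += 1

    all_leaves = point.leaf_names

    def annotate(node: TreeNode) -> frozenset[str]:
        if node.is_leaf():
            return frozenset((node.name,))
        below = frozenset().union(*(annotate(ch) for ch in node.children))
        if 2 <= len(below) <= len(all_leaves) - 2:
            split = min(below, all_leaves - below, key=lambda s: (len(s), sorted(s)))
            node.support = 100.0 * counts.get(split, 0) / n_reps
        return below

    annotate(point.root)
    return point
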