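"""Readers, writers and the pipeline driver.

File formats are the field's plain-text standards: FASTA for sequences
(via Biopython), CSV/TSV for specimens, labels and reports (via pandas),
JSON for keys and configuration, newick for trees (written from our own
tree structure; parsed through dendropy).  Reports use 1-based coordinates
where positions appear; internal indices are 0-based.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from monotax.key import CharacterValue, TaxonomicKey, identify, load_bundled_key
from monotax.morphometrics import (
    MISSING_MARK,
    SpecimenMeasurements,
    indices_table,
)
from monotax.seqdist import (
    DistanceMatrix,
    DivergenceSummary,
    PhyloTree,
    SeqRecord,
    TreeNode,
    bootstrap_support,
    conspecificity_flags,
    distance_matrix,
    group_divergence,
    nj_tree,
    trim_alignment,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "read_specimens",
    "write_specimens",
    "read_evidence",
    "write_newick",
    "read_newick",
    "divergence_table",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read sequences; ids preserved, wrapped lines joined, case and U→T
    normalised.  Duplicate ids and illegal characters raise ValueError."""
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SeqRecord(seq_id=rec.id, residues=str(rec.seq)))
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    bio = [BioSeqRecord(Seq(r.residues), id=r.seq_id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_labels(path: str | Path) -> dict[str, tuple[str, str]]:
    """Label map CSV with columns seq_id, species, genus."""
    df = pd.read_csv(path, dtype=str)
    required = {"seq_id", "species", "genus"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"label map missing columns: {sorted(missing)}")
    return {r.seq_id: (r.species, r.genus) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# specimens CSV

_NUMERIC_COLUMNS = (
    "body_length", "tail_length", "pharynx_length", "max_body_diameter",
    "body_diameter_at_anus", "vulva_distance", "anterior_gonad_length",
    "posterior_gonad_length", "buccal_capsule_length", "buccal_capsule_width",
    "tooth_apex_distance", "lip_region_width", "rectum_length",
)
_MISSING_TOKENS = {"", "-", MISSING_MARK, "na", "NA", "nan", "NaN", None}


def _parse_cell(raw, row: int, column: str) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text in _MISSING_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise ValueError(f"row {row}, column {column!r}: not a number: {text!r}") from None


def read_specimens(path: str | Path) -> list[SpecimenMeasurements]:
    """Specimen CSV, one row per specimen, canonical column names, values
    in µm.  En-dash/empty cells parse to missing; unknown numeric columns
    are carried in the open ``extra`` map."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "specimen_id" not in df.columns or "body_length" not in df.columns:
        raise ValueError("specimen CSV requires specimen_id and body_length columns")
    known = set(_NUMERIC_COLUMNS) | {"specimen_id", "taxon_label"}
    out: list[SpecimenMeasurements] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        record = row._asdict()
        fields = {
            col: _parse_cell(record.get(col), i, col) for col in _NUMERIC_COLUMNS
        }
        if fields["body_length"] is None:
            raise ValueError(f"row {i}: body_length is required")
        extra = {
            col: v
            for col in df.columns
            if col not in known
            and (v := _parse_cell(record.get(col), i, col)) is not None
        }
        out.append(
            SpecimenMeasurements(
                specimen_id=str(record["specimen_id"]),
                taxon_label=str(record.get("taxon_label") or "") or None,
                extra=extra,
                **fields,
            )
        )
    return out


def write_specimens(specimens: Iterable[SpecimenMeasurements], path: str | Path) -> None:
    rows = []
    for m in specimens:
        row = {"specimen_id": m.specimen_id, "taxon_label": m.taxon_label or ""}
        for col in _NUMERIC_COLUMNS:
            v = getattr(m, col)
            row[col] = "" if v is None else v
        row.update(m.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_evidence(path: str | Path, key: TaxonomicKey) -> list[CharacterValue]:
    """Evidence CSV with columns char_id, value; a value is a number, a
    closed range ``lo-hi`` (or ``lo–hi``), or a qualitative state."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "char_id" not in df.columns or "value" not in df.columns:
        raise ValueError("evidence CSV requires char_id and value columns")
    out: list[CharacterValue] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        char_id, raw = row.char_id.strip(), row.value.strip()
        cdef = key.characters.get(char_id)
        if cdef is not None and cdef.kind == "qualitative":
            out.append(CharacterValue(char_id, raw))
            continue
        for dash in ("–", ".."):
            raw = raw.replace(dash, "-")
        parts = raw.split("-")
        try:
            if len(parts) == 2 and parts[0]:
                out.append(CharacterValue(char_id, (float(parts[0]), float(parts[1]))))
            else:
                out.append(CharacterValue(char_id, float(raw)))
        except ValueError:
            raise ValueError(f"row {i}: cannot parse value {row.value!r} for {char_id!r}") from None
    return out


# ---------------------------------------------------------------------------
# newick

def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n", encoding="utf-8")


def read_newick(source: str | Path) -> PhyloTree:
    """Parse newick (file path or literal string) into a :class:`PhyloTree`;
    internal node labels are read as bootstrap supports."""
    text = source if isinstance(source, str) and source.strip().endswith(";") else Path(source).read_text()
    dtree = dendropy.Tree.get(data=text, schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            support=float(dnode.label) if (dnode.label and not dnode.taxon) else None,
        )
        node.children = [convert(ch) for ch in dnode.child_nodes()]
        return node

    return PhyloTree(root=convert(dtree.seed_node))


# ---------------------------------------------------------------------------
# reports and pipeline

def divergence_table(summaries: Sequence[DivergenceSummary]) -> pd.DataFrame:
    """Divergence tiers as a table: differences (nt) and p-distance (%)
    ranges per comparison group."""
    def rng(lo, hi, decimals=None):
        f = (lambda x: f"{x:.1f}") if decimals else (lambda x: str(int(x)))
        return f(lo) if lo == hi else f"{f(lo)}–{f(hi)}"

    return pd.DataFrame(
        {
            "Divergence": [s.tier for s in summaries],
            "Taxa": [s.label for s in summaries],
            "n pairs": [s.n_pairs for s in summaries],
            "Differences (nt)": [rng(s.nt_min, s.nt_max) for s in summaries],
            "p-distance (%)": [rng(s.pct_min, s.pct_max, 1) for s in summaries],
        }
    )


@dataclass
class PipelineConfig:
    """Everything one run needs; all randomness flows from ``seed``."""

    out_dir: str | Path = "monotax_out"
    specimens_csv: str | Path | None = None
    fasta: str | Path | None = None
    labels_csv: str | Path | None = None
    key_name: str = "mononchus"
    deletion: str = "pairwise"  # pairwise | complete
    rounding: str = "away"  # away | even
    trim: bool = False
    bootstrap_reps: int = 0
    seed: int = 0
    exclude: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.seed < 0 or self.bootstrap_reps < 0:
            raise ValueError("seed and bootstrap_reps must be non-negative")
        if self.deletion not in ("pairwise", "complete"):
            raise ValueError(f"unknown deletion mode {self.deletion!r}")
        if self.rounding not in ("away", "even"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")


def _measurement_evidence(m: SpecimenMeasurements) -> list[CharacterValue]:
    """Quantitative key evidence derivable from raw measurements alone."""
    from monotax.morphometrics import compute_indices

    idx = compute_indices(m)
    pairs: dict[str, float | None] = {
        "body_length": idx.L,
        "c": idx.c,
        "c_prime": idx.c_prime,
        "bc_ratio": idx.bc_ratio,
        "tooth_position": idx.tooth_position,
        "tail_length": m.tail_length,
        "buccal_capsule_length": m.buccal_capsule_length,
        "lip_region_width": m.lip_region_width,
        "rectum_length": m.rectum_length,
    }
    if m.buccal_capsule_length is not None and m.lip_region_width is not None:
        pairs["buccal_vs_labial"] = m.buccal_capsule_length / m.lip_region_width
    return [CharacterValue(c, float(v)) for c, v in pairs.items() if v is not None]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the stages for which inputs exist, write the report bundle,
    and return a summary dict.

    Morphometrics: indices table per taxon group plus a per-specimen
    identification report against the configured key.  Sequences: distance
    matrix, divergence tiers, conspecificity/misplacement flags (reference
    band = the observed interspecific tier), and an NJ tree (bootstrapped
    when ``bootstrap_reps`` > 0).  A provenance log records parameters.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": []}

    try:
        if config.specimens_csv is not None:
            specimens = read_specimens(config.specimens_csv)
            table = indices_table(specimens)
            table.to_csv(out_dir / "indices.tsv", sep="\t")
            key = load_bundled_key(config.key_name)
            id_rows = []
            for m in specimens:
                res = identify(key, _measurement_evidence(m), sex="female")
                id_rows.append(
                    {
                        "specimen_id": m.specimen_id,
                        "status": res.status,
                        "candidates": "; ".join(sorted(res.candidates)),
                    }
                )
            pd.DataFrame(id_rows).to_csv(out_dir / "identification.tsv", sep="\t", index=False)
            summary["stages"].append("morphometrics")
            summary["n_specimens"] = len(specimens)

        if config.fasta is not None:
            seqs = read_fasta(config.fasta)
            if config.trim:
                seqs = trim_alignment(seqs)
            dm = distance_matrix(seqs, deletion=config.deletion)
            pd.DataFrame(dm.p_dist, index=dm.ids, columns=dm.ids).to_csv(
                out_dir / "p_distances.tsv", sep="\t"
            )
            if config.labels_csv is not None:
                labels = read_labels(config.labels_csv)
                summaries = group_divergence(dm, labels, exclude=config.exclude)
                divergence_table(summaries).to_csv(
                    out_dir / "divergence.tsv", sep="\t", index=False
                )
                inter = [s for s in summaries if s.tier == "interspecific"]
                if inter:
                    ref_min = min(s.pct_min for s in inter)
                    ref_max = max(s.pct_max for s in inter)
                    flags = conspecificity_flags(
                        [s for s in summaries if s.tier != "interspecific"], ref_min, ref_max
                    )
                    pd.DataFrame([dataclasses.asdict(f) for f in flags]).to_csv(
                        out_dir / "flags.tsv", sep="\t", index=False
                    )
                    summary["n_flags"] = len(flags)
            if len(seqs) >= 3:
                if config.bootstrap_reps > 0 and len(seqs) >= 4:
                    tree = bootstrap_support(
                        seqs, n_reps=config.bootstrap_reps, seed=config.seed,
                        deletion=config.deletion,
                    )
                else:
                    tree = nj_tree(dm)
                write_newick(tree, out_dir / "nj_tree.nwk")
            summary["stages"].append("seqdist")
            summary["n_sequences"] = len(seqs)
    except Exception as exc:  # pragma: no cover - re-raised with stage context
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    import monotax

    provenance = {
        "monotax_version": monotax.__version__,
        "python": sys.version.split()[0],
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    summary["out_dir"] = str(out_dir)
    return summary
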