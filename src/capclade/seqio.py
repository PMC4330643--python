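"""Readers and writers for the formats the pipeline touches.

FASTA sequences, Newick and NEXUS trees/alignments, and the TSV report
tables all pass through this module, which also serves the packaged
reference data: the murine eIF4E sequence (1L8B numbering), the LG/WAG/JTT
substitution-model data and BLOSUM62.

Coordinate convention: everything written to or read from a file is
1-based; in memory all coordinates are 0-based half-open.  The conversion
happens here and nowhere else.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

GROUPS = (
    "core_dino",
    "syndinean",
    "perkinsus",
    "apicomplexan",
    "ciliate",
    "heterokont",
    "reference",
    "other",
)

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class SeqRecord:
    """One surveyed protein: id, species, taxonomic group and residues.

    ``residues`` is an uppercase, ungapped amino-acid string over the 20
    standard letters plus X for unknown.
    """

    id: str
    species: str = ""
    group: str = "other"
    residues: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r} for {self.id}")
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise ValueError(
                f"sequence {self.id}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def _record_from_header(header: str, residues: str) -> SeqRecord:
    # Header convention: "id|species|group"; missing fields default to
    # species="" and group="other".
    parts = header.split("|")
    sid = parts[0].strip()
    species = parts[1].strip() if len(parts) > 1 else ""
    group = parts[2].strip().split()[0] if len(parts) > 2 else "other"
    if group not in GROUPS:
        group = "other"
    return SeqRecord(id=sid, species=species, group=group, residues=residues)


def read_fasta(path, metadata: pd.DataFrame | None = None) -> list[SeqRecord]:
    """Read a protein FASTA into :class:`SeqRecord` objects.

    Headers follow the ``id|species|group`` convention; a sidecar metadata
    table (columns id, species, group) overrides header-derived fields.
    A single terminal ``*`` is stripped; any other non-amino-acid character
    raises.  Duplicate ids raise, naming the offender.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if residues.endswith("*"):
            residues = residues[:-1]
        header = rec.description or rec.id
        sr = _record_from_header(header, residues)
        if sr.id in seen:
            raise ValueError(f"duplicate sequence id {sr.id!r} in {path}")
        seen.add(sr.id)
        records.append(sr)
    if metadata is not None:
        meta = metadata.set_index("id")
        out = []
        for sr in records:
            if sr.id in meta.index:
                row = meta.loc[sr.id]
                sr = SeqRecord(
                    id=sr.id,
                    species=str(row.get("species", sr.species)),
                    group=str(row.get("group", sr.group)),
                    residues=sr.residues,
                )
            out.append(sr)
        records = out
    return records


def write_fasta(records, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}|{r.species}|{r.group}\n")
            for i in range(0, len(r.residues), width):
                fh.write(r.residues[i : i + width] + "\n")


def read_metadata_tsv(path) -> pd.DataFrame:
    """Sidecar id -> species, group table (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "species", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata table missing column(s) {sorted(missing)}")
    return df


# --- trees ----------------------------------------------------------------

TAXON_NAMESPACE_KW = dict(suppress_internal_node_taxa=True)


def read_newick(text_or_path) -> dendropy.Tree:
    """Parse Newick into a dendropy Tree.

    Internal node labels are interpreted as bootstrap support on [0, 100]
    and stored both as ``node.label`` and ``edge.support``; absent branch
    lengths default to 0.
    """
    src = str(text_or_path)
    if "(" in src and ";" in src:
        data = src
    else:
        data = Path(text_or_path).read_text()
    tree = dendropy.Tree.get(
        data=data,
        schema="newick",
        suppress_internal_node_taxa=True,
    )
    for node in tree:
        if node.edge.length is None:
            node.edge.length = 0.0
        if not node.is_leaf() and node.label is not None:
            try:
                node.edge.support = float(node.label)
            except ValueError:
                pass
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_nexus(path, require: tuple[str, ...] = ()):
    """Read a NEXUS file, returning ``(alignment_rows, trees)``.

    ``alignment_rows`` is a list of ``(id, gapped_string)`` pairs from the
    DATA/CHARACTERS block; ``trees`` is a list of dendropy Trees with
    TRANSLATE tables resolved.  ``require`` may name blocks ("matrix",
    "trees") whose absence is an error.  Square-bracket comments are
    tolerated anywhere (TreeBase dialect).
    """
    ds = dendropy.DataSet.get(path=str(path), schema="nexus")
    rows: list[tuple[str, str]] = []
    for matrix in ds.char_matrices:
        for taxon in matrix:
            rows.append((taxon.label, str(matrix[taxon])))
    trees: list[dendropy.Tree] = []
    for tl in ds.tree_lists:
        trees.extend(tl)
    if "matrix" in require and not rows:
        raise ValueError(f"{path}: NEXUS file has no DATA/CHARACTERS block")
    if "trees" in require and not trees:
        raise ValueError(f"{path}: NEXUS file has no TREES block")
    return rows, trees


# --- packaged reference data ---------------------------------------------


def _data_text(name: str) -> str:
    return resources.files("capclade.data").joinpath(name).read_text()


def murine_reference() -> SeqRecord:
    """The murine eIF4E sequence in 1L8B numbering (position = index + 1)."""
    fh = io.StringIO(_data_text("murine_eif4e.faa"))
    rec = next(SeqIO.parse(fh, "fasta"))
    residues = str(rec.seq).upper()
    return SeqRecord(
        id="murine_eIF4E", species="Mus_musculus", group="reference",
        residues=residues,
    )


def load_paml_matrix(name: str):
    """Load a PAML-format amino-acid model file (lg, wag, jtt).

    Returns ``(S, pi)``: the symmetric 20x20 exchangeability matrix and the
    model equilibrium frequencies, both in ARNDCQEGHILKMFPSTWYV order.
    """
    lines = [ln for ln in _data_text(f"{name.lower()}.dat").splitlines() if ln.strip()]
    S = np.zeros((20, 20))
    for i, ln in enumerate(lines[:19], start=1):
        vals = [float(x) for x in ln.split()]
        S[i, : len(vals)] = vals
    S = S + S.T
    pi = np.array([float(x) for x in lines[19].split()])
    pi = pi / pi.sum()
    return S, pi


def blosum62(x_scores_zero: bool = True):
    """BLOSUM62 as a biopython substitution matrix.

    With ``x_scores_zero`` the X (unknown residue) row and column are set
    to 0 so X is neutral in every comparison.
    """
    m = substitution_matrices.load("BLOSUM62")
    if x_scores_zero:
        m = m.copy()
        for a in m.alphabet:
            m["X", a] = 0.0
            m[a, "X"] = 0.0
    return m
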