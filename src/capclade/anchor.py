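"""Reference-anchored alignment to the murine eIF4E core.

Every surveyed sequence is aligned pairwise (global, free end gaps) to the
murine reference, giving each residue either a murine 1L8B position or an
insertion code.  Sequences are then trimmed to the core window — five
residues upstream of W43 through ten residues downstream of W166, i.e.
murine 38..176, 139 positions — and stacked into a column-consistent
multiple alignment whose column semantics are exactly the murine numbering.

This replaces a simultaneous multiple alignment: it is deterministic and
makes downstream per-position statistics unambiguous, at the cost of
carrying insertions as per-row annotations rather than alignment columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from . import seqio
from .search import SearchParams, _aligner
from .seqio import SeqRecord

CORE_START = 43 - 5    # murine position, inclusive
CORE_END = 166 + 10    # murine position, inclusive
CORE_LENGTH = CORE_END - CORE_START + 1   # 139 columns


@dataclass(frozen=True)
class ReferenceAnchors:
    """Murine anchor positions and the derived core/insertion windows."""

    anchors: tuple[int, ...] = (43, 46, 56, 73, 102, 103, 112, 130, 157, 162, 166)
    core_start: int = CORE_START
    core_end: int = CORE_END
    insertion_windows: tuple[tuple[int, int], ...] = ((73, 102), (130, 166))

    def __post_init__(self):
        if list(self.anchors) != sorted(set(self.anchors)):
            raise ValueError("anchors must be strictly increasing")


# A map entry is ("M", murine_pos) for a matched residue or
# ("I", after_position, offset) for the offset-th inserted residue after
# that murine position (offset starts at 1).
MapEntry = tuple


@dataclass
class AnchoredAlignment:
    """A sequence with its murine-position map.

    ``residues[i]`` corresponds to ``mapping[i]``.  ``cterm_extension`` is
    the number of residues of the untrimmed sequence lying beyond murine
    position 176; ``partial`` flags alignments covering less than half the
    core window.
    """

    seq_id: str
    residues: str
    mapping: list[MapEntry]
    score: float = 0.0
    partial: bool = False
    cterm_extension: int = 0

    def __post_init__(self):
        if len(self.residues) != len(self.mapping):
            raise ValueError("mapping and residues length mismatch")

    def position_of(self, murine_pos: int) -> int | None:
        """Sequence index (0-based) mapped to a murine position, or None."""
        for i, entry in enumerate(self.mapping):
            if entry[0] == "M" and entry[1] == murine_pos:
                return i
        return None

    def insertions(self) -> list[tuple[int, str]]:
        """Contiguous insertion segments as (after_position, segment)."""
        segs: list[tuple[int, str]] = []
        cur_after, cur = None, []
        for res, entry in zip(self.residues, self.mapping):
            if entry[0] == "I":
                after = entry[1]
                if cur_after == after:
                    cur.append(res)
                else:
                    if cur:
                        segs.append((cur_after, "".join(cur)))
                    cur_after, cur = after, [res]
            else:
                if cur:
                    segs.append((cur_after, "".join(cur)))
                    cur_after, cur = None, []
        if cur:
            segs.append((cur_after, "".join(cur)))
        return segs


def align_to_reference(
    seq: SeqRecord,
    reference: SeqRecord | None = None,
    params: SearchParams | None = None,
) -> AnchoredAlignment:
    """Globally align a sequence to the murine reference with free end gaps
    and derive its murine-numbering map."""
    reference = reference or seqio.murine_reference()
    params = params or SearchParams()
    aligner = _aligner(params, mode="global")
    aln = next(iter(aligner.align(reference.residues, seq.residues)))
    ref_row, seq_row = str(aln[0]), str(aln[1])

    mapping: list[MapEntry] = []
    residues: list[str] = []
    ref_pos = 0           # last murine position consumed (1-based)
    ins_offset = 0
    for rc, sc in zip(ref_row, seq_row):
        if rc != "-":
            ref_pos += 1
            ins_offset = 0
        if sc == "-":
            continue
        residues.append(sc)
        if rc != "-":
            mapping.append(("M", ref_pos))
        else:
            ins_offset += 1
            mapping.append(("I", ref_pos, ins_offset))

    core_mapped = sum(
        1 for e in mapping if e[0] == "M" and CORE_START <= e[1] <= CORE_END
    )
    last_in_core = -1
    for i, e in enumerate(mapping):
        if e[0] == "M" and e[1] <= CORE_END:
            last_in_core = i
    cterm = len(residues) - (last_in_core + 1) if last_in_core >= 0 else 0
    return AnchoredAlignment(
        seq_id=seq.id,
        residues="".join(residues),
        mapping=mapping,
        score=float(aln.score),
        partial=core_mapped < CORE_LENGTH / 2,
        cterm_extension=cterm,
    )


def trim_core(a: AnchoredAlignment, anchors: ReferenceAnchors | None = None) -> AnchoredAlignment:
    """Restrict an anchored alignment to the murine core window.

    Match residues at murine ``core_start..core_end`` are kept, as are
    insertions whose after-position lies in ``[core_start, core_end)``.
    """
    anchors = anchors or ReferenceAnchors()
    lo, hi = anchors.core_start, anchors.core_end
    keep_res, keep_map = [], []
    for res, entry in zip(a.residues, a.mapping):
        if entry[0] == "M" and lo <= entry[1] <= hi:
            keep_res.append(res)
            keep_map.append(entry)
        elif entry[0] == "I" and lo <= entry[1] < hi:
            keep_res.append(res)
            keep_map.append(entry)
    if not keep_map:
        raise ValueError(f"{a.seq_id}: no core domain (nothing maps to {lo}..{hi})")
    return AnchoredAlignment(
        seq_id=a.seq_id,
        residues="".join(keep_res),
        mapping=keep_map,
        score=a.score,
        partial=a.partial,
        cterm_extension=a.cterm_extension,
    )


@dataclass
class MultiAlignment:
    """Core-window alignment stacked by murine position.

    ``matrix[i][j]`` is row i's residue at murine position
    ``core_start + j`` ('-' when unmapped); insertions are carried per row
    as (after_position, segment) records and take no columns.
    """

    ids: list[str]
    matrix: list[str]
    insertions: dict[str, list[tuple[int, str]]]
    core_start: int = CORE_START

    @property
    def n_columns(self) -> int:
        return len(self.matrix[0]) if self.matrix else 0

    def row(self, seq_id: str) -> str:
        return self.matrix[self.ids.index(seq_id)]

    def column(self, murine_pos: int) -> str:
        j = murine_pos - self.core_start
        if not (0 <= j < self.n_columns):
            raise ValueError(f"murine position {murine_pos} outside core window")
        return "".join(row[j] for row in self.matrix)


def stack_alignment(
    alignments: list[AnchoredAlignment],
    anchors: ReferenceAnchors | None = None,
) -> MultiAlignment:
    """Stack trimmed anchored alignments into a MultiAlignment."""
    anchors = anchors or ReferenceAnchors()
    lo, hi = anchors.core_start, anchors.core_end
    ncol = hi - lo + 1
    ids, matrix, insertions = [], [], {}
    for a in alignments:
        if a.seq_id in insertions:
            raise ValueError(f"duplicate row id {a.seq_id!r}")
        row = ["-"] * ncol
        for res, entry in zip(a.residues, a.mapping):
            if entry[0] == "M" and lo <= entry[1] <= hi:
                row[entry[1] - lo] = res
        ids.append(a.seq_id)
        matrix.append("".join(row))
        insertions[a.seq_id] = [
            (after, seg) for after, seg in a.insertions() if lo <= after < hi
        ]
    return MultiAlignment(ids=ids, matrix=matrix, insertions=insertions, core_start=lo)


def map_position(a: AnchoredAlignment, murine_pos: int) -> str:
    """Residue at a murine core position, or '-' when unmapped."""
    if not (CORE_START <= murine_pos <= CORE_END):
        raise ValueError(f"position {murine_pos} outside core window "
                         f"{CORE_START}..{CORE_END}")
    i = a.position_of(murine_pos)
    return a.residues[i] if i is not None else "-"


def numbering_table(alignments: list[AnchoredAlignment]):
    """Long-format numbering map: seq_id, seq_pos (1-based), murine code."""
    import pandas as pd

    rows = []
    for a in alignments:
        for i, entry in enumerate(a.mapping):
            code = (
                str(entry[1]) if entry[0] == "M" else f"ins:{entry[1]}+{entry[2]}"
            )
            rows.append({"seq_id": a.seq_id, "seq_pos": i + 1, "murine_pos_or_insert_code": code})
    return pd.DataFrame(rows, columns=["seq_id", "seq_pos", "murine_pos_or_insert_code"])


def write_stacked_fasta(m: MultiAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, row in zip(m.ids, m.matrix):
            fh.write(f">{sid}\n{row}\n")
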