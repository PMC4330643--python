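"""Diagnostic residue annotation and rule-based clade typing.

The cap-binding pocket of eIF4E is defined by a small set of residues in
murine numbering: the aromatic sandwich W56/W102 with E103, the methyl
contact W166 and the charge contacts R112/R157/K162, plus the eIF4G
recognition motif S/TVxxFW ending at W73.  The three dinoflagellate clades
carry characteristic states at these positions (e.g. H112 with long
insertions in clade 1, C112/V162 in clade 2, the canonical W56/R112/K162
set in clade 3) and the metazoan Class II diagnostic is an aromatic loss
at W43.  This module reads those states off an anchored alignment and
applies the rules.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .anchor import AnchoredAlignment, MultiAlignment, ReferenceAnchors

REPORT_ANCHORS = (43, 46, 56, 73, 102, 103, 112, 157, 162, 166)
MOTIF_WINDOW = (68, 73)   # murine positions, inclusive
MOTIF_PATTERN = re.compile(r"^[ST]V..[FWYL][WFYL]$")

VARIANT_CLASSES = ("polar_1a1b", "acidic_1c", "basic_1d", "canonical", "other")
DIAGNOSTIC_LABELS = (
    "clade1_like", "clade2_like", "clade3_like", "metazoan_classII_like",
    "unclassified",
)


@dataclass
class ResidueReport:
    seq_id: str
    states: dict[int, str]                 # anchor position -> residue or '-'
    insertion_lengths: dict[tuple[int, int], int]
    cterm_extension: int = 0


@dataclass
class MotifHit:
    seq_id: str
    hexamer: str                           # '-' for unmapped positions
    matches_consensus: bool
    variant_class: str


@dataclass
class DiagnosticClass:
    seq_id: str
    label: str
    evidence: list[str]


def _window_insertion_length(insertions, window) -> int:
    lo, hi = window
    return sum(len(seg) for after, seg in insertions if lo <= after < hi)


def residue_states(
    m: MultiAlignment | AnchoredAlignment,
    anchors: ReferenceAnchors | None = None,
) -> list[ResidueReport]:
    """One report per row: anchor states, insertion-window lengths and the
    carboxy-terminal extension (the latter only when annotated upstream)."""
    anchors = anchors or ReferenceAnchors()
    if isinstance(m, AnchoredAlignment):
        from .anchor import stack_alignment

        m = stack_alignment([m], anchors)
    reports = []
    for i, sid in enumerate(m.ids):
        row = m.matrix[i]
        states = {}
        for pos in REPORT_ANCHORS:
            j = pos - m.core_start
            states[pos] = row[j] if 0 <= j < len(row) else "-"
        ins = {
            w: _window_insertion_length(m.insertions.get(sid, []), w)
            for w in anchors.insertion_windows
        }
        reports.append(ResidueReport(seq_id=sid, states=states, insertion_lengths=ins))
    return reports


def _charge_class(residue: str) -> str | None:
    if residue in "QN":
        return "polar_1a1b"
    if residue in "DE":
        return "acidic_1c"
    if residue in "KR":
        return "basic_1d"
    return None


def scan_eif4g_motif(m: MultiAlignment, seq_id: str) -> MotifHit:
    """Read the eIF4G-binding hexamer at murine 68..73 and classify it.

    The consensus is [ST]V..[FWYL][WFYL]; the variable third/fourth
    positions split the clade-1 sub-clade flavours: polar (TVQeFW, 1a/1b),
    acidic (TVEEFW, 1c) and basic (TVKgFW, 1d).
    """
    row = m.row(seq_id)
    lo, hi = MOTIF_WINDOW
    hexamer = "".join(
        row[p - m.core_start] if 0 <= p - m.core_start < len(row) else "-"
        for p in range(lo, hi + 1)
    )
    if "-" in hexamer:
        return MotifHit(seq_id, hexamer, False, "other")
    matches = bool(MOTIF_PATTERN.match(hexamer))
    if not matches:
        return MotifHit(seq_id, hexamer, False, "other")
    variant = _charge_class(hexamer[2]) or _charge_class(hexamer[3]) or "canonical"
    return MotifHit(seq_id, hexamer, True, variant)


def classify_diagnostics(
    r: ResidueReport,
    motif: MotifHit | None = None,
    insertion_threshold: int = 5,
) -> DiagnosticClass:
    """Rule-based clade typing from anchor states; first matching rule wins.

    1. Y/F/L at 43 -> metazoan Class II-like (aromatic loss diagnostic).
    2. insertions >= threshold in BOTH windows and H112 -> clade 1-like.
    3. C112 and V/A 162 -> clade 2-like.
    4. W56, R112, K162 and no long window insertions -> clade 3-like.

    Sub-clade resolution (e.g. the R102 of eIF4E-3b) is deliberately left
    to the tree; such states are recorded as evidence only.
    """
    evidence: list[str] = []
    s = r.states
    w1, w2 = sorted(r.insertion_lengths)
    ins1, ins2 = r.insertion_lengths[w1], r.insertion_lengths[w2]

    if s.get(43) in "YFL":
        evidence.append(f"aromatic loss at 43 ({s[43]})")
        return DiagnosticClass(r.seq_id, "metazoan_classII_like", evidence)
    if ins1 >= insertion_threshold and ins2 >= insertion_threshold and s.get(112) == "H":
        evidence.append(f"insertions {ins1}aa in {w1} and {ins2}aa in {w2}")
        evidence.append("H at 112")
        if s.get(56) == "Y":
            evidence.append("Y at 56")
        return DiagnosticClass(r.seq_id, "clade1_like", evidence)
    if s.get(112) == "C" and s.get(162) in "VA":
        evidence.append("C at 112")
        evidence.append(f"{s[162]} at 162")
        return DiagnosticClass(r.seq_id, "clade2_like", evidence)
    if (
        s.get(56) == "W"
        and s.get(112) == "R"
        and s.get(162) == "K"
        and ins1 < insertion_threshold
        and ins2 < insertion_threshold
    ):
        evidence.append("canonical W56/R112/K162, no window insertions")
        if s.get(102) == "R":
            evidence.append("R at 102 (3b-type substitution)")
        return DiagnosticClass(r.seq_id, "clade3_like", evidence)
    return DiagnosticClass(r.seq_id, "unclassified", [])


def annotate_alignment(
    m: MultiAlignment,
    cterm_extensions: dict[str, int] | None = None,
    anchors: ReferenceAnchors | None = None,
) -> pd.DataFrame:
    """Full residues.tsv table: anchor states, insertion lengths, motif and
    diagnostic label for every row of a stacked alignment."""
    anchors = anchors or ReferenceAnchors()
    reports = residue_states(m, anchors)
    rows = []
    for rep in reports:
        if cterm_extensions:
            rep.cterm_extension = cterm_extensions.get(rep.seq_id, 0)
        motif = scan_eif4g_motif(m, rep.seq_id)
        diag = classify_diagnostics(rep, motif)
        row = {"seq_id": rep.seq_id}
        for pos in REPORT_ANCHORS:
            row[f"state_{pos}"] = rep.states[pos]
        for w in anchors.insertion_windows:
            row[f"ins_{w[0]}_{w[1]}"] = rep.insertion_lengths[w]
        row["cterm_extension"] = rep.cterm_extension
        row["motif_hexamer"] = motif.hexamer
        row["motif_matches"] = motif.matches_consensus
        row["variant_class"] = motif.variant_class
        row["diagnostic_label"] = diag.label
        row["evidence"] = ";".join(diag.evidence)
        rows.append(row)
    return pd.DataFrame(rows)
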