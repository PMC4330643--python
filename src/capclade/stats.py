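"""Row-composition bias tests, identity/variability summaries and logos.

The composition test follows the Tree-Puzzle convention: each alignment
row's amino-acid counts are compared by chi-squared against expected
counts under the alignment-wide (pooled, gap-free) frequencies.  Logo
information content uses the Schneider small-sample correction
e_n = 19 / (2 ln2 n).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .anchor import MultiAlignment
from .seqio import AMINO_ACIDS

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
MAX_BITS = math.log2(20)


@dataclass
class CompositionTest:
    seq_id: str
    chi2: float
    df: int
    p_value: float
    flagged: bool


def _counts(row: str) -> np.ndarray:
    c = np.zeros(20)
    for ch in row:
        i = _AA_INDEX.get(ch)
        if i is not None:
            c[i] += 1
    return c


def composition_chi2(m: MultiAlignment, alpha: float = 0.05) -> list[CompositionTest]:
    """Per-row composition chi-squared against pooled frequencies.

    Gaps (and X) are excluded everywhere.  Expected cells below 1 are
    pooled into one "rare" cell before the statistic, with df reduced
    accordingly; df = (#cells) - 1.  Rows with no residues are skipped
    with a warning.
    """
    if len(m.ids) < 2:
        raise ValueError("composition test needs >= 2 rows")
    per_row = np.stack([_counts(r) for r in m.matrix])
    pooled = per_row.sum(axis=0)
    f = pooled / pooled.sum()
    present = f > 0

    out = []
    for sid, counts in zip(m.ids, per_row):
        n_i = counts.sum()
        if n_i == 0:
            warnings.warn(f"row {sid!r} has no residues; composition test skipped")
            continue
        expected = n_i * f[present]
        observed = counts[present]
        rare = expected < 1.0
        if rare.any():
            obs_cells = np.append(observed[~rare], observed[rare].sum())
            exp_cells = np.append(expected[~rare], expected[rare].sum())
        else:
            obs_cells, exp_cells = observed, expected
        keep = exp_cells > 0
        obs_cells, exp_cells = obs_cells[keep], exp_cells[keep]
        chi2 = float(((obs_cells - exp_cells) ** 2 / exp_cells).sum())
        df = max(len(exp_cells) - 1, 1)
        p = float(chi2_dist.sf(chi2, df))
        out.append(CompositionTest(seq_id=sid, chi2=chi2, df=df,
                                   p_value=p, flagged=p < alpha))
    return out


def percent_identity(row_a: str, row_b: str) -> float:
    """100 x matches / mutually-non-gap columns (X counts as a residue)."""
    pairs = [(a, b) for a, b in zip(row_a, row_b) if a != "-" and b != "-"]
    if not pairs:
        raise ValueError("no mutually non-gap columns")
    matches = sum(1 for a, b in pairs if a == b)
    return 100.0 * matches / len(pairs)


def whole_sequence_identity(seq_a: str, seq_b: str, params=None) -> float:
    """Identity over a free-end-gap global alignment of the untrimmed
    sequences (the 'across the entire sequence' mode)."""
    from .search import SearchParams, _aligner

    aligner = _aligner(params or SearchParams(), mode="global")
    aln = next(iter(aligner.align(seq_a, seq_b)))
    return percent_identity(str(aln[0]), str(aln[1]))


def column_variability(rows: list[str]) -> float:
    """Percent of comparable columns (>= 2 non-gap residues) holding >= 2
    distinct residues."""
    if len(rows) < 2:
        raise ValueError("need >= 2 rows")
    ncol = len(rows[0])
    comparable = variable = 0
    for j in range(ncol):
        col = [r[j] for r in rows if r[j] != "-"]
        if len(col) >= 2:
            comparable += 1
            if len(set(col)) >= 2:
                variable += 1
    if comparable == 0:
        return 0.0
    return 100.0 * variable / comparable


@dataclass
class LogoMatrix:
    """Per-column information content and letter heights, in bits."""

    positions: list[int]           # murine positions
    information: np.ndarray        # R per column
    heights: np.ndarray            # (ncol, 20) letter heights
    n_nongap: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.heights, columns=list(AMINO_ACIDS))
        df.insert(0, "murine_pos", self.positions)
        df.insert(1, "R_bits", self.information)
        df.insert(2, "n_nongap", self.n_nongap)
        return df


def logo_matrix(rows: list[str], core_start: int = 38) -> LogoMatrix:
    """Sequence-logo information content per column.

    R = max(0, log2 20 - H - e_n) with H the Shannon entropy of the
    non-gap residue frequencies and e_n = 19/(2 ln2 n) the small-sample
    correction; letter heights are p_a * R.
    """
    if not rows:
        raise ValueError("need >= 1 row")
    ncol = len(rows[0])
    R = np.zeros(ncol)
    heights = np.zeros((ncol, 20))
    n_nongap = np.zeros(ncol, dtype=int)
    for j in range(ncol):
        col = [r[j] for r in rows if r[j] != "-" and r[j] in _AA_INDEX]
        n = len(col)
        n_nongap[j] = n
        if n == 0:
            continue
        counts = _counts("".join(col))
        p = counts / n
        nz = p > 0
        H = float(-(p[nz] * np.log2(p[nz])).sum())
        e_n = 19.0 / (2.0 * math.log(2) * n)
        Rj = max(0.0, MAX_BITS - H - e_n)
        R[j] = Rj
        heights[j] = p * Rj
    positions = list(range(core_start, core_start + ncol))
    return LogoMatrix(positions=positions, information=R,
                      heights=heights, n_nongap=n_nongap)


def plot_logo(logo: LogoMatrix, path, title: str = "") -> None:
    """Minimal stacked-bar rendering of a logo matrix (one bar per column,
    segments in increasing height order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(logo.positions) / 8), 2.5))
    for j, pos in enumerate(logo.positions):
        bottom = 0.0
        order = np.argsort(logo.heights[j])
        for i in order:
            h = logo.heights[j, i]
            if h <= 0:
                continue
            ax.bar(pos, h, bottom=bottom, width=0.9)
            bottom += h
    ax.set_xlabel("murine position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, MAX_BITS)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def composition_table(tests: list[CompositionTest]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"seq_id": t.seq_id, "chi2": t.chi2, "df": t.df,
          "p_value": t.p_value, "flagged": t.flagged} for t in tests]
    )


def identity_table(m: MultiAlignment) -> pd.DataFrame:
    """Long-format pairwise core identities for all row pairs."""
    rows = []
    for i in range(len(m.ids)):
        for j in range(i + 1, len(m.ids)):
            try:
                pid = percent_identity(m.matrix[i], m.matrix[j])
            except ValueError:
                continue
            rows.append({"id_a": m.ids[i], "id_b": m.ids[j],
                         "percent_identity": pid})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "percent_identity"])
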