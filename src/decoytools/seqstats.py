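"""Per-position statistics over decoy sequence populations.

Frequency matrices, top-vs-population enrichment differences, Shannon
information content for logo plots, and per-residue substitution-matrix
(e.g. BLOSUM62) scoring of one design against its reference sequence.

The alphabet is the 20 standard amino acids in alphabetical order
(``ACDEFGHIKLMNPQRSTVWY``); gaps count as mutations elsewhere in the
library but are by default excluded from frequency normalisation (each
position is normalised over its non-gap observations; an optional gap
column can be requested).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import (AA_ALPHABET, GAP, DesignTable, FrequencyMatrix,
                         ReferenceSequence, get_sequence, sequence_column)


def sequence_frequencies(table: DesignTable, chain: str,
                         include_gap: bool = False) -> FrequencyMatrix:
    """Per-position relative residue frequencies of a population.

    Cell (i, a) is the count of letter ``a`` at position ``i`` divided by
    the number of non-gap observations there (or by all observations when
    ``include_gap``).  Positions are reference-numbered via the table's
    shift for the chain; all-gap positions come back as all-zero rows and
    are flagged in ``empty_positions``.
    """
    col = table.sequence_column(chain)
    seqs = table[col].astype(str).tolist()
    if not seqs:
        raise ValueError("empty table")
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"ragged sequences for chain {chain}: "
                         f"lengths {sorted(lengths)}")
    length = lengths.pop()
    shift = table.sequence_shift(chain)
    letters = list(AA_ALPHABET) + ([GAP] if include_gap else [])
    arr = np.array([list(s) for s in seqs])
    counts = np.zeros((length, len(letters)))
    for j, letter in enumerate(letters):
        counts[:, j] = (arr == letter).sum(axis=0)
    totals = counts.sum(axis=1)
    empty = [shift + i for i in range(length) if totals[i] == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    df = pd.DataFrame(freq, columns=letters,
                      index=range(shift, shift + length))
    return FrequencyMatrix(df, kind="frequency",
                           reference=table.references.get(chain),
                           empty_positions=empty)


def enrichment_difference(top: FrequencyMatrix,
                          population: FrequencyMatrix) -> FrequencyMatrix:
    """Cellwise ``top - population`` difference matrix (rows sum to 0)."""
    return top - population


def overrepresented(diff: FrequencyMatrix,
                    threshold: float = 0.20) -> list[tuple[int, str]]:
    """Positions whose maximal enrichment exceeds ``threshold``.

    For each selected position the argmax letter is reported, i.e. the
    residue type overrepresented in the top fraction by more than the
    threshold (the customary 20% rule is ``threshold=0.20``).
    """
    if diff.kind != "difference":
        raise ValueError("expected a difference matrix")
    out = []
    for pos, row in diff.df.iterrows():
        if row.max() > threshold:
            out.append((int(pos), str(row.idxmax())))
    return out


def information_content(fm: FrequencyMatrix,
                        small_sample_n: int | None = None) -> pd.Series:
    """Per-position information content in bits (Schneider-Stephens logos).

    ``bits(i) = log2(20) - H(i)`` with ``H`` the Shannon entropy over
    non-zero cells.  No small-sample correction is applied unless a
    population size is given via ``small_sample_n`` (correction
    ``e(n) = (s - 1) / (2 ln 2 n)``).  All-zero rows (no observations) are
    excluded from the result.
    """
    if fm.kind != "frequency":
        raise ValueError("information content requires a frequency matrix")
    s = len(fm.df.columns)
    # gap column (if any) does not enlarge the alphabet for max entropy
    max_bits = math.log2(len([c for c in fm.df.columns if c != GAP]))
    correction = 0.0
    if small_sample_n:
        correction = (s - 1) / (2 * math.log(2) * small_sample_n)
    bits = {}
    for pos, row in fm.df.iterrows():
        values = row.to_numpy(dtype=float)
        total = values.sum()
        if total <= 0:
            continue  # no observations
        p = values[values > 0]
        entropy = float(-(p * np.log2(p)).sum())
        bits[pos] = max(max_bits - entropy - correction, 0.0)
    return pd.Series(bits, name="bits")


def letter_heights(fm: FrequencyMatrix,
                   small_sample_n: int | None = None) -> pd.DataFrame:
    """Logo letter heights: frequency times the position's bits."""
    bits = information_content(fm, small_sample_n=small_sample_n)
    heights = fm.df.loc[bits.index].mul(bits, axis=0)
    return heights


# ---------------------------------------------------------------------------
# substitution-matrix scoring
# ---------------------------------------------------------------------------

@dataclass
class PositionScoreTrack:
    """Per-position substitution score of a design against its reference.

    ``scores`` holds NaN wherever either sequence has a gap or a
    non-standard letter (positional lookup only; no alignment, no gap
    penalties).
    """
    positions: np.ndarray
    scores: np.ndarray
    matrix: str
    query_id: str
    reference_id: str

    def as_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.positions,
                         name=f"{self.matrix}({self.query_id})")

    def total(self) -> float:
        return float(np.nansum(self.scores))


def _load_matrix(name: str):
    from Bio.Align import substitution_matrices
    try:
        return substitution_matrices.load(name.upper())
    except FileNotFoundError:
        available = ", ".join(substitution_matrices.load())
        raise KeyError(f"unknown substitution matrix {name!r}; "
                       f"available: {available}") from None


def per_residue_matrix_score(row: pd.Series, chain: str,
                             reference: ReferenceSequence,
                             matrix: str = "BLOSUM62") -> PositionScoreTrack:
    """Positional ``M[design_i, reference_i]`` lookup along the chain.

    Positive cells mark residue pairs that interchange freely among
    evolutionarily related proteins, so a high per-position score means the
    design stays close (in substitution terms) to the reference; the
    diagonal is recovered when design equals reference (A/A = 4,
    W/W = 11 for BLOSUM62).
    """
    M = _load_matrix(matrix)
    seq = get_sequence(row, chain)
    ref = reference.sequence
    n = min(len(seq), len(ref))
    positions = np.arange(reference.shift, reference.shift + n)
    scores = np.full(n, np.nan)
    for i in range(n):
        a, b = seq[i], ref[i]
        if a in AA_ALPHABET and b in AA_ALPHABET:
            scores[i] = float(M[a, b])
    return PositionScoreTrack(positions=positions, scores=scores,
                              matrix=matrix.upper(),
                              query_id=str(row.get("description", "query")),
                              reference_id=reference.chain)
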