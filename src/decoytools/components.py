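"""Tabular containers for decoy populations and the operations that compose them.

The central object is :class:`DesignTable`, a :class:`pandas.DataFrame`
subclass in which every row is one designed decoy and the columns hold
numeric score terms, a ``description`` identifier and per-chain sequence /
secondary-structure strings (columns ``sequence_<chain>`` and
``structure_<chain>``).  A per-chain :class:`ReferenceSequence` (typically
the design template or the wild-type protein) can be attached; all
mutation-aware operations — mutant identification, combinatorial variant
generation, wild-type reversions, resfile writing — are expressed in the
reference numbering, i.e. residue ``i`` of the stored string corresponds to
position ``shift + i`` (1-based, inclusive everywhere).

Also defined here are the two other population-level containers,
:class:`FrequencyMatrix` (positions x amino-acid letters, the PSSM-like
object produced by per-position frequency analysis) and
:class:`FragmentSet` (backbone fragment libraries with per-residue
phi/psi/omega), plus :class:`StructureRecord` for parsed backbones and
:class:`SelectionRange`, the 1-based inclusive residue-range expression
(``"43-64"``, comma-separated unions) used to slice sequences, matrices and
plots.
"""

from __future__ import annotations

import itertools
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

#: The 20 standard amino-acid one-letter codes, alphabetical.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Gap character used in alignments; counts as a mutation, excluded from
#: frequency normalisation by default.
GAP = "-"

#: Name of the decoy-identifier column.
ID_COLUMN = "description"


# ---------------------------------------------------------------------------
# selection ranges
# ---------------------------------------------------------------------------

class SelectionRange:
    """A 1-based inclusive residue selection such as ``"43-64"`` or ``"3,7-9"``.

    Accepts hyphen or en-dash range separators and comma-separated unions,
    or an explicit iterable of integer positions.  Positions are interpreted
    in reference numbering (i.e. after any reference ``shift`` is applied).
    """

    def __init__(self, expr: "str | Iterable[int] | SelectionRange"):
        if isinstance(expr, SelectionRange):
            self._positions = tuple(expr._positions)
            return
        positions: set[int] = set()
        if isinstance(expr, str):
            text = expr.replace("–", "-").replace("−", "-")
            for part in text.split(","):
                part = part.strip()
                if not part:
                    continue
                if "-" in part:
                    lo_s, hi_s = part.split("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                    if lo > hi:
                        raise ValueError(f"descending range {part!r} in selection")
                    positions.update(range(lo, hi + 1))
                else:
                    positions.add(int(part))
        else:
            positions.update(int(p) for p in expr)
        if not positions:
            raise ValueError("empty selection expression")
        self._positions = tuple(sorted(positions))

    def positions(self) -> tuple[int, ...]:
        return self._positions

    def __contains__(self, pos: int) -> bool:
        return pos in set(self._positions)

    def __iter__(self) -> Iterator[int]:
        return iter(self._positions)

    def __len__(self) -> int:
        return len(self._positions)

    @property
    def lo(self) -> int:
        return self._positions[0]

    @property
    def hi(self) -> int:
        return self._positions[-1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"SelectionRange({','.join(map(str, self._positions))})"


def as_selection(key_residues: "str | Iterable[int] | SelectionRange | None",
                 ) -> "SelectionRange | None":
    """Coerce a user-facing selection argument; ``None`` means *all*."""
    if key_residues is None:
        return None
    return SelectionRange(key_residues)


# ---------------------------------------------------------------------------
# small domain types
# ---------------------------------------------------------------------------

#: Documented lower bound for reference shifts (arbitrary but fixed).
MIN_SHIFT = -9999


@dataclass(frozen=True)
class ReferenceSequence:
    """A chain's reference (template / wild-type) sequence.

    ``shift`` is the 1-based residue number of the first letter, so letter
    ``i`` (0-based) sits at position ``shift + i``.
    """

    chain: str
    sequence: str
    shift: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if self.shift < MIN_SHIFT:
            raise ValueError(f"shift {self.shift} below minimum {MIN_SHIFT}")

    def position_of(self, index: int) -> int:
        """Reference position of 0-based string index."""
        return self.shift + index

    def index_of(self, position: int) -> int:
        """0-based string index of a reference position (bounds-checked)."""
        idx = position - self.shift
        if not 0 <= idx < len(self.sequence):
            raise IndexError(
                f"position {position} outside reference range "
                f"{self.shift}-{self.shift + len(self.sequence) - 1}")
        return idx

    @property
    def positions(self) -> range:
        return range(self.shift, self.shift + len(self.sequence))


@dataclass(frozen=True)
class MutationSpec:
    """Allowed residue types at one reference position.

    ``options`` is an ordered set of amino-acid letters; the wild-type
    letter is included only if explicitly listed.
    """

    position: int
    options: tuple[str, ...]

    def __init__(self, position: int, options: Iterable[str]):
        opts = tuple(dict.fromkeys(options))  # ordered, unique
        if not opts:
            raise ValueError("MutationSpec options must be non-empty")
        bad = [o for o in opts if o not in AA_ALPHABET]
        if bad:
            raise ValueError(
                f"options {bad} at position {position} outside the 20-letter "
                f"alphabet {AA_ALPHABET}")
        object.__setattr__(self, "position", int(position))
        object.__setattr__(self, "options", opts)


# ---------------------------------------------------------------------------
# DesignTable
# ---------------------------------------------------------------------------

def sequence_column(chain: str) -> str:
    return f"sequence_{chain}"


def structure_column(chain: str) -> str:
    return f"structure_{chain}"


class DesignTable(pd.DataFrame):
    """One row per decoy; scores, identifier and per-chain strings.

    Subclasses :class:`pandas.DataFrame`, so all ordinary data-frame
    operations (sorting, boolean selection, ``merge``, CSV round-trips,
    seaborn plotting ...) work directly, and casting to/from a plain frame
    preserves every cell.  Per-chain reference sequences ride along in
    ``_metadata`` and survive ordinary pandas operations.
    """

    _metadata = ["_references", "_shifts"]

    @property
    def _constructor(self):
        return DesignTable

    # -- metadata plumbing -------------------------------------------------

    @property
    def references(self) -> dict[str, ReferenceSequence]:
        ref = getattr(self, "_references", None)
        if ref is None:
            ref = {}
            object.__setattr__(self, "_references", ref)
        return ref

    @property
    def shifts(self) -> dict[str, int]:
        sh = getattr(self, "_shifts", None)
        if sh is None:
            sh = {}
            object.__setattr__(self, "_shifts", sh)
        return sh

    # -- chains and sequences ----------------------------------------------

    def available_chains(self) -> list[str]:
        return [c.split("_", 1)[1] for c in self.columns
                if isinstance(c, str) and c.startswith("sequence_")]

    def sequence_column(self, chain: str) -> str:
        col = sequence_column(chain)
        if col not in self.columns:
            raise KeyError(
                f"no sequence column for chain {chain!r}; available chains: "
                f"{self.available_chains() or 'none'}")
        return col

    def get_sequence(self, chain: str, index: int = 0) -> str:
        """Sequence string of row ``index`` (positional), returned verbatim."""
        return str(self[self.sequence_column(chain)].iloc[index])

    def sequence_shift(self, chain: str) -> int:
        ref = self.references.get(chain)
        if ref is not None:
            return ref.shift
        return self.shifts.get(chain, 1)

    def _pos_to_index(self, chain: str, position: int, length: int) -> int:
        shift = self.sequence_shift(chain)
        idx = position - shift
        if not 0 <= idx < length:
            raise IndexError(
                f"position {position} outside chain {chain} range "
                f"{shift}-{shift + length - 1}")
        return idx

    # -- reference sequences -----------------------------------------------

    def add_reference_sequence(self, chain: str, sequence: str,
                               shift: int = 1) -> "DesignTable":
        """Attach (or replace: last write wins) a reference for ``chain``.

        If the chain's sequence column exists, the reference must have the
        same length as the stored strings.
        """
        col = sequence_column(chain)
        if col in self.columns and len(self):
            col_len = len(str(self[col].iloc[0]))
            if len(sequence) != col_len:
                raise ValueError(
                    f"reference length {len(sequence)} != chain {chain} "
                    f"sequence column length {col_len}")
        elif col not in self.columns:
            raise KeyError(
                f"cannot set reference for unknown chain {chain!r}; "
                f"available chains: {self.available_chains() or 'none'}")
        self.references[chain] = ReferenceSequence(chain, sequence, shift)
        return self

    def get_reference(self, chain: str) -> ReferenceSequence:
        try:
            return self.references[chain]
        except KeyError:
            raise KeyError(
                f"no reference sequence for chain {chain!r}; call "
                f"add_reference_sequence first") from None

    # -- selection ----------------------------------------------------------

    def get_sequence_with(self, chain: str,
                          pairs: Sequence[tuple[int, str]],
                          confidence: float = 1.0,
                          invert: bool = False) -> "DesignTable":
        """Rows whose residues match ``pairs`` at a given confidence.

        A row matches iff the fraction of ``(position, letter)`` pairs whose
        letter equals the row's residue at that (reference-numbered)
        position is ``>= confidence``.  ``invert`` returns the exact
        complement, so e.g. ``confidence=0.25`` over four pairs with
        ``invert=True`` selects rows carrying *none* of the four residues.
        """
        if not pairs:
            raise ValueError("pairs must be non-empty")
        if not 0 < confidence <= 1:
            raise ValueError(f"confidence must be in (0, 1], got {confidence}")
        col = self.sequence_column(chain)

        def _matches(seq: str) -> bool:
            hits = 0
            for pos, letter in pairs:
                idx = self._pos_to_index(chain, int(pos), len(seq))
                if seq[idx] == letter:
                    hits += 1
            return hits / len(pairs) >= confidence

        mask = self[col].astype(str).map(_matches)
        if invert:
            mask = ~mask
        out = self[mask]
        return out.__finalize__(self)

    def filter_quantile(self, term: str, q: float = 0.05,
                        lower_is_better: bool = True) -> "DesignTable":
        """Rows strictly beyond the ``q`` tail quantile of ``term``.

        With ``lower_is_better`` keeps rows with ``term < quantile(q)``
        (linear-interpolation quantile); otherwise ``term > quantile(1-q)``.
        The strict inequality means an all-equal column selects nothing.
        """
        if not 0 < q < 1:
            raise ValueError(f"q must be in (0, 1), got {q}")
        if term not in self.columns:
            raise KeyError(f"unknown score term {term!r}")
        series = pd.to_numeric(self[term], errors="coerce")
        if series.isna().all():
            raise TypeError(f"score term {term!r} is not numeric")
        if lower_is_better:
            out = self[series < series.quantile(q)]
        else:
            out = self[series > series.quantile(1 - q)]
        return out.__finalize__(self)

    # -- mutation bookkeeping ------------------------------------------------

    def identify_mutants(self, chain: str) -> "DesignTable":
        """Annotate each row with its mutations relative to the reference.

        Adds ``mutant_count_<chain>``, ``mutants_<chain>`` (comma-joined
        ``<refAA><position><newAA>`` tokens, e.g. ``P46G``) and
        ``mutant_positions_<chain>``.  Positions are in reference numbering;
        a gap opposite a letter counts as a mutation.
        """
        ref = self.get_reference(chain)
        col = self.sequence_column(chain)
        counts, tokens, positions = [], [], []
        for seq in self[col].astype(str):
            muts = mutation_tokens(ref.sequence, seq, ref.shift)
            counts.append(len(muts))
            tokens.append(",".join(t for _, t in muts))
            positions.append(",".join(str(p) for p, _ in muts))
        out = self.copy()
        out[f"mutant_count_{chain}"] = counts
        out[f"mutants_{chain}"] = tokens
        out[f"mutant_positions_{chain}"] = positions
        return out.__finalize__(self)

    def generate_mutant_variants(self, chain: str,
                                 specs: Sequence[MutationSpec | tuple],
                                 index: int = 0) -> "DesignTable":
        """Cartesian product of allowed residues over the listed positions.

        See :func:`generate_mutant_variants`; uses row ``index`` as the
        template and this table's reference for numbering.
        """
        row = self.iloc[index]
        out = generate_mutant_variants(row, chain, specs,
                                       reference=self.references.get(chain))
        if chain in self.references:
            out.references[chain] = self.references[chain]
        return out

    def generate_wt_reversions(self, chain: str,
                               key_residues=None,
                               index: int = 0) -> "DesignTable":
        row = self.iloc[index]
        out = generate_wt_reversions(row, chain, self.get_reference(chain),
                                     key_residues=key_residues)
        out.references[chain] = self.references[chain]
        return out

    def make_resfile(self, chain: str, header: str = "NATAA",
                     path_pattern: str = "{description}.resfile",
                     ) -> "DesignTable":
        """Write one Rosetta resfile per row and record its path.

        The resfile dialect is: the header line (default ``NATAA``), a
        ``start`` line, then one ``<resnum> <chain> PIKAA <newAA>`` line per
        mutation relative to the reference.  ``path_pattern`` may contain
        ``{description}`` or ``{index}`` placeholders; a literal path gets a
        numeric suffix inserted when the table has several rows.  Adds the
        column ``resfile_<chain>``.
        """
        ref = self.get_reference(chain)
        col = self.sequence_column(chain)
        paths = []
        for i, (_, row) in enumerate(self.iterrows()):
            path = _resfile_path(path_pattern, str(row.get(ID_COLUMN, i)), i,
                                 len(self))
            muts = mutation_tokens(ref.sequence, str(row[col]), ref.shift)
            lines = [header, "start"]
            lines += [f"{pos} {chain} PIKAA {tok[-1]}" for pos, tok in muts]
            directory = os.path.dirname(path)
            if directory:
                os.makedirs(directory, exist_ok=True)
            try:
                with open(path, "w") as fh:
                    fh.write("\n".join(lines) + "\n")
            except OSError as exc:
                raise OSError(f"cannot write resfile {path!r}: {exc}") from exc
            paths.append(path)
        out = self.copy()
        out[f"resfile_{chain}"] = paths
        return out.__finalize__(self)

    # -- slicing -------------------------------------------------------------

    def slice_region(self, lo: int, hi: int) -> "DesignTable":
        """Inclusive window ``[lo, hi]`` (reference numbering) of every chain.

        Sequence and secondary-structure strings are cut to the window and
        position labels are preserved: the sliced table remembers ``lo`` as
        the first position of each chain (via the sliced reference, or an
        internal shift when no reference is set), so slicing is idempotent
        and mutation positions stay in the original numbering.
        """
        out = self.copy()
        new_refs: dict[str, ReferenceSequence] = {}
        new_shifts: dict[str, int] = {}
        for chain in self.available_chains():
            shift = self.sequence_shift(chain)
            col = sequence_column(chain)
            length = len(str(self[col].iloc[0])) if len(self) else 0
            if not (shift <= lo <= hi <= shift + length - 1):
                raise IndexError(
                    f"window {lo}-{hi} outside chain {chain} range "
                    f"{shift}-{shift + length - 1}")
            a, b = lo - shift, hi - shift + 1
            out[col] = self[col].astype(str).str.slice(a, b)
            scol = structure_column(chain)
            if scol in self.columns:
                out[scol] = self[scol].astype(str).str.slice(a, b)
            ref = self.references.get(chain)
            if ref is not None:
                new_refs[chain] = ReferenceSequence(
                    chain, ref.sequence[a:b], shift=lo)
            else:
                new_shifts[chain] = lo
        object.__setattr__(out, "_references", new_refs)
        object.__setattr__(out, "_shifts", new_shifts)
        return out


# ---------------------------------------------------------------------------
# row-level operations (a row is a pandas Series)
# ---------------------------------------------------------------------------

def get_sequence(row: pd.Series, chain: str) -> str:
    """The stored sequence string of one decoy row, verbatim (gaps kept)."""
    col = sequence_column(chain)
    if col not in row.index:
        chains = [c.split("_", 1)[1] for c in row.index
                  if isinstance(c, str) and c.startswith("sequence_")]
        raise KeyError(f"row has no sequence for chain {chain!r}; "
                       f"available chains: {chains or 'none'}")
    return str(row[col])


def mutation_tokens(reference: str, sequence: str, shift: int = 1,
                    ) -> list[tuple[int, str]]:
    """``(position, "<ref><pos><new>")`` for every differing aligned position."""
    out = []
    for i, (r, s) in enumerate(zip(reference, sequence)):
        if r != s:
            pos = shift + i
            out.append((pos, f"{r}{pos}{s}"))
    return out


def generate_mutant_variants(row: pd.Series, chain: str,
                             specs: Sequence[MutationSpec | tuple],
                             reference: ReferenceSequence | None = None,
                             ) -> DesignTable:
    """Enumerate the full Cartesian product of allowed residues.

    Each :class:`MutationSpec` lists the residue options at one reference
    position; the output has exactly ``prod(len(options_i))`` rows, one per
    combination, differing from the template only at the listed positions.
    The unmodified template combination appears when (and only when) every
    template letter is among its position's options; it is flagged in the
    boolean ``is_template`` column.  Identifiers are the template identifier
    plus a ``_v<i>`` suffix.
    """
    specs = [s if isinstance(s, MutationSpec) else MutationSpec(*s)
             for s in specs]
    positions = [s.position for s in specs]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate positions in mutation specs: {positions}")
    template = get_sequence(row, chain)
    shift = reference.shift if reference is not None else 1
    if reference is not None and len(reference.sequence) != len(template):
        raise ValueError("reference and template sequence lengths differ")
    indices = []
    for s in specs:
        idx = s.position - shift
        if not 0 <= idx < len(template):
            raise IndexError(
                f"position {s.position} outside sequence range "
                f"{shift}-{shift + len(template) - 1}")
        indices.append(idx)

    base_id = str(row.get(ID_COLUMN, "template"))
    rows = []
    for n, combo in enumerate(itertools.product(*(s.options for s in specs))):
        seq = list(template)
        for idx, letter in zip(indices, combo):
            seq[idx] = letter
        seq = "".join(seq)
        rows.append({ID_COLUMN: f"{base_id}_v{n:04d}",
                     sequence_column(chain): seq,
                     "is_template": seq == template})
    out = DesignTable(rows)
    if reference is not None:
        out.references[chain] = reference
    return out


def generate_wt_reversions(row: pd.Series, chain: str,
                           reference: ReferenceSequence,
                           key_residues=None) -> DesignTable:
    """All ``2^m`` combinations of reverting mutated positions to wild type.

    ``m`` is the number of positions (optionally restricted by
    ``key_residues``) where the row differs from the reference; the output
    includes both the unreverted and the fully reverted sequence, enabling
    the search for the best design with the minimal number of mutations.
    """
    selection = as_selection(key_residues)
    template = get_sequence(row, chain)
    muts = mutation_tokens(reference.sequence, template, reference.shift)
    if selection is not None:
        muts = [(p, t) for p, t in muts if p in selection]
    base_id = str(row.get(ID_COLUMN, "template"))
    rows = []
    for n, flags in enumerate(itertools.product((False, True),
                                                repeat=len(muts))):
        seq = list(template)
        n_rev = 0
        for (pos, tok), revert in zip(muts, flags):
            if revert:
                seq[pos - reference.shift] = tok[0]
                n_rev += 1
        rows.append({ID_COLUMN: f"{base_id}_r{n:04d}",
                     sequence_column(chain): "".join(seq),
                     "n_reversions": n_rev})
    out = DesignTable(rows)
    out.references[chain] = reference
    return out


def _resfile_path(pattern: str, description: str, index: int, n: int) -> str:
    if "{" in pattern:
        return pattern.format(description=description, index=index)
    if n <= 1:
        return pattern
    stem, ext = os.path.splitext(pattern)
    return f"{stem}_{index:04d}{ext}"


# ---------------------------------------------------------------------------
# merging experiments
# ---------------------------------------------------------------------------

def merge_experiments(tables: Sequence[pd.DataFrame],
                      on: str = ID_COLUMN,
                      labels: Sequence[str] | None = None,
                      label_column: str = "experiment") -> DesignTable:
    """Combine outputs for the same decoys, or stack labelled populations.

    Without ``labels``: inner join of all tables on the identifier column,
    so different evaluations of the same decoys line up row-wise; colliding
    column names get deterministic ``_2``, ``_3`` ... suffixes by table
    order.  With ``labels`` (one per table): row-wise concatenation with a
    provenance column so disjoint populations (e.g. different protocol
    conditions) can be compared side by side.
    """
    if not tables:
        raise ValueError("no tables to merge")
    for i, t in enumerate(tables):
        if on not in t.columns:
            raise KeyError(f"table {i} lacks identifier column {on!r}")
    if labels is not None:
        if len(labels) != len(tables):
            raise ValueError("one label per table required")
        parts = []
        for t, lab in zip(tables, labels):
            part = pd.DataFrame(t).copy()
            part[label_column] = lab
            parts.append(part)
        return DesignTable(pd.concat(parts, ignore_index=True))
    merged = pd.DataFrame(tables[0])
    for i, t in enumerate(tables[1:], start=2):
        merged = merged.merge(pd.DataFrame(t), on=on, how="inner",
                              suffixes=("", f"_{i}"))
    return DesignTable(merged)


# ---------------------------------------------------------------------------
# FrequencyMatrix
# ---------------------------------------------------------------------------

class FrequencyMatrix:
    """Positions x letters matrix of per-position residue frequencies.

    ``kind="frequency"`` rows sum to 1 (rows with zero observations are
    all-zero and listed in :attr:`empty_positions`); ``kind="difference"``
    rows (e.g. top-fraction minus whole-population) sum to 0.  The row index
    holds reference-numbered positions; subtraction of two matrices with
    identical shape yields a difference matrix.
    """

    def __init__(self, df: pd.DataFrame, kind: str = "frequency",
                 reference: ReferenceSequence | None = None,
                 empty_positions: Sequence[int] = ()):
        if kind not in ("frequency", "difference"):
            raise ValueError(f"unknown kind {kind!r}")
        self.df = df.astype(float)
        self.kind = kind
        self.reference = reference
        self.empty_positions = tuple(empty_positions)
        self._validate()

    def _validate(self):
        sums = self.df.sum(axis=1)
        if self.kind == "frequency":
            target = pd.Series(1.0, index=self.df.index)
            target[list(self.empty_positions)] = 0.0
        else:
            target = pd.Series(0.0, index=self.df.index)
        if not np.allclose(sums, target, atol=1e-9):
            bad = sums.index[~np.isclose(sums, target, atol=1e-9)].tolist()
            raise ValueError(
                f"{self.kind} matrix rows at positions {bad} do not sum to "
                f"{'1' if self.kind == 'frequency' else '0'}")

    @property
    def positions(self) -> list[int]:
        return list(self.df.index)

    @property
    def letters(self) -> list[str]:
        return list(self.df.columns)

    def __sub__(self, other: "FrequencyMatrix") -> "FrequencyMatrix":
        if (self.df.shape != other.df.shape
                or list(self.df.index) != list(other.df.index)
                or list(self.df.columns) != list(other.df.columns)):
            raise ValueError("frequency matrices differ in positions/alphabet")
        return FrequencyMatrix(self.df - other.df, kind="difference",
                               reference=self.reference)

    def slice_region(self, lo: int, hi: int) -> "FrequencyMatrix":
        """Inclusive position window; labels preserved, not renumbered."""
        if not (self.df.index.min() <= lo <= hi <= self.df.index.max()):
            raise IndexError(
                f"window {lo}-{hi} outside positions "
                f"{self.df.index.min()}-{self.df.index.max()}")
        keep = [p for p in self.df.index if lo <= p <= hi]
        ref = self.reference
        if ref is not None:
            a = lo - ref.shift
            b = hi - ref.shift + 1
            if 0 <= a and b <= len(ref.sequence):
                ref = ReferenceSequence(ref.chain, ref.sequence[a:b], shift=lo)
        return FrequencyMatrix(
            self.df.loc[keep], kind=self.kind, reference=ref,
            empty_positions=[p for p in self.empty_positions if lo <= p <= hi])

    def select(self, key_residues=None) -> "FrequencyMatrix":
        sel = as_selection(key_residues)
        if sel is None:
            return self
        keep = [p for p in self.df.index if p in sel]
        if not keep:
            raise IndexError("selection matches no positions in matrix")
        return FrequencyMatrix(
            self.df.loc[keep], kind=self.kind, reference=self.reference,
            empty_positions=[p for p in self.empty_positions if p in sel])

    def to_csv(self, path: str):
        self.df.to_csv(path, index_label="position")

    @classmethod
    def from_csv(cls, path: str, kind: str = "frequency") -> "FrequencyMatrix":
        df = pd.read_csv(path, index_col="position")
        empty = df.index[(df.sum(axis=1) == 0)] if kind == "frequency" else ()
        return cls(df, kind=kind, empty_positions=list(empty))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FrequencyMatrix(kind={self.kind}, "
                f"{len(self.df)} positions x {len(self.df.columns)} letters)")


# ---------------------------------------------------------------------------
# FragmentSet
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FragmentResidue:
    """One residue of one fragment instance (angles in degrees, (-180, 180])."""
    source_id: str
    chain: str
    residue: int
    aa: str
    ss: str
    phi: float
    psi: float
    omega: float


@dataclass(frozen=True)
class FragmentInstance:
    """One neighbor: ``frame_size`` consecutive residues from a source."""
    residues: tuple[FragmentResidue, ...]

    def __len__(self) -> int:
        return len(self.residues)

    def angles(self) -> np.ndarray:
        """(n, 3) array of (phi, psi, omega)."""
        return np.array([(r.phi, r.psi, r.omega) for r in self.residues])


@dataclass
class FragmentFrame:
    """All neighbors proposed for one query position."""
    position: int
    instances: list[FragmentInstance] = field(default_factory=list)


class FragmentSet:
    """A fragment library: frames of fixed-size backbone fragments.

    ``quality`` (set by ``geometry.fragment_quality``) is a data frame with
    columns ``position``, ``neighbor``, ``rmsd`` holding the CA RMSD of each
    neighbor against the query structure window; NaN marks frames whose
    query window could not be evaluated.
    """

    def __init__(self, frames: Sequence[FragmentFrame], frame_size: int,
                 quality: pd.DataFrame | None = None):
        for fr in frames:
            for inst in fr.instances:
                if len(inst) != frame_size:
                    raise ValueError(
                        f"fragment at frame {fr.position} has "
                        f"{len(inst)} residues, expected {frame_size}")
        self.frames = list(frames)
        self.frame_size = int(frame_size)
        self.quality = quality

    @property
    def positions(self) -> list[int]:
        return [f.position for f in self.frames]

    def n_instances(self) -> int:
        return sum(len(f.instances) for f in self.frames)

    def slice_region(self, lo: int, hi: int) -> "FragmentSet":
        """Frames whose query position lies in ``[lo, hi]``; labels kept."""
        if not self.frames:
            raise IndexError("empty fragment set")
        pmin, pmax = min(self.positions), max(self.positions)
        if not (pmin <= lo <= hi <= pmax):
            raise IndexError(
                f"window {lo}-{hi} outside frame positions {pmin}-{pmax}")
        frames = [f for f in self.frames if lo <= f.position <= hi]
        quality = None
        if self.quality is not None:
            quality = self.quality[
                (self.quality["position"] >= lo)
                & (self.quality["position"] <= hi)].reset_index(drop=True)
        return FragmentSet(frames, self.frame_size, quality=quality)

    def quality_profile(self, stat: str = "min") -> pd.Series:
        """Per-frame ``min`` or ``mean`` RMSD (requires quality)."""
        if self.quality is None:
            raise ValueError("no quality measure; run "
                             "geometry.fragment_quality first")
        grouped = self.quality.groupby("position")["rmsd"]
        return getattr(grouped, stat)()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FragmentSet({len(self.frames)} frames x ~"
                f"{len(self.frames[0].instances) if self.frames else 0} "
                f"neighbors, frame_size={self.frame_size})")


# ---------------------------------------------------------------------------
# StructureRecord
# ---------------------------------------------------------------------------

@dataclass
class BackboneResidue:
    """Backbone heavy atoms of one residue; ``complete`` when N, CA and C exist."""
    number: int
    aa: str
    coords: dict[str, np.ndarray]
    icode: str = ""
    complete: bool = True

    @property
    def label(self) -> str:
        return f"{self.number}{self.icode}".strip()


class StructureRecord:
    """Ordered backbone residues per chain, parsed from a PDB file."""

    def __init__(self, chains: Mapping[str, Sequence[BackboneResidue]]):
        self.chains: dict[str, list[BackboneResidue]] = {
            c: list(res) for c, res in chains.items()}

    def residues(self, chain: str) -> list[BackboneResidue]:
        if chain not in self.chains:
            raise KeyError(f"no chain {chain!r}; available: "
                           f"{sorted(self.chains)}")
        return self.chains[chain]

    def sequence(self, chain: str) -> str:
        return "".join(r.aa for r in self.residues(chain))

    def ca_coordinates(self, chain: str) -> np.ndarray:
        """(n, 3) CA coordinates; NaN rows for residues without a CA."""
        out = np.full((len(self.residues(chain)), 3), np.nan)
        for i, r in enumerate(self.residues(chain)):
            if "CA" in r.coords:
                out[i] = r.coords["CA"]
        return out


# ---------------------------------------------------------------------------
# generic slice dispatch
# ---------------------------------------------------------------------------

def slice_region(obj, lo: int, hi: int):
    """Inclusive 1-based window of a DesignTable, FrequencyMatrix or FragmentSet."""
    if hasattr(obj, "slice_region"):
        return obj.slice_region(lo, hi)
    raise TypeError(f"cannot slice object of type {type(obj).__name__}")


def deduplicate_identifiers(table: DesignTable,
                            suffix: str = "_r{n}") -> DesignTable:
    """Disambiguate repeated decoy identifiers with a numeric suffix.

    Rosetta reruns commonly repeat names; parsers keep duplicates but warn,
    and this helper renames the second and later occurrences on request.
    """
    if ID_COLUMN not in table.columns:
        return table
    seen: dict[str, int] = {}
    names = []
    for name in table[ID_COLUMN].astype(str):
        n = seen.get(name, 0)
        seen[name] = n + 1
        names.append(name if n == 0 else name + suffix.format(n=n + 1))
    out = table.copy()
    out[ID_COLUMN] = names
    return out.__finalize__(table)
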