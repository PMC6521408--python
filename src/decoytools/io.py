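"""Readers and writers for the external formats the workflows touch.

Covered formats: Rosetta silent score tables (score subset: SCORE / SEQUENCE
/ ANNOTATED_SEQUENCE lines, coordinate lines skipped), JSON-lines score
files, FASTA, Clustal alignments, PDB backbones, Rosetta fragment
libraries, plain CSV reference tables and the project's own CSV dialects
for circular-dichroism and surface-plasmon-resonance traces.  Every text
reader transparently accepts gzip-compressed input (``*.gz``).

The silent writer here is deliberately minimal (SCORE header + rows +
sequence lines): it exists so score-table round-trips can be tested, not to
produce files Rosetta itself could rebuild coordinates from.
"""

from __future__ import annotations

import gzip
import io as _stdio
import json
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import (AA_ALPHABET, GAP, ID_COLUMN, BackboneResidue,
                         DesignTable, FragmentFrame, FragmentInstance,
                         FragmentResidue, FragmentSet, StructureRecord,
                         sequence_column)
from .geometry import wrap_angle

_ANNOTATION = re.compile(r"\[[^\]]*\]")


def _open_text(path: str, mode: str = "rt"):
    """Open a text file, transparently decompressing ``*.gz``."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _coerce(value: str):
    try:
        return int(value)
    except ValueError:
        try:
            return float(value)
        except ValueError:
            return value


# ---------------------------------------------------------------------------
# Rosetta silent score tables
# ---------------------------------------------------------------------------

def parse_silent(path: str, chain: str = "A") -> DesignTable:
    """Parse the score subset of a Rosetta silent file.

    The first ``SCORE:`` line is the header (its last field must be
    ``description``); later ``SCORE:`` lines are decoy rows, with numeric
    cells typed as numbers and everything else kept as text.  A row whose
    field count disagrees with the header is skipped with a warning.
    ``ANNOTATED_SEQUENCE:`` lines (Rosetta ``[...]`` annotation suffixes
    stripped) attach the decoy sequence under ``sequence_<chain>``; a
    leading global ``SEQUENCE:`` line and all other line types (coordinates
    etc.) are ignored.
    """
    header: list[str] | None = None
    rows: list[dict] = []
    sequences: dict[str, str] = {}
    last_description: str | None = None
    skipped = 0
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("SCORE:"):
                fields = line.split()[1:]
                if header is None:
                    header = fields
                    continue
                if len(fields) != len(header):
                    skipped += 1
                    warnings.warn(
                        f"silent row with {len(fields)} fields "
                        f"(header has {len(header)}) skipped")
                    continue
                row = {k: _coerce(v) for k, v in zip(header, fields)}
                rows.append(row)
                last_description = str(row.get(ID_COLUMN, ""))
            elif line.startswith("ANNOTATED_SEQUENCE:"):
                parts = line.split()
                if len(parts) < 2:
                    continue
                seq = _ANNOTATION.sub("", parts[1])
                tag = parts[2] if len(parts) > 2 else last_description
                if tag is not None:
                    sequences[tag] = seq
    if header is None:
        raise ValueError(f"{path}: no SCORE: header line found")
    table = DesignTable(rows, columns=header) if rows else \
        DesignTable(columns=header)
    if sequences:
        table[sequence_column(chain)] = \
            table[ID_COLUMN].astype(str).map(sequences)
    dup = table[ID_COLUMN].duplicated() if ID_COLUMN in table.columns \
        else pd.Series(False)
    if getattr(dup, "any", lambda: False)():
        warnings.warn(f"{path}: duplicate decoy identifiers present "
                      f"({int(dup.sum())} repeats); use "
                      f"components.deduplicate_identifiers to rename")
    table.attrs["skipped_rows"] = skipped
    return table


def write_silent(table: pd.DataFrame, path: str, chain: str = "A"):
    """Minimal silent writer (score table + sequence lines) for round-trips."""
    df = pd.DataFrame(table)
    seq_col = sequence_column(chain)
    score_cols = [c for c in df.columns
                  if c != seq_col and not str(c).startswith(("sequence_",
                                                             "structure_"))]
    if ID_COLUMN in score_cols:  # description is conventionally last
        score_cols = [c for c in score_cols if c != ID_COLUMN] + [ID_COLUMN]
    with _open_text(path, "wt") as fh:
        if seq_col in df.columns and len(df):
            fh.write(f"SEQUENCE: {df[seq_col].iloc[0]}\n")
        fh.write("SCORE: " + " ".join(map(str, score_cols)) + "\n")
        for _, row in df.iterrows():
            fh.write("SCORE: " + " ".join(str(row[c]) for c in score_cols)
                     + "\n")
            if seq_col in df.columns and isinstance(row[seq_col], str):
                fh.write(f"ANNOTATED_SEQUENCE: {row[seq_col]} "
                         f"{row[ID_COLUMN]}\n")


# ---------------------------------------------------------------------------
# JSON-lines score files
# ---------------------------------------------------------------------------

def parse_scorejson(path: str) -> DesignTable:
    """One JSON object per line; the union of keys becomes the columns."""
    records = []
    with _open_text(path) as fh:
        for n, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                records.append(json.loads(line))
            except json.JSONDecodeError:
                warnings.warn(f"{path}:{n}: malformed JSON line skipped")
    return DesignTable(records)


def write_scorejson(table: pd.DataFrame, path: str):
    with _open_text(path, "wt") as fh:
        for _, row in pd.DataFrame(table).iterrows():
            record = {k: (None if isinstance(v, float) and np.isnan(v) else v)
                      for k, v in row.items()}
            fh.write(json.dumps(record) + "\n")


# ---------------------------------------------------------------------------
# FASTA / Clustal
# ---------------------------------------------------------------------------

def parse_fasta(path: str, chain: str = "A") -> DesignTable:
    """FASTA records as a DesignTable (description = first header token)."""
    from Bio import SeqIO
    ids, seqs = [], []
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            seq = str(record.seq)
            bad = set(seq) - set(AA_ALPHABET + GAP)
            if bad:
                warnings.warn(f"{record.id}: non-standard characters "
                              f"{sorted(bad)} kept verbatim")
            ids.append(record.id)
            seqs.append(seq)
    return DesignTable({ID_COLUMN: ids, sequence_column(chain): seqs})


def write_fasta(table: pd.DataFrame, chain: str, path: str, width: int = 60):
    df = pd.DataFrame(table)
    col = sequence_column(chain)
    if col not in df.columns:
        raise KeyError(f"table has no sequence column for chain {chain!r}")
    with _open_text(path, "wt") as fh:
        for _, row in df.iterrows():
            fh.write(f">{row[ID_COLUMN]}\n")
            seq = str(row[col])
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


_CLUSTAL_HEADERS = ("CLUSTAL", "MUSCLE", "PROBCONS", "KALIGN", "MSAPROBS")


def parse_clustal(path: str, chain: str = "A") -> DesignTable:
    """Clustal alignment blocks concatenated per id; gaps preserved.

    Identifiers are the full first token of each line, so ids sharing a
    prefix stay distinct; conservation lines (indented) are ignored and a
    per-block consensus line is not required.  Ragged alignments raise,
    naming the offending identifier.
    """
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        lines = fh.readlines()
    first = lines[0].split() if lines else []
    if not first or first[0].upper().rstrip("W") not in _CLUSTAL_HEADERS:
        raise ValueError(f"{path}: missing CLUSTAL header line")
    for line in lines[1:]:
        if not line.strip():
            continue
        if line[0] in " \t":  # conservation line
            continue
        fields = line.split()
        if len(fields) < 2:
            continue
        seqs[fields[0]] = seqs.get(fields[0], "") + fields[1]
    if not seqs:
        return DesignTable(columns=[ID_COLUMN, sequence_column(chain)])
    lengths = {name: len(s) for name, s in seqs.items()}
    majority = max(set(lengths.values()),
                   key=lambda n: sum(v == n for v in lengths.values()))
    bad = [name for name, n in lengths.items() if n != majority]
    if bad:
        raise ValueError(f"{path}: inconsistent block lengths for id(s) "
                         f"{bad}")
    return DesignTable({ID_COLUMN: list(seqs),
                        sequence_column(chain): list(seqs.values())})


# ---------------------------------------------------------------------------
# Rosetta fragment libraries
# ---------------------------------------------------------------------------

_FRAME_HEADER = re.compile(r"position:\s*(\d+)\s+neighbors:\s*(\d+)")


def parse_fragments(path: str) -> FragmentSet:
    """Parse a Rosetta fragment-library text file.

    Frames start with ``position: <p> neighbors: <n>`` headers; each
    neighbor is a blank-line-separated run of per-residue lines
    ``<source pdb> <chain> <resnum> <aa> <ss> <phi> <psi> <omega>``.  The
    frame size is inferred from the first neighbor and must be constant;
    angles outside (-180, 180] are normalised with a warning.
    """
    frames: list[FragmentFrame] = []
    current: FragmentFrame | None = None
    pending: list[FragmentResidue] = []
    sizes: set[int] = set()
    warned = False

    def close_neighbor():
        nonlocal pending
        if pending and current is not None:
            sizes.add(len(pending))
            current.instances.append(FragmentInstance(tuple(pending)))
        pending = []

    with _open_text(path) as fh:
        for line in fh:
            header = _FRAME_HEADER.search(line)
            if header:
                close_neighbor()
                current = FragmentFrame(position=int(header.group(1)))
                frames.append(current)
                continue
            if not line.strip():
                close_neighbor()
                continue
            parts = line.split()
            if current is None or len(parts) < 8:
                continue
            phi, psi, omega = (float(x) for x in parts[5:8])
            for name, val in (("phi", phi), ("psi", psi), ("omega", omega)):
                if not (-180.0 < val <= 180.0) and not warned:
                    warnings.warn(f"{path}: {name} angle {val} outside "
                                  f"(-180, 180], normalising")
                    warned = True
            pending.append(FragmentResidue(
                source_id=parts[0], chain=parts[1], residue=int(parts[2]),
                aa=parts[3], ss=parts[4], phi=wrap_angle(phi),
                psi=wrap_angle(psi), omega=wrap_angle(omega)))
        close_neighbor()
    if not sizes:
        raise ValueError(f"{path}: no fragments found")
    if len(sizes) > 1:
        raise ValueError(f"{path}: inconsistent fragment lengths {sorted(sizes)}")
    return FragmentSet(frames, frame_size=sizes.pop())


def write_fragments(fragments: FragmentSet, path: str):
    with _open_text(path, "wt") as fh:
        for frame in fragments.frames:
            fh.write(f" position: {frame.position:>12} neighbors: "
                     f"{len(frame.instances):>12}\n\n")
            for inst in frame.instances:
                for r in inst.residues:
                    # re-wrap after rounding so -179.9996 prints as 180.000
                    phi, psi, omega = (wrap_angle(round(v, 3)) for v in
                                       (r.phi, r.psi, r.omega))
                    fh.write(f" {r.source_id} {r.chain} {r.residue:>5} "
                             f"{r.aa} {r.ss} {phi:>9.3f} {psi:>9.3f} "
                             f"{omega:>9.3f}\n")
                fh.write("\n")


# ---------------------------------------------------------------------------
# PDB backbones
# ---------------------------------------------------------------------------

_BACKBONE_ATOMS = ("N", "CA", "C", "O")


def parse_pdb_backbone(path: str) -> StructureRecord:
    """Read backbone N/CA/C(/O) atoms of the first model of a PDB file.

    HETATM records are ignored, the first altLoc is kept, insertion codes
    are preserved in residue labels, and residues missing any of N/CA/C are
    flagged incomplete (their dihedrals come out undefined) rather than
    dropped.
    """
    from Bio.Data.IUPACData import protein_letters_3to1
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True, PERMISSIVE=True)
    with _open_text(path) as fh:
        structure = parser.get_structure("query", fh)
    model = next(iter(structure))  # first MODEL only
    chains: dict[str, list[BackboneResidue]] = {}
    for chain in model:
        residues = []
        for res in chain:
            hetflag, number, icode = res.get_id()
            if hetflag.strip():
                continue  # HETATM / water
            name3 = res.get_resname().capitalize()
            aa = protein_letters_3to1.get(name3, "X")
            coords = {}
            for atom_name in _BACKBONE_ATOMS:
                if atom_name in res:
                    atom = res[atom_name]
                    if atom.is_disordered():
                        atom = atom.disordered_get_list()[0]
                    coords[atom_name] = np.asarray(atom.get_coord(),
                                                   dtype=float)
            complete = all(a in coords for a in ("N", "CA", "C"))
            residues.append(BackboneResidue(
                number=int(number), aa=aa, coords=coords,
                icode=icode.strip(), complete=complete))
        if residues:
            chains[chain.id] = residues
    if not chains:
        raise ValueError(f"{path}: no protein ATOM records found")
    return StructureRecord(chains)


def write_pdb_backbone(structure: StructureRecord, path: str):
    """Write backbone atoms as standard fixed-column ATOM records."""
    from Bio.Data.IUPACData import protein_letters_1to3
    serial = 1
    with _open_text(path, "wt") as fh:
        for chain_id, residues in structure.chains.items():
            for res in residues:
                name3 = protein_letters_1to3.get(res.aa.upper(),
                                                 "UNK").upper()
                for atom_name in _BACKBONE_ATOMS:
                    if atom_name not in res.coords:
                        continue
                    x, y, z = res.coords[atom_name]
                    element = atom_name[0]
                    name_field = f" {atom_name:<3}" if len(atom_name) < 4 \
                        else atom_name
                    fh.write(
                        f"ATOM  {serial:>5} {name_field} {name3:>3} "
                        f"{chain_id}{res.number:>4}{res.icode or ' ':1}   "
                        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                        f"          {element:>2}\n")
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# CD / SPR traces
# ---------------------------------------------------------------------------

@dataclass
class CDTrace:
    """Circular-dichroism melt: long-format frame with columns
    ``wavelength`` (nm), ``ellipticity`` (mean-residue ellipticity,
    deg cm^2 dmol^-1) and ``temperature`` (series label)."""
    data: pd.DataFrame

    @property
    def temperatures(self) -> list:
        return sorted(self.data["temperature"].unique())


@dataclass
class SPRTrace:
    """Surface-plasmon-resonance sensorgrams: columns ``time`` (s),
    ``response`` (RU), ``series`` ({measured, fitted}) and
    ``concentration`` (analyte concentration label)."""
    data: pd.DataFrame

    @property
    def concentrations(self) -> list:
        return sorted(self.data["concentration"].unique())


def read_CD(path: str) -> CDTrace:
    """Read the project's CD CSV dialect (wavelength,ellipticity,temperature)."""
    df = pd.read_csv(_open_text(path))
    required = {"wavelength", "ellipticity", "temperature"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing CD columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty CD data section")
    for temp, grp in df.groupby("temperature"):
        w = grp["wavelength"].to_numpy()
        if not (np.all(np.diff(w) > 0) or np.all(np.diff(w) < 0)):
            raise ValueError(f"{path}: wavelengths not strictly monotone "
                             f"for temperature {temp}")
    return CDTrace(df)


def read_SPR(path: str) -> SPRTrace:
    """Read the project's SPR CSV dialect (time,response,series,concentration)."""
    df = pd.read_csv(_open_text(path))
    required = {"time", "response", "series", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SPR columns {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: empty SPR data section")
    for (series, conc), grp in df.groupby(["series", "concentration"]):
        t = grp["time"].to_numpy()
        if np.any(np.diff(t) < 0):
            raise ValueError(f"{path}: time not monotone for series "
                             f"{series}/{conc}")
    return SPRTrace(df)


def write_CD(trace: CDTrace, path: str):
    trace.data.to_csv(_open_text(path, "wt"), index=False)


def write_SPR(trace: SPRTrace, path: str):
    trace.data.to_csv(_open_text(path, "wt"), index=False)


# ---------------------------------------------------------------------------
# reference tables
# ---------------------------------------------------------------------------

def load_reference_table(path: str) -> pd.DataFrame:
    """Generic CSV of reference domains (id, length, score, ... columns)."""
    return pd.read_csv(_open_text(path))


def filter_reference_by_length(reference: pd.DataFrame, length: int,
                               window: int = 5) -> pd.DataFrame:
    """Rows whose ``length`` lies within ``length +- window`` (inclusive)."""
    if "length" not in reference.columns:
        raise KeyError("reference table lacks a 'length' column")
    return reference[(reference["length"] >= length - window)
                     & (reference["length"] <= length + window)]
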