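"""Backbone geometry: dihedrals, Ramachandran classes, superposition, fragments.

Dihedral angles follow the IUPAC sign convention and live in (-180, 180]
degrees.  phi(i) = C(i-1)-N(i)-CA(i)-C(i), psi(i) = N(i)-CA(i)-C(i)-N(i+1),
omega(i) = CA(i)-C(i)-N(i+1)-CA(i+1); angles are undefined (NaN) at chain
termini, at chain breaks and around residues with missing backbone atoms.

Fragment quality is measured without any external scoring program: each
fragment instance carries per-residue phi/psi/omega, from which its backbone
is rebuilt by forward kinematics with ideal bond lengths and angles, then
superposed (Kabsch) onto the query structure's CA window to obtain an RMSD.
Because the rebuild assumes ideal covalent geometry, absolute values against
experimentally determined structures are approximate; orderings between
fragment sets are meaningful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import (BackboneResidue, FragmentSet, StructureRecord)

# Ideal backbone covalent geometry used for fragment reconstruction
# (lengths in Angstrom, angles in degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7

#: CA-CA distance above which consecutive residues are treated as a break.
CHAIN_BREAK_CA_DISTANCE = 4.5


# ---------------------------------------------------------------------------
# torsion
# ---------------------------------------------------------------------------

def torsion(p1, p2, p3, p4) -> float:
    """Dihedral angle of four points, degrees in (-180, 180].

    Computed as atan2(((b1 x b2) x (b2 x b3)) . b2_hat, (b1 x b2).(b2 x b3))
    with b_i the consecutive bond vectors.  Returns NaN (rather than
    raising) when either bonded triple is collinear or points coincide,
    since real structures contain such degeneracies.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        return math.nan
    y = np.dot(np.cross(n1, n2), b2 / b2n)
    x = np.dot(n1, n2)
    ang = math.degrees(math.atan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return ang


def wrap_angle(angle: float) -> float:
    """Map any angle in degrees into (-180, 180]."""
    a = (angle + 180.0) % 360.0 - 180.0
    if a <= -180.0:
        a += 360.0
    return a


# ---------------------------------------------------------------------------
# backbone dihedrals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DihedralTriple:
    """phi/psi/omega of one residue; NaN marks undefined angles."""
    phi: float
    psi: float
    omega: float

    def defined(self) -> bool:
        return not (math.isnan(self.phi) or math.isnan(self.psi))


def _is_break(r1: BackboneResidue, r2: BackboneResidue) -> bool:
    # numbering gap (insertion-coded residues share a number or are +1)
    if r2.number - r1.number not in (0, 1):
        return True
    if "CA" not in r1.coords or "CA" not in r2.coords:
        return True  # cannot verify continuity without CAs
    return bool(np.linalg.norm(r2.coords["CA"] - r1.coords["CA"])
                > CHAIN_BREAK_CA_DISTANCE)


def backbone_dihedrals(structure: StructureRecord, chain: str,
                       ) -> list[DihedralTriple]:
    """Per-residue phi/psi/omega for one chain.

    phi is undefined for the first residue of each continuous segment, psi
    and omega for the last; chain breaks (numbering gap or CA-CA distance
    above 4.5 A) split segments, and incomplete residues leave every
    dihedral that involves a missing atom undefined.
    """
    residues = structure.residues(chain)
    n = len(residues)
    linked = [False] * max(n - 1, 0)  # residue i connected to i+1
    for i in range(n - 1):
        a, b = residues[i], residues[i + 1]
        linked[i] = (a.complete and b.complete and not _is_break(a, b))

    out = []
    for i, r in enumerate(residues):
        phi = psi = omega = math.nan
        if r.complete:
            if i > 0 and linked[i - 1]:
                prev = residues[i - 1]
                phi = torsion(prev.coords["C"], r.coords["N"],
                              r.coords["CA"], r.coords["C"])
            if i < n - 1 and linked[i]:
                nxt = residues[i + 1]
                psi = torsion(r.coords["N"], r.coords["CA"],
                              r.coords["C"], nxt.coords["N"])
                omega = torsion(r.coords["CA"], r.coords["C"],
                                nxt.coords["N"], nxt.coords["CA"])
        out.append(DihedralTriple(phi, psi, omega))
    return out


def dihedral_table(structure: StructureRecord, chain: str) -> pd.DataFrame:
    """Convenience frame: residue number, aa, phi, psi, omega, rama class."""
    residues = structure.residues(chain)
    triples = backbone_dihedrals(structure, chain)
    seq = structure.sequence(chain)
    rows = []
    for i, (r, t) in enumerate(zip(residues, triples)):
        nxt = seq[i + 1] if i + 1 < len(seq) else None
        rows.append({"residue": r.number, "aa": r.aa,
                     "phi": t.phi, "psi": t.psi, "omega": t.omega,
                     "rama": rama_class(r.aa, nxt)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ramachandran flavours
# ---------------------------------------------------------------------------

RAMA_FLAVOURS = ("GENERAL", "GLY", "PRE-PRO", "PRO")


def rama_class(aa: str, next_aa: str | None = None) -> str:
    """Ramachandran flavour of a residue given its successor.

    Precedence: proline is PRO; otherwise a residue immediately before a
    proline is PRE-PRO (so G before P is PRE-PRO, not GLY); otherwise
    glycine is GLY; everything else GENERAL.  Unknown letters fall back to
    GENERAL with a warning.
    """
    import warnings
    if aa == "P":
        return "PRO"
    if next_aa == "P":
        return "PRE-PRO"
    if aa == "G":
        return "GLY"
    if aa not in "ACDEFGHIKLMNPQRSTVWY":
        warnings.warn(f"unknown residue letter {aa!r}; classified GENERAL")
    return "GENERAL"


def secondary_structure_from_dihedrals(phi: float, psi: float) -> str:
    """Coarse H/E/L call from phi/psi alone.

    This is an approximate, dihedral-only heuristic (broad alpha and beta
    boxes), not a hydrogen-bond based assignment; undefined angles give 'L'.
    """
    if math.isnan(phi) or math.isnan(psi):
        return "L"
    if -100 <= phi <= -30 and -80 <= psi <= -5:
        return "H"
    if -180 <= phi <= -45 and (psi >= 90 or psi <= -150):
        return "E"
    return "L"


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch_superpose(A: np.ndarray, B: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set A onto B.

    Returns ``(R, t, rmsd)`` with the proper rotation R (reflections
    corrected via the determinant sign) and translation t such that
    ``A @ R.T + t`` best matches B; rmsd = sqrt(mean ||A' - B||^2).  For
    degenerate (e.g. collinear) sets the rmsd is still the optimum but the
    rotation may not be unique.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError(f"point sets must both be (n, 3); got {A.shape} "
                         f"and {B.shape}")
    if A.shape[0] < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    H = A0.T @ B0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = A0 @ R.T - B0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(A)))
    return R, t, rmsd


def rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Minimal RMSD between two equally sized coordinate sets."""
    return kabsch_superpose(A, B)[2]


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                length: float, angle: float, dihedral: float) -> np.ndarray:
    # NeRF: place atom d with bond c-d of given length, angle b-c-d and
    # dihedral a-b-c-d.
    ang = math.radians(angle)
    tor = math.radians(dihedral)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-length * math.cos(ang),
                   length * math.sin(ang) * math.cos(tor),
                   length * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone(phi: np.ndarray, psi: np.ndarray, omega: np.ndarray,
                   ) -> np.ndarray:
    """Backbone N/CA/C coordinates from dihedrals with ideal geometry.

    ``phi[0]`` and the last residue's ``psi``/``omega`` do not influence the
    build (they describe torsions around bonds that do not exist here).
    Returns an (n, 3, 3) array indexed [residue, atom(N, CA, C), xyz].
    """
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n = len(phi)
    if not (len(psi) == len(omega) == n):
        raise ValueError("phi/psi/omega must have equal lengths")
    coords = np.zeros((n, 3, 3))
    # first residue in a canonical pose
    coords[0, 0] = (0.0, 0.0, 0.0)                      # N
    coords[0, 1] = (BOND_N_CA, 0.0, 0.0)                # CA
    ang = math.radians(180.0 - ANGLE_N_CA_C)
    coords[0, 2] = coords[0, 1] + BOND_CA_C * np.array(
        [math.cos(ang), math.sin(ang), 0.0])            # C
    for i in range(1, n):
        N_prev, CA_prev, C_prev = coords[i - 1]
        N = _place_atom(N_prev, CA_prev, C_prev,
                        BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA = _place_atom(CA_prev, C_prev, N,
                         BOND_N_CA, ANGLE_C_N_CA, omega[i - 1])
        C = _place_atom(C_prev, N, CA,
                        BOND_CA_C, ANGLE_N_CA_C, phi[i])
        coords[i] = (N, CA, C)
    return coords


def backbone_to_structure(coords: np.ndarray, sequence: str,
                          chain: str = "A", first_residue: int = 1,
                          ) -> StructureRecord:
    """Wrap an (n, 3, 3) backbone array as a StructureRecord."""
    if len(sequence) != len(coords):
        raise ValueError("sequence length does not match coordinates")
    residues = [BackboneResidue(number=first_residue + i, aa=sequence[i],
                                coords={"N": coords[i, 0].copy(),
                                        "CA": coords[i, 1].copy(),
                                        "C": coords[i, 2].copy()})
                for i in range(len(coords))]
    return StructureRecord({chain: residues})


# ---------------------------------------------------------------------------
# fragment quality
# ---------------------------------------------------------------------------

def fragment_ca_coordinates(angles: np.ndarray) -> np.ndarray:
    """CA coordinates of a fragment rebuilt from its (n, 3) dihedral rows."""
    coords = build_backbone(angles[:, 0], angles[:, 1], angles[:, 2])
    return coords[:, 1, :]


def fragment_quality(fragments: FragmentSet, query: StructureRecord,
                     chain: str = "A") -> FragmentSet:
    """CA RMSD of every fragment instance against its query window.

    The query window for a frame at position p covers residues
    p .. p + frame_size - 1 (1-based order along the chain).  Each instance
    is rebuilt from its dihedrals with ideal geometry and superposed onto
    the window's CA trace; frames whose window is incomplete (missing CAs,
    chain break, or running off the chain end) get NaN quality and are
    excluded from profiles.
    """
    residues = query.residues(chain)
    ca = query.ca_coordinates(chain)
    k = fragments.frame_size
    # continuity between consecutive residues, for break detection
    cont = np.ones(max(len(residues) - 1, 0), dtype=bool)
    for i in range(len(residues) - 1):
        cont[i] = not _is_break(residues[i], residues[i + 1])

    records = []
    for frame in fragments.frames:
        lo = frame.position - 1  # 0-based window start
        hi = lo + k
        window_ok = (0 <= lo and hi <= len(residues)
                     and not np.isnan(ca[lo:hi]).any()
                     and cont[lo:hi - 1].all())
        for j, inst in enumerate(frame.instances):
            if not window_ok:
                records.append((frame.position, j, math.nan))
                continue
            frag_ca = fragment_ca_coordinates(inst.angles())
            records.append(
                (frame.position, j, rmsd(frag_ca, ca[lo:hi])))
    quality = pd.DataFrame(records, columns=["position", "neighbor", "rmsd"])
    return FragmentSet(fragments.frames, fragments.frame_size,
                       quality=quality)
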