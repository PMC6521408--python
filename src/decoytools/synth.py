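"""Deterministic synthetic fixtures: populations, backbones, fragments, traces.

Everything the library consumes can be generated here without any design
software or downloads, with explicit seeding (numpy ``default_rng``; no
global random state) so a fixed :class:`FixtureConfig` yields byte-identical
files across runs.

What the generators emulate (and what they do not):

* :func:`make_population` — a scored decoy population whose top-scoring
  fraction carries planted residue enrichment at chosen positions, the
  signal an iterative design workflow mines to bias its next generation.
  Scores are draws from a normal model plus an RMSD-like term correlated
  with score (so score-vs-rms scatter shows a funnel); they are not
  physical energies.
* :func:`make_backbone` — an ideal-geometry backbone built by forward
  kinematics from per-segment dihedrals (helix/strand/loop); real
  structures deviate from ideal covalent geometry.
* :func:`make_fragments` — a fragment library whose neighbors are the
  source structure's own dihedral windows plus zero-mean angular noise, so
  fragment quality degrades smoothly with the noise scale.
* :func:`make_traces` — a two-state helix-coil CD melt and a 1:1 Langmuir
  SPR binding model with additive noise, in the project's CSV dialects.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as dio
from .components import (AA_ALPHABET, DesignTable, FragmentFrame,
                         FragmentInstance, FragmentResidue, FragmentSet,
                         StructureRecord, sequence_column)
from .geometry import (backbone_dihedrals, backbone_to_structure,
                       build_backbone, wrap_angle)

#: Canonical per-segment dihedrals (phi, psi) used by the backbone builder.
SEGMENT_DIHEDRALS = {"H": (-60.0, -45.0), "E": (-120.0, 120.0),
                     "L": (-75.0, 150.0)}


@dataclass(frozen=True)
class FixtureConfig:
    """All knobs of the synthetic corpus; the defaults are the study
    conditions exercised by the test suite.

    A 60-residue single-chain design population of 1000 decoys; four
    planted positions whose enriched residue types are overrepresented in
    the top 5% by score with a frequency margin of 0.30 over the whole
    population (enriched-letter background frequency 0.30 outside the top
    set); 9-mer fragments with 200 neighbors per frame; a
    helix-loop-strand-loop-helix backbone.
    """

    seed: int = 0
    # population
    n_decoys: int = 1000
    length: int = 60
    chain: str = "A"
    planted_positions: tuple[int, ...] = (34, 35, 46, 47)
    enriched_letters: tuple[str, ...] = ("L", "E", "G", "K")
    top_fraction: float = 0.05
    enrichment_margin: float = 0.30
    background_enriched_freq: float = 0.30
    score_mean: float = -300.0
    score_sd: float = 15.0
    # fragments
    frame_size: int = 9
    n_neighbors: int = 200
    fragment_noise_sd: float = 10.0
    # backbone: (segment type, length) pairs; must sum to `length`
    segments: tuple[tuple[str, int], ...] = (
        ("H", 20), ("L", 4), ("E", 10), ("L", 4), ("H", 22))
    # traces
    n_temperatures: int = 7
    melt_tm: float = 55.0
    n_concentrations: int = 5
    kd_nM: float = 20.0

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


# ---------------------------------------------------------------------------
# decoy population
# ---------------------------------------------------------------------------

def secondary_structure_string(cfg: FixtureConfig) -> str:
    ss = "".join(kind * n for kind, n in cfg.segments)
    if len(ss) != cfg.length:
        raise ValueError(f"segments sum to {len(ss)}, expected {cfg.length}")
    return ss


def make_population(cfg: FixtureConfig,
                    silent_path: str | None = None) -> DesignTable:
    """A scored population with planted top-fraction sequence enrichment.

    The number of enriched-letter carriers is set deterministically in both
    the top-q (by score, strict ``<`` quantile rule) subset and the rest,
    so the realised top-vs-all frequency difference at each planted
    position equals the configured margin up to rounding — a margin of
    0.30 is recovered exactly by a 0.20 overrepresentation threshold.
    Optionally also writes the population as a silent file.
    """
    rng = cfg.rng(1)
    n = cfg.n_decoys
    scores = rng.normal(cfg.score_mean, cfg.score_sd, size=n)
    # RMSD-like term correlated with score: a funnel in (rms, score)
    rms = np.clip(0.5 + 0.02 * (scores - scores.min())
                  + rng.normal(0, 0.35, size=n), 0.2, None)
    q = np.quantile(scores, cfg.top_fraction)  # linear-interpolation
    top = scores < q

    letters = np.array(list(AA_ALPHABET))
    seq_matrix = letters[rng.integers(0, len(letters), size=(n, cfg.length))]
    p_rest = cfg.background_enriched_freq
    p_top = p_rest + cfg.enrichment_margin / (1.0 - cfg.top_fraction)
    if not 0 <= p_top <= 1:
        raise ValueError("margin/background combination exceeds frequency 1")
    for pos, enriched in zip(cfg.planted_positions, cfg.enriched_letters):
        col = pos - 1
        others = np.array([a for a in AA_ALPHABET if a != enriched])
        # fill everyone with non-enriched letters first
        seq_matrix[:, col] = others[rng.integers(0, len(others), size=n)]
        for mask, p in ((top, p_top), (~top, p_rest)):
            idx = np.flatnonzero(mask)
            k = int(round(p * len(idx)))
            chosen = rng.choice(idx, size=k, replace=False)
            seq_matrix[chosen, col] = enriched
    ss = secondary_structure_string(cfg)
    table = DesignTable({
        "score": np.round(scores, 3),
        "rms": np.round(rms, 3),
        "description": [f"decoy_{i:05d}" for i in range(n)],
        sequence_column(cfg.chain): ["".join(r) for r in seq_matrix],
        f"structure_{cfg.chain}": [ss] * n,
    })
    if silent_path is not None:
        dio.write_silent(table, silent_path, chain=cfg.chain)
    return table


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

def segment_dihedrals(cfg: FixtureConfig) -> np.ndarray:
    """(n, 3) phi/psi/omega per residue from the segment layout."""
    rows = []
    for kind, n in cfg.segments:
        phi, psi = SEGMENT_DIHEDRALS[kind]
        rows += [(phi, psi, 180.0)] * n
    return np.asarray(rows, dtype=float)


def make_backbone(cfg: FixtureConfig,
                  pdb_path: str | None = None,
                  sequence: str | None = None) -> StructureRecord:
    """Ideal-geometry backbone from the configured segment dihedrals."""
    angles = segment_dihedrals(cfg)
    coords = build_backbone(angles[:, 0], angles[:, 1], angles[:, 2])
    if sequence is None:
        rng = cfg.rng(2)
        letters = np.array(list(AA_ALPHABET))
        sequence = "".join(letters[rng.integers(0, len(letters),
                                                size=cfg.length)])
    structure = backbone_to_structure(coords, sequence, chain=cfg.chain)
    if pdb_path is not None:
        dio.write_pdb_backbone(structure, pdb_path)
    return structure


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def make_fragments(cfg: FixtureConfig, source: StructureRecord,
                   path: str | None = None,
                   noise_sd: float | None = None) -> FragmentSet:
    """Fragment library sampled around the source structure's dihedrals.

    Each frame at position p holds ``n_neighbors`` instances whose angles
    are the source window's phi/psi/omega plus independent zero-mean
    normal noise of ``noise_sd`` degrees (wrapped into (-180, 180]).
    Angles that are undefined at the source termini are stored as 0.0; the
    reconstruction never consumes them.  With ``noise_sd=0`` the first
    neighbor of every frame reproduces the query window exactly.
    """
    if noise_sd is None:
        noise_sd = cfg.fragment_noise_sd
    rng = cfg.rng(3)
    chain = cfg.chain
    triples = backbone_dihedrals(source, chain)
    seq = source.sequence(chain)
    residues = source.residues(chain)
    angles = np.array([(t.phi, t.psi, t.omega) for t in triples])
    angles = np.nan_to_num(angles, nan=0.0)
    k = cfg.frame_size
    frames = []
    for p in range(1, len(residues) - k + 2):
        frame = FragmentFrame(position=p)
        window = angles[p - 1:p - 1 + k]
        for j in range(cfg.n_neighbors):
            noise = rng.normal(0.0, noise_sd, size=(k, 3)) \
                if noise_sd > 0 else np.zeros((k, 3))
            if j == 0:
                noise[:] = 0.0  # first neighbor is the exact window
            vals = window + noise
            residues_out = []
            for i in range(k):
                residue = residues[p - 1 + i]
                residues_out.append(FragmentResidue(
                    source_id="synth", chain=chain, residue=residue.number,
                    aa=seq[p - 1 + i], ss="L",
                    phi=wrap_angle(vals[i, 0]), psi=wrap_angle(vals[i, 1]),
                    omega=wrap_angle(vals[i, 2])))
            frame.instances.append(FragmentInstance(tuple(residues_out)))
        frames.append(frame)
    fs = FragmentSet(frames, frame_size=k)
    if path is not None:
        dio.write_fragments(fs, path)
    return fs


# ---------------------------------------------------------------------------
# experimental-style traces
# ---------------------------------------------------------------------------

def make_traces(cfg: FixtureConfig,
                cd_path: str | None = None,
                spr_path: str | None = None,
                ) -> tuple[dio.CDTrace, dio.SPRTrace]:
    """Synthetic CD melt (two-state helix-coil) and SPR (1:1 Langmuir) data."""
    rng = cfg.rng(4)
    # CD: helix fraction melts sigmoidally around Tm
    wavelengths = np.arange(195.0, 260.5, 1.0)
    temps = np.linspace(20.0, 90.0, cfg.n_temperatures)
    helix = (-12 * np.exp(-((wavelengths - 208.0) / 6.0) ** 2)
             - 11 * np.exp(-((wavelengths - 222.0) / 8.0) ** 2)
             + 18 * np.exp(-((wavelengths - 193.0) / 5.0) ** 2)) * 1000
    coil = (-14 * np.exp(-((wavelengths - 198.0) / 6.0) ** 2)
            + 2 * np.exp(-((wavelengths - 220.0) / 15.0) ** 2)) * 1000
    cd_rows = []
    for T in temps:
        f_helix = 1.0 / (1.0 + np.exp((T - cfg.melt_tm) / 6.0))
        spectrum = f_helix * helix + (1 - f_helix) * coil
        spectrum = spectrum + rng.normal(0, 120.0, size=len(wavelengths))
        for w, e in zip(wavelengths, spectrum):
            cd_rows.append({"wavelength": w, "ellipticity": round(e, 2),
                            "temperature": round(T, 1)})
    cd = dio.CDTrace(pd.DataFrame(cd_rows))

    # SPR: association 0-120 s, dissociation 120-300 s
    kd = cfg.kd_nM
    kon = 1e-3          # 1/(nM s)
    koff = kon * kd     # 1/s
    rmax = 120.0
    t_assoc = np.arange(0.0, 120.0, 1.0)
    t_dissoc = np.arange(120.0, 300.0, 1.0)
    concs = kd * np.array([0.25, 0.5, 1, 2, 4])[:cfg.n_concentrations]
    spr_rows = []
    for c in concs:
        kobs = kon * c + koff
        req = rmax * c / (c + kd)
        assoc = req * (1 - np.exp(-kobs * t_assoc))
        r0 = assoc[-1]
        dissoc = r0 * np.exp(-koff * (t_dissoc - t_assoc[-1]))
        fitted = np.concatenate([assoc, dissoc])
        times = np.concatenate([t_assoc, t_dissoc])
        measured = fitted + rng.normal(0, 1.0, size=len(fitted))
        label = f"{c:g}nM"
        for t, r in zip(times, measured):
            spr_rows.append({"time": t, "response": round(r, 3),
                             "series": "measured", "concentration": label})
        for t, r in zip(times, fitted):
            spr_rows.append({"time": t, "response": round(r, 3),
                             "series": "fitted", "concentration": label})
    spr = dio.SPRTrace(pd.DataFrame(spr_rows))

    if cd_path is not None:
        dio.write_CD(cd, cd_path)
    if spr_path is not None:
        dio.write_SPR(spr, spr_path)
    return cd, spr


# ---------------------------------------------------------------------------
# reference domain table
# ---------------------------------------------------------------------------

def make_reference_table(cfg: FixtureConfig, n_domains: int = 50,
                         path: str | None = None) -> pd.DataFrame:
    """A synthetic stand-in for a pre-calculated domain reference set.

    Columns id/length/score/cav_vol, lengths spread around the design
    length, scores loosely length-dependent.  Purely synthetic: a generic
    user-supplied reference table, not data from any real domain database.
    """
    rng = cfg.rng(5)
    lengths = rng.integers(cfg.length - 15, cfg.length + 16, size=n_domains)
    scores = -2.1 * lengths + rng.normal(0, 12, size=n_domains)
    cav = np.abs(rng.normal(30, 18, size=n_domains))
    df = pd.DataFrame({
        "id": [f"dom_{i:04d}" for i in range(n_domains)],
        "length": lengths,
        "score": np.round(scores, 2),
        "cav_vol": np.round(cav, 1),
    })
    if path is not None:
        df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# full corpus
# ---------------------------------------------------------------------------

def make_corpus(cfg: FixtureConfig, out_dir: str,
                parts: tuple[str, ...] = ("population", "backbone",
                                          "fragments", "traces",
                                          "reference")) -> dict[str, str]:
    """Generate the whole synthetic corpus and a manifest of output paths."""
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict[str, str] = {}
    structure = None
    if "population" in parts:
        path = os.path.join(out_dir, "population.silent")
        make_population(cfg, silent_path=path)
        manifest["population"] = path
    if "backbone" in parts or "fragments" in parts:
        path = os.path.join(out_dir, "backbone.pdb")
        structure = make_backbone(cfg, pdb_path=path)
        manifest["backbone"] = path
    if "fragments" in parts:
        path = os.path.join(out_dir, "fragments.9mers")
        make_fragments(cfg, structure, path=path)
        manifest["fragments"] = path
    if "traces" in parts:
        cd_path = os.path.join(out_dir, "cd.csv")
        spr_path = os.path.join(out_dir, "spr.csv")
        make_traces(cfg, cd_path=cd_path, spr_path=spr_path)
        manifest["cd"] = cd_path
        manifest["spr"] = spr_path
    if "reference" in parts:
        path = os.path.join(out_dir, "reference.csv")
        make_reference_table(cfg, path=path)
        manifest["reference"] = path
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({"config": dataclasses.asdict(cfg), "files": manifest},
                  fh, indent=2)
    manifest["manifest"] = manifest_path
    return manifest
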