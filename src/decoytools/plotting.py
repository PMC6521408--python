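"""The plot gallery: logos, heatmaps, Ramachandran panels, score profiles.

All functions render onto a supplied matplotlib Axes (or create one), never
mutate their input containers, and work headlessly (Agg).  Figure sizes can
be given in millimetres via :func:`mm_figure` (journals typically ask for
170 mm wide figures); output goes to PNG (dpi configurable, 300 by
default) or SVG through :func:`save_panel`.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import matplotlib
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.font_manager import FontProperties
from matplotlib.patches import PathPatch, Polygon, Rectangle
from matplotlib.textpath import TextPath
from matplotlib.transforms import Affine2D

from .components import (DesignTable, FragmentSet, FrequencyMatrix,
                         SelectionRange, as_selection)
from .io import CDTrace, SPRTrace
from .seqstats import PositionScoreTrack, letter_heights

MM_PER_INCH = 25.4


def mm_figure(width_mm: float = 170.0, height_mm: float = 170.0,
              ) -> plt.Figure:
    """A figure sized in millimetres."""
    return plt.figure(figsize=(width_mm / MM_PER_INCH,
                               height_mm / MM_PER_INCH))


def save_panel(fig: plt.Figure, path: str, dpi: int = 300):
    fig.savefig(path, dpi=dpi, bbox_inches="tight")


def add_top_title(ax: plt.Axes, title: str, **kwargs):
    ax.set_title(title, **kwargs)


def _ensure_ax(ax: plt.Axes | None) -> plt.Axes:
    if ax is None:
        _, ax = plt.subplots()
    return ax


# ---------------------------------------------------------------------------
# Ramachandran
# ---------------------------------------------------------------------------

# Coarse embedded favoured/allowed regions per flavour: rough convex
# polygons around the canonical basins (alpha, beta, left-handed alpha and
# the glycine/proline-specific variants).  These are deliberately coarse
# backgrounds for orientation, not statistical contours.
_ALPHA = [(-160, -70), (-160, -5), (-45, -5), (-45, -70)]
_BETA = [(-180, 90), (-180, 180), (-45, 180), (-45, 90)]
_BETA_LOW = [(-180, -180), (-180, -150), (-45, -150), (-45, -180)]
_LALPHA = [(40, 0), (40, 90), (100, 90), (100, 0)]

RAMA_REGIONS: dict[str, list[list[tuple[float, float]]]] = {
    "GENERAL": [_ALPHA, _BETA, _BETA_LOW, _LALPHA],
    "GLY": [_ALPHA, _BETA, _BETA_LOW, _LALPHA,
            [(45, -90), (45, 0), (180, 0), (180, -90)]],
    "PRE-PRO": [_ALPHA, _BETA, _BETA_LOW, _LALPHA],
    "PRO": [[(-110, -60), (-110, 0), (-45, 0), (-45, -60)],
            [(-110, 100), (-110, 180), (-45, 180), (-45, 100)]],
}


def plot_ramachandran(dihedrals, classes: Sequence[str],
                      flavour: str = "GENERAL",
                      ax: plt.Axes | None = None,
                      color: str = "C0") -> plt.Axes:
    """Scatter phi/psi of the residues of one Ramachandran flavour.

    ``dihedrals`` is a sequence of objects with ``phi``/``psi`` attributes
    (``geometry.DihedralTriple``); ``classes`` the parallel flavour labels.
    Backgrounds are the coarse embedded favoured regions; axes span
    exactly [-180, 180].  An empty flavour renders an annotated empty panel.
    """
    if flavour not in RAMA_REGIONS:
        raise ValueError(f"unknown flavour {flavour!r}; "
                         f"choose from {sorted(RAMA_REGIONS)}")
    ax = _ensure_ax(ax)
    for poly in RAMA_REGIONS[flavour]:
        ax.add_patch(Polygon(poly, closed=True, facecolor="0.85",
                             edgecolor="0.7", zorder=0))
    phis, psis = [], []
    for t, cls in zip(dihedrals, classes):
        if cls == flavour and not (math.isnan(t.phi) or math.isnan(t.psi)):
            phis.append(t.phi)
            psis.append(t.psi)
    if phis:
        ax.scatter(phis, psis, s=12, c=color, zorder=2)
    else:
        ax.text(0, 0, f"no {flavour} residues", ha="center", va="center",
                fontsize=8, color="0.4")
    ax.set_xlim(-180, 180)
    ax.set_ylim(-180, 180)
    ax.axhline(0, color="0.6", lw=0.5)
    ax.axvline(0, color="0.6", lw=0.5)
    ax.set_xlabel(r"$\phi$ (deg)")
    ax.set_ylabel(r"$\psi$ (deg)")
    ax.set_title(flavour)
    return ax


# ---------------------------------------------------------------------------
# fragment quality
# ---------------------------------------------------------------------------

def plot_fragment_quality(fragments: FragmentSet,
                          region=None,
                          ax: plt.Axes | None = None,
                          color: str = "C0") -> plt.Axes:
    """Per-neighbor RMSD points and the per-frame minimum line vs position."""
    if fragments.quality is None:
        raise ValueError("fragment set has no quality; run "
                         "geometry.fragment_quality first")
    fs = fragments
    sel = as_selection(region)
    if sel is not None:
        fs = fragments.slice_region(sel.lo, sel.hi)
    ax = _ensure_ax(ax)
    q = fs.quality.dropna(subset=["rmsd"])
    ax.scatter(q["position"], q["rmsd"], s=4, alpha=0.25, c=color,
               edgecolors="none")
    profile = q.groupby("position")["rmsd"].min()
    ax.plot(profile.index, profile.to_numpy(), color=color, lw=1.5,
            label="per-frame min")
    ax.set_xlabel("position")
    ax.set_ylabel("CA RMSD (Å)")
    ax.set_ylim(bottom=0)
    return ax


# ---------------------------------------------------------------------------
# sequence logo
# ---------------------------------------------------------------------------

# WebLogo-style chemistry colours.
AA_COLORS = {}
for _aa in "GSTYC":           # polar
    AA_COLORS[_aa] = "#109648"
for _aa in "NQ":              # neutral amides
    AA_COLORS[_aa] = "#5E239D"
for _aa in "KRH":             # basic
    AA_COLORS[_aa] = "#255C99"
for _aa in "DE":              # acidic
    AA_COLORS[_aa] = "#D62839"
for _aa in "AVLIPWFM":        # hydrophobic
    AA_COLORS[_aa] = "#221E22"

_LOGO_FONT = FontProperties(family="DejaVu Sans", weight="bold")


def _draw_letter(ax, letter: str, x: float, y: float, width: float,
                 height: float, color: str):
    tp = TextPath((0, 0), letter, size=1.0, prop=_LOGO_FONT)
    bbox = tp.get_extents()
    if bbox.width == 0 or bbox.height == 0 or height <= 0:
        return
    transform = (Affine2D()
                 .translate(-bbox.x0, -bbox.y0)
                 .scale(width / bbox.width, height / bbox.height)
                 .translate(x, y))
    ax.add_patch(PathPatch(tp.transformed(transform), facecolor=color,
                           edgecolor="none"))


def plot_logo(fm: FrequencyMatrix, key_residues=None,
              ax: plt.Axes | None = None,
              show_reference: bool = True,
              heights: str = "bits") -> plt.Axes:
    """Stacked-letter sequence logo of a frequency matrix.

    Letter heights are information-content based (frequency x bits,
    ``heights="bits"``) or raw frequencies (``heights="frequency"``);
    stacks are drawn in ascending frequency order.  When a reference
    sequence is attached and ``show_reference`` is set, the template's
    residue types are shown along an upper x axis.
    """
    sub = fm.select(key_residues)
    if len(sub.df) == 0:
        raise ValueError("empty selection for logo plot")
    ax = _ensure_ax(ax)
    if heights == "bits":
        hmat = letter_heights(sub)
        ymax = math.log2(20)
        ax.set_ylabel("bits")
    elif heights == "frequency":
        hmat = sub.df
        ymax = 1.0
        ax.set_ylabel("frequency")
    else:
        raise ValueError(f"unknown heights mode {heights!r}")
    positions = list(hmat.index)
    for x, pos in enumerate(positions):
        row = hmat.loc[pos]
        y = 0.0
        for letter, h in row[row > 1e-9].sort_values().items():
            _draw_letter(ax, str(letter), x + 0.05, y, 0.9, float(h),
                         AA_COLORS.get(str(letter), "0.3"))
            y += float(h)
    ax.set_xlim(0, len(positions))
    ax.set_ylim(0, ymax)
    ax.set_xticks([i + 0.5 for i in range(len(positions))])
    ax.set_xticklabels([str(p) for p in positions], rotation=90, fontsize=7)
    ax.set_xlabel("position")
    if show_reference and sub.reference is not None:
        top = ax.secondary_xaxis("top")
        top.set_xticks([i + 0.5 for i in range(len(positions))])
        ref = sub.reference
        labels = []
        for p in positions:
            idx = p - ref.shift
            labels.append(ref.sequence[idx]
                          if 0 <= idx < len(ref.sequence) else "")
        top.set_xticklabels(labels, fontsize=7)
    return ax


# ---------------------------------------------------------------------------
# frequency heatmap
# ---------------------------------------------------------------------------

def plot_frequency_heatmap(fm: FrequencyMatrix, key_residues=None,
                           clean_unused: float | None = None,
                           ax: plt.Axes | None = None,
                           cbar: bool = True,
                           cbar_ax: plt.Axes | None = None,
                           xrotation: float = 90) -> plt.Axes:
    """Position x letter heatmap (darker blue = higher frequency).

    Letters whose maximum frequency over the shown positions is below
    ``clean_unused`` are dropped from the y axis; when a reference is
    attached its residue types are outlined in green frames.
    """
    import seaborn as sns
    sub = fm.select(key_residues)
    data = sub.df.copy()
    if clean_unused is not None:
        keep = [c for c in data.columns if data[c].max() >= clean_unused]
        data = data[keep]
    ax = _ensure_ax(ax)
    sns.heatmap(data.T, ax=ax, cmap="Blues", vmin=0,
                vmax=max(float(data.to_numpy().max()), 1e-9),
                cbar=cbar or cbar_ax is not None, cbar_ax=cbar_ax)
    if sub.reference is not None:
        letters = list(data.columns)
        for x, pos in enumerate(data.index):
            idx = pos - sub.reference.shift
            if 0 <= idx < len(sub.reference.sequence):
                aa = sub.reference.sequence[idx]
                if aa in letters:
                    y = letters.index(aa)
                    ax.add_patch(Rectangle((x, y), 1, 1, fill=False,
                                           edgecolor="green", lw=1.5))
    ax.set_xticks(np.arange(len(data.index)) + 0.5)
    ax.set_xticklabels([str(p) for p in data.index], rotation=xrotation,
                       fontsize=7)
    ax.set_xlabel("position")
    return ax


# ---------------------------------------------------------------------------
# distributions and context
# ---------------------------------------------------------------------------

def plot_distributions(table: pd.DataFrame, terms: Sequence[str],
                       fig: plt.Figure | None = None,
                       grid: tuple[int, int] | None = None,
                       group_by: str | None = None,
                       order: Sequence[str] | None = None,
                       refdata: pd.DataFrame | None = None,
                       labels: Sequence[str] | None = None,
                       violins: bool = False,
                       showfliers: bool = False) -> list[plt.Axes]:
    """One box/violin panel per score term, optionally against a reference.

    ``group_by`` draws one box per category (in ``order``, which also fixes
    the colour cycle); ``refdata`` overlays a second population side by
    side (labelled via ``labels``, default population/reference).
    ``labels`` may also rename the panel titles when it matches ``terms``.
    """
    import seaborn as sns
    for term in terms:
        if not pd.api.types.is_numeric_dtype(pd.DataFrame(table)[term]):
            raise TypeError(f"score term {term!r} is not numeric")
    if fig is None:
        fig = mm_figure(170, 60 * ((len(terms) + 3) // 4))
    if grid is None:
        grid = (1, len(terms))
    axes = []
    plotter = sns.violinplot if violins else sns.boxplot
    for i, term in enumerate(terms):
        ax = fig.add_subplot(grid[0], grid[1], i + 1)
        df = pd.DataFrame(table)
        if refdata is not None:
            lab = labels if labels and len(labels) == 2 \
                else ("population", "reference")
            a = df[[c for c in df.columns]].copy()
            a["__pop__"] = lab[0]
            b = pd.DataFrame(refdata).copy()
            b["__pop__"] = lab[1]
            both = pd.concat([a, b], ignore_index=True)
            kwargs = {} if violins else {"showfliers": showfliers}
            plotter(data=both, x="__pop__", y=term, hue="__pop__",
                    order=list(lab), ax=ax, **kwargs)
            ax.set_xlabel("")
        elif group_by is not None:
            kwargs = {} if violins else {"showfliers": showfliers}
            plotter(data=df, x=group_by, y=term, hue=group_by,
                    order=list(order) if order else None, ax=ax, **kwargs)
        else:
            kwargs = {} if violins else {"showfliers": showfliers}
            plotter(data=df, y=term, ax=ax, **kwargs)
        ax.set_title(term)
        axes.append(ax)
    fig.tight_layout()
    return axes


def plot_in_context(query: pd.DataFrame, reference: pd.DataFrame,
                    terms: Sequence[str],
                    fig: plt.Figure | None = None,
                    baselines: dict[str, float] | None = None,
                    ) -> list[plt.Axes]:
    """Reference distributions per term with the query decoys marked.

    Each panel shows the reference population (e.g. natural domains of
    similar size) as a histogram with the query decoys as vertical marks;
    ``baselines`` adds a dashed black line per term (e.g. the original
    scaffold's value).
    """
    ref = pd.DataFrame(reference)
    if ref.empty:
        raise ValueError("empty reference table")
    for term in terms:
        if term not in ref.columns:
            raise KeyError(f"term {term!r} absent from reference table")
    if fig is None:
        fig = mm_figure(170, 60)
    axes = []
    qdf = pd.DataFrame(query)
    for i, term in enumerate(terms):
        ax = fig.add_subplot(1, len(terms), i + 1)
        ax.hist(ref[term].dropna(), bins=30, color="0.8",
                edgecolor="0.6", density=True)
        if term in qdf.columns:
            for value in qdf[term].dropna():
                ax.axvline(value, color="C0", lw=1.2, alpha=0.8)
        if baselines and term in baselines:
            ax.axvline(baselines[term], color="k", linestyle="--")
        ax.set_xlabel(term)
        axes.append(ax)
    fig.tight_layout()
    return axes


# ---------------------------------------------------------------------------
# per-residue score track
# ---------------------------------------------------------------------------

def plot_score_track(tracks: "PositionScoreTrack | Sequence[PositionScoreTrack]",
                     selections: Sequence[tuple] = (),
                     ax: plt.Axes | None = None,
                     colors: Sequence[str] | None = None) -> plt.Axes:
    """Per-position substitution-score lines with highlighted ranges.

    Undefined (NaN) cells break the line; each ``(range, colour)`` entry in
    ``selections`` shades the inclusive residue range (e.g. a binding
    region) across the panel.
    """
    if isinstance(tracks, PositionScoreTrack):
        tracks = [tracks]
    ax = _ensure_ax(ax)
    colors = colors or [f"C{i}" for i in range(len(tracks))]
    for track, color in zip(tracks, colors):
        ax.plot(track.positions, track.scores, color=color, lw=1.2,
                label=track.query_id)
    for expr, color in selections:
        sel = SelectionRange(expr)
        ax.axvspan(sel.lo - 0.5, sel.hi + 0.5, color=color, alpha=0.25,
                   zorder=0)
    ax.set_xlabel("position")
    ax.set_ylabel(f"{tracks[0].matrix} score")
    ax.axhline(0, color="0.6", lw=0.5)
    return ax


# ---------------------------------------------------------------------------
# experimental traces
# ---------------------------------------------------------------------------

def plot_cd(trace: CDTrace, ax: plt.Axes | None = None,
            sample: int | None = None) -> plt.Axes:
    """Mean-residue ellipticity vs wavelength, one line per temperature.

    ``sample`` thins the melt to that many evenly spaced temperatures.
    """
    temps = trace.temperatures
    if not temps:
        raise ValueError("CD trace has no series")
    if sample is not None and sample < len(temps):
        idx = np.linspace(0, len(temps) - 1, sample).round().astype(int)
        temps = [temps[i] for i in sorted(set(idx))]
    ax = _ensure_ax(ax)
    cmap = matplotlib.colormaps["coolwarm"]
    for i, temp in enumerate(temps):
        grp = trace.data[trace.data["temperature"] == temp]
        ax.plot(grp["wavelength"], grp["ellipticity"],
                color=cmap(i / max(len(temps) - 1, 1)), label=str(temp))
    ax.set_xlabel("wavelength (nm)")
    ax.set_ylabel(r"MRE (deg cm$^2$ dmol$^{-1}$)")
    ax.legend(fontsize=6, title="T", ncol=2)
    return ax


def plot_spr(trace: SPRTrace, ax: plt.Axes | None = None,
             fitcolor: str = "black") -> plt.Axes:
    """Sensorgrams: measured series per concentration, fits in one colour."""
    if trace.data.empty:
        raise ValueError("SPR trace has no series")
    ax = _ensure_ax(ax)
    concs = trace.concentrations
    cmap = matplotlib.colormaps["viridis"]
    for i, conc in enumerate(concs):
        sub = trace.data[trace.data["concentration"] == conc]
        measured = sub[sub["series"] == "measured"]
        fitted = sub[sub["series"] == "fitted"]
        if not measured.empty:
            ax.plot(measured["time"], measured["response"],
                    color=cmap(i / max(len(concs) - 1, 1)), lw=1.0,
                    label=str(conc))
        if not fitted.empty:
            ax.plot(fitted["time"], fitted["response"], color=fitcolor,
                    lw=1.0, linestyle="--")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("response (RU)")
    ax.legend(fontsize=6, title="conc")
    return ax
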