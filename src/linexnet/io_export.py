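"""Reading abundance tables; exporting networks, tables, colors and HTML.

The abundance table is the single input of an analysis: a rectangular
CSV/TSV of samples × lipid species (either orientation; auto-detected by
which axis parses as lipid names) plus a group label per sample, given
as a column of the table or a separate two-column file.

Networks are exported as GraphML and node-link JSON (both read back
losslessly), node/edge attribute CSVs, and a self-contained static HTML
view.  A shipped color scheme assigns each of 46 common lipid classes a
hex color; classes of one family share a hue, lyso species are brighter
and ether species darker than their parent class.
"""

from __future__ import annotations

import colorsys
import html
import json
import warnings
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import networkx as nx
import numpy as np
import pandas as pd

from .differential_stats import AbundanceTable, ChangeCategory
from .lipid_model import LipidParseError, canonical_name, parse_lipid_name
from .network_builder import LipidNetwork
from .reaction_rules import RuleSet, default_ruleset

__all__ = [
    "read_abundance_table",
    "write_graphml",
    "read_graphml",
    "write_json",
    "read_json",
    "write_node_table",
    "write_edge_table",
    "default_color_scheme",
    "apply_colors",
    "hex_lightness",
    "lyso_parent",
    "ether_parent",
    "render_html",
    "CHANGE_CATEGORY_COLORS",
    "REACTION_TYPE_COLORS",
    "FALLBACK_COLOR",
]

JSON_SCHEMA_VERSION = 1
FALLBACK_COLOR = "#808080"

#: Edge palette for correlation-change categories (legend semantics:
#: green = became significant, cyan = lost significance, gray = never
#: significant, blue = stayed significant, magenta = flipped sign).
CHANGE_CATEGORY_COLORS: Dict[str, str] = {
    ChangeCategory.TURNED_SIGNIFICANT.value: "#2ca02c",
    ChangeCategory.TURNED_INSIGNIFICANT.value: "#17becf",
    ChangeCategory.UNCHANGED_INSIGNIFICANT.value: "#aaaaaa",
    ChangeCategory.UNCHANGED_SIGNIFICANT.value: "#1f77b4",
    ChangeCategory.SIGN_CHANGE.value: "#e31ec8",
}

REACTION_TYPE_COLORS: Dict[str, str] = {
    "class_conversion": "#7f3fbf",
    "fa_addition_removal": "#d97f32",
    "elongation": "#3f8f3f",
    "desaturation": "#b02f2f",
    "oxidation": "#2f6fb0",
}


# ---------------------------------------------------------------------------
# Abundance table input
# ---------------------------------------------------------------------------

def _read_rectangular(path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab (decimal point only)
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def _parse_rate(names: Iterable[str], registry, synonyms: Mapping[str, str]) -> float:
    names = list(names)
    if not names:
        return 0.0
    ok = 0
    for name in names:
        try:
            parse_lipid_name(synonyms.get(str(name), str(name)), registry)
            ok += 1
        except (LipidParseError, ValueError):
            pass
    return ok / len(names)


def _load_synonyms(source) -> Dict[str, str]:
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return {str(k): str(v) for k, v in source.items()}
    frame = pd.read_csv(source, sep=None, engine="python", header=None)
    if frame.shape[1] < 2:
        raise ValueError("synonym file needs two columns: alias, name")
    first = frame.iloc[0]
    if str(first[0]).lower() in {"alias", "synonym", "from"}:
        frame = frame.iloc[1:]
    return {str(a): str(b) for a, b in zip(frame.iloc[:, 0], frame.iloc[:, 1])}


def _load_groups(source, sample_ids: List[str]) -> pd.Series:
    frame = pd.read_csv(source, sep=None, engine="python", header=None)
    if frame.shape[1] < 2:
        raise ValueError("group file needs two columns: sample, group")
    if str(frame.iloc[0, 0]) not in set(map(str, sample_ids)):
        frame = frame.iloc[1:]  # header row
    return pd.Series(
        frame.iloc[:, 1].astype(str).to_numpy(),
        index=frame.iloc[:, 0].astype(str).to_numpy(),
    )


def read_abundance_table(
    path,
    orientation: str = "auto",
    group_col: Optional[str] = None,
    group_file=None,
    rules: Optional[RuleSet] = None,
    synonyms=None,
    drop_unparseable: bool = False,
) -> AbundanceTable:
    """Read a samples × lipids abundance table with group labels.

    Parameters
    ----------
    orientation:
        ``"samples_rows"``, ``"lipids_rows"`` or ``"auto"``: with auto,
        the axis whose labels parse as lipid names at the higher rate
        becomes the lipid axis.
    group_col:
        Name of a table column holding the group label per sample
        (samples-rows orientation).
    group_file:
        Two-column CSV/TSV (sample id, group label); header optional.
    synonyms:
        Optional mapping or two-column file translating dataset-specific
        aliases (e.g. ``Cholesterol ester(18:2)``) to parseable names.
    drop_unparseable:
        Drop lipid columns that fail to parse (with a warning) instead
        of raising.

    Lipid names are canonicalized; collisions after canonicalization are
    an error listing the colliding inputs.
    """
    rules = rules or default_ruleset()
    registry = rules.registry
    synonym_map = _load_synonyms(synonyms)

    frame = _read_rectangular(path)

    if orientation == "auto":
        col_names = [c for c in frame.columns if c != group_col]
        rate_cols = _parse_rate(col_names, registry, synonym_map)
        rate_rows = _parse_rate(frame.index, registry, synonym_map)
        orientation = "lipids_rows" if rate_rows > rate_cols else "samples_rows"
    if orientation == "lipids_rows":
        frame = frame.T
    elif orientation != "samples_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    groups: Optional[pd.Series] = None
    if group_col is not None:
        if group_col not in frame.columns:
            raise ValueError(f"group column {group_col!r} not in table")
        groups = frame[group_col].astype(str)
        frame = frame.drop(columns=[group_col])
    if group_file is not None:
        groups = _load_groups(group_file, [str(i) for i in frame.index])
    if groups is None:
        raise ValueError("no group annotation: pass group_col or group_file")

    canonical: Dict[str, str] = {}
    collisions: Dict[str, List[str]] = {}
    unparseable: List[str] = []
    for raw in frame.columns:
        name = synonym_map.get(str(raw), str(raw))
        try:
            species = parse_lipid_name(name, registry)
        except (LipidParseError, ValueError):
            unparseable.append(str(raw))
            continue
        canon = canonical_name(species)
        collisions.setdefault(canon, []).append(str(raw))
        canonical[str(raw)] = canon

    if unparseable:
        if not drop_unparseable:
            raise ValueError(
                f"{len(unparseable)} lipid name(s) failed to parse: "
                + ", ".join(unparseable)
            )
        warnings.warn(
            f"dropping {len(unparseable)} unparseable lipid name(s): "
            + ", ".join(unparseable[:10]),
            stacklevel=2,
        )
        frame = frame.drop(columns=unparseable)
    if not canonical:
        raise ValueError("no parseable lipid names in table")

    clashes = {c: raws for c, raws in collisions.items() if len(raws) > 1}
    if clashes:
        detail = "; ".join(f"{c} <- {raws}" for c, raws in sorted(clashes.items()))
        raise ValueError(f"duplicate lipids after canonicalization: {detail}")

    frame = frame.rename(columns=canonical)
    frame = frame.astype(float)
    frame.index = frame.index.astype(str)
    frame.index.name = "sample"
    frame.columns.name = None
    groups.index = groups.index.astype(str)
    missing = frame.index.difference(groups.index)
    if len(missing):
        raise ValueError(f"samples without group label: {missing.tolist()}")
    return AbundanceTable(data=frame, groups=groups.loc[frame.index])


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------

_SCALAR_TYPES = (str, int, float, bool, np.integer, np.floating)


def _flatten(net: LipidNetwork) -> nx.Graph:
    """Copy with only scalar attributes (objects like the parsed species
    are represented by the flat attributes written at build time)."""
    flat = nx.Graph()
    for key, value in net.graph.items():
        if isinstance(value, _SCALAR_TYPES):
            flat.graph[key] = value
    for node, data in net.nodes(data=True):
        flat.add_node(
            node,
            **{k: v for k, v in data.items() if isinstance(v, _SCALAR_TYPES)},
        )
    for u, v, data in net.edges(data=True):
        flat.add_edge(
            u, v, **{k: w for k, w in data.items() if isinstance(w, _SCALAR_TYPES)}
        )
    return flat


def write_graphml(net: LipidNetwork, path) -> None:
    """Write the network as GraphML with typed attribute keys."""
    nx.write_graphml(_flatten(net), path)


def read_graphml(path) -> LipidNetwork:
    return nx.read_graphml(path)


def write_json(net: LipidNetwork, path) -> None:
    """Write the network as node-link JSON with a schema version."""
    doc = nx.node_link_data(_flatten(net), edges="links")
    doc["schema_version"] = JSON_SCHEMA_VERSION
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(doc, handle, indent=1)


def read_json(path) -> LipidNetwork:
    with open(path, "r", encoding="utf-8") as handle:
        doc = json.load(handle)
    doc.pop("schema_version", None)
    return nx.node_link_graph(doc, edges="links")


def write_node_table(net: LipidNetwork, path) -> None:
    """One CSV row per node, one column per scalar attribute."""
    flat = _flatten(net)
    frame = pd.DataFrame.from_dict(dict(flat.nodes(data=True)), orient="index")
    frame.index.name = "lipid"
    frame.sort_index().to_csv(path)


def write_edge_table(net: LipidNetwork, path) -> None:
    """One CSV row per edge, one column per scalar attribute."""
    flat = _flatten(net)
    rows = [
        {"lipid_a": u, "lipid_b": v, **data} for u, v, data in flat.edges(data=True)
    ]
    frame = pd.DataFrame(rows, columns=None if rows else ["lipid_a", "lipid_b"])
    if rows:
        frame = frame.sort_values(["lipid_a", "lipid_b"])
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Color scheme
# ---------------------------------------------------------------------------

#: (class name, hue in degrees). Family membership is encoded by hue;
#: lyso (leading "L", or MLCL) and ether (" O-"/" P-" suffix) variants
#: derive their lightness from the diacyl parent.
_COLOR_CLASSES: Tuple[Tuple[str, float], ...] = (
    ("PC", 210), ("LPC", 210), ("PC O-", 214), ("LPC O-", 214),
    ("PC P-", 218), ("LPC P-", 218),
    ("PE", 25), ("LPE", 25), ("PE O-", 29), ("LPE O-", 29),
    ("PE P-", 33), ("LPE P-", 33),
    ("PS", 270), ("LPS", 270),
    ("PI", 120), ("LPI", 120), ("PIP", 128), ("PIP2", 134), ("PIP3", 140),
    ("PG", 160), ("LPG", 160), ("BMP", 168),
    ("PA", 0), ("LPA", 0),
    ("CL", 330), ("MLCL", 330),
    ("MG", 45), ("DG", 49), ("TG", 53), ("DG O-", 49), ("TG O-", 53),
    ("CE", 60), ("Chol", 64),
    ("FA", 20), ("FAHFA", 16), ("AC", 12),
    ("SPB", 290), ("S1P", 294), ("Cer", 300), ("CerP", 304), ("SM", 308),
    ("HexCer", 312), ("Hex2Cer", 316), ("Hex3Cer", 320),
    ("Sulfatide", 324), ("GM3", 286),
)

_BASE_LIGHTNESS = 0.45
_LYSO_DELTA = 0.18
_ETHER_DELTA = -0.13
_SATURATION = 0.60


def lyso_parent(class_name: str) -> Optional[str]:
    """Parent diacyl class of a lyso class (``LPC O-`` → ``PC O-``)."""
    if class_name == "MLCL":
        return "CL"
    if class_name.startswith("L") and len(class_name) > 1:
        return class_name[1:]
    return None


def ether_parent(class_name: str) -> Optional[str]:
    """Ester-linked counterpart of an ether class (``PE O-`` → ``PE``)."""
    for suffix in (" O-", " P-"):
        if class_name.endswith(suffix):
            return class_name[: -len(suffix)]
    return None


def _hex_color(hue_deg: float, lightness: float, saturation: float) -> str:
    r, g, b = colorsys.hls_to_rgb(hue_deg / 360.0, lightness, saturation)
    return "#{:02x}{:02x}{:02x}".format(
        round(r * 255), round(g * 255), round(b * 255)
    )


def hex_lightness(color: str) -> float:
    """HSL lightness component of a ``#RRGGBB`` color, in [0, 1]."""
    r, g, b = (int(color[i : i + 2], 16) / 255.0 for i in (1, 3, 5))
    return (max(r, g, b) + min(r, g, b)) / 2.0


def default_color_scheme() -> Dict[str, str]:
    """Hex colors for 46 common lipid classes.

    Classes of one family share a hue; every lyso class is strictly
    lighter and every ether class strictly darker than its parent.
    """
    scheme: Dict[str, str] = {}
    names = {name for name, _ in _COLOR_CLASSES}
    for name, hue in _COLOR_CLASSES:
        lightness = _BASE_LIGHTNESS
        if lyso_parent(name) in names or name == "MLCL":
            lightness += _LYSO_DELTA
        if ether_parent(name) in names:
            lightness += _ETHER_DELTA
        scheme[name] = _hex_color(hue, lightness, _SATURATION)
    return scheme


def apply_colors(
    net: LipidNetwork, scheme: Optional[Mapping[str, str]] = None
) -> LipidNetwork:
    """Attach a ``color`` node attribute from the class color scheme.

    Classes not covered by the scheme fall back to gray ``#808080``.
    """
    scheme = scheme if scheme is not None else default_color_scheme()
    for node, data in net.nodes(data=True):
        data["color"] = scheme.get(data.get("lipid_class", ""), FALLBACK_COLOR)
    return net


# ---------------------------------------------------------------------------
# Standalone HTML rendering
# ---------------------------------------------------------------------------

def _edge_color(data: Mapping, color_edges_by: Optional[str]) -> str:
    if color_edges_by and data.get(color_edges_by):
        return CHANGE_CATEGORY_COLORS.get(str(data[color_edges_by]), FALLBACK_COLOR)
    return REACTION_TYPE_COLORS.get(str(data.get("reaction_type", "")), FALLBACK_COLOR)


def render_html(
    net: LipidNetwork,
    path,
    color_edges_by: Optional[str] = None,
    seed: int = 42,
    title: str = "Lipid network",
) -> None:
    """Write a self-contained static HTML view of the network.

    A force-directed (spring) layout is computed here and embedded as
    SVG together with the node-link JSON and a legend; the file opens
    without any network access.  ``color_edges_by`` names an edge
    attribute holding correlation-change categories (e.g.
    ``change_A_vs_B``) to color edges by; otherwise edges are colored by
    reaction type.
    """
    flat = _flatten(net)
    pos = nx.spring_layout(flat, seed=seed) if len(flat) else {}
    width, height, margin = 900, 640, 60
    xs = [p[0] for p in pos.values()] or [0.0]
    ys = [p[1] for p in pos.values()] or [0.0]
    span_x = (max(xs) - min(xs)) or 1.0
    span_y = (max(ys) - min(ys)) or 1.0

    def project(p):
        x = margin + (p[0] - min(xs)) / span_x * (width - 2 * margin)
        y = margin + (p[1] - min(ys)) / span_y * (height - 2 * margin)
        return x, y

    svg: List[str] = []
    for u, v, data in flat.edges(data=True):
        (x1, y1), (x2, y2) = project(pos[u]), project(pos[v])
        svg.append(
            f'<line x1="{x1:.1f}" y1="{y1:.1f}" x2="{x2:.1f}" y2="{y2:.1f}" '
            f'stroke="{_edge_color(data, color_edges_by)}" stroke-width="2">'
            f"<title>{html.escape(str(data.get('reaction_type', '')))}</title></line>"
        )
    for node, data in flat.nodes(data=True):
        x, y = project(pos[node])
        color = data.get("color", FALLBACK_COLOR)
        svg.append(
            f'<circle cx="{x:.1f}" cy="{y:.1f}" r="9" fill="{color}" '
            f'stroke="#333"/>'
            f'<text x="{x + 11:.1f}" y="{y + 4:.1f}" font-size="11">'
            f"{html.escape(str(node))}</text>"
        )

    legend_rows = [
        f'<span style="color:{c}">&#9632;</span> {html.escape(label)}'
        for label, c in (
            [(f"edge: {k}", v) for k, v in CHANGE_CATEGORY_COLORS.items()]
            if color_edges_by
            else [(f"edge: {k}", v) for k, v in REACTION_TYPE_COLORS.items()]
        )
    ]
    doc = nx.node_link_data(flat, edges="links")
    doc["schema_version"] = JSON_SCHEMA_VERSION
    page = f"""<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{html.escape(title)}</title></head>
<body>
<h2>{html.escape(title)}</h2>
<svg width="{width}" height="{height}" xmlns="http://www.w3.org/2000/svg"
 style="border:1px solid #ccc;background:#fff">{''.join(svg)}</svg>
<p>{' &nbsp; '.join(legend_rows)}</p>
<p>Node color: lipid class; edge color: {'correlation change' if color_edges_by else 'reaction type'}.</p>
<script type="application/json" id="network-data">{json.dumps(doc)}</script>
</body></html>
"""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(page)
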