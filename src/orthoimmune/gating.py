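"""Per-cell event tables and hierarchical gating into leaf immune populations.

Gating mirrors conventional manual cytometry analysis: a tree of gate nodes,
each restricting one or two arcsinh-transformed surface channels to an
interval, with the 21 leaf nodes naming the immune populations of interest.
Cell frequencies use two denominators: neutrophils are expressed as a
percentage of gated singlets, every other population as a percentage of
mononuclear cells (CD45+ Ly6G-).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import PanelConfig

logger = logging.getLogger(__name__)

UNGATED = "UNGATED"
META_COLUMNS = ("sample_id", "animal_id", "sex", "timepoint")

#: Default arcsinh threshold separating "low" from "high" marker expression.
DEFAULT_GATE_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

@dataclass
class EventTable:
    """Per-cell raw marker intensities with sample annotations.

    ``data`` has one row per cell with the metadata columns
    (sample_id, animal_id, sex, timepoint) followed by one raw-intensity
    column per panel marker.  Arcsinh values are derived on demand so the
    raw and transformed scales can never drift apart.
    """

    data: pd.DataFrame
    panel: PanelConfig

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing metadata columns: {missing}")
        missing = [m for m in self.panel.markers if m not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing marker channels: {missing}")
        bad_sex = set(self.data["sex"].unique()) - {"M", "F"}
        if bad_sex:
            raise ValueError(f"sex labels must be 'M' or 'F', got {sorted(bad_sex)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> pd.DataFrame:
        """One metadata row per sample."""
        return (
            self.data[list(META_COLUMNS)]
            .drop_duplicates("sample_id")
            .set_index("sample_id", drop=False)
        )

    def arcsinh(self, markers=None) -> pd.DataFrame:
        """Arcsinh-transformed intensities for the requested markers."""
        markers = list(markers) if markers is not None else list(self.panel.markers)
        out = self.panel.arcsinh(self.data[markers].to_numpy())
        return pd.DataFrame(out, columns=markers, index=self.data.index)

    # -- text round trip ----------------------------------------------------

    def write(self, directory) -> None:
        """Write one delimited event file per sample plus a cohort manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = self.samples.reset_index(drop=True).copy()
        files = []
        for sid, chunk in self.data.groupby("sample_id", sort=True):
            fname = f"events_{sid}.csv"
            cols = list(self.panel.markers)
            tbl = chunk[cols].reset_index(drop=True)
            tbl.insert(0, "cell_id", np.arange(len(tbl)))
            tbl.to_csv(directory / fname, index=False, float_format="%.6g")
            files.append((sid, fname))
        fmap = dict(files)
        manifest["file"] = manifest["sample_id"].map(fmap)
        manifest.to_csv(directory / "manifest.csv", index=False)

    @classmethod
    def read(cls, directory, panel: PanelConfig) -> "EventTable":
        directory = Path(directory)
        manifest = pd.read_csv(directory / "manifest.csv")
        parts = []
        for row in manifest.itertuples(index=False):
            tbl = pd.read_csv(directory / row.file)
            tbl = tbl.drop(columns=["cell_id"], errors="ignore")
            for col in META_COLUMNS:
                tbl.insert(0, col, getattr(row, col))
            parts.append(tbl[list(META_COLUMNS) + list(panel.markers)])
        data = pd.concat(parts, ignore_index=True)
        return cls(data=data, panel=panel)


# ---------------------------------------------------------------------------
# Gating scheme
# ---------------------------------------------------------------------------

@dataclass
class GateNode:
    """One node of the gate hierarchy.

    ``gates`` maps marker name -> (lo, hi) interval on the arcsinh scale;
    ``None`` bounds are open.  A cell satisfies the node if it satisfies the
    node's own interval(s) and every ancestor's.
    """

    name: str
    parent: str | None
    gates: dict[str, tuple[float | None, float | None]] = field(default_factory=dict)


@dataclass
class GatingScheme:
    """Declarative gate tree with designated leaf populations and denominators."""

    nodes: dict[str, GateNode]
    leaves: tuple[str, ...]
    denominators: dict[str, str]  # role ("singlets"/"mononuclear") -> node name

    def __post_init__(self) -> None:
        self.leaves = tuple(self.leaves)
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError(f"gating scheme must have exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent is not None and node.parent not in self.nodes:
                raise ValueError(f"node {node.name!r} has unknown parent {node.parent!r}")
        children = {name: [] for name in self.nodes}
        for node in self.nodes.values():
            if node.parent is not None:
                children[node.parent].append(node.name)
        for leaf in self.leaves:
            if leaf not in self.nodes:
                raise ValueError(f"leaf {leaf!r} not in scheme")
            if children[leaf]:
                raise ValueError(f"leaf {leaf!r} has children")
        for role, name in self.denominators.items():
            if name not in self.nodes:
                raise ValueError(f"denominator {role!r} points at unknown node {name!r}")
        # cycle check via walk to root
        for name in self.nodes:
            seen = set()
            cur = name
            while cur is not None:
                if cur in seen:
                    raise ValueError("gating scheme contains a cycle")
                seen.add(cur)
                cur = self.nodes[cur].parent
        self._children = children

    @property
    def root(self) -> str:
        return next(n.name for n in self.nodes.values() if n.parent is None)

    def path(self, name: str) -> list[str]:
        """Node names from root to ``name`` inclusive."""
        out = []
        cur = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def required_markers(self) -> set[str]:
        return {m for node in self.nodes.values() for m in node.gates}

    def path_constraints(self, leaf: str) -> dict[str, tuple[float | None, float | None]]:
        """Intersection of gate intervals along the path to ``leaf``."""
        out: dict[str, tuple[float | None, float | None]] = {}
        for name in self.path(leaf):
            for marker, (lo, hi) in self.nodes[name].gates.items():
                plo, phi = out.get(marker, (None, None))
                lo = plo if lo is None else (lo if plo is None else max(lo, plo))
                hi = phi if hi is None else (hi if phi is None else min(hi, phi))
                out[marker] = (lo, hi)
        return out

    def leaf_order(self) -> list[str]:
        """Leaves in depth-first order (assignment priority)."""
        order = []

        def visit(name: str) -> None:
            if name in self.leaves:
                order.append(name)
            for child in sorted(self._children[name]):
                visit(child)

        visit(self.root)
        return order

    # -- YAML round trip ----------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "leaves": list(self.leaves),
            "denominators": dict(self.denominators),
            "nodes": [
                {
                    "name": n.name,
                    "parent": n.parent,
                    "gates": {m: [lo, hi] for m, (lo, hi) in n.gates.items()},
                }
                for n in self.nodes.values()
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GatingScheme":
        doc = yaml.safe_load(Path(path).read_text())
        nodes = {
            spec["name"]: GateNode(
                name=spec["name"],
                parent=spec["parent"],
                gates={m: tuple(iv) for m, iv in (spec.get("gates") or {}).items()},
            )
            for spec in doc["nodes"]
        }
        return cls(nodes=nodes, leaves=tuple(doc["leaves"]), denominators=doc["denominators"])


# ---------------------------------------------------------------------------
# Default scheme: 21 murine whole-blood populations
# ---------------------------------------------------------------------------

# (name, parent, marker, side): side "+" means arcsinh >= threshold, "-" below.
_DEFAULT_TREE: tuple[tuple[str, str | None, tuple[tuple[str, str], ...]], ...] = (
    ("singlets", None, ()),
    ("CD45pos", "singlets", (("CD45", "+"),)),
    ("Neutrophils", "CD45pos", (("Ly6G", "+"),)),
    ("mononuclear", "CD45pos", (("Ly6G", "-"),)),
    ("Tcells", "mononuclear", (("CD3", "+"),)),
    ("gdT", "Tcells", (("TCRgd", "+"),)),
    ("abT", "Tcells", (("TCRgd", "-"),)),
    ("NKT", "abT", (("NK1.1", "+"),)),
    ("convT", "abT", (("NK1.1", "-"),)),
    ("CD4T", "convT", (("CD4", "+"),)),
    ("Tregs", "CD4T", (("CD25", "+"),)),
    ("CD4nonTreg", "CD4T", (("CD25", "-"),)),
    ("CD4Tmem", "CD4nonTreg", (("CD44", "+"),)),
    ("CD4Tnaive", "CD4nonTreg", (("CD44", "-"),)),
    ("CD8T", "convT", (("CD8", "+"), ("CD4", "-"))),
    ("CD8Tmem", "CD8T", (("CD44", "+"),)),
    ("CD8Tnaive", "CD8T", (("CD44", "-"),)),
    ("nonT", "mononuclear", (("CD3", "-"),)),
    ("Blineage", "nonT", (("CD19", "+"),)),
    ("Bmem", "Blineage", (("CD44", "+"),)),
    ("Bcells", "Blineage", (("CD44", "-"),)),
    ("nonB", "nonT", (("CD19", "-"),)),
    ("Plasmablasts", "nonB", (("CD138", "+"),)),
    ("nonPB", "nonB", (("CD138", "-"),)),
    ("NK", "nonPB", (("NK1.1", "+"),)),
    ("nonNK", "nonPB", (("NK1.1", "-"),)),
    ("pDC", "nonNK", (("B220", "+"),)),
    ("nonpDC", "nonNK", (("B220", "-"),)),
    ("Eosinophils", "nonpDC", (("SiglecF", "+"),)),
    ("nonEos", "nonpDC", (("SiglecF", "-"),)),
    ("Basophils", "nonEos", (("FceRI", "+"),)),
    ("nonBaso", "nonEos", (("FceRI", "-"),)),
    ("mDC", "nonBaso", (("CD11c", "+"),)),
    ("nonDC", "nonBaso", (("CD11c", "-"),)),
    ("myeloid", "nonDC", (("CD64", "+"),)),
    ("Macrophages", "myeloid", (("F4_80", "+"),)),
    ("monocytes", "myeloid", (("F4_80", "-"),)),
    ("Ly6Chi", "monocytes", (("Ly6C", "+"),)),
    ("intMC", "Ly6Chi", (("MHCII", "+"),)),
    ("cMC", "Ly6Chi", (("MHCII", "-"),)),
    ("ncMC", "monocytes", (("Ly6C", "-"),)),
    ("nonMyeloid", "nonDC", (("CD64", "-"),)),
    ("ILC", "nonMyeloid", (("CD25", "+"),)),
)

#: The 21 default leaf populations, population-major display order.
DEFAULT_POPULATIONS: tuple[str, ...] = (
    "Neutrophils", "cMC", "intMC", "ncMC", "Macrophages", "mDC", "pDC",
    "Eosinophils", "Basophils", "NK", "ILC", "NKT", "gdT", "Bcells", "Bmem",
    "Plasmablasts", "CD4Tnaive", "CD4Tmem", "Tregs", "CD8Tnaive", "CD8Tmem",
)

INNATE_POPULATIONS: frozenset[str] = frozenset(
    {"Neutrophils", "cMC", "intMC", "ncMC", "Macrophages", "mDC", "pDC",
     "Eosinophils", "Basophils", "NK", "ILC"}
)
ADAPTIVE_POPULATIONS: frozenset[str] = frozenset(
    {"NKT", "gdT", "Bcells", "Bmem", "Plasmablasts", "CD4Tnaive", "CD4Tmem",
     "Tregs", "CD8Tnaive", "CD8Tmem"}
)


def compartment_of(population: str) -> str:
    """Innate/adaptive compartment annotation for a default population."""
    if population in INNATE_POPULATIONS:
        return "innate"
    if population in ADAPTIVE_POPULATIONS:
        return "adaptive"
    return "unassigned"


def default_gating_scheme(
    populations=None, threshold: float = DEFAULT_GATE_THRESHOLD
) -> GatingScheme:
    """Build the default 21-leaf gate tree, optionally pruned to a subset.

    Parameters
    ----------
    populations
        Leaf populations to keep (default: all 21).  Internal nodes with no
        retained leaf below them are dropped.
    threshold
        Arcsinh cut separating low from high expression for every gate.
    """
    keep = set(DEFAULT_POPULATIONS if populations is None else populations)
    unknown = keep - set(DEFAULT_POPULATIONS)
    if unknown:
        raise ValueError(f"unknown populations: {sorted(unknown)}")

    nodes: dict[str, GateNode] = {}
    for name, parent, gates in _DEFAULT_TREE:
        iv = {
            m: ((threshold, None) if side == "+" else (None, threshold))
            for m, side in gates
        }
        nodes[name] = GateNode(name=name, parent=parent, gates=iv)

    # prune: keep a node iff some retained leaf passes through it
    needed: set[str] = set()
    for leaf in keep:
        cur: str | None = leaf
        while cur is not None:
            needed.add(cur)
            cur = nodes[cur].parent
    needed.update({"singlets", "CD45pos", "mononuclear"})  # denominators stay
    pruned = {n: node for n, node in nodes.items() if n in needed}

    leaves = tuple(p for p in DEFAULT_POPULATIONS if p in keep)
    return GatingScheme(
        nodes=pruned,
        leaves=leaves,
        denominators={"singlets": "singlets", "mononuclear": "mononuclear"},
    )


def population_signature(
    scheme: GatingScheme,
    leaf: str,
    hi: float = 6.5,
    lo: float = 0.3,
) -> dict[str, float]:
    """Arcsinh-scale surface signature implied by a leaf's gate path.

    Markers constrained high along the path get mean ``hi``, constrained low
    get ``lo``; unconstrained markers default to ``lo``.  Used by the
    synthetic generator so that generated populations land well inside their
    gates.
    """
    sig: dict[str, float] = {}
    for marker, (glo, ghi) in scheme.path_constraints(leaf).items():
        if glo is not None and ghi is not None and glo > ghi:
            raise ValueError(f"contradictory gates for {marker!r} on path to {leaf!r}")
        sig[marker] = hi if glo is not None else lo
    return sig


# ---------------------------------------------------------------------------
# Gating application
# ---------------------------------------------------------------------------

def _node_masks(scheme: GatingScheme, arcsinh: pd.DataFrame) -> dict[str, np.ndarray]:
    masks: dict[str, np.ndarray] = {}

    def mask_of(name: str) -> np.ndarray:
        if name in masks:
            return masks[name]
        node = scheme.nodes[name]
        m = (
            np.ones(len(arcsinh), dtype=bool)
            if node.parent is None
            else mask_of(node.parent).copy()
        )
        for marker, (lo, hi) in node.gates.items():
            vals = arcsinh[marker].to_numpy()
            if lo is not None:
                m &= vals >= lo
            if hi is not None:
                m &= vals < hi
        masks[name] = m
        return m

    for name in scheme.nodes:
        mask_of(name)
    return masks


def apply_gating(events: EventTable, scheme: GatingScheme) -> pd.Series:
    """Assign each cell to a leaf population (or UNGATED).

    Leaves are visited depth-first; because sibling gates partition their
    parent, at most one leaf can match a cell.  Cells matching no leaf are
    labeled ``UNGATED`` but still count toward any denominator gate they
    satisfy.
    """
    missing = scheme.required_markers() - set(events.panel.markers)
    if missing:
        raise ValueError(f"gating scheme references unknown channels: {sorted(missing)}")
    if len(events) == 0:
        return pd.Series([], dtype=object, name="population")

    arcs = events.arcsinh(sorted(scheme.required_markers()))
    masks = _node_masks(scheme, arcs)
    labels = np.full(len(events), UNGATED, dtype=object)
    assigned = np.zeros(len(events), dtype=bool)
    for leaf in scheme.leaf_order():
        sel = masks[leaf] & ~assigned
        labels[sel] = leaf
        assigned |= sel
    return pd.Series(labels, index=events.data.index, name="population")


def compute_frequencies(
    events: EventTable, labels: pd.Series, scheme: GatingScheme
) -> pd.DataFrame:
    """Per-sample population frequencies (%) with the study's denominators.

    Neutrophils are a percentage of singlets; all other populations a
    percentage of mononuclear (CD45+ Ly6G-) cells.  A zero-count denominator
    yields NaN for the affected populations (missing, never a silent zero).
    """
    arcs = events.arcsinh(sorted(scheme.required_markers()))
    masks = _node_masks(scheme, arcs)
    sample_ids = events.data["sample_id"].to_numpy()
    samples = sorted(events.data["sample_id"].unique())

    def counts_per_sample(mask: np.ndarray) -> pd.Series:
        return (
            pd.Series(sample_ids[mask]).value_counts().reindex(samples).fillna(0.0)
        )

    n_singlets = counts_per_sample(masks[scheme.denominators["singlets"]])
    n_mono = counts_per_sample(masks[scheme.denominators["mononuclear"]])

    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"), dtype=float)
    lab = labels.to_numpy()
    for pop in scheme.leaves:
        num = counts_per_sample(lab == pop)
        denom = n_singlets if pop == "Neutrophils" else n_mono
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = 100.0 * num / denom.replace(0.0, np.nan)
        if denom.eq(0).any():
            bad = list(denom.index[denom.eq(0)])
            logger.warning("zero denominator for %s in samples %s", pop, bad)
        out[pop] = freq
    return out
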