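"""Antibody panel configuration and the arcsinh intensity transform.

A mass-cytometry panel is described by its surface (phenotyping) markers and
its functional (intracellular signaling) markers.  All gating and feature
derivation operate on arcsinh-transformed intensities,
``asinh(raw / cofactor)``, the standard variance-stabilizing transform for
cytometry data; the default cofactor of 5 is the mass-cytometry convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default 20-marker surface panel used for hierarchical gating of murine
#: whole blood (lineage markers covering granulocyte, monocyte/macrophage,
#: dendritic, NK, B and T compartments).
DEFAULT_SURFACE_MARKERS: tuple[str, ...] = (
    "CD45", "Ly6G", "CD11b", "Ly6C", "CD64", "CD11c", "MHCII", "B220",
    "CD19", "CD138", "CD3", "CD4", "CD8", "CD25", "CD44", "TCRgd",
    "NK1.1", "SiglecF", "FceRI", "F4_80",
)

#: Default 12-marker functional (intracellular signaling) panel.
DEFAULT_FUNCTIONAL_MARKERS: tuple[str, ...] = (
    "pSTAT1", "pSTAT3", "pSTAT5", "pSTAT6", "p-p38", "pCREB", "pNFkB",
    "pERK", "MAPKAPK2", "CD62L", "pS6", "IkB",
)

FREQUENCY = "FREQUENCY"


@dataclass(frozen=True)
class PanelConfig:
    """Marker panel: surface markers, functional markers, arcsinh cofactor."""

    surface_markers: tuple[str, ...] = DEFAULT_SURFACE_MARKERS
    functional_markers: tuple[str, ...] = DEFAULT_FUNCTIONAL_MARKERS
    arcsinh_cofactor: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "surface_markers", tuple(self.surface_markers))
        object.__setattr__(self, "functional_markers", tuple(self.functional_markers))
        markers = self.surface_markers + self.functional_markers
        if len(set(markers)) != len(markers):
            raise ValueError("marker names must be unique across the panel")
        if not self.surface_markers or not self.functional_markers:
            raise ValueError("panel needs at least one surface and one functional marker")
        if self.arcsinh_cofactor <= 0:
            raise ValueError("arcsinh cofactor must be positive")

    @property
    def markers(self) -> tuple[str, ...]:
        """All markers, surface first, in panel order."""
        return self.surface_markers + self.functional_markers

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def arcsinh(self, x):
        """Transform raw intensities to the arcsinh scale."""
        return np.arcsinh(np.asarray(x, dtype=float) / self.arcsinh_cofactor)

    def inverse_arcsinh(self, y):
        """Map arcsinh-scale values back to raw intensities."""
        return self.arcsinh_cofactor * np.sinh(np.asarray(y, dtype=float))
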