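"""Icosahedral shell and cargo-packing geometry of the β-carboxysome.

The β-carboxysome is an icosahedral bacterial microcompartment: 20
triangular facets tiled by CcmK hexamers with CcmL pentamers at the 12
vertices, enclosing paracrystalline arrays of Rubisco holoenzymes.  This
module implements the facet-edge arithmetic that turns measured lengths
(facet edge, hexamer edge, Rubisco diameter) into protein counts:

* hexamers along one facet edge arrange as alternating pairs and singles
  between the two vertex pentamers;
* Rubisco under one facet stacks as a tetrahedral (triangular-pyramid)
  close packing, ``n(n+1)(n+2)/6`` spheres for ``n`` per edge;
* twenty such facet modules assemble the full icosahedron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CarboxysomeGeometry",
    "DEFAULT_GEOMETRY",
    "tetrahedral_count",
    "rubisco_per_edge",
    "total_rubisco",
    "hexamer_edge_pattern",
    "icosahedron_size",
    "geometry_report",
]


@dataclass(frozen=True)
class CarboxysomeGeometry:
    """Measured lengths (nm) parameterising the packing model.

    ``facet_edge`` is vertex-to-vertex; ``hexamer_edge`` is the CcmK
    hexagon edge; ``hexamer_span`` its vertex-to-vertex length;
    ``rubisco_diameter`` the holoenzyme diameter; ``n_facets`` is 20 for
    an icosahedron.
    """

    facet_edge: float = 72.16
    hexamer_edge: float = 3.5
    hexamer_span: float = 7.5
    rubisco_diameter: float = 10.0
    shell_thickness: float = 4.51
    inner_gap: float = 2.0
    n_facets: int = 20

    def __post_init__(self) -> None:
        for name in (
            "facet_edge",
            "hexamer_edge",
            "hexamer_span",
            "rubisco_diameter",
            "shell_thickness",
            "inner_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.facet_edge <= self.hexamer_span:
            raise ValueError("facet_edge must exceed hexamer_span")
        if self.n_facets < 1:
            raise ValueError("n_facets must be >= 1")


DEFAULT_GEOMETRY = CarboxysomeGeometry()


def tetrahedral_count(n_edge: int) -> int:
    """Spheres in a close-packed triangular pyramid with ``n_edge`` per edge.

    Layer ``i`` (from the apex) is the i-th triangular number, so the total
    is the tetrahedral number n(n+1)(n+2)/6.
    """
    if isinstance(n_edge, bool) or not float(n_edge).is_integer():
        raise ValueError("n_edge must be an integer")
    n = int(n_edge)
    if n < 1:
        raise ValueError("n_edge must be >= 1")
    return n * (n + 1) * (n + 2) // 6


def rubisco_per_edge(facet_edge: float, rubisco_diameter: float) -> int:
    """How many Rubisco of a given diameter fit along one facet edge."""
    if facet_edge <= 0 or rubisco_diameter <= 0:
        raise ValueError("lengths must be > 0")
    return int(math.floor(facet_edge / rubisco_diameter))


def total_rubisco(per_pyramid: int, n_facets: int = 20) -> int:
    """Total cargo count over all facet modules (no sharing deduction)."""
    if per_pyramid < 0 or n_facets < 0:
        raise ValueError("counts must be non-negative")
    return int(per_pyramid) * int(n_facets)


def hexamer_edge_pattern(facet_edge: float, hexamer_edge: float) -> tuple[int, int, int]:
    """Alternating pair/single hexamer arrangement along one facet edge.

    Positions advance by the across-flats width of the hexamer,
    ``sqrt(3) * hexamer_edge``; ``N = floor(facet_edge / (sqrt(3) * e))``
    positions alternate pair, single, pair, ... starting and ending with a
    pair.  Returns ``(n_pairs, n_singles, n_total_hexamers)``.
    """
    if facet_edge <= 0 or hexamer_edge <= 0:
        raise ValueError("lengths must be > 0")
    step = math.sqrt(3.0) * hexamer_edge
    n_positions = int(math.floor(facet_edge / step))
    if n_positions < 1:
        raise ValueError("facet edge too short for a single hexamer position")
    n_pairs = (n_positions + 1) // 2
    n_singles = n_positions // 2
    return n_pairs, n_singles, 2 * n_pairs + n_singles


def icosahedron_size(facet_edge: float) -> dict[str, float]:
    """Circumscribed diameter and inradius of an icosahedron of given edge."""
    if facet_edge < 0:
        raise ValueError("facet_edge must be >= 0")
    a = facet_edge
    return {
        "circumdiameter": a * math.sqrt(10.0 + 2.0 * math.sqrt(5.0)) / 2.0,
        "inradius": a * math.sqrt(3.0) * (3.0 + math.sqrt(5.0)) / 12.0,
    }


def geometry_report(geom: CarboxysomeGeometry = DEFAULT_GEOMETRY) -> dict:
    """Full packing report for one shell geometry.

    Composes the edge arrangement, per-edge cargo count, tetrahedral
    packing and icosahedron size into a single structure with all inputs
    echoed.  The total assumes 20 independent facet pyramids with no
    edge/vertex sharing deduction (upper bound).
    """
    pairs, singles, hexamers = hexamer_edge_pattern(geom.facet_edge, geom.hexamer_edge)
    n_edge = rubisco_per_edge(geom.facet_edge, geom.rubisco_diameter)
    per_pyramid = tetrahedral_count(n_edge)
    total = total_rubisco(per_pyramid, geom.n_facets)
    return {
        "inputs": {
            "facet_edge_nm": geom.facet_edge,
            "hexamer_edge_nm": geom.hexamer_edge,
            "hexamer_span_nm": geom.hexamer_span,
            "rubisco_diameter_nm": geom.rubisco_diameter,
            "shell_thickness_nm": geom.shell_thickness,
            "inner_gap_nm": geom.inner_gap,
            "n_facets": geom.n_facets,
        },
        "facet_edge_arrangement": {
            "hexamer_pairs": pairs,
            "single_hexamers": singles,
            "hexamers_per_edge": hexamers,
        },
        "rubisco_packing": {
            "per_facet_edge": n_edge,
            "per_pyramid": per_pyramid,
            "total": total,
            "counting_convention": "upper bound: 20 independent facet pyramids, no edge/vertex sharing deduction",
        },
        "icosahedron": icosahedron_size(geom.facet_edge),
    }
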