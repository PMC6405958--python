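"""Compartment-level spatial organization mapping.

Space is modeled as a graph of well-stirred compartments connected by
diffusion links; each compartment carries a set of present species.  The
*spatial organization* of a compartment is the organization generated (via
closure and self-maintaining shrinkage) by the union of species found in
its hop-distance neighborhood, including the compartment itself.  Two
compartments with identical contents can map to different organizations
when their neighborhoods differ — the neighborhood radius sets the implicit
time scale of the prediction.

By convention each compartment holds at most one kinetochore, so KinU and
KinA never share a compartment; the loader enforces this when the flag is
set in the compartment-graph document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import yaml

from .network import ReactionNetwork
from .organizations import Organization, generate_organization

__all__ = [
    "CompartmentGraph",
    "SpatialOrgMap",
    "load_compartment_graph",
    "neighborhood_species",
    "spatial_organization_map",
    "example_compartment_path",
]


@dataclass
class CompartmentGraph:
    """Ordered compartments with species contents and undirected links."""

    compartments: list[str]                       # compartment ids, ordered
    species: dict[str, frozenset[str]]            # id -> present species
    edges: list[tuple[str, str]]
    kinetochore_exclusive: bool = True
    _graph: nx.Graph = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        ids = set(self.compartments)
        for a, b in self.edges:
            if a not in ids or b not in ids:
                raise ValueError(f"edge ({a}, {b}) references unknown compartment")
        if self.kinetochore_exclusive:
            for cid, sp in self.species.items():
                kin = {s for s in sp if s in ("KinU", "KinA")}
                if len(kin) > 1:
                    raise ValueError(
                        f"compartment {cid!r} holds both KinU and KinA"
                    )
        g = nx.Graph()
        g.add_nodes_from(self.compartments)
        g.add_edges_from(self.edges)
        self._graph = g

    def graph(self) -> nx.Graph:
        return self._graph


def load_compartment_graph(text: str) -> CompartmentGraph:
    """Read a compartment graph from JSON or YAML.

    Document shape::

        compartments:
          - {id: c1, species: [Activator, KinU]}
          - {id: c2, species: [Inhibitor]}
        edges: [[c1, c2]]
        kinetochore_exclusive: true
    """
    doc = yaml.safe_load(text) if not text.lstrip().startswith("{") else json.loads(text)
    comps = [str(c["id"]) for c in doc["compartments"]]
    species = {
        str(c["id"]): frozenset(c.get("species", [])) for c in doc["compartments"]
    }
    edges = [(str(a), str(b)) for a, b in doc.get("edges", [])]
    return CompartmentGraph(
        compartments=comps,
        species=species,
        edges=edges,
        kinetochore_exclusive=bool(doc.get("kinetochore_exclusive", True)),
    )


def neighborhood_species(graph: CompartmentGraph, compartment: str, radius: int) -> frozenset[str]:
    """Union of species over compartments within hop distance <= radius
    (always including the compartment itself)."""
    if compartment not in graph.species:
        raise KeyError(f"unknown compartment {compartment!r}")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    lengths = nx.single_source_shortest_path_length(
        graph.graph(), compartment, cutoff=radius
    )
    out: set[str] = set()
    for cid in lengths:
        out |= graph.species[cid]
    return frozenset(out)


@dataclass
class SpatialOrgMap:
    network: ReactionNetwork
    radius: int
    neighborhoods: dict[str, frozenset[str]]
    organizations: dict[str, Organization]

    def to_json(self) -> str:
        payload = {
            cid: {
                "neighborhood_species": sorted(self.neighborhoods[cid]),
                "organization": sorted(self.organizations[cid].members),
            }
            for cid in self.neighborhoods
        }
        return json.dumps(payload, indent=2)


def spatial_organization_map(
    graph: CompartmentGraph, net: ReactionNetwork, radius: int = 1
) -> SpatialOrgMap:
    """Map every compartment to the organization generated by its
    neighborhood species union under the given network."""
    stray = set().union(*graph.species.values()) - set(net.species) if graph.species else set()
    if stray:
        raise KeyError(f"compartment species not in the network: {sorted(stray)}")
    neighborhoods = {
        cid: neighborhood_species(graph, cid, radius) for cid in graph.compartments
    }
    orgs = {cid: generate_organization(net, nb) for cid, nb in neighborhoods.items()}
    return SpatialOrgMap(network=net, radius=radius,
                         neighborhoods=neighborhoods, organizations=orgs)


def example_compartment_path() -> CompartmentGraph:
    """The bundled five-compartment diffusion path (short-timescale setting).

    A mitotic-transition snapshot: compartments 1–2 still hold unattached
    kinetochores with inhibitor, compartment 3 an attached kinetochore with
    inhibitor, compartments 4–5 attached kinetochores where the activator
    has appeared.  With radius 1, compartment 4's neighborhood is
    {Activator, Inhibitor, KinA} and generates {Activator, KinA}.
    """
    from importlib import resources

    text = resources.files("chemorg.data").joinpath("compartments_path.json").read_text()
    return load_compartment_graph(text)
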