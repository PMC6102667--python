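"""Packaged example networks and their provenance.

The fixtures are transcriptions of published logical models, shipped as
cnet truth-table files so that no network access is ever needed:

* ``thaliana`` — the gene regulatory network of floral organ determination
  in *Arabidopsis thaliana* (Chaos et al. 2006, J Plant Growth Regul 25;
  the Boolean lineage of Espinosa-Soto et al. 2004, Plant Cell 16).
  Constitutively expressed genes (LUG, CLF) are constant nodes; the free
  developmental input UFO holds its state through an identity self-input.
  The synchronous dynamics has ten fixed-point attractors matching the
  published inflorescence/sepal/petal/stamen/carpel taxonomy.
* ``budding_yeast`` — the cell-cycle network of Li et al. 2004 (PNAS 101),
  threshold rules tabulated to LUTs; seven fixed points with the G1 state
  (Cdh1, Sic1 on) draining 1764 of the 2048 configurations, as published.
* ``drosophila_cell`` — a simplified single-cell rendering of the
  *Drosophila melanogaster* segment-polarity model (Albert & Othmer 2003,
  J Theor Biol 223): one parasegment cell with the neighbouring WG/HH
  signals and the SLP prepattern aggregated into held external inputs.
  This synthetic reduction ships as a convenience, without published
  validation numbers.
* ``motif_*`` — small wiring motifs (chain, mutual inhibition, copy loop)
  of the kind used to study driver-variable control.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .exceptions import FixtureNotFoundError
from .network import BooleanNetwork, parse_cnet


@dataclass(frozen=True)
class FixtureInfo:
    name: str
    filename: str
    n_nodes: int
    description: str
    source: str
    validation: str


_MANIFEST: tuple[FixtureInfo, ...] = (
    FixtureInfo(
        name="thaliana",
        filename="thaliana.cnet",
        n_nodes=15,
        description=(
            "Arabidopsis thaliana floral organ determination GRN "
            "(synchronous Boolean model, ten fixed-point attractors)"
        ),
        source="Chaos et al. 2006, J Plant Growth Regul 25:278-289 "
        "(Boolean rules after Espinosa-Soto et al. 2004, Plant Cell 16:2923)",
        validation=(
            "TFL1 turns on iff LFY=0 and EMF1=1 and AP1=0 (AP2 is a fully "
            "redundant input); exactly 10 synchronous attractors"
        ),
    ),
    FixtureInfo(
        name="budding_yeast",
        filename="budding_yeast.cnet",
        n_nodes=11,
        description="Budding yeast cell-cycle regulatory network (threshold rules as LUTs)",
        source="Li et al. 2004, PNAS 101:4781-4786",
        validation="7 fixed points; G1 state (Cdh1, Sic1) basin of 1764",
    ),
    FixtureInfo(
        name="drosophila_cell",
        filename="drosophila_cell.cnet",
        n_nodes=15,
        description=(
            "Drosophila segment-polarity network, simplified synthetic "
            "single-cell variant with aggregated neighbour signals"
        ),
        source="simplified from Albert & Othmer 2003, J Theor Biol 223:1-18",
        validation="ships as a convenience; no published numbers asserted",
    ),
    FixtureInfo(
        name="motif_chain",
        filename="motif_chain.cnet",
        n_nodes=3,
        description="three-node copy chain with a held source node",
        source="control-motif family of Gates & Rocha 2016, Sci Rep 6:24456",
        validation="none",
    ),
    FixtureInfo(
        name="motif_mutual_inhibition",
        filename="motif_mutual_inhibition.cnet",
        n_nodes=2,
        description="two nodes negating each other",
        source="control-motif family of Gates & Rocha 2016, Sci Rep 6:24456",
        validation="none",
    ),
    FixtureInfo(
        name="motif_copy_loop",
        filename="motif_copy_loop.cnet",
        n_nodes=2,
        description="two nodes copying each other (bistable loop)",
        source="control-motif family of Gates & Rocha 2016, Sci Rep 6:24456",
        validation="none",
    ),
)


def fixture_manifest() -> tuple[FixtureInfo, ...]:
    """Catalog of packaged networks with provenance and validation notes."""
    return _MANIFEST


def fixture_text(name: str) -> str:
    """Raw cnet text of a packaged fixture."""
    for info in _MANIFEST:
        if info.name == name:
            return (
                resources.files("bncana").joinpath("data", info.filename).read_text()
            )
    raise FixtureNotFoundError(
        f"unknown example {name!r}; available: "
        + ", ".join(info.name for info in _MANIFEST)
    )


def load_example(name: str) -> BooleanNetwork:
    """Parse a packaged fixture into a :class:`BooleanNetwork`."""
    return parse_cnet(fixture_text(name))
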