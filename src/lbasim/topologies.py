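"""Parameterized builders for the study's two 11-taxon model topologies.

Topology A carries two elongated *terminal* branches (leaves t3 and t7,
length LtB) sitting in cherries whose stems are the short internal branches
(SiB); it probes signal erosion (class II) and mutual attraction of long
terminals (class III, the Felsenstein case).

Topology B carries two elongated *internal* branches (length LiB) on either
side of a short central branch (SiB) flanked by the short terminal leaves
t5 and t6; it probes erroneous grouping of the short terminals by shared
ancestral states (class I).

All remaining branches (RB) are held constant, default 0.05
substitutions/site.  The exact arrangement of background taxa is a fixed,
overridable convention of this package (see docs/methods.md); every branch
length named above is placed verbatim on its designated edge and can be
queried by bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trees import Tree, parse_newick

__all__ = ["DEFAULT_RB", "TopologySpec", "build_topology_a", "build_topology_b",
           "topology_a_spec", "topology_b_spec", "build_topology"]

DEFAULT_RB = 0.05


@dataclass(frozen=True)
class TopologySpec:
    """Identifies the focal long and short elements used in error scoring.

    ``focal_long`` holds two leaf labels for kind A (the long terminal
    branches) and two frozensets of leaf labels for kind B (the clades
    subtended by the long internal branches).  ``focal_short_pair`` is the
    pair of short terminals flanking the central branch and exists only for
    kind B; class III scoring applies only to kind A.  ``outgroup`` is
    reporting metadata; likelihoods and distances treat trees as unrooted.
    """

    kind: str
    focal_long: tuple
    outgroup: str
    focal_short_pair: tuple | None = None

    def __post_init__(self):
        if self.kind not in ("A", "B"):
            raise ValueError(f"kind must be 'A' or 'B', got {self.kind!r}")
        if self.kind == "B" and self.focal_short_pair is None:
            raise ValueError("kind B requires a focal_short_pair")
        if self.kind == "A" and self.focal_short_pair is not None:
            raise ValueError("focal_short_pair is defined only for kind B")


def _check_nonneg(**lengths: float) -> None:
    for name, value in lengths.items():
        if not float(value) >= 0:
            raise ValueError(f"branch length {name} must be >= 0, got {value}")


def build_topology_a(ltb: float, sib: float, rb: float = DEFAULT_RB) -> Tree:
    """11-taxon tree with long terminal branches on the non-adjacent
    leaves t3 and t7 (length ``ltb``); each sits in a cherry (partners t4,
    t8) whose stem has length ``sib``; every other edge has length ``rb``.
    """
    _check_nonneg(ltb=ltb, sib=sib, rb=rb)
    nwk = (
        "((((t1:{rb},t2:{rb}):{rb},(t3:{ltb},t4:{rb}):{sib}):{rb},"
        "((t5:{rb},t6:{rb}):{rb},(t7:{ltb},t8:{rb}):{sib}):{rb}):{rb},"
        "(t9:{rb},t10:{rb}):{rb},t11:{rb});"
    ).format(ltb=repr(float(ltb)), sib=repr(float(sib)), rb=repr(float(rb)))
    return parse_newick(nwk)


def build_topology_b(lib: float, sib: float, rb: float = DEFAULT_RB) -> Tree:
    """11-taxon tree with a central edge of length ``sib`` whose endpoints
    bear the short terminals t5 and t6 and, via internal edges of length
    ``lib``, a 4-leaf clade {t1..t4} and a 5-leaf clade {t7..t11}.  t5 and
    t6 are not sisters in this tree; all unnamed edges have length ``rb``.
    """
    _check_nonneg(lib=lib, sib=sib, rb=rb)
    nwk = (
        "(((t1:{rb},t2:{rb}):{rb},(t3:{rb},t4:{rb}):{rb}):{lib},t5:{rb},"
        "(((t7:{rb},t8:{rb}):{rb},(t9:{rb},(t10:{rb},t11:{rb}):{rb}):{rb}):{lib},"
        "t6:{rb}):{sib});"
    ).format(lib=repr(float(lib)), sib=repr(float(sib)), rb=repr(float(rb)))
    return parse_newick(nwk)


def topology_a_spec() -> TopologySpec:
    return TopologySpec(kind="A", focal_long=("t3", "t7"), outgroup="t11")


def topology_b_spec() -> TopologySpec:
    return TopologySpec(
        kind="B",
        focal_long=(
            frozenset({"t1", "t2", "t3", "t4"}),
            frozenset({"t7", "t8", "t9", "t10", "t11"}),
        ),
        focal_short_pair=("t5", "t6"),
        outgroup="t11",
    )


def build_topology(kind: str, long_branch: float, sib: float,
                   rb: float = DEFAULT_RB) -> tuple[Tree, TopologySpec]:
    """Build either model topology together with its scoring spec."""
    if kind == "A":
        return build_topology_a(long_branch, sib, rb), topology_a_spec()
    if kind == "B":
        return build_topology_b(long_branch, sib, rb), topology_b_spec()
    raise ValueError(f"unknown topology kind {kind!r}")
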