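"""Regulator→target network assembly from TF signatures.

Builds the directed binding network obtained by restricting each regulator's
promoter-bound target signature to a list of up-regulated genes, marks
targets bound by every regulator as "common", and checks subset relations
between signatures within a scope (e.g. whether all genes bound by one
regulator are contained in another's bound set among the up-regulated genes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import reduce

import pandas as pd

from prelsc.errors import InputError
from prelsc.regulome import TFSignature
from prelsc.setscan import GeneSet

__all__ = ["RegulatoryNetwork", "build_network", "subset_check", "write_network"]


@dataclass
class RegulatoryNetwork:
    regulators: tuple[str, ...]
    edges: list[tuple[str, str]]  # (regulator, target)
    common_targets: frozenset[str]
    upregulated: frozenset[str]
    self_loops: frozenset[str] = field(default_factory=frozenset)

    @property
    def targets(self) -> frozenset[str]:
        return frozenset(t for _, t in self.edges)

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"regulator": r, "target": t, "common": t in self.common_targets}
                for r, t in sorted(self.edges)
            ]
        )

    def nodes_frame(self) -> pd.DataFrame:
        rows = [
            {"id": r, "role": "regulator", "upregulated": r in self.upregulated}
            for r in self.regulators
        ]
        rows += [
            {"id": t, "role": "target", "upregulated": True}
            for t in sorted(self.targets - set(self.regulators))
        ]
        return pd.DataFrame(rows)


def build_network(
    signatures: list[TFSignature], upregulated: GeneSet
) -> RegulatoryNetwork:
    """Directed edges regulator→gene for signature genes in the up-regulated list.

    Targets bound by *every* listed regulator are marked common.  A regulator
    binding its own promoter yields an allowed, flagged self-loop.
    """
    if not signatures:
        raise InputError("need at least one signature")
    up = set(upregulated.genes)
    restricted = {sig.regulator: sig.genes & up for sig in signatures}
    edges = [
        (reg, gene) for reg, genes in restricted.items() for gene in sorted(genes)
    ]
    common = reduce(lambda a, b: a & b, restricted.values())
    self_loops = frozenset(
        reg for reg, genes in restricted.items() if reg in genes
    )
    return RegulatoryNetwork(
        regulators=tuple(sig.regulator for sig in signatures),
        edges=edges,
        common_targets=frozenset(common),
        upregulated=frozenset(up),
        self_loops=self_loops,
    )


def subset_check(
    inner: TFSignature, outer: TFSignature, scope: GeneSet
) -> tuple[bool, frozenset[str]]:
    """Is (inner ∩ scope) ⊆ (outer ∩ scope)?  Returns (verdict, witnesses).

    The witness set holds the violating genes (empty when the relation
    holds; an empty inner set holds vacuously).
    """
    s = set(scope.genes)
    witnesses = (inner.genes & s) - (outer.genes & s)
    return (len(witnesses) == 0, frozenset(witnesses))


def write_network(net: RegulatoryNetwork, edges_path, nodes_path) -> None:
    """Serialize as edge-list and node-attribute TSVs (GraphML-compatible)."""
    net.edges_frame().to_csv(edges_path, sep="\t", index=False)
    net.nodes_frame().to_csv(nodes_path, sep="\t", index=False)
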