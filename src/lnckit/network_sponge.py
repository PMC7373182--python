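"""Knowledge-based interaction network and ceRNA sponge inference.

The network is an undirected typed graph: nodes are molecules (lncRNA,
mRNA, miRNA, protein, TF) carrying differential-expression status and
annotation terms; edges carry evidence class (validated / predicted) and
database provenance, with parallel records collapsed. Sponge inference is
set logic: starting from the miRNAs predicted to bind a lncRNA, take the
union T of their experimentally validated mRNA targets, then intersect T
with the significantly deregulated mRNAs (sponge candidates), with the
predicted direct lncRNA-mRNA partners (direct candidates), and with both
(triple candidates — the strongest working hypotheses).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .expression import DEResult
from .interaction_scan import DuplexHit
from .ioformats import InteractionRecord


@dataclass(frozen=True)
class SpongeResult:
    """Outcome of the miRNA-sponging set logic."""

    mirnas_predicted: frozenset[str]
    validated_targets: frozenset[str]  # T: union of validated targets of the miRNAs
    sponge_candidates: frozenset[str]  # T ∩ D (deregulated mRNAs)
    direct_candidates: frozenset[str]  # T ∩ P (predicted direct partners)
    triple_candidates: frozenset[str]  # T ∩ D ∩ P


def build_network(
    validated: Sequence[InteractionRecord],
    predicted: Sequence[InteractionRecord],
    de_results: Sequence[DEResult] = (),
) -> nx.Graph:
    """Assemble the typed knowledge network from interaction records.

    One node per molecule id; DE flag and log2FC are overlaid where ids
    match. Duplicate edges collapse with provenance union, and an edge seen
    as both validated and predicted keeps both evidence tags. Conflicting
    molecule types for one id are a hard error.
    """
    g = nx.Graph()
    de_by_id = {r.gene_id: r for r in de_results}

    def add_node(node_id: str, moltype: str) -> None:
        if node_id in g.nodes:
            existing = g.nodes[node_id]["moltype"]
            if existing != moltype:
                raise ValueError(
                    f"conflicting molecule types for {node_id!r}: {existing} vs {moltype}"
                )
            return
        de = de_by_id.get(node_id)
        g.add_node(
            node_id,
            label=node_id,
            moltype=moltype,
            de_flag=bool(de.significant) if de else False,
            log2fc=float(de.log2fc) if de else 0.0,
            annotations=set(),
            tissues=set(),
        )

    for rec in sorted(
        list(validated) + list(predicted),
        key=lambda r: (r.source_id, r.target_id, r.evidence, r.provenance),
    ):
        add_node(rec.source_id, rec.source_type)
        add_node(rec.target_id, rec.target_type)
        if g.has_edge(rec.source_id, rec.target_id):
            g.edges[rec.source_id, rec.target_id]["evidence"].add(rec.evidence)
            if rec.provenance:
                g.edges[rec.source_id, rec.target_id]["provenance"].add(rec.provenance)
        else:
            g.add_edge(
                rec.source_id,
                rec.target_id,
                evidence={rec.evidence},
                provenance={rec.provenance} if rec.provenance else set(),
            )
    return g


def annotate_nodes(g: nx.Graph, term_genes: Mapping[str, Iterable[str]]) -> None:
    """Attach annotation term ids (term -> gene ids) to network nodes in place."""
    for term, genes in term_genes.items():
        for gene in genes:
            if gene in g.nodes:
                g.nodes[gene]["annotations"].add(term)


def filter_network(
    g: nx.Graph,
    criteria: Callable[[str, dict], bool],
    neighborhood: bool = False,
) -> nx.Graph:
    """Induced subgraph on nodes matching a predicate, optionally grown by
    the matching nodes' direct neighbors.

    ``criteria`` receives (node_id, attribute dict); e.g.
    ``lambda n, d: "GO:0001" in d["annotations"] and d["de_flag"]``.
    """
    selected = {n for n, d in g.nodes(data=True) if criteria(n, d)}
    if neighborhood:
        grown = set(selected)
        for n in selected:
            grown.update(g.neighbors(n))
        selected = grown
    return g.subgraph(selected).copy()


def overlap_with_expression(
    predicted: Sequence[DuplexHit | InteractionRecord],
    de_sig: Sequence[DEResult],
) -> list[str]:
    """Ids both predicted as interactors and significantly deregulated,
    in deterministic lexicographic order."""
    predicted_ids = {
        p.target_id if isinstance(p, (DuplexHit, InteractionRecord)) else str(p)
        for p in predicted
    }
    sig_ids = {r.gene_id for r in de_sig if r.significant}
    return sorted(predicted_ids & sig_ids)


def infer_sponging(
    predicted_mirnas: Iterable[str],
    validated_targets_table: Mapping[str, Iterable[str]],
    de_sig_mrnas: Iterable[str],
    predicted_mrnas: Iterable[str],
) -> SpongeResult:
    """Run the ceRNA sponge set logic.

    miRNAs absent from the validated-target table simply contribute no
    targets. The subset invariants triple ⊆ sponge and triple ⊆ direct
    hold by construction.
    """
    m = frozenset(predicted_mirnas)
    t: set[str] = set()
    for mirna in m:
        t.update(validated_targets_table.get(mirna, ()))
    d = frozenset(de_sig_mrnas)
    p = frozenset(predicted_mrnas)
    t_frozen = frozenset(t)
    return SpongeResult(
        mirnas_predicted=m,
        validated_targets=t_frozen,
        sponge_candidates=t_frozen & d,
        direct_candidates=t_frozen & p,
        triple_candidates=t_frozen & d & p,
    )


def sponge_result_frame(result: SpongeResult):
    """Tabular view of the sponge sets, one row per mRNA with its classes."""
    import pandas as pd

    rows = []
    for mrna in sorted(result.validated_targets):
        rows.append(
            {
                "mrna_id": mrna,
                "validated_target": True,
                "sponge_candidate": mrna in result.sponge_candidates,
                "direct_candidate": mrna in result.direct_candidates,
                "triple_candidate": mrna in result.triple_candidates,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mrna_id",
            "validated_target",
            "sponge_candidate",
            "direct_candidate",
            "triple_candidate",
        ],
    )
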