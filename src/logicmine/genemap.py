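"""Lift probe-level relationships to gene-level relationships.

A gene inherits the relationship of its unique related probe; when several
probes of one gene are related with the same phenotype, the relationship
with the largest mean bidirectional uncertainty coefficient represents the
gene (ties broken by probe id, so output is deterministic).  Gene pairs
inherit analogously from probe pairs, keyed by the unordered gene pair.
Only single-gene probes are expected here; multi-gene probes are excluded
upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

from logicmine.discovery import LogicRelationship
from logicmine.errors import ValidationError
from logicmine.logic import LogicFunction


@dataclass
class GeneRelationship:
    """A gene (or unordered gene pair) related with a phenotype."""

    gene_symbols: tuple[str, ...]
    phenotype: str
    logic_type: LogicFunction
    coefficient: float
    source_probes: tuple[str, ...]
    type_disagreement: bool = False


def _single_gene(probe: str, annotation: Mapping[str, Sequence[str]]) -> str:
    if probe not in annotation:
        raise ValidationError(f"probe absent from annotation: [{probe!r}]")
    genes = annotation[probe]
    if len(genes) != 1:
        raise ValidationError(
            f"probe {probe!r} maps to {len(genes)} genes; only single-gene probes allowed"
        )
    return genes[0]


def _lift(groups: dict, arity: int) -> list[GeneRelationship]:
    out = []
    for (genes, phenotype), members in sorted(groups.items()):
        # representative: maximal mean bidirectional U, ties by probe ids
        members.sort(key=lambda r: (-r.coefficient, r.feature_ids))
        best = members[0]
        disagree = len({r.logic_type.type_index for r in members}) > 1
        if disagree:
            warnings.warn(
                f"probes of {'/'.join(genes)} disagree on logic type for "
                f"{phenotype}; keeping the max-coefficient probe "
                f"{best.feature_ids} ({best.logic_type.name})"
            )
        out.append(
            GeneRelationship(
                gene_symbols=genes,
                phenotype=phenotype,
                logic_type=best.logic_type,
                coefficient=best.coefficient,
                source_probes=best.feature_ids,
                type_disagreement=disagree,
            )
        )
    return out


def map_lower(
    probe_rels: Sequence[LogicRelationship],
    annotation: Mapping[str, Sequence[str]],
) -> list[GeneRelationship]:
    """Gene-phenotype relationships from single-probe relationships."""
    groups: dict = {}
    for rel in probe_rels:
        if rel.logic_type.arity != 1:
            raise ValidationError("map_lower expects arity-1 relationships")
        gene = _single_gene(rel.feature_ids[0], annotation)
        groups.setdefault(((gene,), rel.phenotype), []).append(rel)
    return _lift(groups, 1)


def map_higher(
    pair_rels: Sequence[LogicRelationship],
    annotation: Mapping[str, Sequence[str]],
) -> list[GeneRelationship]:
    """Gene-pair-phenotype relationships from probe-pair relationships.

    Probe pairs mapping to the same unordered gene pair are merged; the
    max-coefficient probe pair represents the gene pair.
    """
    groups: dict = {}
    for rel in pair_rels:
        if rel.logic_type.arity != 2:
            raise ValidationError("map_higher expects arity-2 relationships")
        g1 = _single_gene(rel.feature_ids[0], annotation)
        g2 = _single_gene(rel.feature_ids[1], annotation)
        genes = tuple(sorted((g1, g2)))
        groups.setdefault((genes, rel.phenotype), []).append(rel)
    return _lift(groups, 2)
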