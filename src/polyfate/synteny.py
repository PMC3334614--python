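"""Synteny-based virtual gene ordering.

For an unsequenced target genome, the order of genes along a chromosome
group is simulated from the positions of their orthologs in sequenced
reference genomes.  Genes anchored in the top-priority reference take that
reference's order; genes missing there are interpolated from the next
reference between their nearest already-placed neighbours, and so on down
the priority list (the canonical grass priority being rice > Brachypodium >
sorghum > maize).  Genes that cannot be placed consistently are reported as
unplaced, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class SyntenyAnchor:
    """Position of a target gene's ortholog in one reference genome."""

    target_gene_id: str
    reference_name: str
    reference_chromosome: str
    reference_rank: int

    def __post_init__(self) -> None:
        if self.reference_rank < 0:
            raise ValueError("reference_rank must be >= 0")


@dataclass
class SyntenyBlock:
    """A maximal run of anchors collinear on one reference chromosome."""

    reference_name: str
    reference_chromosome: str
    anchors: list[SyntenyAnchor]
    direction: int  # +1 increasing, -1 decreasing, 0 singleton


@dataclass
class VirtualGeneMap:
    chromosome_group: str
    ordered_gene_ids: list[str]
    source_reference_per_gene: dict[str, str]
    unplaced: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.ordered_gene_ids)) != len(self.ordered_gene_ids):
            raise ValueError("virtual gene order contains duplicate gene ids")


def detect_blocks(anchors: Sequence[SyntenyAnchor], gap_limit: int = 5) -> list[SyntenyBlock]:
    """Split an anchor list (given in target order) into maximal collinear
    runs per reference chromosome.

    A run extends while consecutive reference ranks move in one direction
    with at most ``gap_limit`` missing rank positions between neighbours.
    Anchors from different reference chromosomes never share a block.
    """
    if not anchors:
        raise ValueError("anchors must be non-empty")
    groups: dict[tuple[str, str], list[SyntenyAnchor]] = {}
    order: list[tuple[str, str]] = []
    for a in anchors:
        key = (a.reference_name, a.reference_chromosome)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(a)

    blocks: list[SyntenyBlock] = []
    for key in order:
        run = groups[key]
        i = 0
        while i < len(run):
            j = i + 1
            direction = 0
            while j < len(run):
                delta = run[j].reference_rank - run[j - 1].reference_rank
                step = 1 if delta > 0 else -1 if delta < 0 else 0
                if step == 0 or abs(delta) - 1 > gap_limit:
                    break
                if direction == 0:
                    direction = step
                elif step != direction:
                    break
                j += 1
            blocks.append(
                SyntenyBlock(
                    reference_name=key[0],
                    reference_chromosome=key[1],
                    anchors=run[i:j],
                    direction=direction,
                )
            )
            i = j
    return blocks


def build_consensus_order(
    anchors: Sequence[SyntenyAnchor],
    priority: Sequence[str],
    chromosome_group: str = "group1",
) -> VirtualGeneMap:
    """Merge anchor sets from several references into one consensus order.

    The top-priority reference fixes the backbone; each lower-priority
    reference inserts its exclusive genes between their nearest neighbours
    that are already placed, in an order that keeps the deciding reference's
    ranks (ties broken by gene id).  Contradictory interpolations (left
    neighbour after right neighbour) leave the gene unplaced.  A gene
    already placed by a higher-priority reference is never moved.
    """
    refs_present = {a.reference_name for a in anchors}
    missing = refs_present - set(priority)
    if missing:
        raise ValueError(f"priority list does not cover references: {sorted(missing)}")

    by_ref: dict[str, list[SyntenyAnchor]] = {r: [] for r in priority}
    for a in anchors:
        by_ref[a.reference_name].append(a)

    def ref_order(ref: str) -> list[str]:
        seen: dict[str, SyntenyAnchor] = {}
        for a in by_ref[ref]:
            seen.setdefault(a.target_gene_id, a)
        return [
            a.target_gene_id
            for a in sorted(
                seen.values(),
                key=lambda x: (x.reference_chromosome, x.reference_rank, x.target_gene_id),
            )
        ]

    placed: list[str] = []
    source: dict[str, str] = {}
    position: dict[str, int] = {}

    def rebuild_positions() -> None:
        position.clear()
        position.update({g: i for i, g in enumerate(placed)})

    top, *rest = [r for r in priority if by_ref[r]] or [None]
    if top is None:
        return VirtualGeneMap(chromosome_group, [], {}, sorted({a.target_gene_id for a in anchors}))
    placed = ref_order(top)
    source = {g: top for g in placed}
    rebuild_positions()

    unplaced: list[str] = []
    for ref in rest:
        order = ref_order(ref)
        for idx, gene in enumerate(order):
            if gene in position:
                continue
            left = next((g for g in reversed(order[:idx]) if g in position), None)
            right = next((g for g in order[idx + 1 :] if g in position), None)
            if left is None and right is None:
                unplaced.append(gene)
                continue
            if left is not None and right is not None:
                if position[left] >= position[right]:
                    unplaced.append(gene)  # contradictory interpolation
                    continue
                at = position[right]
            elif left is not None:
                at = position[left] + 1
            else:
                at = position[right]
            placed.insert(at, gene)
            source[gene] = ref
            rebuild_positions()

    all_genes = {a.target_gene_id for a in anchors}
    final_unplaced = sorted((set(unplaced) | all_genes) - set(placed))
    return VirtualGeneMap(
        chromosome_group=chromosome_group,
        ordered_gene_ids=placed,
        source_reference_per_gene=source,
        unplaced=final_unplaced,
    )


def read_anchors(path) -> list[SyntenyAnchor]:
    df = pd.read_csv(path, sep="\t")
    return [
        SyntenyAnchor(
            target_gene_id=str(r.target_gene_id),
            reference_name=str(r.reference_name),
            reference_chromosome=str(r.reference_chromosome),
            reference_rank=int(r.reference_rank),
        )
        for r in df.itertuples(index=False)
    ]


def write_virtual_map(vmap: VirtualGeneMap, map_path, unplaced_path, bed_path=None) -> None:
    pd.DataFrame(
        {
            "position": range(len(vmap.ordered_gene_ids)),
            "gene_id": vmap.ordered_gene_ids,
            "source_reference": [
                vmap.source_reference_per_gene[g] for g in vmap.ordered_gene_ids
            ],
        }
    ).to_csv(map_path, sep="\t", index=False)
    pd.DataFrame({"gene_id": vmap.unplaced}).to_csv(unplaced_path, sep="\t", index=False)
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for i, g in enumerate(vmap.ordered_gene_ids):
                fh.write(f"{vmap.chromosome_group}\t{i}\t{i + 1}\t{g}\n")
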