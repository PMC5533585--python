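"""Cross-dataset hit-set contrasts, pairwise overlaps, and network export.

Hit sets from different BioID baits (dynein/dynactin subunits, or activator
N- and C-terminal fusions) are contrasted to label every protein with the
exact combination of datasets it appears in.  For the activator C-termini —
the cargo-binding ends — hits shared with any N-terminal dataset are first
removed, and the remaining CT-specific sets are compared pairwise: the
count for a pair is the number of proteins shared by exactly those two
activators, and the percentage expresses that count against the column
activator's input size, rounded half-up to one decimal.

Shared hits can be exported as a bipartite dataset-to-protein network in
SIF and GraphML form for downstream graph tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd


@dataclass
class HitSet:
    """One dataset's hit list with its bookkeeping labels."""

    dataset_label: str
    proteins: frozenset
    terminus: str = "NA"  # NT, CT or NA
    family: str = ""      # e.g. BICD, HOOK, NIN, core

    def __post_init__(self):
        self.proteins = frozenset(self.proteins)

    @property
    def input_n(self) -> int:
        return len(self.proteins)


def contrast_datasets(hit_sets: list[HitSet]) -> pd.DataFrame:
    """Label every protein with the exact subset of datasets containing it.

    Returns one row per protein in the union, with a ``datasets`` tuple
    (sorted labels), ``n_datasets``, and a ``category`` of ``unique``
    (exactly one dataset) or ``shared`` (two or more).  The rows partition
    the union exactly.
    """
    labels = [hs.dataset_label for hs in hit_sets]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate dataset labels")
    if len(hit_sets) < 2:
        raise ValueError("need at least two datasets to contrast")
    membership: dict[str, list[str]] = {}
    for hs in hit_sets:
        for pid in hs.proteins:
            membership.setdefault(pid, []).append(hs.dataset_label)
    rows = []
    for pid in sorted(membership):
        found_in = tuple(sorted(membership[pid]))
        rows.append(
            {
                "protein_id": pid,
                "datasets": found_in,
                "n_datasets": len(found_in),
                "category": "unique" if len(found_in) == 1 else "shared",
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def family_core_hits(families: dict[str, list[HitSet]]) -> frozenset:
    """Proteins present in at least one dataset of every family.

    ``families`` maps family name (e.g. BICD, HOOK, NIN) to that family's
    hit sets.  An empty family is an error — it would make the intersection
    vacuously empty.
    """
    if len(families) < 2:
        raise ValueError("need at least two families")
    per_family = []
    for name, sets in families.items():
        if not sets:
            raise ValueError(f"family {name!r} has no datasets")
        union = frozenset().union(*(hs.proteins for hs in sets))
        per_family.append(union)
    return frozenset.intersection(*per_family)


def ct_specific_inputs(
    nt_sets: list[HitSet], ct_sets: list[HitSet]
) -> dict[str, HitSet]:
    """CT-specific hits per activator: CT hits minus the union of all NT hits.

    Returns a mapping activator label -> HitSet of the remaining proteins;
    the resulting ``input_n`` values are the denominators of the pairwise
    overlap table.
    """
    nt_union = frozenset().union(*(hs.proteins for hs in nt_sets)) if nt_sets else frozenset()
    out = {}
    for hs in ct_sets:
        out[hs.dataset_label] = HitSet(
            dataset_label=hs.dataset_label,
            proteins=hs.proteins - nt_union,
            terminus="CT",
            family=hs.family,
        )
    return out


@dataclass
class OverlapMatrix:
    """Pairwise-overlap counts and column-normalized percentages.

    ``counts`` is symmetric: counts.loc[r, c] proteins occur in exactly the
    pair {r, c}.  ``percent.loc[r, c]`` = 100 * counts.loc[r, c] /
    input_n[c], rounded half-up to one decimal — generally asymmetric.
    Columns with input_n == 0 carry NaN percentages.
    """

    counts: pd.DataFrame
    percent: pd.DataFrame
    input_n: pd.Series


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in the printed tables
    (banker's rounding would turn 50.65 into 50.6, not 50.7)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def pairwise_ct_overlap(
    ct_specific: dict[str, HitSet], exclusive: bool = True
) -> OverlapMatrix:
    """Pairwise overlap between CT-specific hit sets.

    In the default ``exclusive`` mode the count for pair (r, c) is the
    number of proteins present in r and c and in no other set — overlap
    involving a third activator is excluded, matching the published table's
    convention.  The inclusive mode counts plain pairwise intersections.
    Percentages are taken against the *column* activator's input size.
    """
    labels = list(ct_specific)
    if len(labels) < 2:
        raise ValueError("need at least two CT-specific sets")
    input_n = pd.Series({lab: ct_specific[lab].input_n for lab in labels})
    counts = pd.DataFrame(0, index=labels, columns=labels)

    if exclusive:
        membership: dict[str, set] = {}
        for lab in labels:
            for pid in ct_specific[lab].proteins:
                membership.setdefault(pid, set()).add(lab)
        for pid, found_in in membership.items():
            if len(found_in) == 2:
                r, c = sorted(found_in)
                counts.loc[r, c] += 1
                counts.loc[c, r] += 1
    else:
        for i, r in enumerate(labels):
            for c in labels[i + 1 :]:
                n = len(ct_specific[r].proteins & ct_specific[c].proteins)
                counts.loc[r, c] = n
                counts.loc[c, r] = n

    percent = pd.DataFrame(float("nan"), index=labels, columns=labels)
    for r in labels:
        for c in labels:
            if r == c:
                continue
            if input_n[c] > 0:
                percent.loc[r, c] = round_half_up(
                    100.0 * counts.loc[r, c] / input_n[c], 1
                )
    return OverlapMatrix(counts=counts, percent=percent, input_n=input_n)


def build_network(hit_sets: list[HitSet], shared_only: bool = True) -> nx.Graph:
    """Bipartite dataset-anchor / hit-protein graph.

    Anchors carry ``role='dataset'`` plus family/terminus attributes; hit
    nodes carry ``role='hit'``, the families they connect, and a
    ``three_family`` flag set when the protein touches at least one dataset
    of three different families.  Edges carry the dataset label and
    terminus.  With ``shared_only`` (the published convention) proteins
    found in a single dataset are omitted.
    """
    graph = nx.Graph()
    membership: dict[str, list[HitSet]] = {}
    for hs in hit_sets:
        for pid in hs.proteins:
            membership.setdefault(pid, []).append(hs)
    for pid, sets in membership.items():
        if shared_only and len(sets) < 2:
            continue
        families = sorted({hs.family for hs in sets if hs.family})
        for hs in sets:
            if hs.dataset_label not in graph:
                graph.add_node(
                    hs.dataset_label,
                    role="dataset",
                    family=hs.family,
                    terminus=hs.terminus,
                )
            graph.add_edge(
                pid, hs.dataset_label, dataset=hs.dataset_label, terminus=hs.terminus
            )
        graph.nodes[pid].update(
            role="hit",
            families=",".join(families),
            color_class=("cross-family" if len(families) > 1 else "family-specific"),
            three_family=len(families) >= 3,
        )
    return graph


def export_network(graph: nx.Graph, sif_path, graphml_path=None) -> None:
    """Write the network as SIF (``anchor<TAB>hit<TAB>protein``) and,
    optionally, GraphML.  An empty graph produces valid empty files."""
    sif_path = Path(sif_path)
    with sif_path.open("w") as fh:
        for u, v, data in graph.edges(data=True):
            anchor, hit = (u, v) if graph.nodes[u].get("role") == "dataset" else (v, u)
            fh.write(f"{anchor}\thit\t{hit}\n")
    if graphml_path is not None:
        nx.write_graphml(graph, graphml_path)
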