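"""Origin-and-fate labels for every leaf of a family tree.

Each leaf gets exactly one label, by precedence (first match wins):

1. ``seed`` (orange) — a seed enzyme from the Enzyme DB;
2. ``recruitment`` (blue) — an NP-DB sequence pulled into the tree by a
   member hit (experimentally characterized biosynthetic enzyme);
3. ``transition`` (purple) — a genome copy that is both conserved (BBH to
   a seed) and inside a predicted cluster;
4. ``conserved`` (red) — BBH partner of a seed (central metabolism);
5. ``antismash`` (cyan) — inside a predicted cluster; cyan wins over green
   when a copy would qualify for both;
6. ``prediction`` (green) — a non-conserved genome copy whose minimum
   patristic distance to a blue leaf is strictly smaller than to a
   red/purple (conserved) leaf; never fires when there are no blue leaves;
7. ``unknown`` (grey) — anything else, including exact distance ties.

"Closer" is measured as minimum patristic distance on the family tree;
this is the pluggable default (see ``distance_to_sets``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from skbio import TreeNode

from .families import EnzymeFamily
from .io import LABEL_COLOURS
from .records import ClusterAnnotation, NPRecord
from .search import ENZYME_DB_BBH, Hit, Thresholds, bbh, search_db
from .tree import patristic_matrix

#: NP-DB recruitment search uses the E-value gate alone.
NP_SEARCH = Thresholds(max_evalue=0.001, min_bitscore=0.0)


@dataclass(frozen=True)
class LeafLabel:
    sequence_id: str
    label: str
    colour: str
    evidence: str = ""
    nearest_blue: float | None = None
    nearest_red: float | None = None


def find_conserved(
    family: EnzymeFamily,
    thresholds: Thresholds = ENZYME_DB_BBH,
) -> set[str]:
    """Member ids that are BBH partners of a seed, evaluated per genome.

    Reciprocity is checked within each genome's members (orthology is a
    per-proteome notion: the seed's best hit in genome A and in genome B
    can both be conserved). The Enzyme-DB profile (>=30 % identity over
    >=80 % of both lengths) applies.
    """
    conserved: set[str] = set()
    by_genome: dict[str, list] = {}
    for m in family.members:
        by_genome.setdefault(m.genome_id, []).append(m)
    for members in by_genome.values():
        for member_id, _seed_id in bbh(members, family.seeds, thresholds):
            conserved.add(member_id)
    return conserved


def find_recruitments(
    family: EnzymeFamily,
    np_db: Sequence[NPRecord],
    thresholds: Thresholds = NP_SEARCH,
) -> tuple[list[str], dict[str, Hit]]:
    """NP-DB sequences hit by at least one member at E <= 0.001.

    Returns the NP protein ids to append to the family's tree input (blue
    leaves) and, per member, its best NP hit as recruitment evidence.
    """
    if not np_db:
        raise ValueError("empty NP database")
    np_ids: set[str] = set()
    evidence: dict[str, Hit] = {}
    for member in family.members:
        hits = search_db(member, np_db, thresholds)
        if hits:
            evidence[member.protein_id] = hits[0]
            np_ids.update(h.subject_id for h in hits)
    return sorted(np_ids), evidence


def find_antismash(
    family: EnzymeFamily, clusters: Iterable[ClusterAnnotation]
) -> set[str]:
    """Members whose gene overlaps (>=1 bp, inclusive, same genome and
    contig) a predicted cluster interval."""
    clusters = list(clusters)
    return {
        m.protein_id
        for m in family.members
        if any(c.overlaps(m) for c in clusters)
    }


def distance_to_sets(
    tree: TreeNode, targets_blue: set[str], targets_red: set[str]
) -> dict[str, tuple[float | None, float | None]]:
    """Minimum patristic distance from every leaf to the blue and red
    reference sets (None for an empty set)."""
    leaves = [t.name for t in tree.tips()]
    dm = patristic_matrix(tree) if len(leaves) > 1 else None
    out = {}
    for leaf in leaves:
        def _min(targets):
            ts = [t for t in targets if t != leaf]
            if not ts or dm is None:
                return None
            return min(float(dm[leaf, t]) for t in ts)
        out[leaf] = (_min(targets_blue), _min(targets_red))
    return out


def assign_labels(
    tree: TreeNode,
    family: EnzymeFamily,
    conserved_set: set[str],
    blue_set: set[str],
    antismash_set: set[str],
    seed_ids: set[str] | None = None,
) -> list[LeafLabel]:
    """Apply the precedence rules to every leaf of the family tree.

    The red reference for the "closer to recruitments" rule is the set of
    conserved leaves (red and purple alike — purple is conserved too).
    Exact distance ties are conservatively labelled grey.
    """
    seed_ids = seed_ids if seed_ids is not None else family.seed_ids
    leaves = [t.name for t in tree.tips()]
    leaf_set = set(leaves)
    for name, ids in (("conserved", conserved_set), ("blue", blue_set),
                      ("antismash", antismash_set), ("seed", seed_ids)):
        missing = ids - leaf_set
        if missing and name != "seed":
            raise ValueError(
                f"{name} ids absent from tree: {sorted(missing)[:5]}"
            )
    red_reference = (conserved_set & leaf_set) - blue_set - seed_ids
    blue_reference = blue_set & leaf_set
    dists = distance_to_sets(tree, blue_reference, red_reference)
    labels = []
    for leaf in leaves:
        d_blue, d_red = dists[leaf]
        if leaf in seed_ids:
            label = "seed"
        elif leaf in blue_set:
            label = "recruitment"
        elif leaf in conserved_set and leaf in antismash_set:
            label = "transition"
        elif leaf in conserved_set:
            label = "conserved"
        elif leaf in antismash_set:
            label = "antismash"
        elif (
            blue_reference
            and red_reference
            and d_blue is not None
            and d_red is not None
            and d_blue < d_red
        ):
            label = "prediction"
        else:
            label = "unknown"
        labels.append(
            LeafLabel(
                sequence_id=leaf,
                label=label,
                colour=LABEL_COLOURS[label],
                evidence=f"d_blue={d_blue}, d_red={d_red}",
                nearest_blue=d_blue,
                nearest_red=d_red,
            )
        )
    return labels


def summarize_labels(labels: Sequence[LeafLabel]) -> dict[str, int]:
    """Label -> leaf count; counts sum to the number of leaves."""
    return dict(Counter(l.label for l in labels))


def label_table(
    family: EnzymeFamily,
    labels: Sequence[LeafLabel],
    genome_of: Mapping[str, str] | None = None,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Per-leaf label table (CSV when ``path`` given): sequence id, genome,
    family, label, colour and the nearest blue/red distances."""
    genome_of = genome_of or {
        m.protein_id: m.genome_id for m in family.members
    }
    rows = [
        {
            "sequence_id": l.sequence_id,
            "genome_id": genome_of.get(l.sequence_id, ""),
            "family_id": family.family_id,
            "label": l.label,
            "colour": l.colour,
            "nearest_blue": l.nearest_blue,
            "nearest_red": l.nearest_red,
        }
        for l in labels
    ]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
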