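import numpy as np
import pytest

from evomine import classify as cl
from evomine import families as fm
from evomine.fixtures import FixtureSpec, generate

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, length):
    return "".join(rng.choice(list(AA20), size=length))


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset with planted ground truth (seed 1)."""
    return generate(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def expanded(bundle):
    """Every fixture family expanded across the fixture genomes."""
    return {
        fam.family_id: fm.expand_family(fam, bundle.genomes)
        for fam in bundle.enzyme_db
    }


@pytest.fixture(scope="session")
def fam_b_labelled(bundle, expanded):
    """fam-b taken through recruitment search, tree building and labels."""
    from evomine.msa import align_family, curate_alignment
    from evomine.tree import build_tree

    family = expanded["fam-b"]
    blue, _ev = cl.find_recruitments(family, bundle.np_db)
    conserved = cl.find_conserved(family)
    anti = cl.find_antismash(family, bundle.clusters)
    np_by = {r.protein_id: r for r in bundle.np_db}
    leaves = (
        [(s.protein_id, s.sequence) for s in family.seeds]
        + [(m.protein_id, m.sequence) for m in family.members]
        + [(p, np_by[p].sequence) for p in blue]
    )
    tree = build_tree(curate_alignment(align_family(leaves)))
    labels = cl.assign_labels(tree, family, conserved, set(blue), anti)
    return {
        "family": family, "blue": blue, "conserved": conserved,
        "anti": anti, "tree": tree, "labels": labels,
    }
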