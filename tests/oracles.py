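"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: the aligner oracle
is a plain Gotoh dynamic program, the statistics oracle recomputes every
quantity from first principles, and the patristic oracle enumerates
root-paths. They are slow and simple on purpose.
"""

from collections import Counter

import numpy as np
from Bio.Align import substitution_matrices

AA = "ACDEFGHIKLMNPQRSTVWYX"
_B62 = substitution_matrices.load("BLOSUM62")
SCORES = {
    (a, b): (0.0 if "X" in (a, b) else float(_B62[a, b]))
    for a in AA for b in AA
}


def sw_score(a: str, b: str, gap_open: float = 12.0, gap_ext: float = 1.0) -> float:
    """Quadratic-space Smith-Waterman score under BLOSUM62 / affine gaps."""
    la, lb = len(a), len(b)
    NEG = -1e9
    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)
    Iy = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    best = 0.0
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            s = SCORES[(ai, b[j - 1])]
            M[i, j] = s + max(0.0, M[i - 1, j - 1], Ix[i - 1, j - 1],
                              Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - gap_open, Ix[i - 1, j] - gap_ext,
                           Iy[i - 1, j] - gap_open)
            Iy[i, j] = max(M[i, j - 1] - gap_open, Iy[i, j - 1] - gap_ext,
                           Ix[i, j - 1] - gap_open)
            if M[i, j] > best:
                best = M[i, j]
    return best


def expansion_stats_oracle(counts, genome_ids):
    """First-principles recomputation of the copy-number statistics."""
    values = list(counts)
    n = len(values)
    mean_all = sum(values) / n
    sd_all = (sum((v - mean_all) ** 2 for v in values) / n) ** 0.5
    nonzero = [v for v in values if v > 0]
    if nonzero:
        freq = Counter(nonzero)
        top = max(freq.values())
        mode = min(v for v, c in freq.items() if c == top)
        mean_nonzero = sum(nonzero) / len(nonzero)
    else:
        mode = 0
        mean_nonzero = 0.0
    frac = len(nonzero) / n
    if frac == 1.0:
        klass = "core"
    elif frac > 0.5:
        klass = "shell"
    else:
        klass = "cloud"
    threshold = mean_all + 2 * sd_all
    return {
        "mean_all": mean_all,
        "sd_all": sd_all,
        "mode": mode,
        "mean_nonzero": mean_nonzero,
        "frac": frac,
        "class": klass,
        "significant": {g for g, v in zip(genome_ids, values)
                        if n > 1 and v > threshold},
        "extra": {g for g, v in zip(genome_ids, values) if v > mode},
    }


def patristic_oracle(tree, leaf_a: str, leaf_b: str) -> float:
    """Path-sum distance via explicit root-path enumeration."""
    def path_to_root(name):
        node = next(t for t in tree.tips() if t.name == name)
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path

    pa = path_to_root(leaf_a)
    pb = path_to_root(leaf_b)
    seen = {id(n) for n in pa}
    lca = next(n for n in pb if id(n) in seen)
    dist = 0.0
    for node in pa:
        if node is lca:
            break
        dist += node.length or 0.0
    for node in pb:
        if node is lca:
            break
        dist += node.length or 0.0
    return dist
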