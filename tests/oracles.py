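"""Independent brute-force oracles used only to cross-check the package."""

from __future__ import annotations

from typing import Optional


def set_partitions(items: list):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def group_compatible(psets: list[dict[str, Optional[frozenset]]]) -> bool:
    """Can one haploid father explain every worker in the group?"""
    loci = psets[0].keys()
    for locus in loci:
        inter: Optional[frozenset] = None
        for ps in psets:
            s = ps[locus]
            if s is None:
                continue
            inter = s if inter is None else inter & s
            if not inter:
                return False
    return True


def min_fathers_bruteforce(psets: list[dict]) -> int:
    """Exhaustive minimum father count over all set partitions (n <= 9)."""
    if not psets:
        return 0
    best = len(psets)
    idx = list(range(len(psets)))
    for part in set_partitions(idx):
        if len(part) >= best:
            continue
        if all(group_compatible([psets[i] for i in grp]) for grp in part):
            best = len(part)
    return best


def vcv_bruteforce(tree) -> tuple[list[str], list[list[float]]]:
    """Shared root-to-tip path lengths by explicit root-path enumeration."""
    leaves = list(tree.leaf_node_iter())

    def root_path(node):
        path = []
        while node.parent_node is not None:
            path.append(node)
            node = node.parent_node
        return path[::-1]  # root-adjacent first

    paths = {leaf.taxon.label: root_path(leaf) for leaf in leaves}
    labels = [leaf.taxon.label for leaf in leaves]
    C = [[0.0] * len(labels) for _ in labels]
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            shared = 0.0
            for na, nb in zip(paths[a], paths[b]):
                if na is nb:
                    shared += na.edge.length or 0.0
                else:
                    break
            C[i][j] = shared
    return labels, C
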