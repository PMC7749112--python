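"""Haplotype-incongruence detection and phylogeny scanning.

In a fully clonal population the two haplotypes of an individual are each
other's closest relatives over long spans, and any inter-individual
clustering is congruent across the genome.  Genetic exchange instead places
the two haplotypes of one individual next to haplotypes of *different*
partners at different loci.  The closest-counterpart procedure detects this:
for each haplotype find its nearest neighbour among other individuals'
haplotypes (requiring an unambiguity margin between the best and second-best
distance, and excluding configurations explainable by gene conversion), keep
reciprocal best matches, and ask whether the two counterparts belong to one
individual (congruent) or two (incongruent).

Trees are built by neighbour joining on SNP-difference distances with
column-bootstrap supports and midpoint rooting; externally inferred newick
trees (e.g. maximum likelihood) can be scanned identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .core import SegmentHaplotypes

__all__ = [
    "CounterpartResult",
    "hap_distance_matrix",
    "closest_counterpart",
    "classify_grouping",
    "paralog_screen",
    "nj_tree",
    "bootstrap_support",
    "midpoint_root",
    "monophyly_scan",
    "read_newick",
    "write_newick",
]


@dataclass(frozen=True)
class CounterpartResult:
    focal: str
    best: str
    d1: int
    d2: int
    margin: int
    unambiguous: bool


def hap_distance_matrix(segment: SegmentHaplotypes) -> pd.DataFrame:
    """Pairwise SNP-difference counts between all haplotypes of a segment.

    Counts run over the phased SNP columns only (other positions are treated
    as monomorphic); divide by the segment length for the proportion scale.
    """
    h = segment.haplotypes
    labels = segment.labels()
    diff = (h[:, None, :] != h[None, :, :]).sum(axis=2)
    return pd.DataFrame(diff, index=labels, columns=labels)


def _individual_of(label: str) -> str:
    return label.rsplit(".", 1)[0]


def closest_counterpart(
    dist: pd.DataFrame, focal: str, margin: int = 3
) -> CounterpartResult:
    """Nearest haplotype of *other* individuals, with the unambiguity rule:
    the match is unambiguous when the second-best candidate is at least
    ``margin`` SNPs farther than the best."""
    ind = _individual_of(focal)
    candidates = [c for c in dist.columns if _individual_of(c) != ind]
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate haplotypes in other individuals")
    d = dist.loc[focal, candidates].to_numpy()
    order = np.argsort(d, kind="stable")
    d1, d2 = int(d[order[0]]), int(d[order[1]])
    return CounterpartResult(
        focal=focal,
        best=candidates[order[0]],
        d1=d1,
        d2=d2,
        margin=margin,
        unambiguous=(d2 - d1) >= margin,
    )


def classify_grouping(
    segment: SegmentHaplotypes, individual: str, margin: int = 3
) -> tuple[str, frozenset | None]:
    """Classify the grouping of one individual's two haplotypes.

    Returns (status, pattern): status "congruent", "incongruent" or
    "undetermined"; for incongruent groupings the pattern is the unordered
    pair of partner individuals.

    Steps: (1) both haplotypes must have unambiguous closest counterparts
    H1', H2' in other individuals; (2) both counterpart distances must be
    smaller than the within-individual distance d(H1, H2) (configurations
    violating this are reachable by gene conversion and are excluded);
    (3) matches must be reciprocal (H1 is H1's counterpart's best match,
    likewise H2).  Congruent iff H1' and H2' belong to one individual.
    """
    dist = hap_distance_matrix(segment)
    h1, h2 = f"{individual}.1", f"{individual}.2"
    c1 = closest_counterpart(dist, h1, margin)
    c2 = closest_counterpart(dist, h2, margin)
    if not (c1.unambiguous and c2.unambiguous):
        return "undetermined", None
    within = dist.loc[h1, h2]
    if not (c1.d1 < within and c2.d1 < within):
        return "undetermined", None
    # reciprocity: the focal haplotype must be its counterpart's unique
    # best match among other individuals' haplotypes
    for c, focal in ((c1, h1), (c2, h2)):
        ind_b = _individual_of(c.best)
        cand = [x for x in dist.columns if _individual_of(x) != ind_b]
        d = dist.loc[c.best, cand]
        dmin = d.min()
        if not (dist.loc[c.best, focal] == dmin and int((d == dmin).sum()) == 1):
            return "undetermined", None
    ia, ib = _individual_of(c1.best), _individual_of(c2.best)
    if ia == ib:
        return "congruent", frozenset([ia])
    return "incongruent", frozenset([ia, ib])


def paralog_screen(
    hits: pd.DataFrame,
    max_contigs: int = 10,
    max_high_identity: int = 2,
    identity_min: float = 0.90,
) -> bool:
    """True (keep segment) unless any haplotype has hits to more than
    ``max_contigs`` distinct contigs or more than ``max_high_identity`` hits
    with identity >= ``identity_min``.

    ``hits`` columns: haplotype, contig, identity (fraction).  Haplotypes
    without rows contribute zero hits.
    """
    if hits.empty:
        return True
    for _hap, sub in hits.groupby("haplotype"):
        if sub["contig"].nunique() > max_contigs:
            return False
        if int((sub["identity"] >= identity_min).sum()) > max_high_identity:
            return False
    return True


# ---------------------------------------------------------------------------
# trees


def nj_tree(dist: pd.DataFrame) -> TreeNode:
    """Unrooted neighbour-joining tree (negative branch lengths clamped)."""
    if dist.shape[0] < 3:
        raise ValueError("need >= 3 leaves")
    dm = DistanceMatrix(dist.to_numpy(float), ids=list(dist.index))
    return nj(dm, neg_as_zero=True)


def _bipartitions(tree: TreeNode, all_tips: frozenset) -> dict[frozenset, TreeNode]:
    """Map each informative bipartition to its node, canonicalised as the
    side not containing the alphabetically first tip."""
    ref = min(all_tips)
    out = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(all_tips - side) < 2:
            continue
        if ref in side:
            side = all_tips - side
        out[side] = node
    return out


def bootstrap_support(
    segment: SegmentHaplotypes,
    n_boot: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> TreeNode:
    """NJ tree with bootstrap supports (% of SNP-column resamples whose NJ
    tree contains each bipartition), stored on internal nodes as
    ``node.support``."""
    rng = np.random.default_rng(rng)
    dist = hap_distance_matrix(segment)
    tree = nj_tree(dist)
    all_tips = frozenset(dist.index)
    main = _bipartitions(tree, all_tips)
    counts = {bp: 0 for bp in main}
    labels = segment.labels()
    m = segment.n_snps
    for _ in range(n_boot):
        cols = rng.integers(0, m, size=m)
        h = segment.haplotypes[:, cols]
        diff = (h[:, None, :] != h[None, :, :]).sum(axis=2)
        rep = nj(DistanceMatrix(diff.astype(float), ids=labels), neg_as_zero=True)
        for bp in _bipartitions(rep, all_tips):
            if bp in counts:
                counts[bp] += 1
    for bp, node in main.items():
        node.support = 100.0 * counts[bp] / n_boot
    return tree


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the path between the two most distant leaves,
    preserving node ``support`` attributes by bipartition identity."""
    all_tips = frozenset(t.name for t in tree.tips())
    supports = {
        bp: getattr(node, "support", None)
        for bp, node in _bipartitions(tree, all_tips).items()
    }
    lengths = [n.length for n in tree.traverse() if n.length]
    rooted = tree.root_at_midpoint()
    if not lengths:
        rooted.flagged_zero_lengths = True
    for bp, node in _bipartitions(rooted, all_tips).items():
        if supports.get(bp) is not None:
            node.support = supports[bp]
    return rooted


@dataclass
class MonophylyReport:
    clades: list[frozenset]  # maximal well-supported target-exclusive clades
    sizes: list[int]
    one_per_individual: list[bool]
    root_separated: list[bool]

    @property
    def any_clade(self) -> bool:
        return bool(self.clades)


def monophyly_scan(
    rooted: TreeNode, targets: set[str], support_min: float = 70.0
) -> MonophylyReport:
    """Maximal clades made exclusively of target haplotypes with bootstrap
    support >= ``support_min`` on a rooted tree.

    For each clade, reports its size, whether it contains exactly one
    haplotype per target individual, and whether it is separated from the
    rest of the tree by the root bipartition (i.e. is a child of the root).
    """
    targets = set(targets)
    qualifying = []
    for node in rooted.non_tips(include_self=False):
        tips = frozenset(t.name for t in node.tips())
        if len(tips) < 2 or not tips <= targets:
            continue
        sup = getattr(node, "support", None)
        if sup is None or sup >= support_min:
            qualifying.append((tips, node))
    # keep maximal ones only
    maximal = [
        (tips, node)
        for tips, node in qualifying
        if not any(tips < other for other, _ in qualifying)
    ]
    maximal.sort(key=lambda x: sorted(x[0]))
    root_children = [frozenset(t.name for t in ch.tips()) for ch in rooted.children]
    clades, sizes, opi, rsep = [], [], [], []
    for tips, _node in maximal:
        inds = [_individual_of(t) for t in tips]
        clades.append(tips)
        sizes.append(len(tips))
        opi.append(len(set(inds)) == len(inds))
        rsep.append(tips in root_children)
    return MonophylyReport(clades, sizes, opi, rsep)


def read_newick(source) -> TreeNode:
    """Read a newick tree (path or string); numeric internal-node labels are
    interpreted as bootstrap supports."""
    if isinstance(source, str) and source.strip().startswith("("):
        tree = TreeNode.read(io.StringIO(source))
    else:
        tree = TreeNode.read(str(source))
    tree.assign_supports()  # numeric internal labels -> node.support
    return tree


def write_newick(tree: TreeNode, path) -> None:
    # skbio's newick writer serialises node.support as the internal label
    tree.write(str(path))
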