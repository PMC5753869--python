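"""Per-window phylogenies and the three-class recombination classifier.

Consensus sequences are cut into nonoverlapping 5-kb windows; each window
yields a pairwise distance matrix (p-distance or Jukes-Cantor corrected), a
neighbor-joining tree rooted at the outgroup, and a recombination class per
focal subspecies read off the rooted topology:

* **A** - at least one focal pseudo-driver tip descends from the MRCA of
  the focal subspecies' noncarriers (very recent / extensive recombination);
* **B** - otherwise, at least one descends from the MRCA of all ingroup
  noncarriers (older / smaller-scale recombination);
* **C** - all focal driver tips sit outside the ingroup noncarrier clade
  (no detectable recombination);
* **U** - unclassifiable (window invariant, truncated preconditions, or an
  outgroup that cannot root the tree).

Windows classified C for every subspecies feed the concatenated global
tree; per-500-kb class fractions reproduce the segment-level summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .pseudot import ConsensusSet

P_DISTANCE = "p"
JC69 = "JC69"

CLASS_A = "A"
CLASS_B = "B"
CLASS_C = "C"
CLASS_U = "U"


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

@dataclass
class WindowAlignment:
    """Compact window alignment: variant columns plus an invariant-column count."""

    interval: tuple[int, int]
    names: list[str]
    meta: dict[str, tuple[str, str, bool]]  # name -> (population, role, is_driver)
    var_positions: np.ndarray               # 0-based positions of stored columns
    var_matrix: np.ndarray                  # (n_columns, n_tips), byte codes
    length: int                             # total columns including invariant
    truncated: bool = False

    @property
    def n_variant_columns(self) -> int:
        if self.var_matrix.size == 0:
            return 0
        return int((self.var_matrix != self.var_matrix[:, [0]]).any(axis=1).sum())

    def mismatch_counts(self, weights: np.ndarray | None = None) -> np.ndarray:
        """(n_tips, n_tips) pairwise mismatching column counts (optionally weighted)."""
        m = self.var_matrix
        n = len(self.names)
        out = np.zeros((n, n))
        if m.size == 0:
            return out
        w = weights if weights is not None else np.ones(m.shape[0])
        for i in range(n):
            neq = m != m[:, [i]]
            out[i] = w @ neq
        return out

    def driver_tips(self, population: str | None = None) -> list[str]:
        return [
            n
            for n in self.names
            if self.meta[n][2] and (population is None or self.meta[n][0] == population)
        ]

    def noncarrier_tips(self, population: str | None = None) -> list[str]:
        return [
            n
            for n in self.names
            if self.meta[n][1] == "noncarrier"
            and not self.meta[n][2]
            and (population is None or self.meta[n][0] == population)
        ]

    def outgroup_tips(self) -> list[str]:
        return [n for n in self.names if self.meta[n][1] == "outgroup"]


def window_alignment(
    consensus: ConsensusSet, window: tuple[int, int], min_variant_columns: int = 1
) -> WindowAlignment:
    """Extract one window from the consensus set.

    Windows extending past the consensus interval are truncated and flagged.
    The alignment is stored as variant columns only; fewer than
    *min_variant_columns* distinct columns marks the window unclassifiable
    downstream (class U).
    """
    a0, b0 = consensus.interval
    a, b = max(window[0], a0), min(window[1], b0)
    if b <= a:
        raise ValueError(f"window {window} outside consensus interval {consensus.interval}")
    names = consensus.names
    positions = sorted(
        {p for name in names for p in consensus.subs[name] if a <= p < b}
    )
    mat = np.zeros((len(positions), len(names)), dtype=np.uint8)
    for j, name in enumerate(names):
        sub = consensus.subs[name]
        for i, p in enumerate(positions):
            base = sub.get(p)
            if base is None:
                base = consensus.ref_seq[p - a0]
            mat[i, j] = ord(base)
    aln = WindowAlignment(
        interval=(a, b),
        names=names,
        meta=consensus.meta,
        var_positions=np.asarray(positions, dtype=np.int64),
        var_matrix=mat,
        length=b - a,
        truncated=(a, b) != (int(window[0]), int(window[1])),
    )
    aln.min_variant_columns = min_variant_columns
    return aln


def is_classifiable(aln: WindowAlignment) -> bool:
    return aln.n_variant_columns >= getattr(aln, "min_variant_columns", 1)


def concatenate_alignments(alignments: list[WindowAlignment]) -> WindowAlignment:
    """Concatenate windows (same tip set) into one alignment."""
    if not alignments:
        raise ValueError("nothing to concatenate")
    names = alignments[0].names
    for a in alignments[1:]:
        if a.names != names:
            raise ValueError("alignments have different tip sets")
    return WindowAlignment(
        interval=(alignments[0].interval[0], alignments[-1].interval[1]),
        names=names,
        meta=alignments[0].meta,
        var_positions=np.concatenate([a.var_positions for a in alignments]),
        var_matrix=np.vstack([a.var_matrix for a in alignments]),
        length=sum(a.length for a in alignments),
    )


# ---------------------------------------------------------------------------
# distances and trees
# ---------------------------------------------------------------------------

def distance_matrix(
    aln: WindowAlignment,
    model: str = P_DISTANCE,
    d_max: float = 5.0,
    weights: np.ndarray | None = None,
) -> DistanceMatrix:
    """Pairwise distances (p or JC69-corrected; p >= 0.75 capped at d_max)."""
    if len(aln.names) < 2:
        raise ValueError("need at least 2 sequences")
    p = aln.mismatch_counts(weights) / aln.length
    if model == P_DISTANCE:
        d = p
    elif model == JC69:
        arg = 1.0 - 4.0 * p / 3.0
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(arg > 0, -0.75 * np.log(np.where(arg > 0, arg, 1.0)), d_max)
        d = np.minimum(d, d_max)
    else:
        raise ValueError(f"unknown distance model {model!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix((d + d.T) / 2.0, aln.names)


def jc69_distance(p: float, d_max: float = 5.0) -> float:
    """Scalar Jukes-Cantor correction, capped at d_max for p >= 0.75."""
    if p >= 0.75:
        return d_max
    return min(-0.75 * math.log(1.0 - 4.0 * p / 3.0), d_max)


def neighbor_joining_tree(dm: DistanceMatrix) -> TreeNode:
    """Deterministic neighbor joining.

    The matrix is re-ordered lexicographically by tip name before
    agglomeration so the output does not depend on input tip order; negative
    branch lengths are clamped to zero.
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    data = np.asarray(dm.data)
    if not np.allclose(data, data.T):
        raise ValueError("distance matrix is not symmetric")
    order = sorted(dm.ids)
    dm_sorted = dm.filter(order)
    return nj(dm_sorted, neg_as_zero=True)


def root_at_outgroup(tree: TreeNode, outgroup: list[str]) -> TreeNode | None:
    """Root on the branch to the outgroup MRCA.

    When the outgroup is not monophyletic, the MRCA is taken from a vantage
    rooted above the lexicographically first ingroup tip; if that MRCA
    covers the whole tree the window cannot be rooted and None is returned.
    """
    tips = {t.name for t in tree.tips()}
    outgroup = [o for o in outgroup if o in tips]
    if not outgroup:
        raise ValueError("no outgroup tips present; cannot root the tree")
    try:
        return tree.root_by_outgroup(outgroup)
    except Exception:
        pass
    ingroup = sorted(tips - set(outgroup))
    if not ingroup:
        return None
    vantage = tree.root_at(ingroup[0], above=True)
    mrca = vantage.lca(outgroup)
    if mrca.is_root() or {t.name for t in mrca.tips()} >= set(ingroup):
        return None
    return vantage.root_at(mrca, above=True)


def tree_splits(tree: TreeNode) -> set[frozenset]:
    """Nontrivial bipartitions of an (un)rooted tree as canonical tip-name sets."""
    all_tips = frozenset(t.name for t in tree.tips())
    splits = set()
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        if 1 < len(below) < len(all_tips) - 1:
            other = all_tips - below
            splits.add(min(below, other, key=lambda s: tuple(sorted(s))))
    return splits


def bootstrap_supports(
    aln: WindowAlignment,
    tree: TreeNode,
    n_replicates: int,
    seed: int,
    model: str = P_DISTANCE,
) -> dict[frozenset, float]:
    """Column-resampling bootstrap support (%) for each split of *tree*.

    Columns are resampled with replacement over the full window length
    (invariant columns included); each replicate is re-estimated by neighbor
    joining.  ``n_replicates=0`` returns an empty mapping (tree unchanged).
    """
    if n_replicates < 0:
        raise ValueError("n_replicates must be >= 0")
    target = tree_splits(tree)
    if n_replicates == 0 or not target:
        return {}
    rng = np.random.default_rng(seed)
    L = aln.length
    n_var = len(aln.var_positions)
    hits = {s: 0 for s in target}
    p_invariant = max(0.0, 1.0 - n_var / L)
    for _ in range(n_replicates):
        counts = rng.multinomial(L, [1.0 / L] * n_var + [p_invariant])
        weights = counts[:n_var].astype(float)
        dm = distance_matrix(aln, model=model, weights=weights)
        rep = neighbor_joining_tree(dm)
        rep_splits = tree_splits(rep)
        for s in target:
            if s in rep_splits:
                hits[s] += 1
    return {s: 100.0 * h / n_replicates for s, h in hits.items()}


def annotate_supports(tree: TreeNode, supports: dict[frozenset, float]) -> TreeNode:
    """Attach bootstrap percentages to the matching internal nodes."""
    all_tips = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        below = frozenset(t.name for t in node.tips())
        key = min(below, all_tips - below, key=lambda s: tuple(sorted(s)))
        if key in supports:
            node.support = supports[key]
    return tree


# ---------------------------------------------------------------------------
# topology classification
# ---------------------------------------------------------------------------

def classify_window_topology(
    rooted: TreeNode | None,
    meta: dict[str, tuple[str, str, bool]],
    focal: str,
    ingroup_populations: list[str] | None = None,
    usable: bool = True,
) -> str:
    """Assign the window's recombination class for one focal subspecies."""
    if rooted is None or not usable:
        return CLASS_U
    names = {t.name for t in rooted.tips()}

    def noncarriers(pop=None):
        return [
            n for n in names
            if meta[n][1] == "noncarrier" and not meta[n][2]
            and (pop is None or meta[n][0] == pop)
        ]

    focal_drivers = [n for n in names if meta[n][2] and meta[n][0] == focal]
    focal_nc = noncarriers(focal)
    pops = ingroup_populations or sorted(
        {meta[n][0] for n in names if meta[n][1] == "noncarrier" and not meta[n][2]}
    )
    other_ok = all(len(noncarriers(p)) >= 1 for p in pops if p != focal)
    if len(focal_drivers) < 1 or len(focal_nc) < 2 or not other_ok:
        return CLASS_U

    sub_clade = {t.name for t in rooted.lca(focal_nc).tips()}
    if any(d in sub_clade for d in focal_drivers):
        return CLASS_A
    all_clade = {t.name for t in rooted.lca(noncarriers()).tips()}
    if any(d in all_clade for d in focal_drivers):
        return CLASS_B
    return CLASS_C


def classify_windows(
    consensus: ConsensusSet,
    windows: list[tuple[int, int]],
    populations: list[str],
    model: str = P_DISTANCE,
    min_variant_columns: int = 1,
    d_max: float = 5.0,
) -> pd.DataFrame:
    """Distance + NJ + rooting + classification for every window.

    Returns a frame with columns start, end and one class column per focal
    population, plus the Newick string of each rooted (or unrooted, when
    rooting failed) tree.
    """
    rows = []
    for (a, b) in windows:
        aln = window_alignment(consensus, (a, b), min_variant_columns)
        rec = {"start": a, "end": b, "newick": ""}
        usable = is_classifiable(aln)
        rooted = None
        if usable and len(aln.names) >= 4:
            dm = distance_matrix(aln, model=model, d_max=d_max)
            tree = neighbor_joining_tree(dm)
            rooted = root_at_outgroup(tree, aln.outgroup_tips())
            rec["newick"] = str(rooted if rooted is not None else tree).strip()
        for pop in populations:
            rec[pop] = classify_window_topology(
                rooted, consensus.meta, pop, ingroup_populations=populations, usable=usable
            )
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregations
# ---------------------------------------------------------------------------

@dataclass
class WindowClassSummary:
    segment_fractions: pd.DataFrame          # segment x population x class fractions
    all_c_windows: list[tuple[int, int]]     # windows class C in every population
    all_c_indices: list[int] = field(default_factory=list)


def aggregate_window_classes(
    class_frame: pd.DataFrame,
    populations: list[str],
    segment_size: int = 500_000,
) -> WindowClassSummary:
    """Per-segment class fractions and the all-C (no recombination) window set."""
    seg_start = (class_frame["start"] // segment_size) * segment_size
    rows = []
    for seg, sub in class_frame.groupby(seg_start):
        for pop in populations:
            counts = sub[pop].value_counts()
            n = len(sub)
            rows.append(
                {
                    "segment_start": int(seg),
                    "population": pop,
                    "n_windows": n,
                    **{
                        f"frac_{c}": counts.get(c, 0) / n
                        for c in (CLASS_A, CLASS_B, CLASS_C, CLASS_U)
                    },
                }
            )
    all_c = np.ones(len(class_frame), dtype=bool)
    for pop in populations:
        all_c &= (class_frame[pop] == CLASS_C).to_numpy()
    idx = list(np.nonzero(all_c)[0])
    windows = [
        (int(class_frame["start"].iloc[i]), int(class_frame["end"].iloc[i])) for i in idx
    ]
    return WindowClassSummary(pd.DataFrame(rows), windows, idx)


def outgroup_subspecies_tally(
    rooted_trees: list[TreeNode],
    meta: dict[str, tuple[str, str, bool]],
    populations: list[str],
    tip_class: str,
) -> pd.Series:
    """Fraction of windows in which each subspecies is the outgroup to the
    other two, for driver tips (``tip_class='driver'``) or noncarrier tips
    (``'noncarrier'``); 'none' counts windows with no qualifying subspecies.
    """
    def class_tips(names, pop):
        if tip_class == "driver":
            return [n for n in names if meta[n][2] and meta[n][0] == pop]
        return [
            n for n in names
            if meta[n][1] == "noncarrier" and not meta[n][2] and meta[n][0] == pop
        ]

    tally = {p: 0 for p in populations}
    tally["none"] = 0
    for tree in rooted_trees:
        names = {t.name for t in tree.tips()}
        winners = []
        for p in populations:
            others = [n for q in populations if q != p for n in class_tips(names, q)]
            mine = class_tips(names, p)
            if not others or not mine:
                continue
            if len([q for q in populations if q != p and class_tips(names, q)]) < 2:
                continue
            clade = {t.name for t in tree.lca(others).tips()}
            if not (clade & set(mine)):
                winners.append(p)
        if len(winners) == 1:
            tally[winners[0]] += 1
        else:
            tally["none"] += 1
    n = len(rooted_trees)
    return pd.Series({k: v / n if n else float("nan") for k, v in tally.items()})
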