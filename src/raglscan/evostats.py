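"""Pairwise/grouped protein identities, distances, neighbor joining and the
two-clan partition check.

Identities come from global Needleman–Wunsch alignments (affine gaps,
BLOSUM62 by default) with identity defined as identical columns divided by
all alignment columns (gap columns included; an ungapped-denominator mode
is available). Distances are simple p-distances (1 - identity/100) or
Poisson-corrected (-ln(identity/100)). Trees are built with canonical
Saitou–Nei neighbor joining with deterministic lexicographic tie-breaking,
and the clan-partition check asks whether some tree edge bipartitions the
taxa exactly into two labelled clans — the desk-scale surrogate for the
observation that RAG1L and Transib proteins form two separate clans.
"""
from __future__ import annotations

import io as _io
import itertools
from dataclasses import dataclass, field

import numpy as np

_DEF_MATRIX = "BLOSUM62"


def _aligner(matrix_name: str, open_gap: float, extend_gap: float):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def global_identity(a: str, b: str, matrix: str = _DEF_MATRIX,
                    open_gap: float = -10.0, extend_gap: float = -0.5,
                    include_gap_columns: bool = True) -> float:
    """Percent identity from a global pairwise alignment.

    identity = identical columns / alignment columns x 100. With
    ``include_gap_columns`` (default) the denominator counts gapped
    columns; otherwise only columns aligned in both sequences.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    aln = _aligner(matrix, open_gap, extend_gap).align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    identical = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    if include_gap_columns:
        columns = len(s1)
    else:
        columns = sum(1 for x, y in zip(s1, s2) if x != "-" and y != "-")
    return 100.0 * identical / columns if columns else 0.0


def pairwise_identity_matrix(seqs: dict, **kwargs):
    """Symmetric percent-identity DataFrame over all sequence pairs."""
    import pandas as pd

    ids = list(seqs)
    mat = np.full((len(ids), len(ids)), 100.0)
    for i, j in itertools.combinations(range(len(ids)), 2):
        ident = global_identity(seqs[ids[i]], seqs[ids[j]], **kwargs)
        mat[i, j] = mat[j, i] = ident
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass
class GroupIdentitySummary:
    """Within/between-group average percent identities."""

    groups: list
    within: dict            # label -> mean % identity (None if <2 members)
    between: dict           # frozenset({a, b}) -> mean % identity
    n_pairs: dict           # same keys as within/between -> pair counts
    combined: float | None  # mean over all cross-group pairs


def group_identity_matrix(seqs: dict, labels: dict, pairwise=None,
                          **kwargs) -> GroupIdentitySummary:
    """Average identities within and between labelled groups.

    Within-group means exclude self-pairs; a single-member group has an
    undefined within average reported as missing (None). The combined
    statistic is the mean over all cross-group pairs.
    """
    groups = sorted(set(labels.values()))
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if pairwise is None:
        pairwise = pairwise_identity_matrix(seqs, **kwargs)
    within, between, n_pairs = {}, {}, {}
    for g in groups:
        members = [i for i in seqs if labels[i] == g]
        vals = [pairwise.loc[i, j] for i, j in itertools.combinations(members, 2)]
        within[g] = float(np.mean(vals)) if vals else None
        n_pairs[g] = len(vals)
    cross_all = []
    for g, h in itertools.combinations(groups, 2):
        mg = [i for i in seqs if labels[i] == g]
        mh = [i for i in seqs if labels[i] == h]
        vals = [pairwise.loc[i, j] for i in mg for j in mh]
        between[frozenset((g, h))] = float(np.mean(vals)) if vals else None
        n_pairs[frozenset((g, h))] = len(vals)
        cross_all.extend(vals)
    combined = float(np.mean(cross_all)) if cross_all else None
    return GroupIdentitySummary(groups, within, between, n_pairs, combined)


def summary_to_tsv(summary: GroupIdentitySummary) -> str:
    lines = ["cell\tmean_percent_identity\tn_pairs"]
    for g in summary.groups:
        v = summary.within[g]
        lines.append(f"within:{g}\t{'' if v is None else f'{v:.2f}'}\t{summary.n_pairs[g]}")
    for key, v in sorted(summary.between.items(), key=lambda kv: sorted(kv[0])):
        a, b = sorted(key)
        lines.append(f"between:{a}|{b}\t{'' if v is None else f'{v:.2f}'}\t{summary.n_pairs[key]}")
    if summary.combined is not None:
        lines.append(f"combined_cross_group\t{summary.combined:.2f}\t")
    return "\n".join(lines) + "\n"


def identity_to_distance(identity, method: str = "p"):
    """Percent identity -> evolutionary distance.

    method='p': d = 1 - identity/100. method='poisson': d = -ln(id/100)
    (identity 0 rejected as infinite).
    """
    arr = np.asarray(identity, dtype=float)
    if (arr < 0).any() or (arr > 100).any():
        raise ValueError("identities must lie in [0, 100]")
    if method == "p":
        out = 1.0 - arr / 100.0
    elif method == "poisson":
        if (arr <= 0).any():
            raise ValueError("identity 0 gives infinite Poisson distance")
        out = -np.log(arr / 100.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(out) if np.isscalar(identity) else out


def distance_matrix(pairwise_identity, method: str = "p"):
    """skbio DistanceMatrix from a pairwise percent-identity DataFrame."""
    from skbio import DistanceMatrix

    d = identity_to_distance(pairwise_identity.values, method)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return DistanceMatrix(d, ids=list(pairwise_identity.index))


def nj_tree(dm) -> str:
    """Canonical neighbor joining; returns a Newick string.

    Accepts an skbio DistanceMatrix or a (ids, square-ndarray) pair.
    Q-criterion joins with ties broken by the lexicographically smallest
    taxon-name pair; branch lengths by the standard Saitou–Nei formulas
    (negative lengths are reported as computed).
    """
    if isinstance(dm, tuple):
        ids, D = list(dm[0]), np.array(dm[1], dtype=float)
    else:
        ids, D = list(dm.ids), np.array(dm.data, dtype=float)
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if D.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    if not np.isfinite(D).all() or (D < -1e-12).any():
        raise ValueError("distances must be finite and nonnegative")

    labels = list(ids)               # newick fragments for active nodes
    names = list(ids)                # lexicographic keys for tie-breaking
    D = D.copy()

    def fmt(x):
        return f"{x:.10g}"

    while len(labels) > 3:
        m = len(labels)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        pairs = [tuple(sorted((i, j))) for i, j in ties if i != j]
        i, j = min(pairs, key=lambda p: tuple(sorted((names[p[0]], names[p[1]]))))
        li = D[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new_label = f"({labels[i]}:{fmt(li)},{labels[j]}:{fmt(lj)})"
        new_name = min(names[i], names[j])
        dk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dk[keep]
        D = D2
        labels = [labels[k] for k in keep] + [new_label]
        names = [names[k] for k in keep] + [new_name]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    return (f"({labels[0]}:{fmt(l0)},{labels[1]}:{fmt(l1)},"
            f"{labels[2]}:{fmt(l2)});")


def read_tree(newick: str):
    from skbio import TreeNode

    return TreeNode.read(_io.StringIO(newick), format="newick",
                         convert_underscores=False)


def write_tree(tree) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def clan_partition_check(tree, labels: dict):
    """Does some tree edge split the taxa exactly into the two clans?

    ``tree`` is a Newick string or skbio TreeNode; ``labels`` maps every
    taxon name to one of exactly two clan labels. Returns (bool, node):
    the child node below the splitting edge, or None.
    """
    if isinstance(tree, str):
        tree = read_tree(tree)
    clans = sorted(set(labels.values()))
    if len(clans) != 2:
        raise ValueError(f"expected exactly two clans, got {clans}")
    tip_names = {t.name for t in tree.tips()}
    unlabelled = tip_names - set(labels)
    if unlabelled:
        raise ValueError(f"unlabelled taxa: {sorted(unlabelled)}")
    targets = [frozenset(t for t in labels if labels[t] == c and t in tip_names)
               for c in clans]
    for node in tree.traverse(include_self=False):
        below = frozenset(t.name for t in node.tips()) if not node.is_tip() \
            else frozenset({node.name})
        if below in targets:
            return True, node
    return False, None
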