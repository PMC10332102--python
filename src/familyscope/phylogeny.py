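"""Multiple alignment, distances, neighbor-joining and clan assignment.

The aligner is a deterministic progressive scheme: a 3-mer-distance UPGMA
guide tree followed by profile-profile global alignment (Needleman-Wunsch
with affine gaps, BLOSUM62, gap open -10 / extend -0.5, diagonal-preferring
tie-breaks).  Distances are p-distance with pairwise deletion, optionally
Poisson-corrected (d = -ln(1 - p), the usual protein default).  Trees are
built with the Saitou-Nei neighbor-joining algorithm; bootstrap supports
come from column resampling, and clans (A1-A6, B1-B6, AP2, RAV) are
assigned by the nearest labelled reference in a joint alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage

from .io_formats import PROTEIN, SequenceSet

logger = logging.getLogger("familyscope")

_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}

_B62_RAW = substitution_matrices.load("BLOSUM62")
_B62 = np.zeros((20, 20))
for _i, _a in enumerate(_ALPHABET):
    for _j, _b in enumerate(_ALPHABET):
        _B62[_i, _j] = _B62_RAW[_a, _b]

GAP_OPEN = -10.0
GAP_EXTEND = -0.5

CLAN_LABELS = tuple(
    [f"A{i}" for i in range(1, 7)] + [f"B{i}" for i in range(1, 7)] + ["AP2", "RAV"]
)


@dataclass
class Msa:
    """A protein multiple alignment; ungapping any row recovers its input."""

    ids: list[str]
    rows: list[str]
    region: str = "full_protein"

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, idx: int) -> str:
        return self.rows[idx].replace("-", "")

    def resample_columns(self, columns) -> "Msa":
        rows = ["".join(row[c] for c in columns) for row in self.rows]
        return Msa(list(self.ids), rows, self.region)


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str  # p_distance | poisson

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.ids):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal not zero")
        if np.any(m < 0):
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree, represented with a trifurcating (or star) root."""

    root: TreeNode

    @property
    def leaf_ids(self) -> list[str]:
        return self.root.leaves()

    def _newick(self, node: TreeNode, length: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(self._newick(c, l) for c, l in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            body = f"({inner}){label}"
        if length is None:
            return body
        return f"{body}:{length:g}"

    def to_newick(self) -> str:
        return self._newick(self.root, None) + ";"

    def splits(self) -> dict[frozenset, TreeNode]:
        """Non-trivial bipartitions (canonical leaf-set side) -> defining node."""
        all_leaves = frozenset(self.leaf_ids)
        ref = min(all_leaves)
        n = len(all_leaves)
        out: dict[frozenset, TreeNode] = {}

        def visit(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(visit(c) for c, _ in node.children))
            if node is not self.root and 2 <= len(below) <= n - 2:
                side = below if ref not in below else all_leaves - below
                out[side] = node
            return below

        visit(self.root)
        return out


# --- alignment ---------------------------------------------------------------


def _profile(rows: list[str]) -> np.ndarray:
    """Column residue counts (L x 20); gaps and unknowns contribute nothing."""
    ncols = len(rows[0])
    prof = np.zeros((ncols, 20))
    for row in rows:
        for pos, aa in enumerate(row):
            idx = _AA_INDEX.get(aa)
            if idx is not None:
                prof[pos, idx] += 1.0
    return prof


def _align_profiles(
    rows_a: list[str], rows_b: list[str]
) -> tuple[list[str], list[str], float]:
    """Gotoh profile-profile NW; returns gapped row groups and the score."""
    prof_a = _profile(rows_a)
    prof_b = _profile(rows_b)
    la, lb = prof_a.shape[0], prof_b.shape[0]
    na = prof_a.sum(axis=1)
    nb = prof_b.sum(axis=1)
    S = prof_a @ _B62 @ prof_b.T
    denom = np.outer(na, nb)
    S = np.divide(S, denom, out=np.zeros_like(S), where=denom > 0)

    NEG = -1e18
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)  # gap in B (consumes A)
    Y = np.full((la + 1, lb + 1), NEG)  # gap in A (consumes B)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.int8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    if la:
        X[1:, 0] = GAP_OPEN + np.arange(la) * GAP_EXTEND
        ptr_x[2:, 0] = 1
    if lb:
        Y[0, 1:] = GAP_OPEN + np.arange(lb) * GAP_EXTEND
        ptr_y[0, 2:] = 1

    j_ext = np.arange(1, lb + 1) * GAP_EXTEND
    for i in range(1, la + 1):
        m_prev, x_prev, y_prev = M[i - 1], X[i - 1], Y[i - 1]
        # match state: diagonal from the best previous state (prefer M, X, Y)
        diag_best = np.maximum(np.maximum(m_prev[:-1], x_prev[:-1]), y_prev[:-1])
        M[i, 1:] = diag_best + S[i - 1]
        ptr_m[i, 1:] = np.where(
            m_prev[:-1] >= diag_best, 0, np.where(x_prev[:-1] >= y_prev[:-1], 1, 2)
        )
        # vertical gap state (consumes A)
        open_x = m_prev[1:] + GAP_OPEN
        ext_x = x_prev[1:] + GAP_EXTEND
        X[i, 1:] = np.maximum(open_x, ext_x)
        ptr_x[i, 1:] = np.where(open_x >= ext_x, 0, 1)
        # horizontal gap state: a running max with linear gap-extension decay
        cand = M[i, :-1] + GAP_OPEN  # opening after M[i, j-1]
        Y[i, 1:] = np.maximum.accumulate(cand - j_ext + GAP_EXTEND) + j_ext - GAP_EXTEND
        ptr_y[i, 1:] = np.where(cand >= Y[i, :-1] + GAP_EXTEND, 0, 1)

    # choose final state, diagonal preferred
    finals = (M[la, lb], X[la, lb], Y[la, lb])
    state = int(np.argmax([finals[0] + 1e-12, finals[1], finals[2]]))
    score = float(max(finals))
    moves: list[str] = []
    i, j = la, lb
    while i > 0 or j > 0:
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        if state == 0:
            moves.append("D")
            state = int(ptr_m[i, j])
            i -= 1
            j -= 1
        elif state == 1:
            moves.append("U")
            state = 0 if ptr_x[i, j] == 0 else 1
            i -= 1
        else:
            moves.append("L")
            state = 0 if ptr_y[i, j] == 0 else 2
            j -= 1
    moves.reverse()

    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for move in moves:
        if move in ("D", "U"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if move in ("D", "L"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b, score


def pairwise_align(seq_a: str, seq_b: str) -> tuple[str, str]:
    """Global pairwise protein alignment (BLOSUM62, affine -10/-0.5)."""
    rows_a, rows_b, _ = _align_profiles([seq_a], [seq_b])
    return rows_a[0], rows_b[0]


def pairwise_align_score(seq_a: str, seq_b: str) -> float:
    return _align_profiles([seq_a], [seq_b])[2]


def _kmer_distance(seq_a: str, seq_b: str, k: int = 3) -> float:
    kmers_a = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    kmers_b = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    if not kmers_a or not kmers_b:
        return 0.0 if seq_a == seq_b else 1.0
    return 1.0 - len(kmers_a & kmers_b) / min(len(kmers_a), len(kmers_b))


def progressive_align(seqs: SequenceSet | list, region: str = "full_protein") -> Msa:
    """Progressive MSA over a k-mer/UPGMA guide tree (deterministic)."""
    records = list(seqs)
    ids = [r for r, _ in records]
    sequences = [s for _, s in records]
    if not records:
        raise ValueError("no sequences to align")
    if len(records) == 1:
        return Msa(ids, [sequences[0]], region)

    n = len(records)
    condensed = []
    for i in range(n):
        for j in range(i + 1, n):
            condensed.append(_kmer_distance(sequences[i], sequences[j]))
    merge_order = linkage(np.asarray(condensed), method="average")

    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    aligned: dict[int, list[str]] = {i: [sequences[i]] for i in range(n)}
    for step, (a, b, _, _) in enumerate(merge_order):
        a, b = int(a), int(b)
        # deterministic orientation: cluster holding the lower original index first
        if min(clusters[a]) > min(clusters[b]):
            a, b = b, a
        rows_a, rows_b, _ = _align_profiles(aligned.pop(a), aligned.pop(b))
        new_id = n + step
        clusters[new_id] = clusters.pop(a) + clusters.pop(b)
        aligned[new_id] = rows_a + rows_b

    final_members = clusters[next(iter(clusters))]
    final_rows = aligned[next(iter(aligned))]
    # restore input order
    order = np.argsort(final_members, kind="stable")
    msa_rows = [final_rows[i] for i in order]
    msa_ids = [ids[final_members[i]] for i in order]
    return Msa(msa_ids, msa_rows, region)


# --- distances ---------------------------------------------------------------


def compute_distances(
    msa: Msa, model: str = "poisson", clamp_saturated: bool = False
) -> DistanceMatrix:
    """Pairwise-deletion p-distances, optionally Poisson-corrected.

    ``clamp_saturated`` (internal, used by the bootstrap) caps p just below
    1 instead of raising when a resampled pair saturates.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    if len(msa.ids) < 2:
        raise ValueError("need >= 2 rows")
    codes = np.frombuffer(
        "".join(msa.rows).encode("latin-1"), dtype=np.uint8
    ).reshape(len(msa.rows), msa.ncols)
    valid = codes != ord("-")
    n = len(msa.ids)
    both = valid[:, None, :] & valid[None, :, :]
    total = both.sum(axis=2)
    np.fill_diagonal(total, 1)  # avoid 0/0 on the diagonal
    if np.any(total == 0):
        i, j = np.argwhere((total == 0) & ~np.eye(n, dtype=bool))[0]
        raise ValueError(
            f"no comparable positions between {msa.ids[i]} and {msa.ids[j]}"
        )
    mismatch = (both & (codes[:, None, :] != codes[None, :, :])).sum(axis=2)
    p = mismatch / total
    if model == "poisson":
        saturated = p >= 1.0
        if saturated.any():
            if clamp_saturated:
                p = np.where(saturated, 1.0 - 1e-6, p)
            else:
                i, j = np.argwhere(saturated)[0]
                raise ValueError(
                    f"p-distance 1.0 between {msa.ids[i]} and {msa.ids[j]}: "
                    "Poisson correction undefined"
                )
        dist = -np.log(1.0 - p)
    else:
        dist = p
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # exact symmetry against float noise
    return DistanceMatrix(list(msa.ids), dist, model)


# --- neighbor joining --------------------------------------------------------


def nj_tree(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Ties are broken by the lowest index pair; negative branch lengths are
    clamped to 0 with the deficit transferred to the sister branch so the
    pair's summed length is preserved.
    """
    ids = dist.ids
    n0 = len(ids)
    if n0 < 3:
        raise ValueError("need >= 3 taxa")
    d = dist.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in ids]
    active = list(range(n0))
    lengths: dict[int, float] = {}
    # grow the matrix as new internal nodes are appended
    size = 2 * n0
    big = np.zeros((size, size))
    big[:n0, :n0] = d
    next_idx = n0

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(active) > 3:
        m = len(active)
        sub = big[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))  # row-major: lowest index pair wins ties
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i_idx, j_idx = active[ai], active[aj]
        dij = big[i_idx, j_idx]
        li = dij / 2.0 + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        li, lj = clamp_pair(li, lj)
        parent = TreeNode(
            children=[(nodes[i_idx], li), (nodes[j_idx], lj)]
        )
        nodes.append(parent)
        new = next_idx
        next_idx += 1
        for k in active:
            if k in (i_idx, j_idx):
                continue
            dk = 0.5 * (big[i_idx, k] + big[j_idx, k] - dij)
            big[new, k] = big[k, new] = max(dk, 0.0)
        active = [k for k in active if k not in (i_idx, j_idx)] + [new]

    a, b, c = active
    la = 0.5 * (big[a, b] + big[a, c] - big[b, c])
    lb = 0.5 * (big[a, b] + big[b, c] - big[a, c])
    lc = 0.5 * (big[a, c] + big[b, c] - big[a, b])
    root = TreeNode(
        children=[
            (nodes[a], max(la, 0.0)),
            (nodes[b], max(lb, 0.0)),
            (nodes[c], max(lc, 0.0)),
        ]
    )
    return PhyloTree(root)


def bootstrap_support(
    msa: Msa,
    n_replicates: int = 1000,
    seed=None,
    model: str = "poisson",
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal edge is the percentage of replicates whose NJ
    tree contains the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if msa.ncols < 2:
        raise ValueError("alignment must have >= 2 columns")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = nj_tree(compute_distances(msa, model))
    target_splits = tree.splits()
    counts = {split: 0 for split in target_splits}
    for _ in range(n_replicates):
        cols = rng.integers(0, msa.ncols, size=msa.ncols)
        replicate = msa.resample_columns(cols)
        try:
            rep_dist = compute_distances(replicate, model, clamp_saturated=True)
        except ValueError:
            continue  # a pair with no comparable resampled positions
        rep_splits = set(nj_tree(rep_dist).splits())
        for split in counts:
            if split in rep_splits:
                counts[split] += 1
    for split, node in target_splits.items():
        node.support = 100.0 * counts[split] / n_replicates
    return tree


# --- clan assignment ---------------------------------------------------------


@dataclass
class ClanAssignment:
    gene_id: str
    clan: str
    margin: float  # distance gap to the second-best reference clan


def assign_clans(
    queries: SequenceSet,
    references: SequenceSet,
    reference_clans: dict[str, str],
    subfamily_overrides: dict[str, str] | None = None,
) -> list[ClanAssignment]:
    """Assign each query the clan of its nearest labelled reference.

    Queries and references are jointly aligned; distances are
    Poisson-corrected.  Ties go to the lower-sorted clan label with margin
    0.  AP2/RAV subfamily calls in ``subfamily_overrides`` override the
    distance-based clan.
    """
    if len(references) == 0:
        raise ValueError("empty reference set")
    for rid in references.ids:
        if rid not in reference_clans:
            raise ValueError(f"reference {rid} has no clan label")
        if reference_clans[rid] not in CLAN_LABELS:
            raise ValueError(
                f"reference clan {reference_clans[rid]!r} outside the 13-group scheme"
            )
    overrides = subfamily_overrides or {}
    joint = SequenceSet.merge(queries, references)
    msa = progressive_align(joint)
    dist = compute_distances(msa, "poisson", clamp_saturated=True)
    index = {gid: i for i, gid in enumerate(dist.ids)}
    out: list[ClanAssignment] = []
    for qid in queries.ids:
        per_clan: dict[str, float] = {}
        for rid in references.ids:
            clan = reference_clans[rid]
            d = dist.matrix[index[qid], index[rid]]
            if clan not in per_clan or d < per_clan[clan]:
                per_clan[clan] = d
        ranked = sorted(per_clan.items(), key=lambda kv: (kv[1], kv[0]))
        best_clan, best_d = ranked[0]
        margin = (ranked[1][1] - best_d) if len(ranked) > 1 else float("inf")
        clan = best_clan
        if overrides.get(qid) in ("AP2", "RAV"):
            clan = overrides[qid]
        out.append(ClanAssignment(qid, clan, margin))
    return out
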