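"""Morphological contour interpolation (MCI) between sparse input slices.

Given binary graft contours traced on a sparse subset of stack slices, MCI
fills every unannotated slice by morphology alone:

1. regions of a pair of consecutive annotated slices are put in
   correspondence by in-plane overlap (one-to-many branching allowed);
2. for each corresponded group, both shapes are translated so their
   centroids meet at the midpoint, and a *transition sequence* is built by
   conditional dilation of the aligned intersection constrained inside the
   aligned union — a chain of shapes gradually transforming one contour
   into the other;
3. the element equally similar to both endpoints (argmax of the smaller of
   the two Jaccard indices, ties to the lower sequence index) becomes the
   middle slice, and the gap is filled by recursive binary subdivision;
4. regions with no partner are eroded toward extinction linearly across
   the gap.

Structuring elements: transition chains alternate 4- and 8-connected 3x3
dilations (octagonal, near-Euclidean growth); erosion of vanishing regions
uses the 3x3 square; region labelling is 4-connected.  Alignment
translations are rounded toward zero.  The whole procedure is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .errors import DistortedInputError
from .grid import VoxelGrid

_SQUARE3 = np.ones((3, 3), dtype=bool)
_CROSS = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


# ---------------------------------------------------------------------------
# Region labelling and correspondence


def connected_regions(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """4-connected regions with a stable ordering.

    Labels are renumbered 1..n by the position of each region's first pixel
    in row-major order (top-most, then left-most), so the numbering does not
    depend on the labelling algorithm's internals.
    """
    mask = np.asarray(mask, dtype=bool)
    lab, n = ndi.label(mask, structure=_CROSS)
    if n == 0:
        return lab, 0
    flat = lab.ravel()
    values, first = np.unique(flat, return_index=True)
    order = [(f, v) for v, f in zip(values, first) if v != 0]
    order.sort()
    remap = np.zeros(n + 1, dtype=lab.dtype)
    for new, (_, old) in enumerate(order, start=1):
        remap[old] = new
    return remap[lab], n


@dataclass
class RegionCorrespondence:
    """Pairing of regions between two slices.

    ``pairs`` holds corresponded groups as ``(ids_in_A, ids_in_B)`` tuples
    of region-id tuples; a group may be one-to-many or many-to-many
    (branching).  Every region id appears exactly once across ``pairs``,
    ``unmatched_A`` and ``unmatched_B``.
    """

    pairs: list = field(default_factory=list)
    unmatched_A: list = field(default_factory=list)
    unmatched_B: list = field(default_factory=list)


def _shift(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = mask[rs_src, cs_src]
    return out


def _trunc(x: float) -> int:
    return int(np.trunc(x))


def correspond_regions(A: np.ndarray, B: np.ndarray) -> RegionCorrespondence:
    """Pair regions of two slices by in-plane overlap.

    Region ``a`` is linked to region ``b`` iff they overlap; for slices at
    most a few voxels apart in a contiguous structure, corresponding
    regions physically overlap in-plane, and an alignment-based rule would
    spuriously match distant regions.  Connected components of the
    bipartite link graph form the corresponded groups (one-to-many
    branching and many-to-many merges allowed).
    """
    labA, nA = connected_regions(A)
    labB, nB = connected_regions(B)
    masksA = {i: labA == i for i in range(1, nA + 1)}
    masksB = {j: labB == j for j in range(1, nB + 1)}
    links = []
    for i, ma in masksA.items():
        for j, mb in masksB.items():
            if (ma & mb).any():
                links.append((i, j))

    # connected components over the bipartite graph
    parent = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        parent.setdefault(x, x)
        parent.setdefault(y, y)
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    for i, j in links:
        union(("A", i), ("B", j))

    groups = {}
    for i, j in links:
        root = find(("A", i))
        groups.setdefault(root, (set(), set()))
        groups[root][0].add(i)
        groups[root][1].add(j)

    matched_A = set().union(*(g[0] for g in groups.values())) if groups else set()
    matched_B = set().union(*(g[1] for g in groups.values())) if groups else set()
    pairs = [
        (tuple(sorted(ga)), tuple(sorted(gb)))
        for ga, gb in sorted(groups.values(), key=lambda g: (min(g[0]), min(g[1])))
    ]
    return RegionCorrespondence(
        pairs=pairs,
        unmatched_A=sorted(set(masksA) - matched_A),
        unmatched_B=sorted(set(masksB) - matched_B),
    )


# ---------------------------------------------------------------------------
# Transition sequence and median shape


@dataclass
class TransitionSequence:
    """Ordered chain of shapes from (aligned) A to (aligned) B.

    ``masks[0]`` equals the aligned A and ``masks[-1]`` the aligned B;
    every element contains the aligned intersection and is contained in the
    aligned union.  ``similarity_to_A`` / ``similarity_to_B`` are the
    per-element Jaccard indices, and ``median_index`` points at the element
    equally similar to both endpoints.
    """

    masks: list
    similarity_to_A: np.ndarray
    similarity_to_B: np.ndarray

    @property
    def median_index(self) -> int:
        return int(np.argmax(np.minimum(self.similarity_to_A, self.similarity_to_B)))


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum()) / float(union)


def _se(step: int) -> np.ndarray:
    """Alternating 4-/8-connected structuring element.

    Alternating cross and square dilations grow octagons, the standard
    discrete approximation of Euclidean (disk) growth; a pure 3x3 square
    would bias the transition shapes toward squares.
    """
    return _CROSS if step % 2 == 1 else _SQUARE3


def _conditional_growth(seed: np.ndarray, target: np.ndarray) -> list[np.ndarray]:
    """Chain of conditional dilations from ``seed`` up to ``target``.

    Components of ``target`` unreachable from ``seed`` (possible for exotic
    groupings) are grown concurrently from their own interior seed so the
    chain always terminates at ``target`` exactly.
    """
    def grow(cur, step):
        nxt = ndi.binary_dilation(cur, _se(step)) & target
        if (nxt == cur).all():
            # a cross step can stall on diagonal-only growth; the square
            # step is a superset, so no progress there means convergence
            nxt = ndi.binary_dilation(cur, _SQUARE3) & target
        return nxt

    seq = [seed]
    cur = seed
    step = 0
    while True:
        step += 1
        nxt = grow(cur, step)
        if (nxt == cur).all():
            break
        seq.append(nxt)
        cur = nxt
    if not (cur == target).all():
        remaining = target & ~cur
        lab, n = connected_regions(remaining)
        seeds = np.zeros_like(target)
        for i in range(1, n + 1):
            comp = lab == i
            d = ndi.distance_transform_edt(comp)
            r, c = np.unravel_index(np.argmax(d), d.shape)
            seeds[r, c] = True
        cur = cur | seeds
        seq.append(cur)
        while True:
            step += 1
            nxt = grow(cur, step)
            if (nxt == cur).all():
                break
            seq.append(nxt)
            cur = nxt
    return seq


def _interior_seed(mask: np.ndarray) -> np.ndarray:
    """Single-pixel seed at the innermost point of ``mask``."""
    d = ndi.distance_transform_edt(mask)
    r, c = np.unravel_index(np.argmax(d), d.shape)
    out = np.zeros_like(mask)
    out[r, c] = True
    return out


def transition_sequence(A: np.ndarray, B: np.ndarray) -> tuple[TransitionSequence, int, int]:
    """Build the aligned transition sequence between two region groups.

    Both masks are translated so their centroids meet at the midpoint
    (integer translation, rounded toward zero).  The sequence element at
    parameter t is ``shrink_A(t) | grow_B(t)`` where ``shrink_A`` runs the
    conditional-dilation chain from the aligned intersection to A backwards
    and ``grow_B`` runs it toward B forwards; the first element is thus
    exactly A and the last exactly B (in the aligned frame).

    If the aligned intersection is empty the chains are grown from each
    shape's own innermost seed pixel instead (documented fallback, no
    exception); the endpoint elements then carry the partner's seed pixel.

    Returns the sequence plus the (dr, dc) translation applied to A, from
    which the caller can undo or reuse the alignment.
    """
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    cA = np.array(ndi.center_of_mass(A))
    cB = np.array(ndi.center_of_mass(B))
    mid = (cA + cB) / 2.0
    drA, dcA = _trunc(mid[0] - cA[0]), _trunc(mid[1] - cA[1])
    drB, dcB = _trunc(mid[0] - cB[0]), _trunc(mid[1] - cB[1])
    Ash = _shift(A, drA, dcA)
    Bsh = _shift(B, drB, dcB)

    inter = Ash & Bsh
    if inter.any():
        chain_A = _conditional_growth(inter, Ash)
        chain_B = _conditional_growth(inter, Bsh)
    else:
        chain_A = _conditional_growth(_interior_seed(Ash), Ash)
        chain_B = _conditional_growth(_interior_seed(Bsh), Bsh)

    ka = len(chain_A) - 1
    kb = len(chain_B) - 1
    L = max(ka, kb, 1)
    masks = []
    for j in range(L + 1):
        t = j / L
        a_part = chain_A[int(round(ka * (1.0 - t)))]
        b_part = chain_B[int(round(kb * t))]
        masks.append(a_part | b_part)
    sim_a = np.array([_jaccard(m, Ash) for m in masks])
    sim_b = np.array([_jaccard(m, Bsh) for m in masks])
    return TransitionSequence(masks, sim_a, sim_b), (drA, dcA), (drB, dcB)


def median_shape(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """The transition-sequence element equally similar to both endpoints.

    The result lives at the midpoint position (the aligned frame), i.e. it
    is returned exactly where the interpolated slice belongs; it satisfies
    ``aligned(A) & aligned(B) <= result <= aligned(A) | aligned(B)``
    whenever the aligned intersection is non-empty.
    """
    seq, _, _ = transition_sequence(A, B)
    return seq.masks[seq.median_index]


# ---------------------------------------------------------------------------
# Gap filling


def _erode_fraction(mask: np.ndarray, t: float) -> np.ndarray:
    """Erode ``mask`` a fraction ``t`` of the way to extinction."""
    if not mask.any():
        return mask
    steps = []
    cur = mask
    while cur.any():
        steps.append(cur)
        cur = ndi.binary_erosion(cur, _SQUARE3)
    k = int(np.floor(t * len(steps)))
    if k >= len(steps):
        return np.zeros_like(mask)
    return steps[k]


def interpolate_gap(A: np.ndarray, B: np.ndarray, i: int, j: int) -> dict:
    """Fill slice indices ``i+1 .. j-1`` between annotated slices A and B.

    Corresponded region groups are filled by recursive binary subdivision
    (median shape at the middle index, then recurse on both halves);
    unmatched regions shrink linearly toward extinction across the gap.
    Returns ``{index: mask}`` for the interior indices.
    """
    if j <= i:
        raise ValueError("gap endpoints must satisfy j > i")
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    out = {k: np.zeros_like(A) for k in range(i + 1, j)}
    if not out:
        return out

    corr = correspond_regions(A, B)
    labA, _ = connected_regions(A)
    labB, _ = connected_regions(B)

    def rec(ga: np.ndarray, lo: int, gb: np.ndarray, hi: int) -> None:
        if hi - lo <= 1:
            return
        mid = (lo + hi) // 2
        m = median_shape(ga, gb)
        out[mid] |= m
        rec(ga, lo, m, mid)
        rec(m, mid, gb, hi)

    for ids_a, ids_b in corr.pairs:
        ga = np.isin(labA, ids_a)
        gb = np.isin(labB, ids_b)
        rec(ga, i, gb, j)

    span = j - i
    for a in corr.unmatched_A:
        ra = labA == a
        for k in range(i + 1, j):
            out[k] |= _erode_fraction(ra, (k - i) / span)
    for b in corr.unmatched_B:
        rb = labB == b
        for k in range(i + 1, j):
            out[k] |= _erode_fraction(rb, (j - k) / span)
    return out


# ---------------------------------------------------------------------------
# Volume assembly


@dataclass
class SparseSliceSet:
    """Binary masks on a sparse, strictly increasing set of stack slices.

    ``slices`` maps slice index to 2-D mask along ``axis``; ``severities``
    records the per-slice artifact severity of the selected slices;
    consecutive selected indices may be at most ``max_gap`` apart, and the
    first/last slices of the graft extent must be included (interpolation
    never extrapolates beyond the annotated range).
    """

    axis: int
    slices: dict
    severities: dict = field(default_factory=dict)
    max_gap: int = 5

    def indices(self) -> list[int]:
        return sorted(self.slices)

    def validate(self) -> None:
        idx = self.indices()
        if not idx:
            raise DistortedInputError("no annotated slices")
        gaps = np.diff(idx)
        if len(gaps) and gaps.max() > self.max_gap:
            raise DistortedInputError(
                f"annotation gap of {int(gaps.max())} slices exceeds "
                f"max_gap={self.max_gap}; the stack is too distorted for "
                "contour interpolation"
            )


def interpolate_volume(
    sparse: SparseSliceSet,
    shape: tuple,
    spacing: float = 0.25,
    origin=None,
) -> VoxelGrid:
    """Fill all unannotated slices of a volume of the given shape.

    Output equals the input masks bit-exactly on annotated indices; slices
    outside the annotated range stay empty.  Raises
    :class:`DistortedInputError` when a gap exceeds ``max_gap``.
    """
    sparse.validate()
    axis = sparse.axis
    out = np.zeros(shape, dtype=np.uint8)
    moved = np.moveaxis(out, axis, 0)
    idx = sparse.indices()
    for k in idx:
        moved[k] = np.asarray(sparse.slices[k], dtype=bool)
    for a, b in zip(idx[:-1], idx[1:]):
        filled = interpolate_gap(
            np.asarray(sparse.slices[a], dtype=bool),
            np.asarray(sparse.slices[b], dtype=bool),
            a,
            b,
        )
        for k, m in filled.items():
            moved[k] = m
    if origin is None:
        origin = np.zeros(3)
    return VoxelGrid(out, spacing, np.asarray(origin, dtype=float))
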