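"""Refinement forests: genealogy-tracked adaptive meshes.

The adaptive mesh is represented as a forest over the initial (root) elements.
Refining a leaf splits it in two (1D) or four (2D red refinement); coarsening
deletes a complete set of sibling leaves.  The conforming mesh handed to the
assembly routines is emitted from the current leaves; in 2D, hanging nodes are
closed with transient green triangles that are recomputed on every emit and are
never refined themselves, so the genealogy stays a pure red forest.  A
1-irregularity rule (edge-neighbour levels differ by at most one) is enforced
during refinement and coarsening.
"""

from __future__ import annotations

import numpy as np

from .mesh import Mesh1D, TriMesh2D, _barycentric

__all__ = ["IntervalForest", "TriForest"]

_ROUND = 10


def _key(x) -> tuple:
    return tuple(np.round(np.atleast_1d(x), _ROUND))


class _Node:
    __slots__ = ("verts", "level", "parent", "children", "uid")

    def __init__(self, verts, level, parent, uid):
        self.verts = verts
        self.level = level
        self.parent = parent
        self.children = None
        self.uid = uid


class _Forest:
    def __init__(self):
        self.roots: list[_Node] = []
        self._uid = 0

    def _new(self, verts, level, parent) -> _Node:
        node = _Node(verts, level, parent, self._uid)
        self._uid += 1
        return node

    def leaves(self) -> list[_Node]:
        out = []

        def rec(n):
            if n.children is None:
                out.append(n)
            else:
                for c in n.children:
                    rec(c)

        for r in self.roots:
            rec(r)
        return out

    @property
    def max_leaf_level(self) -> int:
        return max(lf.level for lf in self.leaves())


# --------------------------------------------------------------------------- #
# 1D
# --------------------------------------------------------------------------- #


class IntervalForest(_Forest):
    """Binary forest over an initially uniform interval mesh."""

    def __init__(self, x_min: float, x_max: float, n_root: int):
        super().__init__()
        if n_root < 1:
            raise ValueError("need at least one root element")
        xs = np.linspace(x_min, x_max, n_root + 1)
        for k in range(n_root):
            self.roots.append(self._new((xs[k], xs[k + 1]), 0, None))

    def refine(self, leaf: _Node) -> None:
        if leaf.children is not None:
            return
        x0, x1 = leaf.verts
        xm = 0.5 * (x0 + x1)
        leaf.children = (
            self._new((x0, xm), leaf.level + 1, leaf),
            self._new((xm, x1), leaf.level + 1, leaf),
        )

    def refine_uniform(self, levels: int = 1) -> None:
        for _ in range(levels):
            for lf in self.leaves():
                self.refine(lf)

    def coarsen(self, leaf: _Node) -> bool:
        """Remove ``leaf`` and its sibling (called once per sibling pair)."""
        parent = leaf.parent
        if parent is None:
            return False
        parent.children = None
        return True

    def apply_flags(self, refine_flags, coarsen_flags, max_level: int | None = None):
        """Adapt given per-leaf boolean flags in current leaf (element) order.

        Coarsening requires both siblings flagged; coarsening a root element is
        ignored.  Returns True when the leaf set changed.
        """
        leaves = self.leaves()
        refine_flags = np.asarray(refine_flags, dtype=bool)
        coarsen_flags = np.asarray(coarsen_flags, dtype=bool)
        changed = False
        flag_of = {lf.uid: (bool(r), bool(c)) for lf, r, c in zip(leaves, refine_flags, coarsen_flags)}
        # unanimous-sibling coarsening first, skipping pairs with a refine flag
        for lf in leaves:
            p = lf.parent
            if p is None or p.children is None:
                continue
            sibs = p.children
            if all(
                s.children is None
                and flag_of.get(s.uid, (False, False))[1]
                and not flag_of.get(s.uid, (False, False))[0]
                for s in sibs
            ):
                p.children = None
                changed = True
        for lf in leaves:
            if flag_of[lf.uid][0] and lf.children is None:
                if max_level is not None and lf.level >= max_level:
                    continue
                # the leaf may have been absorbed by coarsening
                if self._alive(lf):
                    self.refine(lf)
                    changed = True
        return changed

    def _alive(self, node: _Node) -> bool:
        while node.parent is not None:
            if node not in node.parent.children:
                return False
            node = node.parent
        return node in self.roots

    def to_mesh(self) -> Mesh1D:
        leaves = sorted(self.leaves(), key=lambda lf: lf.verts[0])
        xs = np.empty(len(leaves) + 1)
        for k, lf in enumerate(leaves):
            xs[k] = lf.verts[0]
        xs[-1] = leaves[-1].verts[1]
        elements = np.column_stack([np.arange(len(leaves)), np.arange(1, len(leaves) + 1)])
        level = np.array([lf.level for lf in leaves], dtype=int)
        parent = np.array(
            [lf.parent.uid if lf.parent is not None else -1 for lf in leaves], dtype=int
        )
        return Mesh1D(xs, elements, level, parent)


# --------------------------------------------------------------------------- #
# 2D
# --------------------------------------------------------------------------- #


class TriForest(_Forest):
    """Red-refinement forest over the triangles of a conforming 2D mesh."""

    def __init__(self, mesh: TriMesh2D):
        super().__init__()
        for t in mesh.triangles:
            verts = tuple(tuple(mesh.node_coords[v]) for v in t)
            self.roots.append(self._new(verts, 0, None))

    # -- point location in the leaf forest ---------------------------------- #

    def _locate_leaf(self, pt) -> _Node | None:
        def inside(node, tol):
            lam = _barycentric(np.asarray(node.verts), pt)
            return lam.min() >= -tol

        for r in self.roots:
            if inside(r, 1e-10):
                node = r
                while node.children is not None:
                    nxt = None
                    for c in node.children:
                        if inside(c, 1e-10):
                            nxt = c
                            break
                    if nxt is None:  # rounding: pick closest child
                        nxt = max(
                            node.children,
                            key=lambda c: _barycentric(np.asarray(c.verts), pt).min(),
                        )
                    node = nxt
                return node
        return None

    # -- refinement --------------------------------------------------------- #

    def refine(self, leaf: _Node) -> None:
        """Red-split a leaf, first refining coarser edge neighbours so that
        adjacent leaf levels never differ by more than one."""
        if leaf.children is not None:
            return
        self._ensure_neighbor_levels(leaf)
        v = [np.asarray(p) for p in leaf.verts]
        m01 = tuple(0.5 * (v[0] + v[1]))
        m12 = tuple(0.5 * (v[1] + v[2]))
        m20 = tuple(0.5 * (v[2] + v[0]))
        t0, t1, t2 = leaf.verts
        lv = leaf.level + 1
        leaf.children = (
            self._new((t0, m01, m20), lv, leaf),
            self._new((m01, t1, m12), lv, leaf),
            self._new((m20, m12, t2), lv, leaf),
            self._new((m01, m12, m20), lv, leaf),
        )

    def _ensure_neighbor_levels(self, leaf: _Node) -> None:
        v = [np.asarray(p) for p in leaf.verts]
        for a in range(3):
            p0, p1 = v[a], v[(a + 1) % 3]
            opp = v[(a + 2) % 3]
            mid = 0.5 * (p0 + p1)
            out = mid - opp
            edge_len = np.linalg.norm(p1 - p0)
            q = mid + out / np.linalg.norm(out) * 1e-6 * edge_len
            nb = self._locate_leaf(q)
            guard = 0
            while nb is not None and nb.level < leaf.level:
                self.refine(nb)
                nb = self._locate_leaf(q)
                guard += 1
                if guard > 64:
                    raise RuntimeError("neighbour refinement did not terminate")

    def refine_uniform(self, levels: int = 1) -> None:
        for _ in range(levels):
            for lf in self.leaves():
                self.refine(lf)

    def apply_flags(self, refine_flags, coarsen_flags, max_level: int | None = None):
        """Adapt using flags indexed in the element order of the most recent
        :meth:`to_mesh` call (see :attr:`last_emit_leaf_of_element`)."""
        owner = self.last_emit_leaf_of_element
        refine_flags = np.asarray(refine_flags, dtype=bool)
        coarsen_flags = np.asarray(coarsen_flags, dtype=bool)
        if owner is None or len(refine_flags) != len(owner):
            raise ValueError("flags must match the elements of the last emitted mesh")
        ref_leaves: dict[int, _Node] = {}
        crs_votes: dict[int, set[int]] = {}
        leaf_by_uid: dict[int, _Node] = {}
        for e, lf in enumerate(owner):
            leaf_by_uid[lf.uid] = lf
            if refine_flags[e]:
                ref_leaves[lf.uid] = lf
            if coarsen_flags[e]:
                crs_votes.setdefault(lf.uid, set()).add(e)
        changed = False
        # coarsen: all four red siblings flagged (every emitted piece of every
        # sibling), none flagged for refinement, and the merge keeps 1-irregularity
        pieces_of: dict[int, int] = {}
        for lf in owner:
            pieces_of[lf.uid] = pieces_of.get(lf.uid, 0) + 1
        seen_parents = set()
        for lf in owner:
            p = lf.parent
            if p is None or p.children is None or id(p) in seen_parents:
                continue
            seen_parents.add(id(p))
            sibs = p.children
            ok = all(
                s.children is None
                and s.uid in crs_votes
                and len(crs_votes[s.uid]) == pieces_of.get(s.uid, 0)
                and s.uid not in ref_leaves
                for s in sibs
            )
            if ok and self._coarsen_keeps_conformity(p):
                p.children = None
                changed = True
        for uid, lf in ref_leaves.items():
            if lf.children is not None or not self._alive(lf):
                continue
            if max_level is not None and lf.level >= max_level:
                continue
            self.refine(lf)
            changed = True
        return changed

    def _alive(self, node: _Node) -> bool:
        while node.parent is not None:
            if node.parent.children is None or node not in node.parent.children:
                return False
            node = node.parent
        return node in self.roots

    def _coarsen_keeps_conformity(self, parent: _Node) -> bool:
        v = [np.asarray(p) for p in parent.verts]
        L = parent.level + 1  # children's level
        for a in range(3):
            p0, p1 = v[a], v[(a + 1) % 3]
            opp = v[(a + 2) % 3]
            edge = p1 - p0
            edge_len = np.linalg.norm(edge)
            for frac in (0.125, 0.375, 0.625, 0.875):
                mid = p0 + frac * edge
                out = mid - opp
                # project out the tangential part to get the outward normal
                out = out - edge * (out @ edge) / (edge_len**2)
                q = mid + out / np.linalg.norm(out) * 1e-6 * edge_len
                nb = self._locate_leaf(q)
                if nb is not None and nb.level > L:
                    return False
        return True

    # -- conforming mesh emission ------------------------------------------ #

    last_emit_leaf_of_element: list | None = None

    def to_mesh(self) -> TriMesh2D:
        leaves = self.leaves()
        coords: dict[tuple, int] = {}

        def node_id(p) -> int:
            k = _key(p)
            if k not in coords:
                coords[k] = len(coords)
            return coords[k]

        for lf in leaves:
            for p in lf.verts:
                node_id(p)
        vert_keys = set(coords)

        tris, levels, parents, owner = [], [], [], []

        def emit(tri_ids, lf):
            tris.append(tri_ids)
            levels.append(lf.level)
            parents.append(lf.parent.uid if lf.parent is not None else -1)
            owner.append(lf)

        for lf in leaves:
            v = [np.asarray(p) for p in lf.verts]
            vid = [node_id(p) for p in lf.verts]
            mids = []
            hanging = []
            for a in range(3):
                m = 0.5 * (v[a] + v[(a + 1) % 3])
                mk = _key(m)
                mids.append(m)
                hanging.append(mk in vert_keys)
            nh = sum(hanging)
            if nh == 0:
                emit((vid[0], vid[1], vid[2]), lf)
                continue
            if nh == 3:  # transient red closure
                mm = [node_id(m) for m in mids]
                emit((vid[0], mm[0], mm[2]), lf)
                emit((mm[0], vid[1], mm[1]), lf)
                emit((mm[2], mm[1], vid[2]), lf)
                emit((mm[0], mm[1], mm[2]), lf)
                continue
            # rotate so that the split pattern starts at edge 0
            rot = hanging.index(True)
            ridx = [(rot + k) % 3 for k in range(3)]
            rv = [vid[i] for i in ridx]
            rh = [hanging[i] for i in ridx]
            rm = [mids[i] for i in ridx]
            if nh == 1:
                m0 = node_id(rm[0])
                emit((rv[0], m0, rv[2]), lf)
                emit((m0, rv[1], rv[2]), lf)
            else:  # nh == 2; ensure the two split edges are edges 0 and 1
                if not rh[1]:  # split edges are 0 and 2: rotate once more
                    ridx = [(rot + 2 + k) % 3 for k in range(3)]
                    rv = [vid[i] for i in ridx]
                    rm = [mids[i] for i in ridx]
                m0, m1 = node_id(rm[0]), node_id(rm[1])
                emit((rv[0], m0, rv[2]), lf)
                emit((m0, rv[1], m1), lf)
                emit((m0, m1, rv[2]), lf)

        nodes = np.empty((len(coords), 2))
        for k, i in coords.items():
            nodes[i] = k
        mesh = TriMesh2D(
            nodes,
            np.array(tris, dtype=int),
            np.array(levels, dtype=int),
            np.array(parents, dtype=int),
        )
        self.last_emit_leaf_of_element = owner
        return mesh
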