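"""Bottom-up traversal of the lcp-interval tree of a sorted bucket.

An lcp-interval ``l-[e..f]`` of a sorted suffix table H with lcp table L is
a maximal interval whose members all share a prefix of length l:

* ``e == 0`` or ``L[e] < l``;
* ``L[q] >= l`` for all ``e+1 <= q <= f``;
* ``L[q] == l`` for at least one such q;
* ``f == beta-1`` or ``L[f+1] < l``.

Nesting of these intervals forms a (virtual) tree whose leaves are the
singleton intervals ``[e']`` (one per suffix).  The traversal below delivers
every leaf edge, every branch edge and every completed lcp-interval exactly
once, children strictly before their parents, using the classic
stack-driven linear scan (push on rising lcp, complete and pop on falling
lcp) extended with leaf-edge delivery: the pending singleton between two
interval events is attached to the interval on top of the stack at the
moment its position is passed.
"""

from __future__ import annotations

from .spmindex import SortedBucket


class LcpInterval:
    """Stack element of the bottom-up traversal.

    ``rb`` stays undefined (None) until the interval is completed;
    ``firstinW`` is an integer slot used by the SPM enumeration layer.
    """

    __slots__ = ("lcp", "lb", "rb", "firstinW", "_has_edges")

    def __init__(self, lcp: int, lb: int):
        self.lcp = lcp
        self.lb = lb
        self.rb: int | None = None
        self.firstinW: int | None = None
        self._has_edges = False

    def __repr__(self) -> str:  # pragma: no cover
        return f"LcpInterval(lcp={self.lcp}, lb={self.lb}, rb={self.rb})"


class TraversalCallbacks:
    """Callback bundle for :func:`traverse_bucket`.

    ``process_leafedge(firstedge, itv, (strand, offset))`` is invoked once
    per singleton; ``process_branchedge(firstedge, itv, child)`` once per
    completed child interval; ``process_lcpinterval(itv)`` once per interval,
    after all its edges and before the edge attaching it to its parent.
    """

    def process_leafedge(self, firstedge: bool, itv: LcpInterval, leaf: tuple[int, int]) -> None:
        pass

    def process_branchedge(self, firstedge: bool, itv: LcpInterval, child: LcpInterval) -> None:
        pass

    def process_lcpinterval(self, itv: LcpInterval) -> None:
        pass


def traverse_bucket(bucket: SortedBucket, cb: TraversalCallbacks) -> None:
    """Emit the lcp-interval tree of one sorted bucket bottom-up.

    The bucket root is the interval of minimal L value; it is completed and
    delivered last.  A singleton bucket is delivered as one leaf edge from a
    degenerate root interval of lcp 0.
    """
    beta = bucket.beta
    if beta == 0:
        return
    H = list(zip(bucket.strands.tolist(), bucket.offsets.tolist()))
    if beta == 1:
        root = LcpInterval(0, 0)
        root.rb = 0
        cb.process_leafedge(True, root, H[0])
        cb.process_lcpinterval(root)
        return

    L = bucket.L.tolist()
    if min(L) < bucket.k:
        raise ValueError(
            f"malformed lcp table: value {min(L)} below the bucket key length {bucket.k}"
        )

    bottom = LcpInterval(-1, 0)  # virtual, never delivered
    stack = [bottom]
    for j in range(1, beta + 1):
        lv = L[j - 1] if j < beta else -1
        leaf = H[j - 1]
        top = stack[-1]
        if lv > top.lcp:
            # the leaf hangs below a deeper interval opened here
            itv = LcpInterval(lv, j - 1)
            stack.append(itv)
            cb.process_leafedge(True, itv, leaf)
            itv._has_edges = True
            continue
        # the leaf belongs to the interval on top of the stack
        cb.process_leafedge(not top._has_edges, top, leaf)
        top._has_edges = True
        while lv < stack[-1].lcp:
            completed = stack.pop()
            completed.rb = j - 1
            cb.process_lcpinterval(completed)
            top = stack[-1]
            if lv > top.lcp:
                # new interval between the completed child and the old top
                itv = LcpInterval(lv, completed.lb)
                stack.append(itv)
                cb.process_branchedge(True, itv, completed)
                itv._has_edges = True
            elif top is not bottom:  # edges to the virtual bottom are dropped
                cb.process_branchedge(not top._has_edges, top, completed)
                top._has_edges = True
    assert stack == [bottom], "traversal left unfinished intervals"


def naive_lcp_intervals(L: list[int], beta: int) -> set[tuple[int, int, int]]:
    """O(beta^2) reference enumeration of all (lcp, lb, rb) intervals from
    the definition; independent oracle for the stack traversal."""
    out: set[tuple[int, int, int]] = set()
    if beta < 2:
        return out
    for e in range(beta):
        for f in range(e + 1, beta):
            inner = L[e:f]  # L[q] for q in e+1..f (L is 0-indexed by q-1)
            l = min(inner)
            if (e == 0 or L[e - 1] < l) and (f == beta - 1 or L[f] < l):
                out.add((l, e, f))
    return out
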