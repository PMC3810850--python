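"""Partition comparison by normalized mutual information (NMI).

A Partition maps every item (tip label) to a group id; group ids are
arbitrary and NMI is invariant to relabeling.  MI is computed from the
contingency table with natural-log entropies and normalized by the geometric
mean of the two partition entropies (an arithmetic-mean variant is available
for cross-tool comparison).  NMI = 1 means the partitions are identical up to
relabeling; NMI = 0 means they share no information.  The doubly degenerate
case (both partitions a single group) scores 1; exactly one zero-entropy
partition scores 0.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from sklearn.metrics import normalized_mutual_info_score

from .errors import PartitionMismatchError

__all__ = ["Partition", "nmi"]


class Partition(Mapping):
    """An immutable item -> group-id mapping over a finite item set."""

    def __init__(self, assignment: Mapping[str, object]):
        self._map = dict(assignment)

    # Mapping protocol
    def __getitem__(self, item):
        return self._map[item]

    def __iter__(self):
        return iter(self._map)

    def __len__(self):
        return len(self._map)

    @property
    def items_set(self) -> frozenset:
        return frozenset(self._map)

    @property
    def n_groups(self) -> int:
        return len(set(self._map.values()))

    def groups(self) -> list[set]:
        by_group: dict[object, set] = {}
        for item, g in self._map.items():
            by_group.setdefault(g, set()).add(item)
        return list(by_group.values())

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_tsv(cls, path) -> "Partition":
        """Read a two-column (item, group) tab-separated file."""
        out: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise PartitionMismatchError(
                        f"{path}:{lineno}: expected 2 tab-separated columns"
                    )
                item, group = parts
                if item in out:
                    raise PartitionMismatchError(
                        f"{path}:{lineno}: duplicate item {item!r}"
                    )
                out[item] = group
        return cls(out)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for item in sorted(self._map):
                fh.write(f"{item}\t{self._map[item]}\n")

    def __repr__(self) -> str:
        return f"Partition(n_items={len(self)}, n_groups={self.n_groups})"


def nmi(a: Partition | Mapping, b: Partition | Mapping, average: str = "geometric") -> float:
    """NMI between two partitions of the identical item set (>= 2 items)."""
    a = a if isinstance(a, Partition) else Partition(a)
    b = b if isinstance(b, Partition) else Partition(b)
    if a.items_set != b.items_set:
        only_a = sorted(a.items_set - b.items_set)[:10]
        only_b = sorted(b.items_set - a.items_set)[:10]
        raise PartitionMismatchError(
            "partitions are defined on different item sets; "
            f"only in first: {only_a}; only in second: {only_b}"
        )
    items = sorted(a.items_set)
    if len(items) < 2:
        raise PartitionMismatchError("need at least 2 items to compare")
    # map arbitrary group ids to integer codes
    codes_a = {g: i for i, g in enumerate(dict.fromkeys(a[i] for i in items))}
    codes_b = {g: i for i, g in enumerate(dict.fromkeys(b[i] for i in items))}
    la = [codes_a[a[i]] for i in items]
    lb = [codes_b[b[i]] for i in items]
    if average not in ("geometric", "arithmetic"):
        raise ValueError("average must be 'geometric' or 'arithmetic'")
    return float(normalized_mutual_info_score(la, lb, average_method=average))
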