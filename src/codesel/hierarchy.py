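"""Code hierarchies for ICD-10-style and ATC-style terminologies.

Both terminologies are rooted forests: ICD-10 chapters contain block
ranges (``I20-I25``), which contain three-character categories (``I25``),
which contain expansion codes (``I251``); ATC is a fixed-width prefix code
with five levels (1, 3, 4, 5 and 7 characters, e.g. ``C`` > ``C07`` >
``C07A`` > ``C07AB`` > ``C07AB02``).

Because ICD block ranges cannot be derived from a child code string, the
ICD hierarchy is table-driven (rows of ``code,parent,label``); the ATC
hierarchy is rule-driven by prefix truncation.  Node depth counts edges
from the root, so roots (ICD chapters, ATC anatomical main groups) sit at
depth 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: character lengths of the five ATC levels, most specific first
_ATC_LEVELS = (7, 5, 4, 3, 1)


class CodeSystem(str, Enum):
    ICD10 = "ICD10"
    ATC = "ATC"
    SYNTH = "SYNTH"


@dataclass
class CodeNode:
    """A single code with its parent link and tree depth."""

    code: str
    system: CodeSystem = CodeSystem.SYNTH
    parent: str | None = None
    depth: int = 0
    label: str = ""


class HierarchyError(ValueError):
    """Raised for malformed codes, missing parents or cycles."""


def parse_atc_ancestors(code: str) -> list[str]:
    """Proper ancestors of an ATC code, nearest first.

    ATC levels are fixed-width prefixes, so the ancestor chain of a
    7-character substance code is obtained by truncating to 5, 4, 3 and
    1 characters:

    >>> parse_atc_ancestors("C07AB02")
    ['C07AB', 'C07A', 'C07', 'C']
    >>> parse_atc_ancestors("C")
    []
    """
    code = code.strip()
    if len(code) not in _ATC_LEVELS or not code[:1].isalpha():
        raise HierarchyError(f"not a valid ATC code: {code!r}")
    return [code[:n] for n in _ATC_LEVELS if n < len(code)]


@dataclass
class CodeHierarchy:
    """A rooted forest of codes with parent links and depths.

    ``nodes`` maps each code to its :class:`CodeNode`; ``roots`` are the
    codes with no parent.  Every non-root's parent is present, parent
    chains are acyclic, and ``depth(child) == depth(parent) + 1``.
    """

    nodes: dict[str, CodeNode] = field(default_factory=dict)

    @property
    def roots(self) -> list[str]:
        return [c for c, n in self.nodes.items() if n.parent is None]

    def __contains__(self, code: str) -> bool:
        return code in self.nodes

    def depth(self, code: str) -> int:
        return self.nodes[code].depth

    def ancestors(self, code: str) -> list[str]:
        """Proper ancestors of ``code``, nearest first."""
        out: list[str] = []
        cur = self.nodes[code].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def add_singleton_root(self, code: str, system: CodeSystem = CodeSystem.SYNTH) -> CodeNode:
        """Attach an unknown code as a depth-0 root (logged, not rejected).

        Regional terminology extensions make complete lookup tables
        unrealistic, so unresolvable codes degrade gracefully.
        """
        logger.warning("code %s absent from hierarchy; attached as depth-0 root", code)
        node = CodeNode(code=code, system=system, parent=None, depth=0)
        self.nodes[code] = node
        return node

    def resolve(self, code: str, system: CodeSystem = CodeSystem.SYNTH) -> CodeNode:
        """Look up ``code``; for ATC codes derive the chain by prefix rule,
        otherwise fall back to a singleton root."""
        if code in self.nodes:
            return self.nodes[code]
        if system == CodeSystem.ATC:
            chain = [code, *parse_atc_ancestors(code)]
            # insert the missing suffix of the chain, deepest last
            for i in range(len(chain) - 1, -1, -1):
                c = chain[i]
                if c in self.nodes:
                    continue
                parent = chain[i + 1] if i + 1 < len(chain) else None
                depth = 0 if parent is None else self.nodes[parent].depth + 1
                self.nodes[c] = CodeNode(code=c, system=system, parent=parent, depth=depth)
            return self.nodes[code]
        return self.add_singleton_root(code, system)

    def validate(self) -> None:
        for code, node in self.nodes.items():
            if node.parent is not None:
                if node.parent not in self.nodes:
                    raise HierarchyError(f"parent {node.parent!r} of {code!r} missing")
                if node.depth != self.nodes[node.parent].depth + 1:
                    raise HierarchyError(f"depth of {code!r} inconsistent with parent")
            elif node.depth != 0:
                raise HierarchyError(f"root {code!r} has nonzero depth")


def build_icd_hierarchy(
    code_table: Iterable[tuple[str, str | None, str]] | pd.DataFrame,
    system: CodeSystem = CodeSystem.ICD10,
) -> CodeHierarchy:
    """Build a hierarchy from ``(code, parent, label)`` rows.

    An empty/missing parent marks a root.  Raises :class:`HierarchyError`
    listing orphan parent references, or showing the path of a cycle.
    """
    if isinstance(code_table, pd.DataFrame):
        rows = [
            (str(r.code), None if pd.isna(r.parent) or r.parent == "" else str(r.parent),
             "" if "label" not in code_table.columns or pd.isna(getattr(r, "label", "")) else str(r.label))
            for r in code_table.itertuples(index=False)
        ]
    else:
        rows = [(c, (p if p else None), lab) for c, p, lab in code_table]

    seen = set()
    for code, _, _ in rows:
        if code in seen:
            raise HierarchyError(f"duplicate code row: {code!r}")
        seen.add(code)

    parent_of = {code: parent for code, parent, _ in rows}
    missing = sorted({p for p in parent_of.values() if p is not None and p not in parent_of})
    if missing:
        raise HierarchyError(f"missing parent codes: {missing}")

    depths: dict[str, int] = {}

    def _depth(code: str, trail: tuple[str, ...] = ()) -> int:
        if code in depths:
            return depths[code]
        if code in trail:
            cycle = " -> ".join((*trail[trail.index(code):], code))
            raise HierarchyError(f"cycle in hierarchy: {cycle}")
        parent = parent_of[code]
        d = 0 if parent is None else _depth(parent, (*trail, code)) + 1
        depths[code] = d
        return d

    hier = CodeHierarchy()
    for code, parent, label in rows:
        hier.nodes[code] = CodeNode(
            code=code, system=system, parent=parent, depth=_depth(code), label=label
        )
    return hier


def build_atc_hierarchy(codes: Iterable[str]) -> CodeHierarchy:
    """Build the prefix-rule hierarchy spanning ``codes`` and their ancestors."""
    hier = CodeHierarchy()
    for code in codes:
        hier.resolve(code, CodeSystem.ATC)
    return hier


def load_hierarchy_table(path: str | Path, system: CodeSystem = CodeSystem.ICD10) -> CodeHierarchy:
    """Read a delimited ``code,parent,label`` table (empty parent = root)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns={c: c.strip().lower() for c in df.columns})
    if "parent" not in df.columns or "code" not in df.columns:
        raise HierarchyError(f"hierarchy table {path} needs 'code' and 'parent' columns")
    df["parent"] = df["parent"].replace("", None)
    if "label" not in df.columns:
        df["label"] = ""
    return build_icd_hierarchy(df[["code", "parent", "label"]], system=system)


def load_example_hierarchy(which: str = "icd") -> CodeHierarchy:
    """Miniature packaged hierarchy table: ``"icd"`` (cardiovascular /
    respiratory / metabolic chapters) or ``"atc"`` (a few drug chains)."""
    if which not in ("icd", "atc"):
        raise ValueError("which must be 'icd' or 'atc'")
    path = Path(__file__).parent / "data" / f"{which}_mini.csv"
    system = CodeSystem.ICD10 if which == "icd" else CodeSystem.ATC
    return load_hierarchy_table(path, system=system)


def depth_weight(depth: int) -> float:
    """Loss weight ``1 / (1 + depth)`` for a node at the given depth.

    Strictly decreasing in depth: the most general codes (roots, depth 0)
    get weight 1, pushing reconstruction losses toward the top of the
    tree.
    """
    if depth < 0:
        raise ValueError(f"depth must be non-negative, got {depth}")
    return 1.0 / (1.0 + depth)


def depth_weights_for(hierarchy: CodeHierarchy, codes: Sequence[str]) -> list[float]:
    """Eq.-style weights for an ordered list of feature codes."""
    return [depth_weight(hierarchy.depth(c)) for c in codes]
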