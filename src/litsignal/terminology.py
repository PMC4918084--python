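"""MeSH-style terminology modelled as a multi-rooted DAG over tree numbers.

A descriptor carries one or more dot-delimited *tree numbers* (e.g.
``C05.651.869``), each locating it in one branch of the hierarchy.  Following
MeSH practice, the tree numbers — not explicit parent links — are the single
source of hierarchical structure: a term's ancestors are the descriptors
owning any proper prefix of any of its tree numbers.  A descriptor may be
multi-classified (several tree numbers in different branches), which is what
makes the structure a DAG rather than a tree and is the ultimate reason the
enrichment test downstream needs a dependency correction.

Supplementary-concept records (typically drugs) are permitted as descriptors
with zero tree numbers; they take part in drug–event pairing but never in
hierarchical aggregation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ParseError, UnknownTermError, ValidationError

log = logging.getLogger(__name__)


def tree_level(tree_number: str) -> int:
    """Hierarchical depth of a tree number: its number of dot-separated
    segments, 1-based (``"C05"`` is level 1, ``"C05.651"`` level 2)."""
    _validate_tree_number(tree_number)
    return tree_number.count(".") + 1


def _validate_tree_number(tree_number: str) -> None:
    if not tree_number or any(not seg for seg in tree_number.split(".")):
        raise ValidationError(f"malformed tree number: {tree_number!r}")


@dataclass(frozen=True)
class Descriptor:
    """A controlled indexing term: opaque ID, display name, tree numbers."""

    descriptor_id: str
    name: str
    tree_numbers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.descriptor_id:
            raise ValidationError("descriptor_id must be non-empty")
        object.__setattr__(self, "tree_numbers", frozenset(self.tree_numbers))
        for tn in self.tree_numbers:
            _validate_tree_number(tn)


class Terminology:
    """Collection of descriptors indexed by ID and by tree number.

    Each tree number resolves to exactly one descriptor (injective index);
    duplicate descriptor entries are merged by union of their tree numbers.
    """

    def __init__(self, descriptors: Iterable[Descriptor] = ()) -> None:
        self._descriptors: dict[str, Descriptor] = {}
        self._tree_index: dict[str, str] = {}
        for d in descriptors:
            self.add(d)

    def add(self, descriptor: Descriptor) -> None:
        prev = self._descriptors.get(descriptor.descriptor_id)
        if prev is not None:
            descriptor = Descriptor(
                descriptor.descriptor_id,
                prev.name or descriptor.name,
                prev.tree_numbers | descriptor.tree_numbers,
            )
        for tn in descriptor.tree_numbers:
            owner = self._tree_index.get(tn)
            if owner is not None and owner != descriptor.descriptor_id:
                raise ValidationError(
                    f"tree number {tn} assigned to both {owner} "
                    f"and {descriptor.descriptor_id}"
                )
        self._descriptors[descriptor.descriptor_id] = descriptor
        for tn in descriptor.tree_numbers:
            self._tree_index[tn] = descriptor.descriptor_id

    # -- mapping-style access -------------------------------------------------

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self._descriptors

    def __len__(self) -> int:
        return len(self._descriptors)

    def __iter__(self) -> Iterator[Descriptor]:
        return iter(self._descriptors.values())

    def __getitem__(self, descriptor_id: str) -> Descriptor:
        try:
            return self._descriptors[descriptor_id]
        except KeyError:
            raise UnknownTermError(descriptor_id) from None

    def get(self, descriptor_id: str) -> Descriptor | None:
        return self._descriptors.get(descriptor_id)

    @property
    def tree_index(self) -> dict[str, str]:
        return dict(self._tree_index)

    def resolve_tree_number(self, tree_number: str) -> str | None:
        return self._tree_index.get(tree_number)

    # -- hierarchy ------------------------------------------------------------

    def ancestors(self, descriptor_id: str) -> frozenset[str]:
        """Descriptors at every proper prefix of every tree number of the
        term, unioned across its tree numbers.

        The result never contains the term itself unless the term also owns
        one of its own ancestor tree numbers (possible in principle for a
        multi-classified term).
        """
        descriptor = self[descriptor_id]
        out: set[str] = set()
        for tn in descriptor.tree_numbers:
            segments = tn.split(".")
            for i in range(1, len(segments)):
                anc = self._tree_index.get(".".join(segments[:i]))
                if anc is not None:
                    out.add(anc)
        return frozenset(out)

    def ancestor_chain(self, tree_number: str) -> list[str]:
        """Descriptor IDs on the proper-prefix chain of one tree number,
        ordered from the deepest ancestor to the root; prefixes that resolve
        to no descriptor are skipped."""
        segments = tree_number.split(".")
        chain: list[str] = []
        for i in range(len(segments) - 1, 0, -1):
            anc = self._tree_index.get(".".join(segments[:i]))
            if anc is not None:
                chain.append(anc)
        return chain


# -- file dialects ------------------------------------------------------------


def load_terminology(path: str | Path, dialect: str | None = None) -> Terminology:
    """Read a terminology file.

    TSV dialect: three tab-separated columns ``descriptor_id``, ``name``,
    ``tree_numbers`` (``;``-separated, may be empty for supplementary
    concepts); ``#`` starts a comment line; extra columns are ignored.
    JSON dialect: an array of objects with the same keys.
    """
    path = Path(path)
    if dialect is None:
        dialect = "json" if path.suffix.lower() == ".json" else "tsv"
    if dialect == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        descriptors = []
        for i, row in enumerate(rows):
            try:
                tns = row.get("tree_numbers", [])
                if isinstance(tns, str):
                    tns = [t for t in tns.split(";") if t]
                descriptors.append(
                    Descriptor(row["descriptor_id"], row.get("name", ""), frozenset(tns))
                )
            except (KeyError, TypeError, ValidationError) as exc:
                raise ParseError(f"{path}: entry {i}: {exc}") from exc
        return Terminology(descriptors)
    if dialect != "tsv":
        raise ValidationError(f"unknown terminology dialect: {dialect!r}")

    terminology = Terminology()
    with path.open(encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
            descriptor_id, name, tree_field = fields[0], fields[1], fields[2]
            tns = frozenset(t for t in tree_field.split(";") if t)
            try:
                terminology.add(Descriptor(descriptor_id, name, tns))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return terminology


def write_terminology(terminology: Terminology, path: str | Path) -> None:
    """Write the TSV dialect understood by :func:`load_terminology`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# descriptor_id\tname\ttree_numbers\n")
        for d in sorted(terminology, key=lambda d: d.descriptor_id):
            handle.write(f"{d.descriptor_id}\t{d.name}\t{';'.join(sorted(d.tree_numbers))}\n")
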