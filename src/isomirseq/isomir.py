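"""IsomiR classification and dotted-name assignment.

Every aligned read is either canonical (exact mature sequence) or an isomiR in
one of four end-variation classes:

==========  =====================================================
class code  meaning
==========  =====================================================
``"3"``     3' variation only (trim, templated extension, or NTA tail)
``"5"``     5' shift only
``"53"``    variation at both ends
``"0"``     internal substitution(s) only, both ends canonical
==========  =====================================================

Names follow the grammar ``{parent}.{class}.P{n_subst}.S.{serial}``
(e.g. ``hsa-miR-451a.3.P0.S.57``): ``P{n}`` counts internal substitutions,
``S`` introduces the per-parent serial. Serials rank distinct variant
sequences of a parent by total abundance (descending, ties lexicographic by
sequence), so naming is deterministic across reruns on identical input.
A non-templated tail counts as 3' variation, not as substitution, since it
alters the 3' end.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .align import HairpinAlignment

SEED_POSITIONS = range(1, 8)  # mature-relative positions whose change alters the seed

CLASS_CODES = ("0", "3", "5", "53")


@dataclass(frozen=True)
class IsomiRCall:
    parent_mature_id: str
    sequence: str
    offset5: int
    offset3: int
    nta_tail: str
    n_subst: int
    seed_altered: bool
    canonical: bool
    class_code: str  # "" for canonical
    name: str = ""  # assigned by assign_names; canonical calls use parent id
    multiplicity: float = 0.0


def classify(aln: HairpinAlignment) -> IsomiRCall:
    """Classify one alignment; the name is left for :func:`assign_names`."""
    var3 = aln.offset3 != 0 or bool(aln.nta_tail)
    var5 = aln.offset5 != 0
    canonical = not var3 and not var5 and aln.n_subst == 0
    if canonical:
        code = ""
    elif var5 and var3:
        code = "53"
    elif var5:
        code = "5"
    elif var3:
        code = "3"
    else:
        code = "0"
    seed_altered = var5 or any(p in SEED_POSITIONS for p, _, _ in aln.substitutions)
    return IsomiRCall(
        parent_mature_id=aln.mature_id,
        sequence=aln.read,
        offset5=aln.offset5,
        offset3=aln.offset3,
        nta_tail=aln.nta_tail,
        n_subst=aln.n_subst,
        seed_altered=seed_altered,
        canonical=canonical,
        class_code=code,
        name=aln.mature_id if canonical else "",
        multiplicity=aln.multiplicity,
    )


class IsomiRCatalog:
    """Registry of named calls, unique per (parent, sequence)."""

    def __init__(self) -> None:
        self.calls: dict[tuple[str, str], IsomiRCall] = {}

    def lookup(self, parent: str, sequence: str) -> IsomiRCall:
        return self.calls[(parent, sequence)]

    def names(self) -> list[str]:
        return [c.name for c in self.calls.values()]

    def __len__(self) -> int:
        return len(self.calls)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": c.name,
                "parent": c.parent_mature_id,
                "class": c.class_code or "canonical",
                "offset5": c.offset5,
                "offset3": c.offset3,
                "tail": c.nta_tail,
                "n_subst": c.n_subst,
                "seed_altered": c.seed_altered,
                "sequence": c.sequence,
            }
            for c in self.calls.values()
        ]
        return pd.DataFrame(rows)


def assign_names(calls: Iterable[IsomiRCall], order: str = "abundance") -> IsomiRCatalog:
    """Aggregate calls by (parent, sequence) and assign serials per parent.

    ``order="abundance"`` ranks variants by summed multiplicity descending
    (ties by sequence); ``order="lexicographic"`` by sequence alone. Canonical
    calls keep the parent mature id as their name.
    """
    if order not in ("abundance", "lexicographic"):
        raise ValueError(f"unknown order {order!r}")
    pooled: dict[tuple[str, str], IsomiRCall] = {}
    for c in calls:
        key = (c.parent_mature_id, c.sequence)
        if key in pooled:
            prev = pooled[key]
            pooled[key] = replace(prev, multiplicity=prev.multiplicity + c.multiplicity)
        else:
            pooled[key] = c

    catalog = IsomiRCatalog()
    by_parent: dict[str, list[IsomiRCall]] = defaultdict(list)
    for c in pooled.values():
        if c.canonical:
            catalog.calls[(c.parent_mature_id, c.sequence)] = c
        else:
            by_parent[c.parent_mature_id].append(c)
    for parent in sorted(by_parent):
        variants = by_parent[parent]
        if order == "abundance":
            variants.sort(key=lambda c: (-c.multiplicity, c.sequence))
        else:
            variants.sort(key=lambda c: c.sequence)
        for serial, c in enumerate(variants, start=1):
            name = f"{parent}.{c.class_code}.P{c.n_subst}.S.{serial}"
            catalog.calls[(parent, c.sequence)] = replace(c, name=name)
    return catalog


def parse_name(name: str) -> tuple[str, str, int, int]:
    """Invert the naming grammar: -> (parent, class_code, n_subst, serial)."""
    parts = name.rsplit(".", 4)
    if len(parts) != 5 or parts[3] != "S" or not parts[2].startswith("P"):
        raise ValueError(f"not an isomiR name: {name!r}")
    parent, code, p_field, _, serial = parts
    if code not in CLASS_CODES:
        raise ValueError(f"bad class code in {name!r}")
    return parent, code, int(p_field[1:]), int(serial)


def catalog_summary(
    catalog: IsomiRCatalog, counts: pd.DataFrame | None = None
) -> dict[str, pd.DataFrame]:
    """Per-class and per-substitution-stratum frequency tables.

    ``by_class``/``by_subst`` count distinct non-canonical variants; when a
    name-indexed count matrix is supplied, ``reads_by_class`` gives per-sample
    read fractions over isomiR-assigned reads.
    """
    iso = [c for c in catalog.calls.values() if not c.canonical]
    if not iso:
        empty = pd.DataFrame(columns=["n", "fraction"])
        return {"by_class": empty, "by_subst": empty.copy()}
    frame = pd.DataFrame(
        {"class": [c.class_code for c in iso], "n_subst": [c.n_subst for c in iso],
         "name": [c.name for c in iso]}
    )
    total = len(frame)
    by_class = frame.groupby("class").size().to_frame("n")
    by_class["fraction"] = by_class["n"] / total
    by_subst = frame.groupby("n_subst").size().to_frame("n")
    by_subst["fraction"] = by_subst["n"] / total
    out = {"by_class": by_class, "by_subst": by_subst}
    if counts is not None:
        sub = counts.loc[counts.index.intersection(frame["name"])]
        cls = frame.set_index("name").loc[sub.index, "class"]
        reads = sub.groupby(cls).sum()
        out["reads_by_class"] = reads / reads.sum(axis=0)
    return out
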