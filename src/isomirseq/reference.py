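"""miRBase-style reference model: hairpin precursors plus mature-arm coordinates.

All coordinates are 0-based half-open on the hairpin. Sequences are stored as
DNA (U is normalized to T, case to upper) regardless of the input alphabet,
because miRBase ships RNA while sequencers emit DNA.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID = re.compile(r"^[ACGTN]+$")

MIN_MATURE_LEN = 15
MAX_MATURE_LEN = 30

#: seed = mature nucleotides 2-8 (0-based slice [1:8]); the 5' determinant of
#: target specificity, so any 5'-end shift alters it.
SEED_SLICE = slice(1, 8)


class ReferenceError(ValueError):
    """Reference integrity or validation failure."""


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert RNA (U) to DNA (T); reject foreign characters."""
    s = seq.upper().replace("U", "T")
    if not s or not _VALID.match(s):
        raise ReferenceError(f"invalid sequence characters in {seq[:30]!r}")
    return s


@dataclass(frozen=True)
class HairpinRecord:
    hairpin_id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_sequence(self.sequence))

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureAnnotation:
    """A mature miRNA arm located on its precursor hairpin."""

    mature_id: str
    hairpin_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    arm: str = "unassigned"  # {5p, 3p, unassigned}

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p", "unassigned"):
            raise ReferenceError(f"{self.mature_id}: bad arm {self.arm!r}")
        if not (0 <= self.start < self.end):
            raise ReferenceError(f"{self.mature_id}: bad interval [{self.start},{self.end})")
        if not (MIN_MATURE_LEN <= self.end - self.start <= MAX_MATURE_LEN):
            raise ReferenceError(
                f"{self.mature_id}: mature length {self.end - self.start} outside "
                f"[{MIN_MATURE_LEN},{MAX_MATURE_LEN}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReferenceSet:
    """Validated hairpins + matures with an id index used by every stage."""

    hairpins: dict[str, HairpinRecord] = field(default_factory=dict)
    matures: list[MatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, MatureAnnotation] = {}
        for m in self.matures:
            self._register(m)

    def _register(self, m: MatureAnnotation) -> None:
        if m.mature_id in self._index:
            raise ReferenceError(f"duplicate mature_id {m.mature_id}")
        hp = self.hairpins.get(m.hairpin_id)
        if hp is None:
            raise ReferenceError(f"{m.mature_id}: unknown hairpin {m.hairpin_id}")
        if m.end > hp.length:
            raise ReferenceError(
                f"{m.mature_id}: end {m.end} beyond hairpin length {hp.length}"
            )
        self._index[m.mature_id] = m

    def add(self, hairpin: HairpinRecord, matures: Iterable[MatureAnnotation] = ()) -> None:
        if hairpin.hairpin_id in self.hairpins:
            raise ReferenceError(f"duplicate hairpin_id {hairpin.hairpin_id}")
        self.hairpins[hairpin.hairpin_id] = hairpin
        for m in matures:
            self.matures.append(m)
            self._register(m)

    def mature(self, mature_id: str) -> MatureAnnotation:
        try:
            return self._index[mature_id]
        except KeyError:
            raise ReferenceError(f"unknown mature_id {mature_id}") from None

    def mature_ids(self) -> list[str]:
        return [m.mature_id for m in self.matures]

    def mature_sequence(self, mature_id: str) -> str:
        m = self.mature(mature_id)
        return self.hairpins[m.hairpin_id].sequence[m.start : m.end]

    def seed_sequence(self, mature_id: str) -> str:
        return self.mature_sequence(mature_id)[SEED_SLICE]

    def __len__(self) -> int:
        return len(self.matures)


MATURE_COLUMNS = ["mature_id", "hairpin_id", "start", "end", "arm"]


def load_reference(hairpin_fasta: str | Path, mature_table: str | Path) -> ReferenceSet:
    """Load hairpin FASTA + mature coordinate TSV into a validated ReferenceSet.

    The TSV must carry a header with columns mature_id, hairpin_id, start, end,
    arm; coordinates 0-based half-open on the hairpin.
    """
    ref = ReferenceSet()
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        ref.add(HairpinRecord(rec.id, str(rec.seq)))
    table = pd.read_csv(mature_table, sep="\t", dtype={"mature_id": str, "hairpin_id": str})
    missing = set(MATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ReferenceError(f"mature table missing columns: {sorted(missing)}")
    for row in table.itertuples(index=False):
        m = MatureAnnotation(row.mature_id, row.hairpin_id, int(row.start), int(row.end), str(row.arm))
        ref.matures.append(m)
        ref._register(m)
    return ref


def write_reference(ref: ReferenceSet, hairpin_fasta: str | Path, mature_table: str | Path) -> None:
    """Inverse of :func:`load_reference`; round-trips bit-exactly."""
    records = [
        SeqRecord(Seq(hp.sequence), id=hp.hairpin_id, description="")
        for hp in ref.hairpins.values()
    ]
    SeqIO.write(records, str(hairpin_fasta), "fasta")
    rows = [
        (m.mature_id, m.hairpin_id, m.start, m.end, m.arm) for m in ref.matures
    ]
    pd.DataFrame(rows, columns=MATURE_COLUMNS).to_csv(mature_table, sep="\t", index=False)


def load_reference_gff3(hairpin_fasta: str | Path, gff3: str | Path) -> ReferenceSet:
    """Convenience reader for the miRBase GFF3 dialect.

    Expects miRNA_primary_transcript rows (genomic span of each hairpin, with
    an ID attribute matching the FASTA) and miRNA rows carrying ID and
    Derives_from attributes. Mature coordinates are converted from 1-based
    genomic to 0-based half-open hairpin-relative positions; minus-strand
    hairpins are handled by reflecting coordinates.
    """
    ref = ReferenceSet()
    for rec in SeqIO.parse(str(hairpin_fasta), "fasta"):
        ref.add(HairpinRecord(rec.id, str(rec.seq)))

    primaries: dict[str, tuple[int, int, str]] = {}
    matures: list[tuple[str, str, int, int]] = []
    with open(gff3) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            ftype, start, end, strand, attrs = parts[2], int(parts[3]), int(parts[4]), parts[6], parts[8]
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            name = attr.get("Name") or attr.get("ID", "")
            if ftype == "miRNA_primary_transcript":
                primaries[attr.get("ID", name)] = (start, end, strand)
                if name and name != attr.get("ID"):
                    primaries[name] = (start, end, strand)
            elif ftype == "miRNA":
                matures.append((name, attr.get("Derives_from", ""), start, end))

    for mature_id, parent, gstart, gend in matures:
        if parent not in primaries:
            raise ReferenceError(f"{mature_id}: Derives_from {parent!r} not in GFF3")
        pstart, pend, strand = primaries[parent]
        # resolve parent id to the FASTA hairpin id
        hp_id = parent if parent in ref.hairpins else None
        if hp_id is None:
            for key, span in primaries.items():
                if span == (pstart, pend, strand) and key in ref.hairpins:
                    hp_id = key
                    break
        if hp_id is None:
            raise ReferenceError(f"{mature_id}: hairpin for {parent!r} absent from FASTA")
        if strand == "-":
            start, end = pend - gend, pend - gstart + 1
        else:
            start, end = gstart - pstart, gend - pstart + 1
        m = MatureAnnotation(mature_id, hp_id, start, end,
                             "5p" if mature_id.endswith("5p") else "3p" if mature_id.endswith("3p") else "unassigned")
        ref.matures.append(m)
        ref._register(m)
    return ref


def mature_sequence(ref: ReferenceSet, mature_id: str) -> str:
    """Hairpin slice [start, end) for the given mature id."""
    return ref.mature_sequence(mature_id)
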