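"""Offset-aware placement of short reads on precursor hairpins.

Each read is decomposed, against every annotated mature arm, into a templated
body (a hairpin substring starting at mature_start + offset5) plus an optional
non-templated 3' tail, with up to ``max_mismatch`` internal substitutions and
no indels inside the body. Among all admissible decompositions the one with
minimal ``score_key = (n_subst, tail_len, |offset5| + |offset3|)`` wins;
because tail length is compared before end offsets, a 3' base that the hairpin
can still template is always absorbed into the body rather than the tail, which
makes the decomposition of error-free reads unique.

Remaining ties are broken deterministically by (|offset5|, mature_id, offset5,
offset3), so reruns on identical input are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .preprocess import CleanReadBatch
from .reference import ReferenceSet


@dataclass(frozen=True)
class AlignParams:
    max_shift5: int = 4  # |offset5| bound (nt)
    max_shift3: int = 5  # |offset3| bound on the templated 3' end (nt)
    max_tail: int = 3  # longest non-templated 3' tail
    max_mismatch: int = 2  # substitutions inside the templated body
    multi: str = "best"  # "best" or "fractional" handling of score ties


@dataclass
class HairpinAlignment:
    """One read placed on one hairpin.

    offset5 = read_start - mature_start (negative: 5' extension);
    offset3 = templated_read_end - mature_end (positive: templated 3'
    extension). ``substitutions`` holds (mature-relative position, ref base,
    read base). Reverting the substitutions and dropping ``nta_tail``
    reconstructs hairpin[mature_start+offset5 : mature_end+offset3].
    """

    read: str
    multiplicity: float
    mature_id: str
    hairpin_id: str
    offset5: int
    offset3: int
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    nta_tail: str = ""

    @property
    def n_subst(self) -> int:
        return len(self.substitutions)

    @property
    def score_key(self) -> tuple[int, int, int]:
        return (self.n_subst, len(self.nta_tail), abs(self.offset5) + abs(self.offset3))

    @property
    def tiebreak_key(self) -> tuple:
        return self.score_key + (abs(self.offset5), self.mature_id, self.offset5, self.offset3)

    def reconstruct_template(self) -> str:
        """The hairpin slice implied by the alignment (reconstruction invariant)."""
        body = list(self.read[: len(self.read) - len(self.nta_tail)])
        for pos, ref_base, _read_base in self.substitutions:
            body[pos - self.offset5] = ref_base
        return "".join(body)


def enumerate_placements(
    read: str, ref: ReferenceSet, params: AlignParams = AlignParams()
) -> list[HairpinAlignment]:
    """All admissible decompositions of ``read`` over every mature arm."""
    out: list[HairpinAlignment] = []
    L = len(read)
    for m in ref.matures:
        hp = ref.hairpins[m.hairpin_id].sequence
        for offset5 in range(-params.max_shift5, params.max_shift5 + 1):
            start = m.start + offset5
            if start < 0 or start >= len(hp):
                continue
            lo = max(1, L - params.max_tail, m.end - start - params.max_shift3)
            hi = min(L, len(hp) - start, m.end - start + params.max_shift3)
            if lo > hi:
                continue
            # cumulative mismatch positions over the longest body considered
            mism: list[int] = []
            scanned = hi
            for i in range(hi):
                if read[i] != hp[start + i]:
                    mism.append(i)
                    if len(mism) > params.max_mismatch:
                        scanned = i  # bodies of length > i are inadmissible
                        break
            for body_len in range(lo, hi + 1):
                if body_len > scanned and len(mism) > params.max_mismatch:
                    break
                subs_here = [p for p in mism if p < body_len]
                if len(subs_here) > params.max_mismatch:
                    break
                out.append(
                    HairpinAlignment(
                        read=read,
                        multiplicity=0,
                        mature_id=m.mature_id,
                        hairpin_id=m.hairpin_id,
                        offset5=offset5,
                        offset3=start + body_len - m.end,
                        substitutions=[
                            (p + offset5, hp[start + p], read[p]) for p in subs_here
                        ],
                        nta_tail=read[body_len:],
                    )
                )
    return out


def best_placements(
    read: str, ref: ReferenceSet, params: AlignParams = AlignParams()
) -> list[HairpinAlignment]:
    """Placements tied for minimal score_key, ordered by the full tie-break."""
    cands = enumerate_placements(read, ref, params)
    if not cands:
        return []
    cands.sort(key=lambda a: a.tiebreak_key)
    best = cands[0].score_key
    return [c for c in cands if c.score_key == best]


def align_read(
    read: str, ref: ReferenceSet, params: AlignParams = AlignParams()
) -> HairpinAlignment | None:
    """Single best placement under the deterministic tie-break, or None."""
    tied = best_placements(read, ref, params)
    return tied[0] if tied else None


def align_to_hairpins(
    batch: CleanReadBatch, ref: ReferenceSet, params: AlignParams = AlignParams()
) -> tuple[list[HairpinAlignment], int]:
    """Align every collapsed read; returns (alignments, unaligned multiplicity).

    With ``params.multi == "fractional"`` the multiplicity of a read whose best
    score is shared by several placements is split equally among them; the
    default keeps only the deterministic best hit.
    """
    alignments: list[HairpinAlignment] = []
    unaligned = 0
    for seq, mult in batch.reads.items():
        tied = best_placements(seq, ref, params)
        if not tied:
            unaligned += mult
            continue
        if params.multi == "fractional" and len(tied) > 1:
            share = mult / len(tied)
            for t in tied:
                t.multiplicity = share
                alignments.append(t)
        else:
            tied[0].multiplicity = mult
            alignments.append(tied[0])
    return alignments, unaligned


def alignments_to_rows(alignments: Iterable[HairpinAlignment]) -> list[dict]:
    """Flat dict rows for TSV export."""
    return [
        {
            "read": a.read,
            "multiplicity": a.multiplicity,
            "mature_id": a.mature_id,
            "hairpin_id": a.hairpin_id,
            "offset5": a.offset5,
            "offset3": a.offset3,
            "n_subst": a.n_subst,
            "substitutions": ";".join(f"{p}:{r}>{b}" for p, r, b in a.substitutions),
            "nta_tail": a.nta_tail,
        }
        for a in alignments
    ]
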